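"""Deterministic fixed-grid integration of the contagion vector field.

:func:`integrate` is the production path: classical 4th-order Runge-Kutta
on a uniform grid, bit-reproducible for identical inputs.  The system is
non-stiff at the published parameter magnitudes, so a fixed step of 0.01
resolves it comfortably.  :func:`integrate_reference` is a deliberately
independent forward-Euler implementation kept as an internal oracle for
cross-method agreement tests; it shares nothing with the RK4 path except
the vector field itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import (
    NEG_TOL,
    SUM_TOL,
    ModelParameters,
    PopulationState,
    validate_parameters,
    _rhs,
)

__all__ = ["Trajectory", "IntegrationError", "integrate", "integrate_reference"]

Variant = Literal["full", "reduced"]

DEFAULT_DT = 0.01
DEFAULT_T_END = 200.0


class IntegrationError(RuntimeError):
    """A state invariant was violated during integration."""


@dataclass(frozen=True)
class Trajectory:
    """A time grid plus the state sequence of one integration.

    ``states`` has shape ``(len(times), 4)`` with columns S, O, P, U.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    meta: dict = field(default_factory=dict)

    _COLUMNS = ("S", "O", "P", "U")

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.times), 4):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.times)} time points"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def variant(self) -> str:
        return self.meta.get("variant", "full")

    def compartment(self, name: str) -> np.ndarray:
        """Time series of one compartment ('S', 'O', 'P' or 'U')."""
        try:
            return self.states[:, self._COLUMNS.index(name)]
        except ValueError:
            raise KeyError(
                f"unknown compartment {name!r}; expected one of "
                f"{self._COLUMNS}"
            ) from None

    def state_at(self, i: int) -> PopulationState:
        S, O, P, U = self.states[i]
        return PopulationState(S=S, O=O, P=P, U=U, t=float(self.times[i]))

    @property
    def final_state(self) -> PopulationState:
        return self.state_at(len(self) - 1)

    def to_frame(self):
        """Tidy table with columns t, S, O, P, U."""
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, **{c: self.compartment(c) for c in self._COLUMNS}}
        )


def _effective_params(params: ModelParameters, variant: str) -> ModelParameters:
    if variant == "full":
        return params
    if variant == "reduced":
        return params.without_cure()
    raise ValueError(f"unknown variant {variant!r}; expected 'full' or 'reduced'")


def _check_row(y: tuple, t: float, total0: float) -> None:
    if min(y) < -NEG_TOL:
        raise IntegrationError(
            f"compartment went negative at t={t:.6g}: {y}"
        )
    if abs(sum(y) - total0) > SUM_TOL:
        raise IntegrationError(
            f"population total drifted to {sum(y)!r} at t={t:.6g}"
        )


def integrate(
    params: ModelParameters,
    initial: PopulationState,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
    variant: Variant = "full",
) -> Trajectory:
    """Integrate the model with classical RK4 on a uniform grid.

    Parameters
    ----------
    params
        Validated rate constants and coefficients.
    initial
        Starting compartment fractions (summing to 1).
    t_end, dt
        Horizon and fixed step, in dimensionless model time.
    variant
        ``"full"`` for the four-compartment model, ``"reduced"`` for the
        SOSPa-SPSOa reduction (cure rates zeroed; U inert).

    Raises
    ------
    IntegrationError
        If a compartment drops below the nonnegativity slack or the
        population total drifts, reporting the offending time.
    """
    validate_parameters(params)
    initial.validate()
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end!r}")
    if not 0 < dt <= t_end:
        raise ValueError(f"dt must satisfy 0 < dt <= t_end, got {dt!r}")
    p = _effective_params(params, variant)

    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 4))
    y = initial.as_tuple()
    states[0] = y
    total0 = sum(y)
    half = dt / 2.0
    sixth = dt / 6.0
    for i in range(n):
        S, O, P, U = y
        a1, b1, c1, d1 = _rhs(S, O, P, U, p)
        a2, b2, c2, d2 = _rhs(S + half * a1, O + half * b1,
                              P + half * c1, U + half * d1, p)
        a3, b3, c3, d3 = _rhs(S + half * a2, O + half * b2,
                              P + half * c2, U + half * d2, p)
        a4, b4, c4, d4 = _rhs(S + dt * a3, O + dt * b3,
                              P + dt * c3, U + dt * d3, p)
        y = (
            S + sixth * (a1 + 2.0 * (a2 + a3) + a4),
            O + sixth * (b1 + 2.0 * (b2 + b3) + b4),
            P + sixth * (c1 + 2.0 * (c2 + c3) + c4),
            U + sixth * (d1 + 2.0 * (d2 + d3) + d4),
        )
        _check_row(y, times[i + 1], total0)
        states[i + 1] = y

    return Trajectory(
        times=times,
        states=states,
        params=params,
        meta={"method": "rk4", "dt": dt, "t_end": t_end, "variant": variant},
    )


def integrate_reference(
    params: ModelParameters,
    initial: PopulationState,
    t_end: float = 100.0,
    dt: float = 1e-4,
    variant: Variant = "full",
) -> Trajectory:
    """Forward-Euler reference integration (internal oracle).

    First-order only — intended for cross-checking :func:`integrate` at a
    much smaller step, not for production runs.
    """
    validate_parameters(params)
    initial.validate()
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end!r}")
    if not 0 < dt <= t_end:
        raise ValueError(f"dt must satisfy 0 < dt <= t_end, got {dt!r}")
    p = _effective_params(params, variant)

    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 4))
    S, O, P, U = initial.as_tuple()
    states[0] = (S, O, P, U)
    total0 = S + O + P + U
    for i in range(n):
        dS, dO, dP, dU = _rhs(S, O, P, U, p)
        S += dt * dS
        O += dt * dO
        P += dt * dP
        U += dt * dU
        states[i + 1] = (S, O, P, U)
    _check_row((S, O, P, U), times[-1], total0)

    return Trajectory(
        times=times,
        states=states,
        params=params,
        meta={"method": "euler", "dt": dt, "t_end": t_end, "variant": variant},
    )
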