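"""Core state types and vector field of the U-SOSPa-SPSOa contagion model.

The model partitions a crowd caught in a public-health emergency into four
emotional compartments, each a fraction of a population normalised to 1:

* ``S`` — emotionally susceptible (undecided) individuals,
* ``O`` — optimists (positive emotion carriers),
* ``P`` — pessimists (negative/panic emotion carriers),
* ``U`` — emotionally stable personnel (trained responders); absorbing.

Transitions are spontaneous (``alpha``), contact-driven (``beta``),
recoveries (``r``), cross-conversions between O and P (``m``, ``l``) and
contact-mediated "cure" into the stable compartment (``theta``).  Contact
with optimists or stable individuals is linear in the partner fraction,
``g1(x) = k*x``; contact with pessimists saturates with the emergency's
risk coefficient ``a``, ``g2(P) = k*P / (1 + a*P**2)`` — under high risk
people shun panic carriers, damping pessimist contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator

__all__ = [
    "ModelParameters",
    "PopulationState",
    "DerivativeVector",
    "ParameterPreset",
    "ParameterError",
    "StateError",
    "UnknownPresetError",
    "contact_linear",
    "contact_nonlinear",
    "derivatives",
    "derivatives_reduced",
    "validate_parameters",
    "preset",
    "PRESET_NAMES",
]

#: absolute slack allowed on compartment nonnegativity (floating-point drift)
NEG_TOL = 1e-9
#: absolute slack allowed on the S+O+P+U = 1 conservation law
SUM_TOL = 1e-8


class ParameterError(ValueError):
    """A rate constant or coefficient violates its admissible range."""


class StateError(ValueError):
    """A population state violates nonnegativity or conservation."""


class UnknownPresetError(KeyError):
    """Requested preset name is not registered."""


# rate constants bounded to [0, 1]; k and a have their own rules
_RATE_FIELDS = (
    "alpha_o", "alpha_p", "beta_o", "beta_p",
    "r_o", "r_p", "l_o", "l_p", "m_o", "m_p",
    "theta_s", "theta_o", "theta_p",
)


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the model plus the contact/risk coefficients.

    Defaults are the published baseline rates; ``k`` (contact coefficient)
    and ``a`` (risk coefficient) are not published and default to the
    package's neutral calibration ``k=1, a=1``.
    """

    alpha_o: float = 0.18   #: spontaneous S -> O
    alpha_p: float = 0.04   #: spontaneous S -> P
    beta_o: float = 0.02    #: contact S -> O
    beta_p: float = 0.04    #: contact S -> P
    r_o: float = 0.088      #: recovery O -> S
    r_p: float = 0.13       #: recovery P -> S
    l_o: float = 0.13       #: O -> S after O-P contact
    l_p: float = 0.07       #: P -> S after P-O contact
    m_o: float = 0.09       #: O -> P conversion on contact
    m_p: float = 0.009      #: P -> O conversion on contact
    theta_s: float = 0.02   #: cure S -> U on contact with U
    theta_o: float = 0.01   #: cure O -> U on contact with U
    theta_p: float = 0.005  #: cure P -> U on contact with U
    k: float = 1.0          #: contact coefficient (> 0)
    a: float = 1.0          #: risk coefficient (>= 0)

    def validate(self) -> "ModelParameters":
        return validate_parameters(self)

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden (validated)."""
        return validate_parameters(replace(self, **overrides))

    def without_cure(self) -> "ModelParameters":
        """The SOSPa-SPSOa reduction: all cure rates zeroed."""
        return replace(self, theta_s=0.0, theta_o=0.0, theta_p=0.0)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {unknown}")
        return validate_parameters(cls(**data))


def validate_parameters(params: ModelParameters) -> ModelParameters:
    """Return ``params`` unchanged, or raise listing *every* violation."""
    problems = []
    for name in _RATE_FIELDS:
        v = getattr(params, name)
        if not math.isfinite(v) or not 0.0 <= v <= 1.0:
            problems.append(f"{name}={v!r} outside [0, 1]")
    if not math.isfinite(params.k) or params.k <= 0.0:
        problems.append(f"k={params.k!r} must be > 0")
    if not math.isfinite(params.a) or params.a < 0.0:
        problems.append(f"a={params.a!r} must be >= 0")
    if problems:
        raise ParameterError("; ".join(problems))
    return params


@dataclass(frozen=True)
class PopulationState:
    """Compartment fractions ``(S, O, P, U)`` at one time point.

    Fractions must be nonnegative (to floating-point slack) and sum to the
    normalised population total of 1.
    """

    S: float
    O: float
    P: float
    U: float = 0.0
    t: float = 0.0

    def validate(self) -> "PopulationState":
        bad = [n for n in "SOPU" if getattr(self, n) < -NEG_TOL]
        if bad:
            raise StateError(
                f"negative compartment(s) {bad} at t={self.t}: "
                + ", ".join(f"{n}={getattr(self, n)!r}" for n in bad)
            )
        total = self.S + self.O + self.P + self.U
        if abs(total - 1.0) > SUM_TOL:
            raise StateError(f"S+O+P+U={total!r} differs from 1 at t={self.t}")
        return self

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.S, self.O, self.P, self.U)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())

    def to_dict(self) -> dict[str, float]:
        return {"S": self.S, "O": self.O, "P": self.P, "U": self.U, "t": self.t}


@dataclass(frozen=True)
class DerivativeVector:
    """Per-compartment rates of change; components sum to zero."""

    dS: float
    dO: float
    dP: float
    dU: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.dS, self.dO, self.dP, self.dU)

    def sup_norm(self) -> float:
        return max(abs(self.dS), abs(self.dO), abs(self.dP), abs(self.dU))


def contact_linear(x: float, k: float) -> float:
    """Linear contact factor ``g1(x) = k*x`` for optimist/stable contact.

    The caller multiplies by the partner compartment's fraction.
    """
    if x < 0.0:
        raise ParameterError(f"contact fraction must be >= 0, got {x!r}")
    if k <= 0.0:
        raise ParameterError(f"contact coefficient k must be > 0, got {k!r}")
    return k * x


def contact_nonlinear(p: float, k: float, a: float) -> float:
    """Saturating contact factor ``g2(P) = k*P / (1 + a*P**2)``.

    Reduces to the linear form at ``a = 0`` (no-hazard regime); for
    ``a > 0`` contact with pessimists is strictly damped below ``k*p``.
    """
    if p < 0.0:
        raise ParameterError(f"contact fraction must be >= 0, got {p!r}")
    if k <= 0.0:
        raise ParameterError(f"contact coefficient k must be > 0, got {k!r}")
    if a < 0.0:
        raise ParameterError(f"risk coefficient a must be >= 0, got {a!r}")
    return k * p / (1.0 + a * p * p)


def _rhs(S: float, O: float, P: float, U: float, p: ModelParameters
         ) -> tuple[float, float, float, float]:
    """Raw vector field on floats; assembled from one-directional flows so
    that the four components cancel pairwise (conservation by construction).

    Hot path for the fixed-step integrators — no validation here.
    """
    g1O = p.k * O
    g1U = p.k * U
    g2P = p.k * P / (1.0 + p.a * P * P)

    # flows out of S
    f_ao = p.alpha_o * S            # S -> O spontaneous
    f_ap = p.alpha_p * S            # S -> P spontaneous
    f_bo = p.beta_o * g1O * S       # S -> O on optimist contact
    f_bp = p.beta_p * g2P * S       # S -> P on pessimist contact
    # flows into S
    f_ro = p.r_o * O                # O -> S recovery
    f_rp = p.r_p * P                # P -> S recovery
    f_lo = p.l_o * g1O * P          # O -> S after O-P contact
    f_lp = p.l_p * g2P * O          # P -> S after P-O contact
    # O <-> P conversions
    f_mo = p.m_o * g1O * P          # O -> P
    f_mp = p.m_p * g2P * O          # P -> O
    # cures into the absorbing stable compartment
    f_ts = p.theta_s * g1U * S
    f_to = p.theta_o * g1U * O
    f_tp = p.theta_p * g1U * P

    dS = f_ro + f_rp + f_lo + f_lp - f_ao - f_ap - f_bo - f_bp - f_ts
    dO = f_ao + f_bo + f_mp - f_ro - f_lo - f_mo - f_to
    dP = f_ap + f_bp + f_mo - f_rp - f_lp - f_mp - f_tp
    dU = f_ts + f_to + f_tp
    return dS, dO, dP, dU


def derivatives(state: PopulationState, params: ModelParameters
                ) -> DerivativeVector:
    """Evaluate the full four-compartment vector field at ``state``."""
    state.validate()
    validate_parameters(params)
    return DerivativeVector(*_rhs(state.S, state.O, state.P, state.U, params))


def derivatives_reduced(state: PopulationState, params: ModelParameters
                        ) -> DerivativeVector:
    """Vector field of the SOSPa-SPSOa reduction (no stable compartment).

    Identical to :func:`derivatives` with all cure rates zeroed; with
    ``U(0) = 0`` the stable compartment then stays empty for all time.
    """
    state.validate()
    validate_parameters(params)
    return DerivativeVector(
        *_rhs(state.S, state.O, state.P, state.U, params.without_cure())
    )


@dataclass(frozen=True)
class ParameterPreset:
    name: str
    params: ModelParameters
    initial: PopulationState
    description: str = ""


_PRESETS: dict[str, ParameterPreset] = {
    "baseline_sec3": ParameterPreset(
        name="baseline_sec3",
        params=ModelParameters(),
        initial=PopulationState(S=0.7, O=0.1, P=0.15, U=0.05),
        description=(
            "Published baseline: emergency onset with 15% pessimists, "
            "5% trained stable personnel."
        ),
    ),
    "uniform_sec4": ParameterPreset(
        name="uniform_sec4",
        params=ModelParameters(),
        initial=PopulationState(S=0.33, O=0.33, P=0.33, U=0.01),
        description=(
            "Sensitivity-analysis initials: emotional compartments "
            "equalised at 0.33, 1% stable personnel."
        ),
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> ParameterPreset:
    """Look up a registered parameter/initial-condition bundle by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
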