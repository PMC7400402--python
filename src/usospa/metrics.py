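"""Summary quantities extracted from trajectories.

These are the figure-level observables the model is analysed with: the
pessimist peak, the time at which the dynamics settle, the qualitative
shape of a compartment's curve, and the final population composition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .integrate import Trajectory
from .model import ModelParameters, PopulationState

__all__ = [
    "ShapeLabel",
    "TrajectoryShape",
    "peak",
    "equilibrium_time",
    "classify_shape",
    "final_composition",
    "derivative_sup_norm",
    "metrics_record",
]

DEFAULT_EQ_TOL = 1e-3
DEFAULT_SHAPE_DELTA = 1e-3


def _field_arrays(states: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Vectorised evaluation of the vector field along a state sequence."""
    S, O, P, U = states.T
    g1O = p.k * O
    g1U = p.k * U
    g2P = p.k * P / (1.0 + p.a * P * P)
    dS = (p.r_o * O + p.r_p * P - (p.alpha_o + p.alpha_p) * S
          + g1O * (p.l_o * P - p.beta_o * S)
          + g2P * (p.l_p * O - p.beta_p * S)
          - p.theta_s * g1U * S)
    dO = (p.alpha_o * S - p.r_o * O - (p.m_o + p.l_o) * g1O * P
          + p.beta_o * g1O * S + p.m_p * g2P * O - p.theta_o * g1U * O)
    dP = (p.alpha_p * S - p.r_p * P - (p.m_p + p.l_p) * g2P * O
          + p.beta_p * g2P * S + p.m_o * g1O * P - p.theta_p * g1U * P)
    dU = g1U * (p.theta_s * S + p.theta_o * O + p.theta_p * P)
    return np.stack([dS, dO, dP, dU], axis=1)


def _effective_params(traj: Trajectory) -> ModelParameters:
    return traj.params.without_cure() if traj.variant == "reduced" else traj.params


def derivative_sup_norm(traj: Trajectory, compartment: str | None = None
                        ) -> np.ndarray:
    """|dX/dt| along the grid: sup over compartments, or one compartment."""
    d = _field_arrays(traj.states, _effective_params(traj))
    if compartment is None:
        return np.abs(d).max(axis=1)
    idx = Trajectory._COLUMNS.index(compartment)
    return np.abs(d[:, idx])


def peak(traj: Trajectory, compartment: str) -> tuple[float, float]:
    """Global maximum of a compartment over the grid.

    Ties break to the earliest time, so a constant or strictly decreasing
    series peaks at the initial point.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    x = traj.compartment(compartment)
    i = int(np.argmax(x))  # argmax returns the first maximal index
    return float(traj.times[i]), float(x[i])


def equilibrium_time(
    traj: Trajectory,
    tol: float = DEFAULT_EQ_TOL,
    compartment: str | None = None,
) -> float | None:
    """Smallest grid time after which the dynamics stay below ``tol``.

    The rate of change is measured as the sup-norm of the derivative
    vector across all four compartments (pass ``compartment='S'`` for the
    single-compartment reading).  Returns ``None`` when the trajectory
    never settles within its horizon.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol!r}")
    sup = derivative_sup_norm(traj, compartment)
    quiet = sup < tol
    if not quiet[-1]:
        return None
    # first index of the trailing all-quiet run
    noisy = np.nonzero(~quiet)[0]
    i = 0 if len(noisy) == 0 else int(noisy[-1]) + 1
    return float(traj.times[i])


class ShapeLabel(str, enum.Enum):
    INCREASE_THEN_DECREASE = "increase_then_decrease"
    MONOTONE_DECREASE = "monotone_decrease"
    MONOTONE_INCREASE = "monotone_increase"
    OTHER = "other"


@dataclass(frozen=True)
class TrajectoryShape:
    """Qualitative curve shape with its rise above the initial value."""

    label: ShapeLabel
    rise_amount: float


def classify_shape(
    traj: Trajectory,
    compartment: str,
    delta: float = DEFAULT_SHAPE_DELTA,
) -> TrajectoryShape:
    """Label a compartment's curve at tolerance ``delta``.

    ``increase_then_decrease`` requires a rise above the start by more
    than ``delta``, an interior global maximum, and a final value more
    than ``delta`` below that maximum — the "panic flares then subsides"
    signature.  Monotone labels tolerate wiggles smaller than ``delta``.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta!r}")
    x = traj.compartment(compartment)
    rise = float(x.max() - x[0])
    i_max = int(np.argmax(x))
    fall_from_max = float(x.max() - x[-1])
    if rise > delta and i_max < len(x) - 1 and fall_from_max > delta:
        label = ShapeLabel.INCREASE_THEN_DECREASE
    elif float(x[0] - x[-1]) > delta and rise <= delta:
        label = ShapeLabel.MONOTONE_DECREASE
    elif float(x[-1] - x[0]) > delta and fall_from_max <= delta:
        label = ShapeLabel.MONOTONE_INCREASE
    else:
        label = ShapeLabel.OTHER
    return TrajectoryShape(label=label, rise_amount=rise)


def final_composition(traj: Trajectory) -> PopulationState:
    """The last grid state — the settled composition of the crowd."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return traj.final_state


def metrics_record(
    traj: Trajectory,
    compartment: str = "P",
    tol: float = DEFAULT_EQ_TOL,
    delta: float = DEFAULT_SHAPE_DELTA,
    **extra,
) -> dict:
    """One flat summary row for a trajectory, ready for tabular export."""
    t_pk, v_pk = peak(traj, compartment)
    shape = classify_shape(traj, compartment, delta)
    final = final_composition(traj)
    row = {
        "variant": traj.variant,
        "compartment": compartment,
        "peak_t": t_pk,
        "peak_value": v_pk,
        "equilibrium_time": equilibrium_time(traj, tol),
        "shape": shape.label.value,
        "rise_amount": shape.rise_amount,
        "final_S": final.S,
        "final_O": final.O,
        "final_P": final.P,
        "final_U": final.U,
    }
    row.update(extra)
    return row
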