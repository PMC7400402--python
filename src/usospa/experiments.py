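"""Sensitivity experiments: parameter sweeps, critical thresholds, and the
with/without-stable-group model comparison.

The experiment layer never touches the integrator internals; every
operation builds parameter/initial bundles, calls :func:`usospa.integrate`
and summarises the trajectories with :mod:`usospa.metrics`.  All outputs
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

from .integrate import DEFAULT_DT, DEFAULT_T_END, Trajectory, integrate
from .metrics import (
    DEFAULT_EQ_TOL,
    DEFAULT_SHAPE_DELTA,
    ShapeLabel,
    classify_shape,
    equilibrium_time,
    metrics_record,
    peak,
)
from .model import (
    ModelParameters,
    ParameterPreset,
    PopulationState,
    StateError,
    preset,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "ThresholdEstimate",
    "ComparisonResult",
    "NoThresholdError",
    "RuleInapplicableError",
    "run_sweep",
    "critical_initial_p",
    "risk_saturation_point",
    "compare_with_without_u",
    "reproduce_figure",
    "figure_ids",
]

_PARAM_FIELDS = {f.name for f in fields(ModelParameters)}
_INITIAL_KEYS = {"initial_P", "initial_O", "initial_U"}


class NoThresholdError(RuntimeError):
    """The scanned interval contains no shape transition."""


class RuleInapplicableError(RuntimeError):
    """The detection rule's premise fails on the computed response."""


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sensitivity experiment design.

    ``quantity`` is either a :class:`ModelParameters` field name (including
    ``k`` and ``a``) or one of ``initial_P``/``initial_O``/``initial_U``.
    Initial-condition sweeps rebalance S so the population total stays 1.
    """

    preset: str
    quantity: str
    grid: tuple[float, ...]
    variant: str = "full"
    compartment: str = "P"
    dt: float = DEFAULT_DT
    t_end: float = DEFAULT_T_END
    eq_tol: float = DEFAULT_EQ_TOL
    shape_delta: float = DEFAULT_SHAPE_DELTA

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(v) for v in self.grid))
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError(f"sweep grid must be strictly increasing: {self.grid}")
        if self.quantity not in _PARAM_FIELDS | _INITIAL_KEYS:
            raise ValueError(
                f"unknown sweep quantity {self.quantity!r}; expected a model "
                f"parameter or one of {sorted(_INITIAL_KEYS)}"
            )


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-value metric records (ordered as the grid) and trajectories."""

    spec: SweepSpec
    records: tuple[dict, ...]
    trajectories: tuple[Trajectory, ...]

    def values(self, key: str) -> list:
        return [r[key] for r in self.records]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(list(self.records))


@dataclass(frozen=True)
class ThresholdEstimate:
    """A detected critical value with its bracket and detection rule."""

    quantity: str
    estimate: float
    bracket: tuple[float, float]
    rule: str

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not lo <= self.estimate <= hi:
            raise ValueError(
                f"estimate {self.estimate} outside bracket {self.bracket}"
            )

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "estimate": self.estimate,
            "bracket": list(self.bracket),
            "rule": self.rule,
        }


def _rebalanced_initial(base: PopulationState, key: str, value: float
                        ) -> PopulationState:
    """Set one initial compartment, absorbing the change into S."""
    comps = {"S": base.S, "O": base.O, "P": base.P, "U": base.U}
    comps[key.removeprefix("initial_")] = value
    comps["S"] = 1.0 - sum(v for c, v in comps.items() if c != "S")
    if comps["S"] < 0.0:
        raise StateError(
            f"{key}={value} leaves S={comps['S']:.6g} < 0 after rebalancing"
        )
    return PopulationState(**comps, t=base.t)


def _bundle_for(spec_preset: ParameterPreset, quantity: str, value: float
                ) -> tuple[ModelParameters, PopulationState]:
    if quantity in _PARAM_FIELDS:
        return spec_preset.params.replace(**{quantity: value}), spec_preset.initial
    return spec_preset.params, _rebalanced_initial(
        spec_preset.initial, quantity, value
    )


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Integrate the model once per grid value and summarise each run.

    Infeasible initial-condition values (S rebalanced below zero) are
    reported together before any integration starts.
    """
    base = preset(spec.preset)
    bundles = []
    bad = []
    for v in spec.grid:
        try:
            bundles.append(_bundle_for(base, spec.quantity, v))
        except StateError:
            bad.append(v)
    if bad:
        raise StateError(
            f"sweep of {spec.quantity!r} infeasible at grid values {bad}: "
            "rebalancing would drive S negative"
        )
    records = []
    trajectories = []
    for v, (params, initial) in zip(spec.grid, bundles):
        traj = integrate(params, initial, t_end=spec.t_end, dt=spec.dt,
                         variant=spec.variant)
        records.append(
            metrics_record(
                traj,
                compartment=spec.compartment,
                tol=spec.eq_tol,
                delta=spec.shape_delta,
                preset=spec.preset,
                quantity=spec.quantity,
                value=v,
            )
        )
        trajectories.append(traj)
    return SweepResult(spec=spec, records=tuple(records),
                       trajectories=tuple(trajectories))


def _p_shape(
    params: ModelParameters,
    p0: float,
    o0: float,
    u0: float,
    dt: float,
    t_end: float,
    delta: float,
) -> ShapeLabel:
    initial = PopulationState(S=1.0 - p0 - o0 - u0, O=o0, P=p0, U=u0)
    traj = integrate(params, initial, t_end=t_end, dt=dt)
    return classify_shape(traj, "P", delta).label


def critical_initial_p(
    params: ModelParameters,
    o0: float = 0.1,
    u0: float = 0.05,
    resolution: float = 0.005,
    delta: float = DEFAULT_SHAPE_DELTA,
    dt: float = DEFAULT_DT,
    t_end: float = DEFAULT_T_END,
    coarse_step: float = 0.05,
) -> ThresholdEstimate:
    """Critical initial pessimist fraction separating the two panic regimes.

    Below the threshold the pessimist curve first rises then falls (panic
    flares before the stable group reins it in); above it the curve
    declines from the start (pessimists so dominant that crowd rejection
    wins immediately).  The boundary is located by a coarse scan over
    P(0), then bisection down to ``resolution``; S(0) absorbs the
    complement so the population stays normalised.
    """
    if not 0 < o0 + u0 < 1:
        raise ValueError(f"O(0)+U(0)={o0 + u0} must lie in (0, 1)")
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution!r}")
    lo = resolution
    hi = 1.0 - o0 - u0 - resolution

    def rising(p0: float) -> bool:
        return _p_shape(params, p0, o0, u0, dt, t_end, delta) is \
            ShapeLabel.INCREASE_THEN_DECREASE

    # coarse scan for a bracket where the shape flips
    grid = np.arange(lo, hi, coarse_step)
    grid = np.append(grid, hi)
    flags = [rising(v) for v in grid]
    bracket = None
    for (x0, f0), (x1, f1) in zip(zip(grid, flags), zip(grid[1:], flags[1:])):
        if f0 and not f1:
            bracket = (float(x0), float(x1))
            break
    if bracket is None:
        raise NoThresholdError(
            f"no increase-then-decrease -> monotone-decrease transition for "
            f"P(0) in [{lo}, {hi}] at these parameters"
        )
    b_lo, b_hi = bracket
    while b_hi - b_lo > resolution:
        mid = 0.5 * (b_lo + b_hi)
        if rising(mid):
            b_lo = mid
        else:
            b_hi = mid
    return ThresholdEstimate(
        quantity="initial_P",
        estimate=0.5 * (b_lo + b_hi),
        bracket=(b_lo, b_hi),
        rule=(
            f"shape flip increase_then_decrease->monotone_decrease of P(t); "
            f"bisection to {resolution} with O0={o0}, U0={u0}, "
            f"delta={delta}, dt={dt}, t_end={t_end}"
        ),
    )


def risk_saturation_point(
    params: ModelParameters,
    initial: PopulationState,
    a_grid: Sequence[float] = tuple(range(0, 101, 10)),
    slope_fraction: float = 0.1,
    dt: float = DEFAULT_DT,
    t_end: float = DEFAULT_T_END,
    magnitude: bool = False,
) -> ThresholdEstimate:
    """Risk-coefficient value where the pessimist peak's growth levels off.

    Integrates once per ``a`` on the grid, takes the peak of P(t) for
    each, and returns the smallest grid value at which the per-unit-``a``
    increase of the peak drops below ``slope_fraction`` of the increase on
    the first grid interval.  With ``magnitude=True`` the rule is applied
    to the absolute change of the peak instead, which also covers regimes
    where raising the risk coefficient lowers the peak.
    """
    a_grid = tuple(float(v) for v in a_grid)
    if len(a_grid) < 2 or a_grid[0] != 0.0:
        raise ValueError(f"a_grid must start at 0 with >= 2 points: {a_grid}")
    if any(b <= a for a, b in zip(a_grid, a_grid[1:])):
        raise ValueError(f"a_grid must be strictly increasing: {a_grid}")
    if not 0.0 < slope_fraction < 1.0:
        raise ValueError(f"slope_fraction must be in (0, 1): {slope_fraction!r}")

    peaks = []
    for a in a_grid:
        traj = integrate(params.replace(a=a), initial, t_end=t_end, dt=dt)
        peaks.append(peak(traj, "P")[1])
    slopes = [
        (p1 - p0) / (a1 - a0)
        for (a0, p0), (a1, p1) in zip(zip(a_grid, peaks), zip(a_grid[1:], peaks[1:]))
    ]
    if magnitude:
        slopes = [abs(s) for s in slopes]
    if slopes[0] <= 0.0:
        raise RuleInapplicableError(
            f"peak P does not increase on the first grid interval "
            f"(slope {slopes[0]:.3g}); the saturation rule does not apply"
        )
    cutoff = slope_fraction * slopes[0]
    for i, s in enumerate(slopes[1:], start=1):
        if s < cutoff:
            return ThresholdEstimate(
                quantity="a",
                estimate=a_grid[i + 1],
                bracket=(a_grid[i], a_grid[i + 1]),
                rule=(
                    f"per-unit-a {'|peak P| change' if magnitude else 'peak P increase'} "
                    f"< {slope_fraction} x first-interval slope; "
                    f"grid={list(a_grid)}, dt={dt}, t_end={t_end}"
                ),
            )
    raise RuleInapplicableError(
        f"peak P growth never falls below {slope_fraction} of the "
        f"first-interval slope on grid {list(a_grid)}"
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Side-by-side summary of the full model vs its reduction."""

    full: dict
    reduced: dict

    def to_dict(self) -> dict:
        return {"full": self.full, "reduced": self.reduced}


def compare_with_without_u(
    params: ModelParameters,
    initial: PopulationState,
    dt: float = DEFAULT_DT,
    t_end: float = DEFAULT_T_END,
    eq_tol: float = DEFAULT_EQ_TOL,
) -> ComparisonResult:
    """Run the full model and its stable-group-free reduction side by side.

    The reduction removes the cure channels and starts with the stable
    compartment's share folded back into S, keeping the totals comparable.
    """
    traj_full = integrate(params, initial, t_end=t_end, dt=dt, variant="full")
    reduced_initial = PopulationState(
        S=initial.S + initial.U, O=initial.O, P=initial.P, U=0.0, t=initial.t
    )
    traj_red = integrate(params, reduced_initial, t_end=t_end, dt=dt,
                         variant="reduced")

    def summary(traj: Trajectory) -> dict:
        rec = metrics_record(traj, compartment="P", tol=eq_tol)
        return {
            "equilibrium_time": rec["equilibrium_time"],
            "peak_P": rec["peak_value"],
            "peak_P_time": rec["peak_t"],
            "final": {c: rec[f"final_{c}"] for c in "SOPU"},
            "variant": traj.variant,
        }

    return ComparisonResult(full=summary(traj_full), reduced=summary(traj_red))


def _geometric_grid(center: float) -> tuple[float, float, float]:
    # 0.5x / 1x / 2x around the published rate, capped at the [0,1] range
    return (0.5 * center, center, min(2.0 * center, 1.0))


_FIGURE_RECIPES: dict[str, dict] = {
    "fig4": {"kind": "simulate", "preset": "baseline_sec3", "variant": "full"},
    "fig5": {"kind": "simulate", "preset": "baseline_sec3", "variant": "full"},
    "fig6": {"kind": "compare", "preset": "baseline_sec3"},
    "fig7": {"kind": "sweep", "preset": "baseline_sec3", "quantity": "initial_P",
             "grid": (0.01, 0.1, 0.2, 0.3, 0.34, 0.4, 0.5, 0.6, 0.7, 0.8)},
    "fig8": {"kind": "sweep", "preset": "baseline_sec3", "quantity": "initial_P",
             "grid": (0.01, 0.1, 0.2, 0.3, 0.34, 0.4, 0.5, 0.6, 0.7, 0.8)},
    "fig9": {"kind": "sweep2", "preset": "uniform_sec4",
             "quantities": ("alpha_o", "alpha_p"), "compartment": "P"},
    "fig10": {"kind": "sweep2", "preset": "uniform_sec4",
              "quantities": ("alpha_o", "alpha_p"), "compartment": "U"},
    "fig11": {"kind": "sweep2", "preset": "uniform_sec4",
              "quantities": ("beta_o", "beta_p"), "compartment": "P"},
    "fig12": {"kind": "sweep2", "preset": "uniform_sec4",
              "quantities": ("beta_o", "beta_p"), "compartment": "U"},
    "fig13": {"kind": "sweep2", "preset": "uniform_sec4",
              "quantities": ("r_o", "r_p"), "compartment": "P"},
    "fig14": {"kind": "sweep2", "preset": "uniform_sec4",
              "quantities": ("r_o", "r_p"), "compartment": "U"},
    "fig15": {"kind": "sweep2", "preset": "uniform_sec4",
              "quantities": ("theta_s",), "compartment": "P"},
    "fig16": {"kind": "sweep2", "preset": "uniform_sec4",
              "quantities": ("theta_o", "theta_p"), "compartment": "P"},
    "fig17": {"kind": "sweep", "preset": "uniform_sec4", "quantity": "a",
              "grid": tuple(float(v) for v in range(0, 101, 10))},
}


def figure_ids() -> tuple[str, ...]:
    return tuple(_FIGURE_RECIPES)


def reproduce_figure(figure_id: str, dt: float = DEFAULT_DT,
                     t_end: float = DEFAULT_T_END):
    """Run the experiment recipe behind one published-figure id.

    Returns a :class:`Trajectory` (single simulation), a
    :class:`ComparisonResult`, a :class:`SweepResult`, or a list of
    :class:`SweepResult` for two-panel parameter figures.
    """
    try:
        recipe = _FIGURE_RECIPES[figure_id]
    except KeyError:
        raise KeyError(
            f"unknown figure id {figure_id!r}; known: {sorted(_FIGURE_RECIPES)}"
        ) from None
    kind = recipe["kind"]
    if kind == "simulate":
        bundle = preset(recipe["preset"])
        return integrate(bundle.params, bundle.initial, t_end=t_end, dt=dt,
                         variant=recipe["variant"])
    if kind == "compare":
        bundle = preset(recipe["preset"])
        return compare_with_without_u(bundle.params, bundle.initial,
                                      dt=dt, t_end=t_end)
    if kind == "sweep":
        return run_sweep(SweepSpec(preset=recipe["preset"],
                                   quantity=recipe["quantity"],
                                   grid=recipe["grid"], dt=dt, t_end=t_end))
    # two-panel sweeps: one geometric grid per swept rate
    results = []
    bundle = preset(recipe["preset"])
    for q in recipe["quantities"]:
        center = getattr(bundle.params, q)
        results.append(
            run_sweep(
                SweepSpec(
                    preset=recipe["preset"],
                    quantity=q,
                    grid=_geometric_grid(center),
                    compartment=recipe["compartment"],
                    dt=dt,
                    t_end=t_end,
                )
            )
        )
    return results
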