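"""Cost function and constrained Nelder-Mead fitting of the rate parameters.

The cost of one protocol is the sum of squared differences between the
simulated and target summary curves (for the prepulse-independence
protocol it is the dispersion of the peaks around their mean, which
enforces a constant resurgent peak without fixing its magnitude); the
total cost is the weighted sum over protocols.  Positivity of the rate
constants is enforced by optimizing in log-parameter space with an
otherwise unmodified Nelder-Mead simplex; convergence uses a tolerance of
0.01 on both the cost change and the (log-)parameter change.

Experimental target curves are not shipped; targets are either
synthesized from a parameter set (optionally with seeded Gaussian noise,
for parameter-recovery experiments) or supplied by the user.  Because
many parameter sets can produce near-identical curves, recovery is
assessed in curve space, not parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .kinetics import NavModel
from .parameters import PARAMETER_NAMES, RateParameterSet
from .propagation import CurrentModel
from . import protocols as proto

__all__ = [
    "PROTOCOL_IDS",
    "TargetSet",
    "FitResult",
    "run_protocol",
    "protocol_cost",
    "total_cost",
    "synthesize_targets",
    "fit_parameters",
    "refit_scn4b",
    "reduced_protocol_configs",
    "curve_recovery_error",
]


def _run_persistent(model, current, **cfg) -> proto.SummaryCurve:
    value = proto.persistent_fraction(model, current, **cfg)
    return proto.SummaryCurve("persistent", np.array([0.0]), np.array([value]),
                              x_label="-", y_label="persistent fraction",
                              metadata={"model": model.label})


def _run_prepulse(model, current, **cfg) -> proto.SummaryCurve:
    curve, _ = proto.prepulse_peak_spread(model, current, **cfg)
    return curve


_RUNNERS: dict[str, Callable[..., proto.SummaryCurve]] = {
    "availability": proto.availability_curve,
    "activation": proto.activation_curve,
    "tau-inact": proto.inactivation_tau_curve,
    "recovery": proto.recovery_curve,
    "persistent": _run_persistent,
    "inar-ratio": proto.resurgent_ratio_curve,
    "duration": proto.duration_dependence,
    "inar-tau": proto.resurgent_decay_taus,
    "prepulse": _run_prepulse,
}

#: The nine optimization protocols, in their conventional order.
PROTOCOL_IDS: tuple[str, ...] = tuple(_RUNNERS)


def run_protocol(
    params: RateParameterSet,
    protocol_id: str,
    current: CurrentModel | None = None,
    **config,
) -> proto.SummaryCurve:
    """Run one optimization protocol for a parameter set."""
    if protocol_id not in _RUNNERS:
        raise KeyError(
            f"unknown protocol id {protocol_id!r}; expected one of {PROTOCOL_IDS}"
        )
    model = NavModel(params)
    return _RUNNERS[protocol_id](model, current or CurrentModel(), **config)


@dataclass(frozen=True)
class TargetSet:
    """Fitting targets: one SummaryCurve per protocol, with weights.

    ``configs`` holds the per-protocol grid/step options used to generate
    the targets, so the cost function replays the protocols on identical
    grids.
    """

    targets: Mapping[str, proto.SummaryCurve]
    weights: Mapping[str, float] = field(default_factory=dict)
    configs: Mapping[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid in self.targets:
            if pid not in _RUNNERS:
                raise KeyError(f"unknown protocol id {pid!r}")

    def weight(self, pid: str) -> float:
        return float(self.weights.get(pid, 1.0))

    def config(self, pid: str) -> dict:
        return dict(self.configs.get(pid, {}))


def protocol_cost(
    params: RateParameterSet,
    protocol_id: str,
    target: proto.SummaryCurve,
    current: CurrentModel | None = None,
    **config,
) -> float:
    """Sum of squared differences between simulation and target.

    For the prepulse-independence protocol the cost is the dispersion of
    the simulated peaks around their own mean (the target's y values are
    not used), which drives the optimizer toward a voltage-independent
    resurgent peak without prescribing its amplitude.
    """
    curve = run_protocol(params, protocol_id, current, **config)
    if protocol_id == "prepulse":
        return float(np.sum((curve.y - curve.y.mean()) ** 2))
    if curve.x.shape != target.x.shape or not np.allclose(curve.x, target.x):
        raise ValueError(
            f"protocol {protocol_id!r}: simulation grid does not match the target grid"
        )
    return float(np.sum((curve.y - target.y) ** 2))


def total_cost(
    params: RateParameterSet,
    targets: TargetSet,
    current: CurrentModel | None = None,
) -> float:
    """Weighted sum of the per-protocol costs."""
    total = 0.0
    for pid, target in targets.targets.items():
        w = targets.weight(pid)
        if w == 0.0:
            continue
        total += w * protocol_cost(params, pid, target, current, **targets.config(pid))
    return total


def synthesize_targets(
    params: RateParameterSet,
    noise_sd: float = 0.0,
    seed: int | None = None,
    protocol_ids: Sequence[str] = PROTOCOL_IDS,
    configs: Mapping[str, dict] | None = None,
    current: CurrentModel | None = None,
) -> TargetSet:
    """Generate a TargetSet by running the protocols for a parameter set.

    Independent Gaussian noise of standard deviation ``noise_sd`` is added
    to every y value; with a fixed seed the result is reproducible.  This
    stands in for experimental mean curves in recovery experiments.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd!r}")
    rng = np.random.default_rng(seed)
    configs = dict(configs or {})
    out: dict[str, proto.SummaryCurve] = {}
    for pid in protocol_ids:
        curve = run_protocol(params, pid, current, **configs.get(pid, {}))
        y = curve.y + rng.normal(0.0, noise_sd, size=curve.y.shape) if noise_sd else curve.y
        out[pid] = replace(curve, y=np.asarray(y, dtype=float))
    return TargetSet(targets=out, configs={pid: dict(configs.get(pid, {})) for pid in protocol_ids})


@dataclass
class FitResult:
    """Outcome of a Nelder-Mead parameter fit."""

    params: RateParameterSet
    cost: float
    initial_cost: float
    per_protocol_costs: dict[str, float]
    n_evaluations: int
    converged: bool
    cost_trace: np.ndarray  # best cost after each evaluation

    def __post_init__(self) -> None:
        if self.cost > self.initial_cost + 1e-12:
            raise ValueError("final cost exceeds initial cost")


def fit_parameters(
    initial: RateParameterSet,
    targets: TargetSet,
    free: Sequence[str] | None = None,
    current: CurrentModel | None = None,
    cost_tol: float = 0.01,
    param_tol: float = 0.01,
    max_evaluations: int = 5000,
) -> FitResult:
    """Constrained Nelder-Mead fit of the rate parameters.

    Parameters are optimized on a log scale, which keeps every simplex
    vertex strictly positive.  ``free`` restricts the fit to a subset of
    the 24 parameters (the rest stay at their initial values); this is the
    practical mode given the model's limited identifiability.  Convergence
    requires the simplex spread to fall below ``cost_tol`` in cost and
    ``param_tol`` in log-parameter space; hitting ``max_evaluations``
    returns ``converged=False`` rather than raising.
    """
    free_names = tuple(free) if free is not None else PARAMETER_NAMES
    bad = sorted(set(free_names) - set(PARAMETER_NAMES))
    if bad:
        raise KeyError(f"unknown parameter name(s) in free: {', '.join(bad)}")

    x0 = np.log([getattr(initial, name) for name in free_names])

    evals = {"n": 0}
    best = {"cost": np.inf, "x": x0.copy()}
    trace: list[float] = []

    def params_from(x: np.ndarray) -> RateParameterSet:
        updates = {name: float(np.exp(val)) for name, val in zip(free_names, x)}
        return initial.with_values(**updates)

    def objective(x: np.ndarray) -> float:
        if evals["n"] >= max_evaluations:
            return best["cost"]  # freeze once the budget is exhausted
        evals["n"] += 1
        c = total_cost(params_from(x), targets, current)
        if c < best["cost"]:
            best["cost"] = c
            best["x"] = x.copy()
        trace.append(best["cost"])
        return c

    initial_cost = objective(x0)
    if initial_cost < 1e-12:
        fitted = params_from(x0)
        return FitResult(
            params=replace(fitted, label=initial.label),
            cost=initial_cost, initial_cost=initial_cost,
            per_protocol_costs=_per_protocol(fitted, targets, current),
            n_evaluations=evals["n"], converged=True,
            cost_trace=np.asarray(trace),
        )

    # Nelder-Mead with restarts: when the simplex collapses prematurely
    # (common in narrow curved valleys), restart with a fresh simplex from
    # the best point while the evaluation budget lasts.
    converged = False
    x_start = x0
    previous_best = np.inf
    while evals["n"] < max_evaluations:
        budget = max_evaluations - evals["n"]
        result = minimize(
            objective, x_start, method="Nelder-Mead",
            options={
                "fatol": cost_tol, "xatol": param_tol,
                "maxfev": budget, "adaptive": len(free_names) > 6,
            },
        )
        converged = bool(result.success)
        improved = best["cost"] < previous_best * 0.99
        previous_best = best["cost"]
        x_start = best["x"]
        if converged and not improved:
            break
        if best["cost"] < cost_tol * 1e-6:
            break
    fitted = params_from(best["x"])
    fitted = replace(fitted, label=initial.label)
    return FitResult(
        params=fitted,
        cost=float(best["cost"]),
        initial_cost=float(initial_cost),
        per_protocol_costs=_per_protocol(fitted, targets, current),
        n_evaluations=evals["n"],
        converged=converged,
        cost_trace=np.asarray(trace),
    )


def _per_protocol(
    params: RateParameterSet, targets: TargetSet, current: CurrentModel | None
) -> dict[str, float]:
    return {
        pid: protocol_cost(params, pid, target, current, **targets.config(pid))
        for pid, target in targets.targets.items()
    }


def reduced_protocol_configs() -> dict[str, dict]:
    """Coarsened protocol grids and sample steps for fitting runs.

    Fitting replays every protocol at each cost evaluation, so recovery
    experiments use fewer grid points, shorter repolarizations and larger
    sample intervals than the full battery.  Targets and simulations share
    the same configuration, so the coarsening does not bias the cost.
    """
    return {
        "availability": {"conditioning_mV": (-120.0, -100.0, -80.0, -65.0, -50.0, -35.0, -20.0),
                         "dt_ms": 0.01},
        "activation": {"test_mV": (-77.0, -66.0, -55.0, -44.0, -33.0, -22.0, -11.0, 0.0),
                       "dt_ms": 0.01},
        "tau-inact": {"test_mV": (-50.0, -40.0, -30.0, -20.0, -10.0, 0.0),
                      "dt_ms": 0.005, "test_ms": 20.0},
        "recovery": {"intervals_ms": (2, 5, 10, 20, 50, 200), "dt_ms": 0.02},
        "persistent": {"repol_ms": 100.0},
        "inar-ratio": {"repol_mV": (-80.0, -65.0, -45.0, -30.0, -15.0, -5.0),
                       "repol_ms": 60.0, "dt_repol": 0.02, "dt_dep": 0.002},
        "duration": {"durations_ms": (2.0, 8.0, 14.0, 22.0, 30.0, 36.0),
                     "repol_ms": 60.0, "dt_repol": 0.02, "dt_dep": 0.01},
        "inar-tau": {"repol_mV": (-45.0, -25.0, -5.0), "repol_ms": 60.0,
                     "dt_repol": 0.02},
        "prepulse": {"prepulse_mV": (-35.0, -20.0, -5.0), "repol_ms": 60.0},
    }


def curve_recovery_error(
    fitted: RateParameterSet,
    targets: TargetSet,
    current: CurrentModel | None = None,
) -> dict[str, float]:
    """Pointwise curve-space deviation of a fitted model from its targets.

    For each protocol, the maximum |y_sim - y_target| normalized by the
    target curve's amplitude scale (max |y_target|).  Curve space, not
    parameter space, is the meaningful metric: many parameter sets
    produce near-identical protocol outputs.
    """
    out: dict[str, float] = {}
    for pid, target in targets.targets.items():
        sim = run_protocol(fitted, pid, current, **targets.config(pid))
        scale = float(np.max(np.abs(target.y)))
        out[pid] = float(np.max(np.abs(sim.y - target.y)) / scale)
    return out


def refit_scn4b(
    wt_params: RateParameterSet,
    scn4b_ratio_target: proto.SummaryCurve,
    base_targets: TargetSet | None = None,
    free: Sequence[str] | None = None,
    current: CurrentModel | None = None,
    **fit_options,
) -> FitResult:
    """Refit starting from the wild-type optimum with a modified
    resurgent/transient ratio target.

    The resurgent-ratio protocol targets the reduced-amplitude
    (Scn4b-/-) curve while every other protocol keeps its wild-type
    target, so the fit scales the resurgent current without disturbing
    the transient-current properties.
    """
    if base_targets is None:
        base_targets = synthesize_targets(wt_params, current=current)
    new_targets = dict(base_targets.targets)
    if "inar-ratio" not in new_targets:
        raise KeyError("base targets must include the 'inar-ratio' protocol")
    new_targets["inar-ratio"] = scn4b_ratio_target
    merged = TargetSet(targets=new_targets, weights=base_targets.weights,
                       configs=base_targets.configs)
    if free is None:
        # the slow-pathway rates govern the resurgent amplitude
        free = ("a2s_variable1", "b2s_variable1", "a3s_variable1",
                "a6_variable1", "b6_variable1")
    result = fit_parameters(wt_params, merged, free=free, current=current, **fit_options)
    result.params = replace(result.params, label="Scn4b-/- (refit)")
    return result
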