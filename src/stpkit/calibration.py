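"""Objective-based calibration of the kinetic models.

Replaces by-eye parameter tuning with an explicit least-squares objective:
the weighted sum of squared *relative* errors between simulated and target
EPSC-train amplitudes (50 and 500 Hz) and fractional-recovery points, so
datasets of different amplitude scale contribute comparably.  Parameters
can be fitted per experimental condition or *shared* across conditions
(e.g. the two-step scheme constrains release probability and total site
count to common values across phenotypes).  Optimisation is multi-start
bounded derivative-free local search (Nelder-Mead from Latin-hypercube
starts) because the simulator is piecewise-smooth and provides no
gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .models import ParameterError, simulate

__all__ = ["CalibrationProblem", "CalibrationResult", "objective", "fit"]

_DATASET_KEYS = ("train_50hz", "train_500hz", "recovery")


@dataclass
class CalibrationProblem:
    """Specification of a model-calibration task.

    Parameters
    ----------
    model_kind : str
        ``"single_pool"`` or ``"two_step"`` (informational; the kinetic
        scheme is carried by the per-condition base parameter objects).
    base : dict
        ``condition -> (params, dyn_ca, dyn_pr)``: baseline parameter
        containers supplying every value that is not being fitted.
    datasets : dict
        ``condition -> {dataset key -> payload}``.  Payloads:
        ``train_50hz`` / ``train_500hz``: ``(StimulusProtocol,
        target amplitudes)``; ``recovery``: ``(cond_protocol, test_stub,
        intervals, target fractional recovery)``.
    free_params : list of str
        Names fitted independently per condition.  A name is resolved
        against the kinetic-parameter container first, then the calcium and
        release-probability dynamics.
    shared_params : list of str
        Names fitted jointly (one common value for all conditions).
    bounds : dict
        ``name -> (lo, hi)`` for every fitted name; bounds must be finite.
    weights : dict
        Optional per-dataset-key weights (default 1 each).
    """

    model_kind: str
    base: Dict[str, tuple]
    datasets: Dict[str, dict]
    free_params: List[str]
    shared_params: List[str] = field(default_factory=list)
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_kind not in ("single_pool", "two_step"):
            raise ParameterError(f"unknown model_kind {self.model_kind!r}")
        overlap = set(self.free_params) & set(self.shared_params)
        if overlap:
            raise ParameterError(f"params both free and shared: {overlap}")
        for name in list(self.free_params) + list(self.shared_params):
            if name not in self.bounds:
                raise ParameterError(f"no bounds given for parameter {name!r}")
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ParameterError(f"bounds for {name!r} must be finite, lo < hi")
        for cond in self.datasets:
            if cond not in self.base:
                raise ParameterError(f"no base parameters for condition {cond!r}")

    @property
    def conditions(self) -> List[str]:
        return list(self.datasets)


@dataclass
class CalibrationResult:
    """Outcome of a calibration run."""

    fitted: Dict[str, Dict[str, float]]   # condition -> name -> value
    loss: float
    loss_trajectory: np.ndarray           # best-so-far loss per start
    per_dataset_loss: Dict[str, Dict[str, float]]
    converged: bool
    at_bound: List[str]
    seed: Optional[int]
    n_starts: int


def _apply(base: tuple, values: Dict[str, float]):
    """Return (params, dyn_ca, dyn_pr) with named fields overridden."""
    params, dyn_ca, dyn_pr = base
    p_upd, ca_upd, pr_upd = {}, {}, {}
    for name, v in values.items():
        if hasattr(params, name):
            p_upd[name] = v
        elif hasattr(dyn_ca, name):
            ca_upd[name] = v
        elif hasattr(dyn_pr, name):
            pr_upd[name] = v
        else:
            raise ParameterError(f"unknown parameter name {name!r}")
    if p_upd:
        params = replace(params, **p_upd)
    if ca_upd:
        dyn_ca = replace(dyn_ca, **ca_upd)
    if pr_upd:
        dyn_pr = replace(dyn_pr, **pr_upd)
    return params, dyn_ca, dyn_pr


def _condition_loss(problem: CalibrationProblem, cond: str,
                    values: Dict[str, float]) -> Dict[str, float]:
    params, dyn_ca, dyn_pr = _apply(problem.base[cond], values)
    losses: Dict[str, float] = {}
    data = problem.datasets[cond]
    for key in ("train_50hz", "train_500hz"):
        if key not in data:
            continue
        protocol, target = data[key]
        train, _ = simulate(protocol, params, dyn_ca, dyn_pr)
        target = np.asarray(target, dtype=float)
        scale = float(np.sqrt(np.mean(target ** 2)))
        losses[key] = float(np.mean(((train.amplitudes - target) / scale) ** 2))
    if "recovery" in data:
        from .models import recovery_curve

        cond_proto, test_stub, intervals, target = data["recovery"]
        ds = recovery_curve(params, dyn_ca, dyn_pr, cond_proto, intervals,
                            test_stub)
        frac = ds.fractional()
        target = np.asarray(target, dtype=float)
        scale = max(float(np.sqrt(np.mean(target ** 2))), 1e-12)
        losses["recovery"] = float(np.mean(((frac - target) / scale) ** 2))
    return losses


def objective(problem: CalibrationProblem,
              assignments: Dict[str, Dict[str, float]]) -> float:
    """Weighted calibration loss for explicit parameter assignments.

    ``assignments`` maps each condition to the fitted-parameter values to
    apply on top of the condition's base parameters (shared names should
    carry the same value in every condition).  Missing datasets are
    skipped with a warning.
    """
    total = 0.0
    seen = set()
    for cond in problem.conditions:
        losses = _condition_loss(problem, cond, assignments.get(cond, {}))
        for key in _DATASET_KEYS:
            if key in losses:
                total += problem.weights.get(key, 1.0) * losses[key]
                seen.add(key)
    missing = set(_DATASET_KEYS) - seen
    if missing:
        warnings.warn(f"datasets absent from every condition: {sorted(missing)}",
                      RuntimeWarning, stacklevel=2)
    return total


def _vector_layout(problem: CalibrationProblem):
    """Flatten (shared + per-condition free) parameters into one vector."""
    layout = [("__shared__", n) for n in problem.shared_params]
    for cond in problem.conditions:
        layout += [(cond, n) for n in problem.free_params]
    lo = np.array([problem.bounds[n][0] for _, n in layout])
    hi = np.array([problem.bounds[n][1] for _, n in layout])
    return layout, lo, hi


def _assignments_from_vector(problem: CalibrationProblem, layout, x):
    out: Dict[str, Dict[str, float]] = {c: {} for c in problem.conditions}
    for (scope, name), v in zip(layout, x):
        if scope == "__shared__":
            for c in problem.conditions:
                out[c][name] = float(v)
        else:
            out[scope][name] = float(v)
    return out


def fit(problem: CalibrationProblem, n_starts: int = 8,
        seed: Optional[int] = None, maxfev: int = 400,
        xatol: float = 1e-4, fatol: float = 1e-10) -> CalibrationResult:
    """Multi-start bounded Nelder-Mead fit of a calibration problem.

    Starts are a Latin-hypercube sample of the bounded box (plus the box
    centre); the best of the local optima is returned.  Shared parameters
    occupy a single vector slot, so the fitted values are identical across
    conditions by construction.
    """
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")
    layout, lo, hi = _vector_layout(problem)
    if not layout:
        raise ParameterError("nothing to fit: no free or shared parameters")

    def fun(x):
        asg = _assignments_from_vector(problem, layout, x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return objective(problem, asg)
        except (ParameterError, FloatingPointError):
            return 1e12

    sampler = qmc.LatinHypercube(d=len(layout), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    starts[0] = 0.5 * (lo + hi)

    best = None
    traj = []
    failures = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                fun, x0, method="Nelder-Mead",
                bounds=optimize.Bounds(lo, hi),
                options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol})
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
        traj.append(best.fun)
    if best is None:
        raise RuntimeError(
            f"all {n_starts} calibration starts failed: {failures}")

    x = np.clip(best.x, lo, hi)
    asg = _assignments_from_vector(problem, layout, x)
    at_bound = [name for (scope, name), v, l, h in zip(layout, x, lo, hi)
                if v - l <= 1e-6 * (h - l) or h - v <= 1e-6 * (h - l)]
    per_ds = {c: _condition_loss(problem, c, asg[c])
              for c in problem.conditions}
    return CalibrationResult(
        fitted=asg, loss=float(best.fun), loss_trajectory=np.asarray(traj),
        per_dataset_loss=per_ds, converged=bool(best.success),
        at_bound=sorted(set(at_bound)), seed=seed, n_starts=n_starts)
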