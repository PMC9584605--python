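"""Quantal analysis of EPSC trains: RRP size and release probability.

Three classical train-based estimators are provided:

* **EQ** (Elmqvist-Quastel): regression of EPSC amplitude against the
  cumulative amplitude released before that stimulus over the initial,
  near-linear depletion segment; the x-intercept estimates the readily
  releasable pool and ``P_r = EPSC1 / RRP``.
* **SMN** (back-extrapolation): a straight line through the steady-state
  tail of the cumulative-amplitude plot is extrapolated back to stimulus 0;
  the intercept estimates the pool plus, uncorrected, the replenishment
  accumulated before steady state.  The corrected variant iteratively
  removes that replenishment, scaled by the instantaneous vacancy of the
  pool.
* **NpRf**: a direct least-squares fit of the three-parameter
  pool/release-fraction/refill recursion to the full train.

Also included: descriptive train metrics (PPR, steady state, depression
ratio), the effective EPSC duration (charge/amplitude), and the
Boltzmann-fit EPSC onset-delay estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .models import EPSCTrain, ParameterError

__all__ = [
    "QuantalEstimate",
    "TrainMetrics",
    "EstimationError",
    "eq_estimate",
    "smn_estimate",
    "nprf_estimate",
    "train_metrics",
    "effective_duration",
    "onset_delay",
]

#: onset offset of the maximum-curvature point of a Boltzmann sigmoid,
#: in units of its slope factor: t_onset = t50 - k * ln(2 + sqrt(3))
BOLTZMANN_CURVATURE_OFFSET = math.log(2.0 + math.sqrt(3.0))


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a meaningful estimate."""


@dataclass
class QuantalEstimate:
    """RRP/P_r estimate with its method tag.

    ``rrp`` is in the units of the train amplitudes (nA of summed
    amplitude), or in vesicle counts when the train was built with a
    quantal size of 1.
    """

    method: str
    rrp: float
    pr: float
    replenishment: Optional[float] = None
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rrp <= 0:
            raise EstimationError(f"non-positive RRP estimate ({self.rrp:.4g})")
        if not 0 <= self.pr <= 1:
            raise EstimationError(f"P_r estimate outside [0, 1] ({self.pr:.4g})")


@dataclass
class TrainMetrics:
    """Descriptive metrics of an EPSC train."""

    ppr: float
    epsc1: float
    epsc_ss: float
    depression_ratio: float
    effective_durations: Optional[np.ndarray] = None


def eq_estimate(train: EPSCTrain, n_points: int = 4) -> QuantalEstimate:
    """Elmqvist-Quastel pool estimate from the initial depletion segment.

    Amplitude of stimulus j is regressed against the cumulative amplitude
    released before stimulus j over the first ``n_points`` stimuli.  For a
    pure depletion train ``a_j = P_r * (RRP - cum_{j-1})``, so the
    x-intercept is the RRP and the slope is ``-P_r``;  ``P_r`` is reported
    as ``EPSC1 / RRP``.
    """
    a = train.amplitudes
    if not 3 <= n_points <= 6:
        raise ParameterError("n_points must be between 3 and 6")
    if len(a) < n_points + 1:
        raise ParameterError(f"train too short for {n_points}-point EQ fit")
    seg = a[:n_points]
    cum_before = np.concatenate([[0.0], np.cumsum(seg)[:-1]])
    fit = stats.linregress(cum_before, seg)
    if fit.slope >= 0:
        raise EstimationError(
            "no depression over the EQ segment (slope >= 0); EQ inapplicable")
    rrp = -fit.intercept / fit.slope  # x-intercept
    pr = a[0] / rrp
    return QuantalEstimate(
        method="EQ", rrp=float(rrp), pr=float(min(pr, 1.0)),
        fit_diagnostics={"slope": float(fit.slope),
                         "intercept": float(fit.intercept),
                         "r_value": float(fit.rvalue),
                         "n_points": n_points})


def _fit_tail(cum: np.ndarray, ss_window: int):
    idx = np.arange(1, cum.size + 1, dtype=float)
    fit = stats.linregress(idx[-ss_window:], cum[-ss_window:])
    return fit.slope, fit.intercept


def smn_estimate(train: EPSCTrain, ss_window: int = 10,
                 corrected: bool = True, max_iter: int = 10,
                 tol: float = 1e-6) -> QuantalEstimate:
    """Back-extrapolation (SMN) pool estimate from the cumulative plot.

    A line is fitted to the last ``ss_window`` points of cumulative
    amplitude versus stimulus index; its intercept at index 0 is the
    uncorrected RRP (initial pool plus replenishment accrued before steady
    state).  The corrected variant subtracts, from every cumulative point,
    the estimated replenishment before it — the steady-state refill per
    interval (the tail slope) scaled by the instantaneous pool vacancy
    relative to the steady-state vacancy — re-fitting iteratively until the
    intercept converges.
    """
    a = train.amplitudes
    if len(a) < 2 * ss_window:
        raise ParameterError(
            f"train too short for SMN with ss_window={ss_window}")
    cum = np.cumsum(a)
    slope, intercept = _fit_tail(cum, ss_window)
    if slope < 0:
        raise EstimationError("negative steady-state slope; SMN inapplicable")
    if intercept <= 0:
        raise EstimationError("non-positive back-extrapolated intercept")
    diagnostics = {"ss_slope": float(slope),
                   "uncorrected_rrp": float(intercept),
                   "corrected": corrected}
    rrp = float(intercept)
    if corrected and slope > 0:
        # Reconstruct pool occupancy under the current RRP estimate with a
        # per-interval refill slope * v_j / v_ss (v_j: vacancy after stim j),
        # so that refill equals the tail slope at steady state; subtract the
        # accumulated refill from the cumulative plot, re-fit, iterate.
        n = len(a)
        v_ss = 1.0
        for it in range(max_iter):
            refill = np.zeros(n)
            vac = np.zeros(n)
            occ = rrp
            for j in range(n):
                occ_after = occ - a[j]
                vac[j] = max(1.0 - occ_after / rrp, 0.0)
                refill[j] = slope * vac[j] / v_ss
                occ = occ_after + refill[j]
            v_ss_new = max(float(np.mean(vac[-ss_window:])), 1e-9)
            cum_corr = cum - np.concatenate([[0.0], np.cumsum(refill)[:-1]])
            _, new_int = _fit_tail(cum_corr, ss_window)
            diagnostics["iterations"] = it + 1
            if new_int <= 0:
                break
            converged = (abs(new_int - rrp) <= tol * max(abs(rrp), 1.0)
                         and abs(v_ss_new - v_ss) <= tol)
            rrp = float(new_int)
            v_ss = v_ss_new
            if converged:
                break
    pr = a[0] / rrp
    return QuantalEstimate(method="SMN", rrp=rrp, pr=float(min(pr, 1.0)),
                           replenishment=float(slope),
                           fit_diagnostics=diagnostics)


def _nprf_predict(n_stim: int, N: float, p: float, R: float) -> np.ndarray:
    a = np.empty(n_stim)
    n = N
    for j in range(n_stim):
        a[j] = p * n
        vacated = N - (n - a[j])
        n = n - a[j] + R * vacated
    return a


def nprf_estimate(train: EPSCTrain) -> QuantalEstimate:
    """Fit the N/p/Rf pool-release-refill recursion to a depressing train.

    Model: ``a_j = p * n_j``; ``n_{j+1} = n_j - a_j + R * (N - (n_j - a_j))``
    — a pool of ``N`` sites, a fixed release fraction ``p`` per stimulus and
    a fixed per-interval refill fraction ``R`` of vacated sites.  Fitted by
    bounded least squares from a multi-start grid.
    """
    a = train.amplitudes
    if len(a) < 10:
        raise ParameterError("NpRf requires >= 10 stimuli")
    if a[0] <= 0:
        raise EstimationError("non-positive first amplitude")
    if np.ptp(a) < 1e-12 * abs(a[0]):
        raise EstimationError("flat train: release fraction unidentifiable")
    if a[0] <= np.mean(a[-3:]):
        raise EstimationError("train is not depressing; NpRf inapplicable")
    total = float(np.sum(a))

    def resid(theta):
        N, p, R = theta
        return _nprf_predict(len(a), N, p, R) - a

    best = None
    for p0 in (0.05, 0.1, 0.2, 0.4):
        for R0 in (0.05, 0.2, 0.5):
            N0 = a[0] / p0
            try:
                sol = optimize.least_squares(
                    resid, x0=[N0, p0, R0],
                    bounds=([a[0], 1e-6, 0.0], [10 * total, 1.0, 1.0]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise EstimationError("NpRf optimisation did not converge from any start")
    N, p, R = best.x
    return QuantalEstimate(method="NpRf", rrp=float(N), pr=float(p),
                           replenishment=float(R),
                           fit_diagnostics={"cost": float(best.cost),
                                            "status": int(best.status)})


def train_metrics(train: EPSCTrain, ss_window: int = 10) -> TrainMetrics:
    """PPR, first and steady-state amplitude and depression ratio.

    The steady state is the mean over the last ``ss_window`` stimuli
    (clipped to the train length).
    """
    a = train.amplitudes
    if len(a) < 2:
        raise ParameterError("need >= 2 stimuli for train metrics")
    w = min(ss_window, len(a))
    epsc1 = float(a[0])
    epsc_ss = float(np.mean(a[-w:]))
    eff = None
    if train.charges is not None:
        eff = np.array([effective_duration(c, amp)
                        for c, amp in zip(train.charges, a)])
    return TrainMetrics(ppr=float(a[1] / a[0]), epsc1=epsc1, epsc_ss=epsc_ss,
                        depression_ratio=epsc_ss / epsc1,
                        effective_durations=eff)


def effective_duration(charge: float, amplitude: float) -> float:
    """Effective EPSC duration: charge (pC) / amplitude (nA), in ms.

    The width of a square current pulse with the same amplitude and charge
    as the EPSC; a proxy for the synchronicity of vesicle release.
    """
    if amplitude <= 0:
        raise ParameterError("amplitude must be > 0")
    return charge / amplitude


def _boltzmann(t, A, t50, k):
    return A / (1.0 + np.exp((t50 - t) / k))


def onset_delay(time_ms: np.ndarray, current_nA: np.ndarray, stim_time: float,
                fit_window: float = 1.0) -> float:
    """EPSC onset delay from a Boltzmann fit of the rising flank, in µs.

    A sigmoid ``A / (1 + exp((t50 - t)/k))`` is fitted to the rising flank
    of the EPSC following ``stim_time`` (window length ``fit_window`` ms);
    the onset is the maximum-curvature point on the leading edge of the
    fitted sigmoid, ``t_onset = t50 - k * ln(2 + sqrt(3))``, and the delay
    is ``t_onset - stim_time``.

    The trace may be of either polarity; it is rectified to a
    positive-going deflection internally (the curvature point of the
    normalised sigmoid does not depend on amplitude or sign).
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_nA, dtype=float)
    if t.size != i.size:
        raise ParameterError("time and current length mismatch")
    dt = np.diff(t)
    if t.size < 8 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ParameterError("trace must be uniformly sampled")
    sel = (t >= stim_time) & (t <= stim_time + fit_window)
    if sel.sum() < 6:
        raise ParameterError("fit window contains too few samples")
    ts, ys = t[sel], i[sel]
    ys = ys - ys[0]
    if abs(ys.min()) > abs(ys.max()):  # inward (negative) current
        ys = -ys
    i_pk = int(np.argmax(ys))
    if i_pk < 3:
        raise EstimationError("no rising flank found after the stimulus")
    ts, ys = ts[: i_pk + 1], ys[: i_pk + 1]
    A0 = ys[-1]
    half = np.argmax(ys >= A0 / 2)
    p0 = [A0, ts[half], max((ts[-1] - ts[0]) / 10, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(_boltzmann, ts, ys, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise EstimationError(f"Boltzmann fit failed: {exc}") from exc
    A, t50, k = popt
    if k <= 0 or A <= 0:
        raise EstimationError("Boltzmann fit degenerate (non-rising flank)")
    t_onset = t50 - k * BOLTZMANN_CURVATURE_OFFSET
    return (t_onset - stim_time) * 1000.0  # ms -> µs
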