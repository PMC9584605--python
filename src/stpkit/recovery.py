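"""Recovery of synaptic strength after pool-depleting conditioning trains.

After a high-frequency conditioning train has depleted the readily
releasable pool, the amplitude of a test EPSC delivered at increasing
intervals recovers along a time course that is typically bi-exponential: a
fast component (tens of ms, driven by the residually elevated effective
[Ca2+] accelerating priming) and a slow component (seconds, the resting
replenishment rate).  This module provides the fractional-recovery
transform, mono/bi-exponential fitting with nested-model selection by
F-test, and the amplitude-weighted time constant used to summarise
bi-exponential fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, TYPE_CHECKING

import numpy as np
from scipy import optimize, stats

from .models import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .models import EPSCTrain
    from .quantal import QuantalEstimate

__all__ = [
    "RecoveryDataset",
    "ExpFitResult",
    "FitError",
    "fractional_recovery",
    "weighted_tau",
    "fit_recovery",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from every start."""


@dataclass
class RecoveryDataset:
    """A paired-train recovery experiment.

    ``points`` holds (recovery interval in s, test-train) pairs sorted by
    interval; the conditioning-train summary provides the normalisation for
    fractional recovery.
    """

    cond_epsc1: float
    cond_epsc_ss: float
    points: List[Tuple[float, "EPSCTrain"]] = field(default_factory=list)
    cond_rrp: Optional["QuantalEstimate"] = None
    cond_train: Optional["EPSCTrain"] = None

    def __post_init__(self) -> None:
        ivs = [p[0] for p in self.points]
        if any(iv <= 0 for iv in ivs):
            raise ParameterError("recovery intervals must be > 0")
        if any(b <= a for a, b in zip(ivs, ivs[1:])):
            raise ParameterError("recovery intervals must be sorted ascending")

    @property
    def intervals(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    def test_epsc1(self) -> np.ndarray:
        """First-EPSC amplitude of every test train."""
        return np.array([p[1].amplitudes[0] for p in self.points])

    def fractional(self) -> np.ndarray:
        """Fractional recovery of the first test EPSC at every interval."""
        return np.array([
            fractional_recovery(a, self.cond_epsc1, self.cond_epsc_ss)
            for a in self.test_epsc1()
        ])


@dataclass
class ExpFitResult:
    """Result of a mono- or bi-exponential recovery fit.

    For the bi-exponential form ``A * (1 - (f*exp(-t/tau1) +
    (1-f)*exp(-t/tau2)))`` with ``tau1 < tau2``, ``f`` is the fraction of
    the fast component; ``f_slow = 1 - f``.  ``tau_w`` is the
    amplitude-weighted mean time constant.
    """

    model: str
    A: float
    tau1: float
    f: float = 1.0
    tau2: Optional[float] = None
    tau_w: Optional[float] = None
    f_test_p: Optional[float] = None
    rss: float = np.nan

    @property
    def f_slow(self) -> float:
        return 1.0 - self.f

    def __post_init__(self) -> None:
        if self.tau1 <= 0:
            raise ParameterError("tau1 must be > 0")
        if self.model == "bi":
            if self.tau2 is None or self.tau2 <= self.tau1:
                raise ParameterError("bi fit requires tau2 > tau1")
            if not 0 <= self.f <= 1:
                raise ParameterError("f must be in [0, 1]")


def fractional_recovery(epsc_test1: float, cond_epsc1: float,
                        cond_epsc_ss: float) -> float:
    """Fractional recovery of the first test EPSC.

    ``(EPSC_test1 - EPSC_cond_ss) / (EPSC_cond1 - EPSC_cond_ss)`` — 0 means
    no recovery beyond the conditioning steady state, 1 full recovery;
    values above 1 (overshoot) are allowed.
    """
    denom = cond_epsc1 - cond_epsc_ss
    if denom == 0:
        raise ParameterError(
            "conditioning train shows no depression (EPSC1 == EPSC_ss)")
    return (epsc_test1 - cond_epsc_ss) / denom


def weighted_tau(tau_fast: float, tau_slow: float, f_slow: float) -> float:
    """Amplitude-weighted mean time constant of a bi-exponential fit.

    ``tau_w = (1 - f_slow) * tau_fast + f_slow * tau_slow`` (seconds in,
    seconds out).
    """
    if not 0 <= f_slow <= 1:
        raise ParameterError(f"f_slow must be in [0, 1], got {f_slow}")
    if tau_slow < tau_fast:
        raise ParameterError("tau_slow must be >= tau_fast")
    if tau_fast <= 0:
        raise ParameterError("time constants must be > 0")
    return (1.0 - f_slow) * tau_fast + f_slow * tau_slow


def _mono(t, A, tau):
    return A * (1.0 - np.exp(-t / tau))


def _bi(t, A, f, tau1, tau2):
    return A * (1.0 - (f * np.exp(-t / tau1) + (1.0 - f) * np.exp(-t / tau2)))


def _fit_mono(t, v):
    A0 = v[-1] if v[-1] != 0 else 1.0
    best = None
    for tau0 in (0.01, 0.05, 0.2, 1.0, 5.0):
        try:
            popt, _ = optimize.curve_fit(
                _mono, t, v, p0=[A0, tau0],
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=5000)
        except RuntimeError:
            continue
        rss = float(np.sum((v - _mono(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    return best


def _fit_bi(t, v):
    A0 = v[-1] if v[-1] != 0 else 1.0
    best = None
    for tau1 in (0.01, 0.05, 0.2):
        for tau2 in (0.5, 2.0, 5.0):
            for f0 in (0.2, 0.5, 0.8):
                try:
                    popt, _ = optimize.curve_fit(
                        _bi, t, v, p0=[A0, f0, tau1, tau2],
                        bounds=([-np.inf, 0.0, 1e-9, 1e-9],
                                [np.inf, 1.0, np.inf, np.inf]), maxfev=5000)
                except RuntimeError:
                    continue
                rss = float(np.sum((v - _bi(t, *popt)) ** 2))
                if best is None or rss < best[1]:
                    best = (popt, rss)
    return best


def fit_recovery(intervals, values, force_model: str = "auto",
                 alpha: float = 0.05) -> ExpFitResult:
    """Fit a recovery time course with mono- and bi-exponential models.

    Both ``A*(1-exp(-t/tau))`` and the bi-exponential form are fitted by
    multi-start nonlinear least squares; the nested-model F-test
    ``F = ((RSS_mono - RSS_bi)/2) / (RSS_bi/(n-4))`` selects the
    bi-exponential fit when p < ``alpha`` (``force_model`` overrides).
    """
    t = np.asarray(intervals, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ParameterError("intervals and values length mismatch")
    if force_model not in ("auto", "mono", "bi"):
        raise ParameterError(f"unknown force_model {force_model!r}")
    n_min = 5 if force_model == "mono" else 7
    if t.size < n_min:
        raise ParameterError(f"need >= {n_min} points, got {t.size}")
    if np.ptp(v) == 0:
        raise FitError("constant values: time constants unidentifiable")

    mono = _fit_mono(t, v)
    if mono is None:
        raise FitError("mono-exponential fit failed from every start")
    (A_m, tau_m), rss_m = mono

    if force_model == "mono":
        return ExpFitResult(model="mono", A=float(A_m), tau1=float(tau_m),
                            rss=rss_m)

    bi = _fit_bi(t, v)
    if bi is None:
        raise FitError("bi-exponential fit failed from every start")
    (A_b, f_b, tau1_b, tau2_b), rss_b = bi
    if tau2_b < tau1_b:  # canonicalise tau1 < tau2
        tau1_b, tau2_b = tau2_b, tau1_b
        f_b = 1.0 - f_b

    n = t.size
    df_bi = n - 4
    if rss_b <= 0 or df_bi <= 0:
        p = 0.0
    else:
        F = max((rss_m - rss_b) / 2.0, 0.0) / (rss_b / df_bi)
        p = float(stats.f.sf(F, 2, df_bi))

    use_bi = force_model == "bi" or (force_model == "auto" and p < alpha)
    if use_bi:
        if tau2_b == tau1_b:
            tau2_b = tau1_b * (1 + 1e-12)
        tw = weighted_tau(tau1_b, tau2_b, 1.0 - f_b)
        return ExpFitResult(model="bi", A=float(A_b), f=float(f_b),
                            tau1=float(tau1_b), tau2=float(tau2_b),
                            tau_w=float(tw), f_test_p=p, rss=rss_b)
    return ExpFitResult(model="mono", A=float(A_m), tau1=float(tau_m),
                        f_test_p=p, rss=rss_m)
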