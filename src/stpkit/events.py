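"""Analysis of miniature EPSCs and of stimulus-evoked spike timing.

Miniature EPSCs (spontaneous single-vesicle events) are detected on raw
current traces by a threshold of ``baseline_sd_mult`` times the standard
deviation of an event-free baseline window; overlapping events are
excluded.  Spike-timing analysis covers naturalistic (sinusoidally
amplitude-modulated) stimulation: per-stimulus AP success, latency and
jitter, and the exponential-kernel estimate of preceding activity that
summarises the recent firing history beyond the last inter-spike interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import ParameterError

__all__ = [
    "MiniEvent",
    "SpikeRecord",
    "detect_minis",
    "event_metrics",
    "ap_success",
    "delay_jitter",
    "preceding_activity",
    "binned_stats",
]


@dataclass
class MiniEvent:
    """A detected miniature EPSC."""

    t_peak: float          # ms
    amplitude: float       # nA, positive magnitude
    rise_10_90: float      # ms
    fwhm: float            # ms

    def __post_init__(self) -> None:
        if self.rise_10_90 <= 0 or self.fwhm <= 0:
            raise ParameterError("rise and FWHM must be > 0")


@dataclass
class SpikeRecord:
    """Paired stimulus and action-potential times (ms)."""

    stim_times: np.ndarray
    ap_times: np.ndarray

    def __post_init__(self) -> None:
        self.stim_times = np.sort(np.asarray(self.stim_times, dtype=float))
        self.ap_times = np.sort(np.asarray(self.ap_times, dtype=float))

    def match(self, window: float) -> List[Optional[float]]:
        """Greedy earliest-AP matching: for each stimulus, the first
        unconsumed AP in ``(stim, stim + window]``, else None."""
        if window <= 0:
            raise ParameterError("window must be > 0")
        matches: List[Optional[float]] = []
        k = 0
        for s in self.stim_times:
            while k < self.ap_times.size and self.ap_times[k] <= s:
                k += 1
            if k < self.ap_times.size and self.ap_times[k] <= s + window:
                matches.append(float(self.ap_times[k]))
                k += 1
            else:
                matches.append(None)
        return matches


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     rising: bool, last: bool = False) -> Optional[float]:
    """Linear-interpolated crossing of ``level`` (direction-aware).

    For a rising flank leading into a peak the *last* crossing before the
    peak is the robust choice (noise may graze low levels much earlier).
    """
    if rising:
        idx = np.nonzero((y[:-1] < level) & (y[1:] >= level))[0]
    else:
        idx = np.nonzero((y[:-1] >= level) & (y[1:] < level))[0]
    if idx.size == 0:
        return None
    i = idx[-1] if last else idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def event_metrics(time_ms: np.ndarray, waveform: np.ndarray) -> MiniEvent:
    """Amplitude, 10-90% rise time and FWHM of a single-event waveform.

    The waveform is rectified to a positive-going deflection; amplitude is
    peak minus the local baseline (the first sample), rise time is measured
    between the 10% and 90% crossings on the rising flank and the FWHM
    between the interpolated half-amplitude crossings.
    """
    t = np.asarray(time_ms, dtype=float)
    y = np.asarray(waveform, dtype=float)
    # local baseline: median of the leading samples, never reaching past
    # half the rise to the extremum
    j_ext = int(np.argmax(np.abs(y - y[0])))
    n_base = max(3, min(y.size // 20, j_ext // 2)) if j_ext >= 6 else 1
    base = float(np.median(y[:n_base]))
    y = y - base
    if abs(y.min()) > abs(y.max()):
        y = -y
    i_pk = int(np.argmax(y))
    amp = float(y[i_pk])
    if amp <= 0:
        raise ParameterError("waveform has no peak above baseline")
    up = slice(0, i_pk + 1)
    rise_lo = _interp_crossing(t[up], y[up], 0.1 * amp, True, last=True)
    rise_hi = _interp_crossing(t[up], y[up], 0.9 * amp, True, last=True)
    half_up = _interp_crossing(t[up], y[up], 0.5 * amp, True, last=True)
    half_dn = _interp_crossing(t[i_pk:], y[i_pk:], 0.5 * amp, False)
    if rise_lo is None or rise_hi is None:
        raise ParameterError("rise-time thresholds not crossed")
    if half_up is None or half_dn is None:
        raise ParameterError("no half-amplitude down-crossing within window")
    return MiniEvent(t_peak=float(t[i_pk]), amplitude=amp,
                     rise_10_90=rise_hi - rise_lo, fwhm=half_dn - half_up)


def detect_minis(time_ms: np.ndarray, current_nA: np.ndarray,
                 baseline_sd_mult: float = 5.0, min_separation: float = 5.0,
                 baseline_window: Tuple[float, float] = None,
                 event_window: float = 10.0,
                 polarity: int = -1) -> Tuple[List[MiniEvent], float]:
    """Detect miniature EPSCs by a baseline-SD threshold.

    Samples deviating from the baseline mean by more than
    ``baseline_sd_mult`` baseline standard deviations (in the direction set
    by ``polarity``; -1 for inward currents) are grouped into candidate
    events (one per contiguous supra-threshold region).  Events whose peaks
    are closer than ``min_separation`` ms are considered overlapping and
    **all** members of the overlapping group are excluded.  Returns the
    retained events and their frequency in Hz (retained events per trace
    duration).
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_nA, dtype=float)
    if t.size == 0:
        raise ParameterError("empty trace")
    if not 4.0 <= baseline_sd_mult <= 6.0:
        raise ParameterError("baseline_sd_mult must lie in [4, 6]")
    if baseline_window is None:
        baseline_window = (t[0], t[0] + 100.0)
    b0, b1 = baseline_window
    base = i[(t >= b0) & (t <= b1)]
    if base.size < 10:
        raise ParameterError("baseline window too short")
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd == 0:
        sd = 1e-12
    dev = polarity * (i - mu)
    above = dev > baseline_sd_mult * sd
    if np.any(above[(t >= b0) & (t <= b1)]):
        warnings.warn("baseline window contains supra-threshold samples",
                      RuntimeWarning, stacklevel=2)
    # contiguous supra-threshold regions -> candidate peaks
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    peaks = []
    for s, e in zip(starts, ends):
        k = s + int(np.argmax(dev[s:e]))
        peaks.append(k)
    # merge threshold crossings that belong to one event: consecutive
    # candidate peaks with no return toward baseline (valley above half the
    # detection threshold) in between are fragments of the same event
    thr = baseline_sd_mult * sd
    merged = True
    while merged and len(peaks) > 1:
        merged = False
        for a in range(len(peaks) - 1):
            k1, k2 = peaks[a], peaks[a + 1]
            if (t[k2] - t[k1] < min_separation
                    and np.min(dev[k1:k2 + 1]) > 0.5 * thr):
                peaks[a] = k1 if dev[k1] >= dev[k2] else k2
                del peaks[a + 1]
                merged = True
                break
    # overlap exclusion: drop every member of a too-close pair
    peak_t = t[peaks]
    keep = np.ones(len(peaks), dtype=bool)
    for a in range(len(peaks) - 1):
        if peak_t[a + 1] - peak_t[a] < min_separation:
            keep[a] = keep[a + 1] = False
    events = []
    dt = t[1] - t[0] if t.size > 1 else 1.0
    half = max(int(round(event_window / dt)), 2)
    for k, ok in zip(peaks, keep):
        if not ok:
            continue
        lo = max(k - half // 4, 0)
        hi = min(k + half, t.size)
        try:
            ev = event_metrics(t[lo:hi], i[lo:hi])
        except ParameterError:
            continue
        events.append(ev)
    duration_s = (t[-1] - t[0]) / 1000.0
    freq = len(events) / duration_s if duration_s > 0 else 0.0
    return events, freq


def ap_success(record: SpikeRecord, window: float = 2.0) -> float:
    """Fraction of stimuli followed by >= 1 AP within ``window`` ms.

    Each AP is consumed by at most one stimulus (greedy earliest match).
    """
    matches = record.match(window)
    if not matches:
        return 0.0
    return sum(m is not None for m in matches) / len(matches)


def delay_jitter(record: SpikeRecord, window: float = 2.0):
    """Mean AP delay and AP jitter (SD of delays) over successes, in µs."""
    matches = record.match(window)
    delays = [(m - s) * 1000.0 for s, m in zip(record.stim_times, matches)
              if m is not None]
    if len(delays) < 2:
        raise ParameterError("need >= 2 successful stimulus-AP pairs")
    delays = np.asarray(delays)
    return float(np.mean(delays)), float(np.std(delays, ddof=1))


def preceding_activity(ap_times: Sequence[float], index: int,
                       tau: float = 30.0) -> float:
    """Exponential-kernel estimate of activity preceding one AP.

    ``sum over earlier APs of exp(-(t_index - t_earlier) / tau)`` with
    ``tau`` in ms (default 30 ms); emphasises temporally close events over
    distant ones and captures history beyond the last inter-spike interval.
    """
    if tau <= 0:
        raise ParameterError("tau must be > 0")
    t = np.asarray(ap_times, dtype=float)
    if not 0 <= index < t.size:
        raise ParameterError("index out of range")
    dt = t[index] - t[:index]
    return float(np.sum(np.exp(-dt / tau)))


def binned_stats(values: Sequence[float], covariate: Sequence[float],
                 bin_edges: Sequence[float]):
    """Per-bin count, mean and SD of ``values`` grouped by ``covariate``.

    Bins follow the half-open convention ``[left, right)``; a covariate
    exactly at an inner edge belongs to the bin on its right.  Returns a
    dict of arrays (``count``, ``mean``, ``sd``, ``empty``); mean/SD of
    empty bins are NaN and flagged.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    e = np.asarray(bin_edges, dtype=float)
    if v.size != c.size:
        raise ParameterError("values and covariate length mismatch")
    if e.size < 2 or np.any(np.diff(e) <= 0):
        raise ParameterError("bin edges must be sorted strictly ascending")
    nb = e.size - 1
    idx = np.digitize(c, e, right=False) - 1  # [left, right)
    count = np.zeros(nb, dtype=int)
    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b]:
            mean[b] = float(np.mean(v[sel]))
            sd[b] = float(np.std(v[sel], ddof=1)) if count[b] > 1 else 0.0
    return {"count": count, "mean": mean, "sd": sd, "empty": count == 0}
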