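"""Synthetic electrophysiology data with known ground truth.

Every input the analysis chain consumes can be generated here: regular and
paired-train stimulus protocols, amplitude-noise-corrupted EPSC trains,
miniature-EPSC traces (Poisson events convolved with a bi-exponential
kernel plus Gaussian noise), sinusoidally amplitude-modulated (SAM) spike
patterns emulating naturalistic auditory-nerve firing, and ground-truthed
stimulus/AP records for spike-timing analysis.  Each generator is fully
determined by its seed, and emits its ground-truth parameters alongside the
data so downstream recovery tests are self-describing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import EPSCTrain, ParameterError, StimulusProtocol
from .events import SpikeRecord

__all__ = [
    "BiExpKernel",
    "gen_regular_protocol",
    "gen_recovery_protocols",
    "gen_noisy_train",
    "gen_mepsc_trace",
    "gen_sam_spike_pattern",
    "gen_ap_responses",
]

#: modulation-frequency range of naturalistic SAM stimulation, Hz
SAM_MOD_RANGE = (20.0, 2000.0)


@dataclass(frozen=True)
class BiExpKernel:
    """Bi-exponential event kernel ``exp(-t/tau_decay) - exp(-t/tau_rise)``,
    normalised to peak amplitude ``amplitude`` (nA)."""

    tau_rise: float = 0.1    # ms
    tau_decay: float = 0.5   # ms
    amplitude: float = -0.05  # nA; negative = inward current

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= self.tau_rise:
            raise ParameterError("need 0 < tau_rise < tau_decay")
        if self.amplitude == 0:
            raise ParameterError("amplitude must be non-zero")

    @property
    def t_peak(self) -> float:
        r, d = self.tau_rise, self.tau_decay
        return r * d / (d - r) * math.log(d / r)

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.maximum(np.asarray(t_ms, dtype=float), 0.0)
        raw = np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise)
        tp = self.t_peak
        peak = math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise)
        out = raw / peak * self.amplitude
        out[np.asarray(t_ms) < 0] = 0.0
        return out


def gen_regular_protocol(n_stimuli: int, rate: float,
                         label: str = "") -> StimulusProtocol:
    """Evenly spaced stimulus train, first AP at t = 0 (rate in Hz)."""
    if rate <= 0:
        raise ParameterError("rate must be > 0")
    if n_stimuli < 1:
        raise ParameterError("n_stimuli must be >= 1")
    times = np.arange(n_stimuli) / rate
    return StimulusProtocol(times, label or f"{n_stimuli}x{rate:g}Hz")


def gen_recovery_protocols(cond: StimulusProtocol, intervals: Sequence[float],
                           test: StimulusProtocol):
    """Paired conditioning/test protocols for a recovery experiment.

    For each interval the test protocol (times relative to its first
    stimulus) is shifted to start ``interval`` seconds after the last
    conditioning stimulus.  Returns a list of (interval, cond, shifted
    test) triples.
    """
    ivs = np.asarray(intervals, dtype=float)
    if ivs.size == 0:
        raise ParameterError("intervals must be non-empty")
    if np.any(ivs <= 0):
        raise ParameterError("intervals must be > 0")
    cond_end = cond.ap_times[-1]
    out = []
    for iv in np.sort(ivs):
        shifted = test.shifted(cond_end + iv - test.ap_times[0])
        out.append((float(iv), cond, shifted))
    return out


def log_spaced_intervals(lo: float = 0.02, hi: float = 16.0,
                         n: int = 12) -> np.ndarray:
    """Logarithmic recovery-interval grid (default 20 ms to 16 s)."""
    return np.geomspace(lo, hi, n)


def gen_noisy_train(train: EPSCTrain, amp_noise_sd: float,
                    seed: Optional[int] = None) -> EPSCTrain:
    """Add i.i.d. Gaussian amplitude noise (SD in nA) to a train."""
    if amp_noise_sd < 0:
        raise ParameterError("amp_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    amps = train.amplitudes + rng.normal(0.0, amp_noise_sd,
                                         size=train.amplitudes.size)
    return EPSCTrain(ap_times=train.ap_times.copy(), amplitudes=amps,
                     charges=None, quantal_contents=None, pr_per_ap=None,
                     mode="stochastic")


def gen_mepsc_trace(duration: float, rate: float,
                    kernel: BiExpKernel = BiExpKernel(),
                    noise_sd: float = 0.005, seed: Optional[int] = None,
                    sample_rate: float = 50_000.0):
    """Synthetic miniature-EPSC trace.

    Homogeneous Poisson event times at ``rate`` Hz over ``duration`` s; each
    event adds a bi-exponential kernel; Gaussian noise of SD ``noise_sd``
    (nA) is superimposed.  Returns ``(time_ms, current_nA, truth)`` where
    ``truth`` carries the ground-truth event times and parameters.
    """
    if duration <= 0 or rate < 0 or noise_sd < 0:
        raise ParameterError("duration > 0, rate >= 0, noise_sd >= 0 required")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * sample_rate))
    t_ms = np.arange(n_samp) / sample_rate * 1000.0
    trace = rng.normal(0.0, noise_sd, size=n_samp)
    n_ev = rng.poisson(rate * duration)
    ev_times = np.sort(rng.uniform(0.0, duration * 1000.0, size=n_ev))
    span_ms = kernel.tau_decay * 12 + kernel.t_peak
    n_span = int(round(span_ms / 1000.0 * sample_rate))
    rel = np.arange(n_span) / sample_rate * 1000.0
    wf = kernel.waveform(rel)
    for et in ev_times:
        k0 = int(round(et / 1000.0 * sample_rate))
        k1 = min(k0 + n_span, n_samp)
        if k0 < n_samp:
            trace[k0:k1] += wf[: k1 - k0]
    truth = {"event_times_ms": ev_times, "rate_hz": rate,
             "kernel": kernel, "noise_sd": noise_sd, "seed": seed}
    return t_ms, trace, truth


def gen_sam_spike_pattern(duration: float, carrier_rate: float,
                          mod_freq: float, depth: float,
                          seed: Optional[int] = None,
                          refractory_ms: float = 1.0) -> StimulusProtocol:
    """Sinusoidally amplitude-modulated spike pattern (thinned Poisson).

    Intensity ``carrier_rate * (1 + depth * sin(2 pi mod_freq t))``; spikes
    are drawn by the thinning algorithm with an absolute refractory period
    of ``refractory_ms``.  Emulates the fluctuating firing that SAM sound
    stimulation evokes in the auditory nerve (periods of high activity
    interleaved with quiet periods).
    """
    if duration <= 0 or carrier_rate <= 0:
        raise ParameterError("duration and carrier_rate must be > 0")
    if not 0 <= depth <= 1:
        raise ParameterError("depth must be in [0, 1]")
    if not SAM_MOD_RANGE[0] <= mod_freq <= SAM_MOD_RANGE[1]:
        warnings.warn(
            f"mod_freq {mod_freq:g} Hz outside the naturalistic range "
            f"{SAM_MOD_RANGE}", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    lam_max = carrier_rate * (1.0 + depth)
    t = 0.0
    last = -np.inf
    times = []
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= duration:
            break
        lam = carrier_rate * (1.0 + depth * math.sin(2 * math.pi * mod_freq * t))
        if rng.uniform() * lam_max <= lam and (t - last) * 1000.0 >= refractory_ms:
            times.append(t)
            last = t
    if not times:
        raise ParameterError("no spikes generated; increase rate or duration")
    return StimulusProtocol(np.asarray(times),
                            label=f"SAM {mod_freq:g}Hz depth {depth:g}")


def gen_ap_responses(protocol: StimulusProtocol, success_p: float,
                     delay_mean: float, jitter_sd: float,
                     activity_slope: float = 0.0, tau_ms: float = 30.0,
                     seed: Optional[int] = None):
    """Ground-truthed postsynaptic AP responses to a stimulus protocol.

    Each stimulus triggers an AP with probability ``success_p``; its delay
    is ``delay_mean + activity_slope * activity`` plus Gaussian jitter of
    SD ``jitter_sd`` (all in µs), where ``activity`` is the
    exponential-kernel weighted count of preceding *stimuli* (tau in ms).
    Delays are floored at 10 µs to stay causal.  Returns ``(SpikeRecord,
    truth)``.
    """
    if not 0 <= success_p <= 1:
        raise ParameterError("success_p must be in [0, 1]")
    if jitter_sd < 0 or delay_mean <= 0:
        raise ParameterError("delay_mean > 0 and jitter_sd >= 0 required")
    rng = np.random.default_rng(seed)
    stim_ms = protocol.ap_times * 1000.0
    ap_times = []
    for j, s in enumerate(stim_ms):
        if rng.uniform() > success_p:
            continue
        dt = s - stim_ms[:j]
        activity = float(np.sum(np.exp(-dt / tau_ms)))
        delay_us = delay_mean + activity_slope * activity
        if jitter_sd > 0:
            delay_us += rng.normal(0.0, jitter_sd)
        ap_times.append(s + max(delay_us, 10.0) / 1000.0)
    record = SpikeRecord(stim_times=stim_ms, ap_times=np.asarray(ap_times))
    truth = {"success_p": success_p, "delay_mean_us": delay_mean,
             "jitter_sd_us": jitter_sd, "activity_slope": activity_slope,
             "tau_ms": tau_ms, "seed": seed}
    return record, truth
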