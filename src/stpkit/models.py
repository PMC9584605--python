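"""Kinetic models of synaptic vesicle priming, fusion and short-term plasticity.

Two kinetic schemes of the presynaptic release machinery are implemented:

* a **single-pool model** in which vesicles reversibly dock at a single type
  of release site (empty ``ES`` |harr| docked/primed ``DS``) with a
  Ca2+-dependent forward (priming) rate constant ``k_f`` and a fixed backward
  (unpriming) rate constant ``k_b``;
* a **sequential two-step model** in which docked vesicles mature through a
  loosely docked state (``LS``) into a tightly docked, fusion-competent state
  (``TS``); both forward rate constants are Ca2+-dependent and only TS
  vesicles fuse.

Both schemes share the same description of the *effective* cytosolic calcium
concentration (an instantaneous jump at each action potential followed by a
mono-exponential decay to rest) and of release-probability dynamics (a
facilitation variable ``y`` and a depression variable ``z`` multiplying the
resting release probability).

Units: time in seconds, concentrations in nM, rates in 1/s.  The
Michaelis-Menten parameters of the Ca2+ dependence (``sigma``, ``k_half``)
are user-facing in µM and converted internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ParameterError",
    "SimulationError",
    "CalciumDynamics",
    "PrDynamics",
    "SinglePoolParams",
    "TwoStepParams",
    "ModelState",
    "StimulusProtocol",
    "EPSCTrain",
    "priming_rate",
    "ca_after",
    "pr_sequence",
    "resting_state",
    "simulate",
    "recovery_curve",
]


class ParameterError(ValueError):
    """Raised when model parameters violate their physical constraints."""


class SimulationError(RuntimeError):
    """Raised when numerical integration of the kinetic scheme fails."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalciumDynamics:
    """Effective cytosolic [Ca2+] dynamics.

    The effective [Ca2+] jumps instantaneously by ``delta_ca_ap`` at each
    action potential and relaxes back to ``ca_rest`` with rate constant
    ``k_ca``:  d[Ca]/dt = -k_ca * ([Ca] - ca_rest).

    Parameters
    ----------
    ca_rest : float
        Resting [Ca2+] in nM (default 50 nM).
    delta_ca_ap : float
        Instantaneous [Ca2+] increment per AP, nM.
    k_ca : float
        Decay rate constant, 1/s.
    """

    ca_rest: float = 50.0
    delta_ca_ap: float = 0.0
    k_ca: float = 1.0

    def __post_init__(self) -> None:
        if self.ca_rest <= 0:
            raise ParameterError(f"ca_rest must be > 0, got {self.ca_rest}")
        if self.delta_ca_ap < 0:
            raise ParameterError("delta_ca_ap must be >= 0")
        if self.k_ca <= 0:
            raise ParameterError("k_ca must be > 0")


@dataclass(frozen=True)
class PrDynamics:
    """Release-probability dynamics during repetitive stimulation.

    The release probability of the j-th AP is
    ``P_r,j = pr1 * y_j**facilitation_exponent * z_j`` with the facilitation
    variable ``y >= 1`` (tracking the build-up of local [Ca2+]) and the
    depression variable ``z <= 1``.  Both are initialised to 1 at the onset
    of a stimulus train; after each AP ``y`` is incremented by
    ``y_inc1 * (y_max - y)`` and ``z`` decremented by
    ``z_dec1 * (z - z_min)``; between APs both relax exponentially back to 1
    with rate constants ``k_y`` and ``k_z``.
    """

    pr1: float = 0.1
    y_inc1: float = 0.0
    y_max: float = 1.0
    z_dec1: float = 0.0
    z_min: float = 1.0
    k_y: float = 1.0
    k_z: float = 1.0
    facilitation_exponent: float = 4.5

    def __post_init__(self) -> None:
        if not 0 < self.pr1 <= 1:
            raise ParameterError(f"pr1 must be in (0, 1], got {self.pr1}")
        if self.y_max < 1:
            raise ParameterError("y_max must be >= 1")
        if not 0 <= self.z_min <= 1:
            raise ParameterError("z_min must be in [0, 1]")
        if self.k_y <= 0 or self.k_z <= 0:
            raise ParameterError("k_y and k_z must be > 0")
        if not 0 <= self.y_inc1 <= 1 or not 0 <= self.z_dec1 <= 1:
            raise ParameterError("y_inc1 and z_dec1 must be in [0, 1]")


@dataclass(frozen=True)
class SinglePoolParams:
    """Kinetic constants of the single-pool priming scheme.

    ``n_total`` release sites; occupied sites ``n_o`` gain from empty sites
    ``n_e`` with the Ca2+-dependent priming rate ``k_f`` and lose with the
    fixed unpriming rate ``kb``.  ``q`` is the quantal amplitude (nA per
    vesicle) converting quantal content to EPSC amplitude.
    """

    n_total: float = 2000.0
    kf_rest: float = 0.5       # 1/s at resting Ca
    sigma: float = 10.0        # 1/s per µM
    k_half: float = 2.0        # µM above rest
    kb: float = 0.1            # 1/s
    q: float = 0.0075          # nA per SV

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ParameterError("n_total must be > 0")
        if min(self.kf_rest, self.sigma, self.kb) < 0:
            raise ParameterError("rates must be >= 0")
        if self.k_half <= 0:
            raise ParameterError("k_half must be > 0")
        if self.q <= 0:
            raise ParameterError("q must be > 0")

    @property
    def n_states(self) -> int:
        return 2


@dataclass(frozen=True)
class TwoStepParams:
    """Kinetic constants of the sequential two-step priming scheme.

    State chain ES -> LS -> TS with Ca2+-dependent forward rates ``k1``
    (docking, ES->LS) and ``k2`` (tightening, LS->TS), each following the
    same Michaelis-Menten-like saturation as the single-pool ``k_f``, and
    fixed backward rates ``b1`` (LS->ES) and ``b2`` (TS->LS).  Only TS
    vesicles fuse upon AP arrival.
    """

    n_total: float = 3000.0
    k1_rest: float = 2.0
    sigma1: float = 10.0
    k1_half: float = 2.0
    b1: float = 2.0
    k2_rest: float = 2.0
    sigma2: float = 10.0
    k2_half: float = 2.0
    b2: float = 4.0
    q: float = 0.0075

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ParameterError("n_total must be > 0")
        rates = (self.k1_rest, self.sigma1, self.b1,
                 self.k2_rest, self.sigma2, self.b2)
        if min(rates) < 0:
            raise ParameterError("rates must be >= 0")
        if self.k1_half <= 0 or self.k2_half <= 0:
            raise ParameterError("Michaelis constants must be > 0")
        if self.q <= 0:
            raise ParameterError("q must be > 0")

    @property
    def n_states(self) -> int:
        return 3


ModelParams = Union[SinglePoolParams, TwoStepParams]


@dataclass
class ModelState:
    """Instantaneous state of a kinetic simulation.

    ``occupancy`` is ``(n_e, n_o)`` for the single-pool scheme and
    ``(es, ls, ts)`` for the two-step scheme; its sum is conserved.
    """

    t: float
    ca: float
    y: float
    z: float
    occupancy: np.ndarray

    def copy(self) -> "ModelState":
        return ModelState(self.t, self.ca, self.y, self.z,
                          np.array(self.occupancy, dtype=float))


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered sequence of action-potential times (seconds)."""

    ap_times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.ap_times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ParameterError("ap_times must be a non-empty 1-D sequence")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ParameterError("ap_times must be strictly increasing")
        object.__setattr__(self, "ap_times", times)

    def __len__(self) -> int:
        return int(self.ap_times.size)

    def shifted(self, offset: float) -> "StimulusProtocol":
        return StimulusProtocol(self.ap_times + offset, self.label)


@dataclass
class EPSCTrain:
    """Per-stimulus EPSC measurements — the common currency of the package.

    Amplitudes are in nA, charges in pC.  ``quantal_contents`` (vesicles per
    stimulus) and ``pr_per_ap`` are filled by the simulators; experimental
    trains carry only times/amplitudes(/charges).
    """

    ap_times: np.ndarray
    amplitudes: np.ndarray
    charges: Optional[np.ndarray] = None
    quantal_contents: Optional[np.ndarray] = None
    pr_per_ap: Optional[np.ndarray] = None
    mode: str = "experimental"

    def __post_init__(self) -> None:
        self.ap_times = np.asarray(self.ap_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        n = self.ap_times.size
        if self.amplitudes.size != n:
            raise ParameterError("amplitudes and ap_times length mismatch")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ParameterError("amplitudes must be finite")
        for name in ("charges", "quantal_contents", "pr_per_ap"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ParameterError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return int(self.ap_times.size)


# ---------------------------------------------------------------------------
# elementary kinetics
# ---------------------------------------------------------------------------

def priming_rate(ca: float, rest_rate: float, sigma: float, k_half: float,
                 ca_rest: float = 50.0) -> float:
    """Ca2+-dependent priming rate with Michaelis-Menten-like saturation.

    ``k(ca) = (rest_rate + sigma * dCa) / (1 + dCa / k_half)`` where
    ``dCa = ca - ca_rest`` expressed in µM.  At rest the rate equals
    ``rest_rate``; for large dCa it saturates at ``sigma * k_half``.

    Parameters
    ----------
    ca, ca_rest : float
        Effective and resting [Ca2+], nM.
    rest_rate : float
        Rate at resting [Ca2+], 1/s.
    sigma : float
        Initial slope of the Ca2+ dependence, 1/s per µM.
    k_half : float
        Michaelis constant, µM above rest.
    """
    if sigma < 0 or k_half <= 0:
        raise ParameterError("sigma must be >= 0 and k_half > 0")
    dca_um = (ca - ca_rest) / 1000.0  # nM -> µM
    if dca_um < 0:
        dca_um = 0.0
    return (rest_rate + sigma * dca_um) / (1.0 + dca_um / k_half)


def ca_after(ca0: float, dt: float, dyn: CalciumDynamics) -> float:
    """Effective [Ca2+] after a silent interval ``dt`` (closed form).

    ``ca_rest + (ca0 - ca_rest) * exp(-k_ca * dt)``.
    """
    if dt < 0:
        raise ParameterError("dt must be >= 0")
    return dyn.ca_rest + (ca0 - dyn.ca_rest) * math.exp(-dyn.k_ca * dt)


def _pr_value(dyn: PrDynamics, y: float, z: float) -> float:
    pr = dyn.pr1 * y ** dyn.facilitation_exponent * z
    if pr > 1.0:
        warnings.warn(
            f"release probability {pr:.4g} exceeds 1; clipped",
            RuntimeWarning, stacklevel=3)
        pr = 1.0
    return pr


def _apply_pr_increments(dyn: PrDynamics, y: float, z: float) -> tuple:
    y = y + dyn.y_inc1 * (dyn.y_max - y)
    z = z - dyn.z_dec1 * (z - dyn.z_min)
    return y, z


def _relax_yz(dyn: PrDynamics, y: float, z: float, dt: float) -> tuple:
    # d/dt y = (1 - y) k_y  ->  y(t) = 1 + (y0 - 1) exp(-k_y t); same for z
    ey = math.exp(-dyn.k_y * dt)
    ez = math.exp(-dyn.k_z * dt)
    return 1.0 + (y - 1.0) * ey, 1.0 + (z - 1.0) * ez


def pr_sequence(protocol: StimulusProtocol, dyn: PrDynamics) -> np.ndarray:
    """Per-AP release probabilities for a stimulus train.

    ``y`` and ``z`` start at 1; for each AP the current ``P_r`` is evaluated,
    the post-AP increments applied, and both variables relaxed exponentially
    toward 1 over the following inter-stimulus interval.
    """
    times = protocol.ap_times
    y = z = 1.0
    out = np.empty(times.size)
    for j, t in enumerate(times):
        out[j] = _pr_value(dyn, y, z)
        y, z = _apply_pr_increments(dyn, y, z)
        if j + 1 < times.size:
            y, z = _relax_yz(dyn, y, z, times[j + 1] - t)
    return out


# ---------------------------------------------------------------------------
# steady states and continuous evolution
# ---------------------------------------------------------------------------

def _rate_matrix(params: ModelParams, ca: float, ca_rest: float) -> np.ndarray:
    """Generator matrix A with d(occupancy)/dt = A @ occupancy."""
    if isinstance(params, SinglePoolParams):
        kf = priming_rate(ca, params.kf_rest, params.sigma, params.k_half,
                          ca_rest)
        return np.array([[-kf, params.kb],
                         [kf, -params.kb]])
    k1 = priming_rate(ca, params.k1_rest, params.sigma1, params.k1_half,
                      ca_rest)
    k2 = priming_rate(ca, params.k2_rest, params.sigma2, params.k2_half,
                      ca_rest)
    return np.array([[-k1, params.b1, 0.0],
                     [k1, -(params.b1 + k2), params.b2],
                     [0.0, k2, -params.b2]])


def resting_state(params: ModelParams, dyn: CalciumDynamics) -> ModelState:
    """Analytic steady state of the priming scheme at resting [Ca2+].

    For the single pool the occupied fraction is ``k_f / (k_f + k_b)``
    evaluated at rest; for the two-step chain the unique steady state of the
    linear ES<->LS<->TS system is solved directly.  ``y = z = 1``.
    """
    A = _rate_matrix(params, dyn.ca_rest, dyn.ca_rest)
    n = A.shape[0]
    # steady state: A @ x = 0 with sum(x) = n_total
    M = np.vstack([A, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = params.n_total
    occ, res, rank, _ = np.linalg.lstsq(M, rhs, rcond=None)
    if rank < n or np.any(occ < -1e-9 * params.n_total):
        raise ParameterError("no unique non-negative resting state for these rates")
    occ = np.clip(occ, 0.0, None)
    return ModelState(t=0.0, ca=dyn.ca_rest, y=1.0, z=1.0, occupancy=occ)


def _evolve(state: ModelState, dt: float, params: ModelParams,
            dyn_ca: CalciumDynamics, dyn_pr: PrDynamics,
            rtol: float = 1e-8, atol: float = 1e-10) -> ModelState:
    """Evolve the continuous dynamics over an AP-free interval of length dt.

    [Ca2+] and (y, z) follow closed forms; the occupancy ODE (with the
    time-varying Ca2+-dependent forward rates) is integrated with an
    adaptive embedded Runge-Kutta 4(5) scheme on exactly this segment, so no
    event detection is needed.
    """
    if dt < 0:
        raise ParameterError("cannot evolve backwards in time")
    if dt == 0:
        return state.copy()
    ca0 = state.ca

    def rhs(t, occ):
        ca_t = ca_after(ca0, t, dyn_ca)
        return _rate_matrix(params, ca_t, dyn_ca.ca_rest) @ occ

    sol = solve_ivp(rhs, (0.0, dt), state.occupancy, method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(
            f"occupancy integration failed at t={state.t:+.6f}s: {sol.message}")
    y, z = _relax_yz(dyn_pr, state.y, state.z, dt)
    return ModelState(t=state.t + dt, ca=ca_after(ca0, dt, dyn_ca),
                      y=y, z=z, occupancy=sol.y[:, -1])


# ---------------------------------------------------------------------------
# train simulation
# ---------------------------------------------------------------------------

def simulate(protocol: StimulusProtocol, params: ModelParams,
             dyn_ca: CalciumDynamics, dyn_pr: PrDynamics,
             mode: str = "deterministic", seed: Optional[int] = None,
             initial_state: Optional[ModelState] = None,
             rtol: float = 1e-8, atol: float = 1e-10):
    """Simulate an EPSC train for a stimulus protocol.

    At each AP, release is computed from the state immediately before the
    AP: the quantal content is ``m_j = P_r,j * pool_j`` (deterministic,
    mean-field) or a binomial draw ``Binomial(round(pool_j), P_r,j)``
    (stochastic), where the pool is the fusion-competent occupancy (``n_o``
    for the single pool, ``TS`` for the two-step scheme).  Released vesicles
    vacate their sites, which become immediately available for docking; the
    effective [Ca2+] is then incremented and the continuous ODEs are
    integrated to the next AP.

    Returns
    -------
    train : EPSCTrain
        Amplitudes ``m_j * q``, with quantal contents and per-AP release
        probabilities filled in.
    trajectory : list of ModelState
        States immediately before each AP (post-integration, pre-release),
        ending with the state immediately after the last AP.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if initial_state is None:
        state = resting_state(params, dyn_ca)
        state.t = 0.0
    else:
        state = initial_state.copy()
    if protocol.ap_times[0] < state.t:
        raise ParameterError("protocol starts before the initial state time")

    n = len(protocol)
    m = np.empty(n)
    prs = np.empty(n)
    trajectory = []
    for j, t_ap in enumerate(protocol.ap_times):
        state = _evolve(state, t_ap - state.t, params, dyn_ca, dyn_pr,
                        rtol=rtol, atol=atol)
        trajectory.append(state.copy())
        pr_j = _pr_value(dyn_pr, state.y, state.z)
        pool = state.occupancy[-1]
        if mode == "deterministic":
            m_j = pr_j * pool
        else:
            m_j = float(rng.binomial(int(round(max(pool, 0.0))), pr_j))
        state.occupancy[-1] -= m_j
        state.occupancy[0] += m_j
        state.ca += dyn_ca.delta_ca_ap
        state.y, state.z = _apply_pr_increments(dyn_pr, state.y, state.z)
        m[j] = m_j
        prs[j] = pr_j
    trajectory.append(state.copy())
    train = EPSCTrain(ap_times=protocol.ap_times.copy(),
                      amplitudes=m * params.q,
                      quantal_contents=m, pr_per_ap=prs, mode=mode)
    return train, trajectory


def recovery_curve(params: ModelParams, dyn_ca: CalciumDynamics,
                   dyn_pr: PrDynamics, cond_protocol: StimulusProtocol,
                   intervals: Sequence[float],
                   test_protocol_stub: StimulusProtocol,
                   mode: str = "deterministic", seed: Optional[int] = None,
                   ss_window: int = 10):
    """Paired conditioning/test train recovery experiment.

    The conditioning train is simulated from rest; for every recovery
    interval the post-conditioning state is carried through the silent
    interval (closed-form [Ca2+]/y/z relaxation plus the continuous priming
    ODEs) and the test train (stub times taken relative to its own first
    stimulus at 0) is then simulated from the carried state.

    Returns a :class:`~stpkit.recovery.RecoveryDataset`.
    """
    from .recovery import RecoveryDataset  # local import avoids a cycle

    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0 or np.any(intervals <= 0):
        raise ParameterError("intervals must be positive and non-empty")
    intervals = np.sort(intervals)
    cond_train, traj = simulate(cond_protocol, params, dyn_ca, dyn_pr,
                                mode=mode, seed=seed)
    end_state = traj[-1]
    seeds = (None if seed is None
             else np.random.SeedSequence(seed).generate_state(intervals.size) >> 1)
    points = []
    for i, delta in enumerate(intervals):
        test = test_protocol_stub.shifted(end_state.t + delta
                                          - test_protocol_stub.ap_times[0])
        carried = end_state.copy()
        sub_seed = None if seeds is None else int(seeds[i])
        test_train, _ = simulate(test, params, dyn_ca, dyn_pr, mode=mode,
                                 seed=sub_seed, initial_state=carried)
        points.append((float(delta), test_train))
    amps = cond_train.amplitudes
    w = min(ss_window, len(amps))
    return RecoveryDataset(cond_epsc1=float(amps[0]),
                           cond_epsc_ss=float(np.mean(amps[-w:])),
                           points=points, cond_train=cond_train)
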