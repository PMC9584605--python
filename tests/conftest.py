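import numpy as np
import pytest

from stpkit.models import (CalciumDynamics, ModelState, PrDynamics,
                           SinglePoolParams)
from stpkit.synthetic import gen_regular_protocol


@pytest.fixture
def static_pr() -> PrDynamics:
    """Release-probability dynamics disabled (constant P_r)."""
    return PrDynamics(pr1=0.165, y_inc1=0.0, z_dec1=0.0, k_y=1.0, k_z=1.0)


@pytest.fixture
def quiet_calcium() -> CalciumDynamics:
    """No per-AP calcium increment: [Ca2+] stays at rest."""
    return CalciumDynamics(ca_rest=50.0, delta_ca_ap=0.0, k_ca=50.0)


def make_depletion_train(pr: float, pool: float, n_stim: int = 40,
                         rate: float = 500.0, q: float = 1.0):
    """Deterministic pure-depletion train: no replenishment, no unpriming,
    constant release probability.  Amplitudes follow the geometric law
    a_j = pr * pool * (1 - pr)**(j-1) (in units of q)."""
    from stpkit.models import simulate

    params = SinglePoolParams(n_total=pool, kf_rest=0.0, sigma=0.0,
                              k_half=1.0, kb=0.0, q=q)
    dyn_ca = CalciumDynamics(ca_rest=50.0, delta_ca_ap=0.0, k_ca=50.0)
    dyn_pr = PrDynamics(pr1=pr, y_inc1=0.0, z_dec1=0.0, k_y=1.0, k_z=1.0)
    init = ModelState(t=0.0, ca=50.0, y=1.0, z=1.0,
                      occupancy=np.array([0.0, float(pool)]))
    protocol = gen_regular_protocol(n_stim, rate)
    train, traj = simulate(protocol, params, dyn_ca, dyn_pr,
                           initial_state=init)
    return train, traj


@pytest.fixture
def depletion_train():
    return make_depletion_train(pr=0.165, pool=2532.0)[0]
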