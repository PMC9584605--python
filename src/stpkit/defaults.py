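"""Shipped default model calibrations for the two synaptic phenotypes.

The package ships with single-pool and sequential two-step parameter sets
for a **control** calyx-of-Held-like terminal and a **mutant**
(Rac1-deficient-like) terminal.  They are calibration products of this
package, constrained by the phenotype anchors of the modelled synapse:

* control: resting release probability 0.08 and a resting
  readily-releasable pool of 2150 docked vesicles;
* mutant: release probability 0.165 and a resting pool of 2532 vesicles;
* the mutant priming rate is higher at sub-µM effective [Ca2+] but
  saturates faster, so that steady-state release is clearly larger at 50 Hz
  yet similar at 500 Hz;
* for the two-step scheme, release probability and total site count are
  shared between phenotypes (resting tightly-docked pools of 691 and 1666
  vesicles); only the priming-step kinetics differ.

Effective-calcium and release-probability dynamics are shared between the
phenotypes within each scheme.
"""

from __future__ import annotations

from .models import CalciumDynamics, PrDynamics, SinglePoolParams, TwoStepParams

__all__ = [
    "CALCIUM_DEFAULT",
    "PR_DYNAMICS_DEFAULT",
    "SINGLE_POOL_CONTROL",
    "SINGLE_POOL_MUTANT",
    "TWO_STEP_PR_DYNAMICS",
    "TWO_STEP_CONTROL",
    "TWO_STEP_MUTANT",
    "default_calibration",
]

#: effective [Ca2+] dynamics, shared across phenotypes (nM, nM, 1/s)
CALCIUM_DEFAULT = CalciumDynamics(ca_rest=50.0, delta_ca_ap=200.0, k_ca=50.0)

#: release-probability dynamics shared across phenotypes (single-pool);
#: pr1 is phenotype-specific and set via dataclasses.replace
PR_DYNAMICS_DEFAULT = PrDynamics(pr1=0.08, y_inc1=0.035, y_max=2.0,
                                 z_dec1=0.02, z_min=0.5, k_y=50.0, k_z=2.0)

SINGLE_POOL_CONTROL = SinglePoolParams(
    n_total=2700.0, kf_rest=0.3518, sigma=10.0, k_half=2.0, kb=0.09,
    q=0.0076)

SINGLE_POOL_MUTANT = SinglePoolParams(
    n_total=3000.0, kf_rest=0.4869, sigma=16.0, k_half=0.8, kb=0.09,
    q=0.0072)

#: two-step scheme: P_r and N_total shared between phenotypes
TWO_STEP_PR_DYNAMICS = PrDynamics(pr1=0.15, y_inc1=0.042, y_max=2.0,
                                  z_dec1=0.02, z_min=0.5, k_y=50.0, k_z=2.0)

TWO_STEP_CONTROL = TwoStepParams(
    n_total=3000.0, k1_rest=2.0, sigma1=30.0, k1_half=2.0, b1=2.0,
    k2_rest=2.394, sigma2=30.0, k2_half=1.0, b2=4.0, q=0.0125)

TWO_STEP_MUTANT = TwoStepParams(
    n_total=3000.0, k1_rest=2.0, sigma1=30.0, k1_half=2.0, b1=2.0,
    k2_rest=20.0, sigma2=40.0, k2_half=0.5, b2=8.0, q=0.0125)

_REGISTRY = {
    ("single_pool", "control"): SINGLE_POOL_CONTROL,
    ("single_pool", "mutant"): SINGLE_POOL_MUTANT,
    ("two_step", "control"): TWO_STEP_CONTROL,
    ("two_step", "mutant"): TWO_STEP_MUTANT,
}


def default_calibration(model: str = "single_pool",
                        condition: str = "control"):
    """Return ``(params, calcium, pr_dynamics)`` for a shipped calibration.

    ``model`` is ``"single_pool"`` or ``"two_step"``; ``condition`` is
    ``"control"`` or ``"mutant"``.
    """
    from dataclasses import replace

    try:
        params = _REGISTRY[(model, condition)]
    except KeyError:
        raise ValueError(f"unknown calibration {(model, condition)!r}") from None
    if model == "single_pool":
        pr1 = 0.08 if condition == "control" else 0.165
        dyn_pr = replace(PR_DYNAMICS_DEFAULT, pr1=pr1)
    else:
        dyn_pr = TWO_STEP_PR_DYNAMICS
    return params, CALCIUM_DEFAULT, dyn_pr
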