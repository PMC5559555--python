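"""Parameter recovery: re-fitting the channel model from its own targets.

Generates clamp targets from the packaged WT preset, perturbs every rate
coefficient by a random factor in [0.7, 1.4], and runs the Nelder-Mead
fit back.  A small final objective means the optimiser recovered a
model indistinguishable from the truth under the clamp protocol.
"""

import numpy as np

from sqt2sim import clamp_and_fit as cf
from sqt2sim.iks_markov import IKsParams, wt_params

truth = wt_params()
eng = cf._Engine(truth)
targets = cf.FitTargets(
    iv={"WT": eng.activation_iv(cf.standard_protocol())},
    shift_target=-36.0,
    wt_tau_deact=eng.tau_deactivation(),
    wt_t_half_act=eng.t_half_activation(),
    po_max_target=float(sum(eng.steady(60.0)[-2:])),
)
rng = np.random.default_rng(3)
perturbed = {
    c: (a * rng.uniform(0.7, 1.4), b * rng.uniform(0.7, 1.4))
    for c, (a, b) in truth.rate_coefficients.items()
}
start = IKsParams("WT", perturbed)
print(f"objective at perturbed start: "
      f"{cf.fit_objective(start, targets):.3e}")
res = cf.fit_params(start, targets, max_iterations=1500, restarts=0)
print(f"objective after fit: {res.objective:.3e} "
      f"({res.n_iterations} iterations)")
print("Values below ~1e-3 mean the I-V curve and both kinetic targets "
      "are met to measurement precision.")
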