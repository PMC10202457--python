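"""Recover a ligand's (beta, gamma) scalings from noisy traces.

Generates mean clearance traces at three doses for a synthetic low-affinity
ligand (beta = 50, gamma = 100), then fits the two scalings by multi-start
least squares in log space.  With three doses both parameters are
identified; a single weak dose would trip the non-identifiability flag.
"""

import pytagsim as pt

params = pt.ModelParameters()
truth = pt.LigandSpec(name="synthetic-EREG", beta=50.0, gamma=100.0)
doses = (2.0, 20.0, 200.0)

times, observed = pt.observed_mean_traces(params, truth, doses,
                                          n_cells=50, noise_cv=0.05,
                                          seed=123)
fit = pt.fit_ligand_parameters(times, observed, params, doses,
                               options=pt.FitOptions(seed=123))

print(f"true  beta = {truth.beta:6.1f}   gamma = {truth.gamma:6.1f}")
print(f"fit   beta = {fit.beta_hat:6.1f}   gamma = {fit.gamma_hat:6.1f}")
print(f"loss = {fit.loss:.2f} over {fit.n_restarts} restarts, "
      f"non-identifiable: {fit.non_identifiable}")
print(f"relative errors: beta {100 * abs(fit.beta_hat - 50) / 50:.1f} %, "
      f"gamma {100 * abs(fit.gamma_hat - 100) / 100:.1f} %")
# 50 cells per dose at 5% multiplicative noise typically recovers both
# scalings within ~10-15%; run pytagsim.recovery_report for the full
# bias/RMSE table over replicates
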