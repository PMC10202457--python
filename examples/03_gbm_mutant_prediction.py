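"""Predicting the effect of GBM-associated EGFR mutations under EREG.

Wild-type receptor bound to epiregulin (a low-affinity ligand) carries
beta = 50, gamma = 100.  The glioblastoma-associated extracellular point
mutations (R84K, A265V) strengthen dimerization of EREG-bound receptors
~650-fold; the model predicts a stronger and more gradual response.
"""

import pytagsim as pt

params = pt.ModelParameters()
res = pt.simulate_gbm_scenario(params, dose_ng_ml=20.0)

for name, tr in res.items():
    t_half, _ = pt.time_to_half_max(tr.clearance, tr.times)
    print(f"{name:>4}: clearance(30 min) = {tr.clearance_at(1800):5.2f} %, "
          f"t_half = {t_half:6.1f} s, "
          f"(beta={tr.ligand.beta:g}, gamma={tr.ligand.gamma:.4g})")

gain = res["gbm"].clearance_at(1800) / res["wt"].clearance_at(1800)
print(f"mutant/wild-type amplitude ratio at 30 min: {gain:.1f}x")
# the mutant trace is both larger at 30 min and slower to reach half-max:
# stabilized ligand-bound dimers accumulate steadily instead of peaking
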