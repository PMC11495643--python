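"""Planted outcome model: septal negative work predicts reverse remodeling.

Builds a synthetic cohort in which the percent ESV reduction is a linear
function (plus noise) of the baseline septal negative-work fraction, then
recovers that relationship by rerunning the pipeline from the meshes. The
recovered R^2 matches the planted value because the pipeline recomputes
the same metric the outcome was generated from.
"""

import numpy as np

from myowork import (SyntheticCohortConfig, cohort_metric_values, make_cohort,
                     regress_outcome)

cfg = SyntheticCohortConfig(n_patients=24, states=("LBBB",), master_seed=42,
                            target_r2=0.7)
cohort = make_cohort(cfg)

x = cohort_metric_values(cohort, "v_f_stnw", "P_LHC", "LBBB")
y = np.array([p.outcome_desv for p in cohort.patients])
fit = regress_outcome(x, y)

print(f"n = {fit.n} synthetic patients, planted R^2 = {cfg.target_r2}")
print(f"recovered: dESV = {fit.intercept:.1f} + {fit.slope:.1f} * V_f_STNW")
print(f"R^2 = {fit.r2:.3f}, p = {fit.p:.2g}")
print("\nA positive slope means patients with more septal myocardium doing "
      "negative work at\nbaseline remodel more after resynchronization - the "
      "relationship the generator plants.")
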