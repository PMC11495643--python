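"""Knock-out sensitivity: which patient-specific inputs carry the signal?

Substitutes one generator parameter at a time by its cohort average,
reruns the pipeline, and reports how the metric-outcome correlation and
the metric itself change. Only knocking out the dyssynchrony parameters
(the planted driver) destroys the correlation.
"""

from myowork import SyntheticCohortConfig, knockout_analysis, make_cohort

cfg = SyntheticCohortConfig(n_patients=10, states=("LBBB",), master_seed=3,
                            target_r2=0.9)
cohort = make_cohort(cfg)

print(f"{'parameter':<14}{'R2 specific':>12}{'R2 knockout':>12}{'nRMSD':>8}")
for parameter in ("geometry", "dyssynchrony", "pressure", "thickness"):
    res = knockout_analysis(cohort, parameter, metric="v_f_stnw", method="P_LHC")
    print(f"{parameter:<14}{res.r2_specific:>12.3f}{res.r2_knockout:>12.3f}"
          f"{res.nrmsd:>8.3f}")

print("\nnRMSD is the RMS change of V_f_STNW under substitution, normalized "
      "by its range.\nLarge nRMSD + collapsed R2 marks the parameter the "
      "outcome actually depends on.")
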