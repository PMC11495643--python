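"""Responder rules and descriptives on the bundled eight-patient cohort.

Applies the echocardiographic (>10 % ESV reduction) and clinical (>= 1
NYHA class improvement) responder definitions to the published outcomes
and recomputes the baseline summary statistics.
"""

from myowork import classify_cohort, crt_cohort

df = classify_cohort(crt_cohort())
print(df[["patient_id", "desv_lv_pct", "nyha_baseline", "nyha_followup",
          "echo_responder", "clinical_responder", "combined_responder"]]
      .to_string(index=False))

print(f"\necho responders     {int(df.echo_responder.sum())}/8  (>10% ESV reduction)")
print(f"clinical responders {int(df.clinical_responder.sum())}/8  (>=1 NYHA class)")
print(f"combined responders {int(df.combined_responder.sum())}/8  (both criteria)")
print(f"\nbaseline: age {df.age.mean():.0f}±{df.age.std():.0f} y, "
      f"QRSd {df.qrsd_ms.mean():.0f}±{df.qrsd_ms.std():.0f} ms, "
      f"EF {df.ef_pct.mean():.0f}±{df.ef_pct.std():.0f} %")
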