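"""Small bundled datasets.

``crt_cohort`` returns the published characteristics and outcomes of a
well-known eight-patient CRT cohort (dyssynchronous heart failure with
LBBB, biventricular pacing, ~6-month echocardiographic follow-up). It is
the worked example for responder classification and cohort descriptives:
age (years), baseline NYHA class, LV ejection fraction (%), QRS duration
(ms), follow-up NYHA class and the percent reduction in LV end-systolic
volume (positive = reverse remodeling).
"""

from __future__ import annotations

import pandas as pd

_CRT_ROWS = [
    # id,    age, nyha0, ef, qrsd, nyha1, desv
    ("BiV1", 84, 3, 38, 156, 2, 12),
    ("BiV2", 65, 4, 26, 148, 1, -2),
    ("BiV3", 79, 3, 35, 162, 2, 16),
    ("BiV4", 64, 2, 25, 130, 1, -12),
    ("BiV5", 61, 3, 17, 182, 2, 15),
    ("BiV6", 55, 2, 32, 119, 1, 59),
    ("BiV7", 68, 4, 21, 140, 4, -36),
    ("BiV8", 54, 3, 29, 120, 2, 7),
]


def crt_cohort() -> pd.DataFrame:
    """Eight-patient CRT cohort: baseline characteristics and outcomes."""
    return pd.DataFrame(
        _CRT_ROWS,
        columns=[
            "patient_id",
            "age",
            "nyha_baseline",
            "ef_pct",
            "qrsd_ms",
            "nyha_followup",
            "desv_lv_pct",
        ],
    )
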