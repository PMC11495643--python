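"""Responder classification, group statistics and sensitivity analysis.

Response rules
--------------
* Echocardiographic responder: > 10 % reduction in LV end-systolic volume
  at follow-up (strict inequality).
* Clinical responder: improvement of at least one NYHA class (the default;
  a strict mode requiring more than one class is available).
* CRT (combined) responder: both of the above.

Group comparisons use two-sided Student's t-tests (pooled variance across
groups, paired within patient for baseline-vs-CRT contrasts) and a
two-factor fixed-effects ANOVA (response x state). Metric-outcome
relationships use ordinary least squares with significance from the
critical values of Pearson's correlation coefficient (equivalently the
t-test on r with n-2 degrees of freedom).

The knock-out procedure replaces one pipeline input parameter at a time by
its cohort average, reruns the whole analysis, and reports how much the
metric-outcome correlation degrades (R^2) and how far the metric moves
from the fully-specific run (normalized RMS deviation, nRMSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import RegionalWorkMetrics

logger = logging.getLogger(__name__)


class CohortError(ValueError):
    pass


@dataclass
class ResponderFlags:
    echo_responder: bool
    clinical_responder: bool
    combined_responder: bool


@dataclass
class PatientRecord:
    """One subject's outcomes, responder flags and per-state/method metrics."""

    patient_id: str
    nyha_baseline: int
    nyha_followup: int
    desv_lv_pct: float
    flags: ResponderFlags | None = None
    metrics: dict = field(default_factory=dict)  # (state, method) -> RegionalWorkMetrics

    def classify(self, strict_clinical: bool = False) -> ResponderFlags:
        self.flags = classify_response(
            self.desv_lv_pct, self.nyha_baseline, self.nyha_followup, strict_clinical
        )
        return self.flags


def classify_response(
    desv_lv_pct: float,
    nyha_baseline: int,
    nyha_followup: int,
    strict_clinical: bool = False,
) -> ResponderFlags:
    """Apply the responder rules to one patient's outcome record.

    Echo response requires desv > 10 (strictly); clinical response an NYHA
    improvement of >= 1 class (``strict_clinical=True`` requires > 1).
    """
    for c in (nyha_baseline, nyha_followup):
        if not 1 <= int(c) <= 4:
            raise CohortError(f"NYHA class {c} outside I-IV")
    echo = float(desv_lv_pct) > 10.0
    improvement = int(nyha_baseline) - int(nyha_followup)
    clinical = improvement > 1 if strict_clinical else improvement >= 1
    return ResponderFlags(echo, clinical, echo and clinical)


def classify_cohort(df: pd.DataFrame, strict_clinical: bool = False) -> pd.DataFrame:
    """Row-wise responder flags for a cohort table.

    Expects columns desv_lv_pct, nyha_baseline, nyha_followup; returns a
    copy with echo_responder / clinical_responder / combined_responder.
    """
    out = df.copy()
    flags = [
        classify_response(r.desv_lv_pct, r.nyha_baseline, r.nyha_followup, strict_clinical)
        for r in df.itertuples()
    ]
    out["echo_responder"] = [f.echo_responder for f in flags]
    out["clinical_responder"] = [f.clinical_responder for f in flags]
    out["combined_responder"] = [f.combined_responder for f in flags]
    return out


def group_compare(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test between two groups of metric values.

    Pooled-variance unpaired test by default; ``paired=True`` for
    within-patient baseline-vs-CRT contrasts. Degenerate (zero-variance)
    comparisons return t = 0, p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("need at least 2 observations per group")
    if paired:
        if len(a) != len(b):
            raise CohortError("paired test needs equal group sizes")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        logger.warning("degenerate variance in group comparison; p set to 1")
        return 0.0, 1.0
    return float(t), float(p)


def two_way_anova(df: pd.DataFrame, value: str = "value",
                  factor_a: str = "response", factor_b: str = "state") -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA with interaction (type-II SS)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


@dataclass
class RegressionResult:
    """Ordinary least squares fit of outcome on a work metric."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def regress_outcome(metric_values, desv_values) -> RegressionResult:
    """Simple linear regression of reverse remodeling on a work metric.

    R^2 is the squared Pearson correlation; the p-value comes from the
    Pearson critical-value test at n - 2 degrees of freedom.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(desv_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise CohortError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise CohortError("zero variance in predictor; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Knock-out sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class KnockoutResult:
    """Effect of substituting one parameter by its cohort average."""

    parameter: str
    metric: str
    r2_specific: float
    r2_knockout: float
    nrmsd: float
    metric_specific: np.ndarray
    metric_knockout: np.ndarray


def nrmsd(knockout_values, specific_values, normalization: str = "range") -> float:
    """Normalized RMS deviation of a knocked-out metric from the specific run.

    RMSD divided by the range (default) or the absolute mean of the
    fully-specific values; zero exactly when the metrics are identical.
    """
    ko = np.asarray(knockout_values, dtype=float)
    ps = np.asarray(specific_values, dtype=float)
    rmsd = float(np.sqrt(np.mean((ko - ps) ** 2)))
    if rmsd == 0.0:
        return 0.0
    if normalization == "range":
        denom = float(np.ptp(ps))
    elif normalization == "mean":
        denom = abs(float(np.mean(ps)))
    else:
        raise CohortError(f"unknown nRMSD normalization {normalization!r}")
    if denom == 0.0:
        raise CohortError("nRMSD undefined: zero normalization denominator")
    return rmsd / denom


def knockout_analysis(
    cohort,
    parameter: str,
    metric: str = "v_f_stnw",
    method: str = "P_LHC",
    state: str = "LBBB",
    normalization: str = "range",
) -> KnockoutResult:
    """Replace one parameter with the cohort average and rerun the pipeline.

    ``cohort`` is a synthetic cohort (see :mod:`myowork.synthetic`); valid
    parameters are the generator inputs the simplified pipeline consumes:
    'geometry', 'dyssynchrony', 'pressure' and 'thickness'. Reports the
    metric-outcome R^2 after substitution and the nRMSD from the
    fully-specific metrics.
    """
    from .synthetic import KNOCKOUT_PARAMETERS, apply_knockout
    from .pipeline import cohort_metric_values

    if parameter not in KNOCKOUT_PARAMETERS:
        raise CohortError(
            f"unknown knock-out parameter {parameter!r}; expected one of {KNOCKOUT_PARAMETERS}")
    desv = np.array([p.outcome_desv for p in cohort.patients])
    specific = cohort_metric_values(cohort, metric=metric, method=method, state=state)
    ko_cohort = apply_knockout(cohort, parameter)
    knocked = cohort_metric_values(ko_cohort, metric=metric, method=method, state=state)
    r2_ps = regress_outcome(specific, desv).r2
    if np.ptp(knocked) == 0:
        logger.warning("knock-out %r removed all metric variance; R^2 = 0", parameter)
        r2_ko = 0.0
    else:
        r2_ko = regress_outcome(knocked, desv).r2
    return KnockoutResult(
        parameter=parameter,
        metric=metric,
        r2_specific=r2_ps,
        r2_knockout=r2_ko,
        nrmsd=nrmsd(knocked, specific, normalization),
        metric_specific=specific,
        metric_knockout=knocked,
    )
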