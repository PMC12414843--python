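"""Expression transforms, signature scoring, quartile stratification and survival tests.

The validation machinery for a protein/gene signature: expression values are
analysed as log2(x+1) of an RSEM-like estimate; the signature score of a
sample is the unweighted arithmetic mean of the member genes' transformed
values; patients are stratified into lower/middle/upper quartile groups of
the score; and the upper vs lower quartiles are compared with Kaplan-Meier
curves and the log-rank test (disease-specific death = event, everything
else censored).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .diffexp import anova_f

#: The six-gene ECM signature: the collagen family members plus THBS1 and LUM.
DEFAULT_SIGNATURE = ("COL2A1", "COL11A1", "COL6A1", "COL6A2", "THBS1", "LUM")


def log2p1(x):
    """log2(x + 1) for non-negative expression estimates."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    out = np.log2(x + 1.0)
    return float(out) if out.ndim == 0 else out


def group_anova(expr: pd.DataFrame, gene: str, groups: pd.Series) -> tuple[float, float]:
    """One-way ANOVA of one gene's expression across sample groups.

    ``expr`` is genes x samples (already transformed); returns (F, p) with p
    from the F distribution with (k-1, n-k) degrees of freedom.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    groups = pd.Series(groups).loc[expr.columns]
    f = anova_f(expr.loc[gene].to_numpy(), groups.to_numpy())
    k = groups.nunique()
    n = len(groups)
    p = float(stats.f.sf(f, k - 1, n - k))
    return f, p


def signature_score(expr: pd.DataFrame, genes=DEFAULT_SIGNATURE) -> pd.Series:
    """Per-sample unweighted arithmetic mean of the member genes' values."""
    genes = list(genes)
    if not genes:
        raise ValueError("signature is empty")
    if len(set(genes)) != len(genes):
        raise ValueError("signature genes must be unique")
    absent = [g for g in genes if g not in expr.index]
    if absent:
        raise KeyError(f"signature genes missing from expression matrix: {absent}")
    return expr.loc[genes].mean(axis=0)


def quartile_groups(scores: pd.Series, lower_q: float = 0.25, upper_q: float = 0.75) -> pd.Series:
    """Label each sample lower / middle / upper by score quartile.

    Q1 and Q3 use the linear-interpolation quantile convention; membership is
    inclusive at both boundaries (score <= Q1 is lower, score >= Q3 is
    upper), so boundary ties go to the extreme groups. Requires >= 8 samples
    and non-degenerate scores.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 8:
        raise ValueError("need at least 8 samples for quartile stratification")
    if scores.nunique() == 1:
        raise ValueError("scores are all identical; quartiles degenerate")
    q1, q3 = np.quantile(scores.to_numpy(), [lower_q, upper_q])
    labels = pd.Series("middle", index=scores.index)
    labels[scores <= q1] = "lower"
    labels[scores >= q3] = "upper"
    return labels


def km_estimator(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step-function table with columns time, survival, at_risk,
    starting at S(0) = 1. Censored subjects leave the risk set after their
    time; survival drops only at event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter().fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
         "at_risk": at_risk.to_numpy()}
    ).reset_index(drop=True)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value).

    At each distinct event time the observed minus hypergeometric-expected
    events in group A are accumulated; the statistic is (sum(O-E))^2 / sum(V).
    Requires both groups non-empty and at least one event overall.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def survival_comparison(table: pd.DataFrame, score_col: str = "score") -> dict:
    """Upper- vs lower-quartile survival comparison on a patient table.

    ``table`` needs columns time, event and the score column. Returns the
    quartile labels, per-group KM curves for the two extreme groups, and the
    log-rank statistic and p-value. Middle quartiles are excluded from the
    comparison.
    """
    labels = quartile_groups(table[score_col])
    lower = table.loc[labels == "lower"]
    upper = table.loc[labels == "upper"]
    stat, p = logrank_test(upper["time"], upper["event"], lower["time"], lower["event"])
    return {
        "groups": labels,
        "km_lower": km_estimator(lower["time"], lower["event"]),
        "km_upper": km_estimator(upper["time"], upper["event"]),
        "logrank_stat": stat,
        "logrank_p": p,
        "n_lower": len(lower),
        "n_upper": len(upper),
    }
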