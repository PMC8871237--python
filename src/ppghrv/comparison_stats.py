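"""ECG-vs-PPG synchrony measures and two-group discrimination statistics.

Synchrony between a simultaneously recorded RR (ECG) and PP (PPG) series
is quantified by the mean squared error of the paired second-scaled
intervals and by relative errors of beat counts and mean intervals, with
the PPG value as the denominator.  Group discrimination uses Welch's
unequal-variance t-test and ROC analysis with trapezoidal AUC, the
Hanley-McNeil standard error, and an asymptotic normal 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .hrv_metrics import HRVReport
from .signal_io import IntervalSeries

__all__ = [
    "ComparisonReport",
    "TTestResult",
    "ROCResult",
    "mse",
    "relative_error",
    "compare_recordings",
    "welch_ttest",
    "roc_auc",
    "reports_to_table",
    "cohort_discrimination",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonReport:
    n_beats_a: int
    n_beats_b: int
    mean_interval_a_ms: float
    mean_interval_b_ms: float
    mse: float                    # s^2, on second-scaled intervals
    rel_err_count_pct: float
    rel_err_mean_pct: float
    n_pairs: int
    n_truncated: int


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float
    ci95: Tuple[float, float]
    orientation: str  # which group was scored as "positive"


def mse(a: IntervalSeries, b: IntervalSeries) -> float:
    """Mean squared error between paired interval series, in s².

    Intervals are converted to seconds and paired index-by-index after
    truncating to the shorter series (the count of dropped intervals is
    logged).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("mse needs two non-empty interval series")
    n = min(len(a), len(b))
    dropped = max(len(a), len(b)) - n
    if dropped:
        logger.info("mse: truncated %d unpaired intervals", dropped)
    xa = a.intervals_ms[:n] / 1000.0
    xb = b.intervals_ms[:n] / 1000.0
    return float(np.mean((xa - xb) ** 2))


def relative_error(ecg_value: float, ppg_value: float) -> float:
    """Relative error in percent: 100 * |ECG - PPG| / PPG.

    The PPG value is the denominator; this is the convention under which
    the published healthy/syncope beat-count and mean-interval error cells
    are all reproduced at two decimals.
    """
    if ppg_value <= 0:
        raise ValueError("relative_error needs a positive PPG denominator")
    return 100.0 * abs(ecg_value - ppg_value) / ppg_value


def compare_recordings(rr: IntervalSeries, pp: IntervalSeries) -> ComparisonReport:
    """Synchrony report for a simultaneous RR (ECG) / PP (PPG) pair."""
    if len(rr) == 0 or len(pp) == 0:
        raise ValueError("compare_recordings needs two non-empty series")
    n_a = len(rr) + 1  # beats bound one more than intervals
    n_b = len(pp) + 1
    mean_a = float(rr.intervals_ms.mean())
    mean_b = float(pp.intervals_ms.mean())
    n_pairs = min(len(rr), len(pp))
    return ComparisonReport(
        n_beats_a=n_a,
        n_beats_b=n_b,
        mean_interval_a_ms=mean_a,
        mean_interval_b_ms=mean_b,
        mse=mse(rr, pp),
        rel_err_count_pct=relative_error(n_a, n_b),
        rel_err_mean_pct=relative_error(mean_a, mean_b),
        n_pairs=n_pairs,
        n_truncated=max(len(rr), len(pp)) - n_pairs,
    )


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance two-sided t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("degenerate input: both groups have zero variance")
    res = spstats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
    )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc ** 2)
        + (n_neg - 1) * (q2 - auc ** 2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(
    values: Sequence[float],
    labels: Sequence[int],
    orient: str = "auto",
) -> ROCResult:
    """ROC curve and trapezoidal AUC with Hanley-McNeil SE and 95% CI.

    ``labels`` are binary (1 = positive class).  The trapezoidal AUC with
    threshold sweeping equals the midrank Mann-Whitney U/(n1*n2).  With
    ``orient='auto'`` the score sign is flipped when AUC < 0.5 so the
    reported AUC is always >= 0.5; the flip is recorded in
    ``orientation``.  ``orient='fixed'`` scores higher-value-is-positive
    as given.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("roc_auc needs exactly two classes present")
    y = (y == classes.max()).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)

    def _curve(scores: np.ndarray):
        fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
        return fpr, tpr, float(np.trapezoid(tpr, fpr))

    fpr, tpr, auc = _curve(v)
    orientation = "higher-positive"
    if orient == "auto" and auc < 0.5:
        fpr, tpr, auc = _curve(-v)
        orientation = "lower-positive"
    elif orient not in ("auto", "fixed"):
        raise ValueError("orient must be 'auto' or 'fixed'")
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    lo = float(np.clip(auc - 1.96 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.96 * se, 0.0, 1.0))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, se=se, ci95=(lo, hi),
                     orientation=orientation)


def reports_to_table(reports: Iterable[HRVReport],
                     labels: Sequence) -> pd.DataFrame:
    """Flatten HRV reports into a per-subject feature table with a
    ``group`` column."""
    rows = []
    for rep in reports:
        row = {}
        if rep.time is not None:
            row.update({
                "sdnn_ms": rep.time.sdnn_ms,
                "sdann_ms": rep.time.sdann_ms,
                "rmssd_ms": rep.time.rmssd_ms,
                "sdindex_ms": rep.time.sdindex_ms,
            })
        if rep.geometric is not None:
            row.update({
                "hrvti": rep.geometric.hrvti,
                "tinn_ms": rep.geometric.tinn_ms,
                "sd1_ms": rep.geometric.sd1_ms,
                "sd2_ms": rep.geometric.sd2_ms,
            })
        if rep.spectral is not None:
            row.update({
                "power_vlf_ms2": rep.spectral.power_vlf_ms2,
                "power_lf_ms2": rep.spectral.power_lf_ms2,
                "power_hf_ms2": rep.spectral.power_hf_ms2,
                "pct_vlf": rep.spectral.pct_vlf,
                "pct_lf": rep.spectral.pct_lf,
                "pct_hf": rep.spectral.pct_hf,
                "lf_hf_ratio": rep.spectral.lf_hf_ratio,
            })
        rows.append(row)
    table = pd.DataFrame(rows)
    table["group"] = list(labels)
    return table


def cohort_discrimination(
    features: pd.DataFrame,
    label_col: str = "group",
    positive_label=None,
) -> pd.DataFrame:
    """Per-metric group discrimination table: means ± SD, Welch p, ROC.

    ``features`` holds one subject per row, HRV metrics in columns, and
    group membership in ``label_col``.  Each metric column yields group
    means/SDs, the Welch t-test, and AUC with Hanley-McNeil SE and
    asymptotic 95% CI.  Metrics that fail (e.g. missing values in a whole
    group) are skipped.
    """
    groups = features[label_col].unique()
    if groups.size != 2:
        raise ValueError("cohort_discrimination needs exactly two groups")
    if positive_label is None:
        positive_label = groups[0]
    neg_label = [g for g in groups if g != positive_label][0]
    rows = []
    for col in features.columns:
        if col == label_col:
            continue
        sub = features[[col, label_col]].dropna()
        a = sub.loc[sub[label_col] == positive_label, col].to_numpy(float)
        b = sub.loc[sub[label_col] == neg_label, col].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        try:
            tt = welch_ttest(a, b)
            labels = np.concatenate((np.ones(len(a)), np.zeros(len(b))))
            roc = roc_auc(np.concatenate((a, b)), labels, orient="auto")
        except ValueError as exc:
            logger.warning("skipping metric %s: %s", col, exc)
            continue
        rows.append({
            "metric": col,
            f"mean_{positive_label}": tt.mean_a,
            f"sd_{positive_label}": tt.sd_a,
            f"mean_{neg_label}": tt.mean_b,
            f"sd_{neg_label}": tt.sd_b,
            "t_stat": tt.t_stat,
            "df": tt.df,
            "p_value": tt.p_value,
            "auc": roc.auc,
            "auc_se": roc.se,
            "auc_ci95_low": roc.ci95[0],
            "auc_ci95_high": roc.ci95[1],
            "orientation": roc.orientation,
        })
    return pd.DataFrame(rows).set_index("metric")
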