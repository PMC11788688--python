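"""Discrimination and calibration statistics for external model validation.

Discrimination: ROC analysis with the AUC computed as the Mann-Whitney
concordance statistic (ties counted 1/2) and its variance from DeLong's
structural components, giving normal-approximation confidence intervals, a
test against AUC = 0.5, and the paired DeLong test for two correlated AUCs
scored on the same patients.

Calibration: the Hosmer-Lemeshow chi-square over quantile bins of predicted
risk, plus the bin-level observed-vs-predicted points used for calibration
plots.  Because the models under validation are *pre-specified* (no
parameter was fitted to the data being scored), the default reference
distribution is chi-square with as many degrees of freedom as bins; the
classical n_bins - 2 convention for models fitted on the same data is
available via ``df_policy="fitted"``.

Operating points: the MedCalc-style "recommended" threshold is the Youden
index maximiser (sensitivity + specificity - 1), ties broken toward the
higher threshold, and a score >= threshold counts as predicted-positive.
The caller decides which outcome class is "positive"; in this package the
default convention is positive = local control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger("sbrt_tcp")

__all__ = [
    "RocResult",
    "CalibrationResult",
    "ConfusionMatrix",
    "CriterionResult",
    "StatsError",
    "roc_auc",
    "delong_paired_test",
    "hosmer_lemeshow",
    "calibration_plot_data",
    "select_criterion",
    "confusion_at",
]


class StatsError(ValueError):
    """Invalid input to a validation statistic."""


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise StatsError(f"scores and labels must be 1-D and equal length, got {s.shape} vs {y.shape}")
    if not np.all(np.isfinite(s)):
        raise StatsError("scores contain NaN or infinite values")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise StatsError(f"labels must be coded 0/1, got values {sorted(uniq)}")
    if uniq != {0, 1}:
        raise StatsError("both outcome classes must be present")
    return s, y.astype(int)


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components V10 (per positive), V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass(frozen=True)
class CriterionResult:
    """A selected probability threshold with its Youden index."""

    threshold: float
    youden_index: float
    degenerate: bool = False  # True when all scores tie and no cut separates anything

    def __float__(self) -> float:  # allow use directly as a threshold
        return self.threshold


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with percent metrics (positive = declared class)."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float
    positive_label: str = "control"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class RocResult:
    """ROC discrimination summary for one model at one horizon."""

    auc: float
    variance: float
    ci95: tuple
    p_value: float  # two-sided vs AUC = 0.5
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    criterion: CriterionResult
    confusion: ConfusionMatrix

    @property
    def sensitivity_pct(self) -> float:
        return self.confusion.sensitivity_pct

    @property
    def specificity_pct(self) -> float:
        return self.confusion.specificity_pct

    @property
    def accuracy_pct(self) -> float:
        return self.confusion.accuracy_pct


@dataclass(frozen=True)
class CalibrationResult:
    """Hosmer-Lemeshow summary plus the bin table used for calibration plots.

    ``bins`` has one row per (possibly merged) risk bin: n, events observed,
    events expected, mean predicted, observed rate, and an over/under flag
    (over-calibrated = predicted above observed; under = predicted below).
    """

    bins: pd.DataFrame
    chi_square: float
    df: int
    p_value: float
    n_bins_requested: int
    n_bins_effective: int
    df_policy: str
    merged: int = 0


def roc_auc(scores, labels) -> RocResult:
    """ROC/AUC with DeLong variance, 95% CI, test vs 0.5 and operating point.

    The AUC is the Mann-Whitney two-sample concordance probability with ties
    counted 1/2; the operating point is the Youden-maximising threshold with
    sensitivity/specificity/accuracy evaluated there.
    """
    s, y = _check_scores_labels(scores, labels)
    auc, v10, v01 = _structural_components(s, y)
    var = _delong_variance(v10, v01)
    se = np.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * norm.sf(abs(z))
        ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
        ci = (auc, auc)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    crit = select_criterion(s, y)
    conf = confusion_at(s, y, crit.threshold)
    return RocResult(
        auc=auc, variance=var, ci95=ci, p_value=float(p),
        fpr=fpr, tpr=tpr, thresholds=thr, criterion=crit, confusion=conf,
    )


def delong_paired_test(scores_a, scores_b, labels):
    """DeLong's test for two correlated AUCs evaluated on the same labels.

    Returns ``(z, p_value, auc_a - auc_b)``.  The covariance of the paired
    structural components enters the variance of the AUC difference, so
    shared patients are handled correctly.  Identical score vectors give
    z = 0 and p exactly 1.
    """
    sa, y = _check_scores_labels(scores_a, labels)
    sb, yb = _check_scores_labels(scores_b, labels)
    if sa.shape != sb.shape:
        raise StatsError("score vectors must have equal length")
    auc_a, v10a, v01a = _structural_components(sa, y)
    auc_b, v10b, v01b = _structural_components(sb, yb)
    m, n = len(v10a), len(v01a)
    var_a = _delong_variance(v10a, v01a)
    var_b = _delong_variance(v10b, v01b)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(v10a, v10b, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(v01a, v01b, ddof=1)[0, 1]) / n
    var_diff = var_a + var_b - 2.0 * cov
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        return 0.0, 1.0, diff
    z = diff / np.sqrt(var_diff)
    return float(z), float(2.0 * norm.sf(abs(z))), float(diff)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _hl_bin_table(pred: np.ndarray, obs: np.ndarray, n_bins: int) -> pd.DataFrame:
    codes = pd.qcut(pred, q=n_bins, labels=False, duplicates="drop")
    if np.all(pd.isna(codes)):  # constant predictions: a single effective bin
        codes = np.zeros(len(pred), dtype=int)
    tbl = (
        pd.DataFrame({"bin": codes, "pred": pred, "obs": obs})
        .groupby("bin", sort=True)
        .agg(n=("obs", "size"), observed=("obs", "sum"), expected=("pred", "sum"),
             mean_predicted=("pred", "mean"))
        .reset_index(drop=True)
    )
    return tbl


def _merge_degenerate_bins(tbl: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Merge bins whose expected events or non-events are ~0 into a neighbour."""
    merged = 0
    rows = tbl.to_dict("records")
    i = 0
    while i < len(rows) and len(rows) > 1:
        r = rows[i]
        if r["expected"] < 1e-12 or (r["n"] - r["expected"]) < 1e-12:
            j = i - 1 if i > 0 else i + 1
            rows[j] = {
                "n": rows[j]["n"] + r["n"],
                "observed": rows[j]["observed"] + r["observed"],
                "expected": rows[j]["expected"] + r["expected"],
                "mean_predicted": 0.0,  # recomputed below
            }
            del rows[i]
            merged += 1
            i = 0  # re-scan; merging can create a new degenerate neighbour
        else:
            i += 1
    out = pd.DataFrame(rows)
    out["mean_predicted"] = out["expected"] / out["n"]
    if merged:
        logger.info("hosmer_lemeshow: merged %d degenerate risk bin(s) into neighbours", merged)
    return out, merged


def hosmer_lemeshow(pred, obs, n_bins: int = 10, df_policy: str = "external") -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over quantile bins of predicted risk.

    chi^2 sums (O - E)^2 / E over both the event and non-event cells of each
    bin.  Ties in predicted risk stay in one bin (quantile binning with
    duplicate edges dropped); bins with zero expected events or non-events
    are merged into a neighbour and logged.  ``df_policy``: "external"
    (default) uses df = effective bins, appropriate for pre-specified
    probabilities; "fitted" uses the classical df = bins - 2.
    """
    p = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise StatsError("pred and obs must be 1-D and of equal length")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatsError("predictions must lie in [0, 1]")
    if len(p) < n_bins:
        raise StatsError(f"need at least n_bins={n_bins} observations, got {len(p)}")
    if df_policy not in ("external", "fitted"):
        raise StatsError(f"df_policy must be 'external' or 'fitted', got {df_policy!r}")

    tbl = _hl_bin_table(p, y, n_bins)
    tbl, merged = _merge_degenerate_bins(tbl)
    o = tbl["observed"].to_numpy()
    e = tbl["expected"].to_numpy()
    nn = tbl["n"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (o - e) ** 2 / e + ((nn - o) - (nn - e)) ** 2 / (nn - e)
    terms = np.where(np.isfinite(terms), terms, 0.0)
    chi_sq = float(terms.sum())
    g = len(tbl)
    df = g if df_policy == "external" else g - 2
    p_value = float(chi2.sf(chi_sq, df)) if df > 0 else float("nan")

    bins = tbl.copy()
    bins["observed_rate"] = bins["observed"] / bins["n"]
    diff = bins["mean_predicted"] - bins["observed_rate"]
    bins["flag"] = np.select([diff > 1e-12, diff < -1e-12], ["over", "under"], default="ok")
    return CalibrationResult(
        bins=bins, chi_square=chi_sq, df=df, p_value=p_value,
        n_bins_requested=n_bins, n_bins_effective=g, df_policy=df_policy, merged=merged,
    )


def calibration_plot_data(pred, obs, n_bins: int = 10, df_policy: str = "external") -> CalibrationResult:
    """Calibration-plot points (mean predicted vs observed rate per bin).

    Same binning and chi-square as :func:`hosmer_lemeshow`; each bin carries
    an over/under flag — "over" when the model predicts a higher probability
    than observed (over-confident), "under" when it predicts lower
    (conservative).  Points are ordered by mean predicted value; the
    identity line is the perfect-calibration reference.
    """
    res = hosmer_lemeshow(pred, obs, n_bins=n_bins, df_policy=df_policy)
    bins = res.bins.sort_values("mean_predicted").reset_index(drop=True)
    return CalibrationResult(
        bins=bins, chi_square=res.chi_square, df=res.df, p_value=res.p_value,
        n_bins_requested=res.n_bins_requested, n_bins_effective=res.n_bins_effective,
        df_policy=res.df_policy, merged=res.merged,
    )


# ---------------------------------------------------------------------------
# operating point
# ---------------------------------------------------------------------------


def select_criterion(scores, labels) -> CriterionResult:
    """Youden-index-maximising threshold (score >= threshold => positive).

    Candidate cutpoints are the distinct observed scores; among ties in the
    Youden index the higher threshold wins.  With all scores tied no
    cutpoint discriminates and the result is flagged degenerate.
    """
    s, y = _check_scores_labels(scores, labels)
    cand = np.unique(s)
    if len(cand) == 1:
        return CriterionResult(threshold=float(cand[0]), youden_index=0.0, degenerate=True)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    pred = s[None, :] >= cand[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    youden = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    best = np.max(youden)
    idx = np.nonzero(youden >= best - 1e-12)[0][-1]  # ties -> higher threshold
    return CriterionResult(threshold=float(cand[idx]), youden_index=float(youden[idx]))


def confusion_at(scores, labels, threshold, positive_label: str = "control") -> ConfusionMatrix:
    """Confusion counts at a threshold; score >= threshold predicts positive."""
    s, y = _check_scores_labels(scores, labels)
    thr = float(threshold)
    if not (0.0 <= thr <= 1.0):
        raise StatsError(f"threshold must lie in [0, 1], got {thr}")
    pred = s >= thr
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        threshold=thr,
        positive_label=positive_label,
    )
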