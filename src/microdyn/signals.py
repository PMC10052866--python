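"""Early-warning signal evaluation: index-vs-abruptness regressions with
FDR control, ROC/AUC diagnostics, and Youden-index thresholds.

Each warning index (energy gap, stable-state entropy, local Lyapunov
stability, local structural stability) at day t is paired with the realized
abruptness at horizon p; abruptness > 0.5 labels an abrupt change.  All
four indices signal instability when HIGH, so the ROC sweep predicts
positive when score >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import ABRUPT_THRESHOLD

INDEX_COLUMNS = ("energy_gap", "stable_state_entropy", "lyapunov", "structural")


class RocError(RuntimeError):
    pass


def build_signal_series(
    indices: pd.DataFrame,
    abruptness: pd.DataFrame,
    p: int = 7,
) -> pd.DataFrame:
    """Join warning indices at day t with abruptness(t, p) and abrupt labels.

    ``indices`` has columns (treatment, replicate, day, <index columns>);
    ``abruptness`` has (treatment, replicate, t, p, abruptness).  Rows
    without both sides (e.g. QC-dropped days, window edges) drop out of the
    join.
    """
    ab = abruptness[abruptness["p"] == p].rename(columns={"t": "day"})
    merged = indices.merge(
        ab[["treatment", "replicate", "day", "abruptness"]],
        on=["treatment", "replicate", "day"],
        how="inner",
    )
    if merged.empty:
        raise ValueError("signal join is empty: no shared (replicate, day) grid")
    merged["is_abrupt"] = merged["abruptness"] > ABRUPT_THRESHOLD
    return merged


def regress_signal(series: pd.DataFrame, index_columns=None) -> pd.DataFrame:
    """Per-replicate OLS of abruptness on each index, BH-FDR within treatment.

    Zero-variance indices yield NA rows; q < 0.05 marks significance.
    """
    index_columns = list(index_columns or [c for c in INDEX_COLUMNS if c in series])
    rows = []
    for (treat, rep), sub in series.groupby(["treatment", "replicate"]):
        for col in index_columns:
            x = sub[col].to_numpy(dtype=float)
            y = sub["abruptness"].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
                rows.append((treat, rep, col, np.nan, np.nan, len(x)))
                continue
            fit = stats.linregress(x, y)
            rows.append((treat, rep, col, fit.slope, fit.pvalue, len(x)))
    out = pd.DataFrame(
        rows, columns=["treatment", "replicate", "index", "slope", "pvalue", "n"]
    )
    out["qvalue"] = np.nan
    for treat, sub in out.groupby("treatment"):
        ok = sub["pvalue"].notna()
        if ok.any():
            _, q, _, _ = multipletests(sub.loc[ok, "pvalue"], method="fdr_bh")
            out.loc[sub.index[ok], "qvalue"] = q
    out["significant"] = out["qvalue"] < 0.05
    return out


@dataclass
class RocCurve:
    thresholds: np.ndarray  # candidate thresholds, descending
    sensitivity: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    auc: float
    youden_threshold: float = field(default=np.nan)
    youden_j: float = field(default=np.nan)


def roc_analysis(scores, labels) -> RocCurve:
    """ROC over the sweep of unique score thresholds (positive iff score >= c).

    AUC by the trapezoidal rule, which equals the normalized Mann-Whitney
    statistic P(score+ > score-) + 0.5 P(tie).  Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise RocError(
            f"ROC needs both classes (positives={n_pos}, negatives={n_neg})"
        )
    uniq = np.unique(scores)[::-1]  # descending: strictest threshold first
    sens = np.empty(len(uniq))
    fpr = np.empty(len(uniq))
    for i, c in enumerate(uniq):
        pred = scores >= c
        sens[i] = (pred & labels).sum() / n_pos
        fpr[i] = (pred & ~labels).sum() / n_neg
    # integrate over the curve including the (0,0) and (1,1) endpoints
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(ys, xs))
    curve = RocCurve(thresholds=uniq, sensitivity=sens, fpr=fpr, auc=auc)
    curve.youden_threshold, curve.youden_j = youden_threshold(curve)
    return curve


def youden_threshold(curve: RocCurve) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties resolve toward sensitivity (the lower threshold).  The returned
    value is the midpoint between the optimal unique score and the next
    lower distinct score, for stability of the cut.
    """
    j = curve.sensitivity - curve.fpr
    best = int(np.flatnonzero(j == j.max())[-1])  # thresholds descend: last = lowest
    c = curve.thresholds[best]
    if best + 1 < len(curve.thresholds):
        c_out = 0.5 * (c + curve.thresholds[best + 1])
    else:
        c_out = c
    return float(c_out), float(j[best])


def pooled_threshold(
    series_by_treatment: dict[str, pd.DataFrame],
    index_columns=None,
) -> pd.DataFrame:
    """Pool (score, label) pairs across treatments, then ROC + Youden per index."""
    pooled = pd.concat(series_by_treatment.values(), ignore_index=True)
    index_columns = list(index_columns or [c for c in INDEX_COLUMNS if c in pooled])
    rows = []
    for col in index_columns:
        ok = pooled[col].notna()
        curve = roc_analysis(pooled.loc[ok, col], pooled.loc[ok, "is_abrupt"])
        rows.append((col, curve.auc, curve.youden_threshold, curve.youden_j))
    return pd.DataFrame(rows, columns=["index", "auc", "threshold", "youden_j"])
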