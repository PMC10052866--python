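"""Diversity metrics and the windowed abruptness statistic.

Abruptness at time t and horizon p is the Bray-Curtis dissimilarity between
the mean relative community composition over the 5-day window [t-4, t] and
that over [t+p, t+p+4].  A value above 0.5 (strict) flags an abrupt
community change: more than half the composition turned over.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import AbundanceTable

ABRUPT_THRESHOLD = 0.5


def bray_curtis(x, y) -> float:
    """sum|x_i - y_i| / sum(x_i + y_i); symmetric, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("compositions must share the taxon set")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("compositions must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero compositions")
    return float(np.abs(x - y).sum() / denom)


def shannon_diversity(x) -> float:
    """Shannon H' in nats after normalization; zero entries ignored."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("Shannon H' undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def _relative_rows(wide: pd.DataFrame) -> pd.DataFrame:
    totals = wide.sum(axis=1)
    rel = wide.div(totals.where(totals > 0, np.nan), axis=0).fillna(0.0)
    return rel


def abruptness(wide: pd.DataFrame, t: int, p: int, window: int = 5) -> float:
    """Abruptness at day t, horizon p, for one replicate.

    ``wide`` is the days x taxa matrix of one replicate community (raw or
    relative scale; each day is renormalized before windows are averaged, so
    the statistic is invariant to per-sample rescaling).
    """
    before_days = range(t - window + 1, t + 1)
    after_days = range(t + p, t + p + window)
    missing = [d for d in (*before_days, *after_days) if d not in wide.index]
    if missing:
        raise ValueError(f"abruptness windows need days {missing} which are absent")
    rel = _relative_rows(wide)
    before = rel.loc[list(before_days)].mean(axis=0).to_numpy()
    after = rel.loc[list(after_days)].mean(axis=0).to_numpy()
    return bray_curtis(before, after)


def abruptness_series(
    wide: pd.DataFrame, p: int, window: int = 5
) -> pd.DataFrame:
    """Abruptness for every valid t of one replicate; flags abrupt days.

    Valid t are those where both 5-day windows fit inside the observed days.
    """
    days = wide.index.to_numpy()
    rows = []
    for t in days:
        lo, hi = t - window + 1, t + p + window - 1
        if lo < days.min() or hi > days.max():
            continue
        try:
            a = abruptness(wide, int(t), p, window=window)
        except ValueError:
            continue
        rows.append((int(t), p, a, a > ABRUPT_THRESHOLD))
    return pd.DataFrame(rows, columns=["t", "p", "abruptness", "is_abrupt"])


def abruptness_table(
    table: AbundanceTable, p: int, window: int = 5
) -> pd.DataFrame:
    """Abruptness series for every replicate of every treatment."""
    out = []
    for treat in table.treatments:
        for rep in table.replicates(treat):
            ser = abruptness_series(table.wide(treat, rep), p, window=window)
            ser.insert(0, "treatment", treat)
            ser.insert(1, "replicate", rep)
            out.append(ser)
    return pd.concat(out, ignore_index=True)


def diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Shannon H' per sample (treatment, replicate, day)."""
    rows = []
    for treat in table.treatments:
        for rep in table.replicates(treat):
            wide = table.wide(treat, rep)
            for day, row in wide.iterrows():
                vals = row.to_numpy()
                h = shannon_diversity(vals) if vals.sum() > 0 else np.nan
                rows.append((treat, rep, int(day), h))
    return pd.DataFrame(rows, columns=["treatment", "replicate", "day", "shannon_h"])
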