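"""Spike-in calibration of read counts to copy concentrations, plus the
quality filters and gap interpolation applied before any dynamics analysis.

Each sample carries five internal-standard sequences at known copy
concentrations.  A per-sample calibration curve (least squares through the
origin of reads on nM) converts taxon read counts into absolute copy
concentrations.  Samples whose curve correlates poorly (Pearson r < 0.7) or
that have too few taxon reads (< 350) are dropped; single missing days are
filled with the mean of the flanking days; taxa present in fewer than 5
samples of every replicate are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ReadTable
from .tables import AbundanceTable


class CalibrationError(RuntimeError):
    pass


@dataclass
class StandardCurve:
    sample_id: str
    slope: float  # reads per nM
    pearson_r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a standard curve needs at least 2 points")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass
class QcReport:
    dropped_low_r: list = field(default_factory=list)
    dropped_low_reads: list = field(default_factory=list)
    interpolated: list = field(default_factory=list)
    retained_taxa: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_low_r": list(self.dropped_low_r),
            "dropped_low_reads": list(self.dropped_low_reads),
            "interpolated": [list(x) for x in self.interpolated],
            "retained_taxa": list(self.retained_taxa),
        }


def fit_standard_curve(spike_reads, spike_nM, sample_id: str = "") -> StandardCurve:
    """Least squares through the origin of reads on nM, plus plain Pearson r.

    Pearson r of a constant vector is defined as 0 (the sample is then
    dropped downstream rather than propagating NaN).
    """
    reads = np.asarray(spike_reads, dtype=float)
    nm = np.asarray(spike_nM, dtype=float)
    if reads.shape != nm.shape or reads.size < 2:
        raise ValueError("spike reads and concentrations must align, length >= 2")
    if np.any(nm <= 0):
        raise ValueError("spike concentrations must be positive")
    if np.all(reads == 0):
        raise CalibrationError(f"sample {sample_id!r} uncalibratable: all spike reads zero")
    slope = float((reads @ nm) / (nm @ nm))
    if reads.std() == 0 or nm.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(reads, nm)[0, 1])
    return StandardCurve(sample_id=sample_id, slope=slope, pearson_r=r, n_points=reads.size)


def calibrate_sample(taxon_reads, curve: StandardCurve) -> np.ndarray:
    """Concentration (nM) = reads / slope, elementwise."""
    if curve.slope <= 0:
        raise CalibrationError(f"sample {curve.sample_id!r}: nonpositive slope")
    return np.asarray(taxon_reads, dtype=float) / curve.slope


def quality_filter(
    sample_stats: pd.DataFrame,
    min_r: float = 0.7,
    min_reads: int = 350,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop samples with Pearson r < min_r or total taxon reads < min_reads.

    ``sample_stats`` has one row per sample with columns ``sample_id``,
    ``pearson_r`` and ``total_reads``.  Thresholds are strict ("less than"),
    so boundary values are kept.  Idempotent.
    """
    report = QcReport()
    low_r = sample_stats["pearson_r"] < min_r
    low_n = sample_stats["total_reads"] < min_reads
    report.dropped_low_r = sample_stats.loc[low_r, "sample_id"].tolist()
    report.dropped_low_reads = sample_stats.loc[low_n, "sample_id"].tolist()
    kept = sample_stats[~(low_r | low_n)].reset_index(drop=True)
    return kept, report


def interpolate_missing(
    table: AbundanceTable, report: QcReport | None = None
) -> AbundanceTable:
    """Fill missing days per (replicate, taxon) series.

    Interior gaps (single or runs) are linearly interpolated between
    flanking observed values; gaps at series ends copy the nearest observed
    value.  Observed values are never altered; every filled (replicate, day)
    is flagged in the QcReport.
    """
    report = report if report is not None else QcReport()
    pieces = []
    filled: set = set()
    for (treat, rep), sub in table.data.groupby(["treatment", "replicate"]):
        wide = sub.pivot(index="day", columns="taxon_id", values="abundance")
        full_days = pd.RangeIndex(int(wide.index.min()), int(wide.index.max()) + 1, name="day")
        wide = wide.reindex(full_days)
        missing_days = wide.index[wide.isna().any(axis=1)]
        out = wide.interpolate(method="linear", limit_direction="both", axis=0)
        out = out.ffill().bfill()
        for d in missing_days:
            filled.add((treat, rep, int(d)))
        long = out.reset_index().melt(id_vars="day", var_name="taxon_id", value_name="abundance")
        long.insert(0, "treatment", treat)
        long.insert(1, "replicate", rep)
        pieces.append(long)
    report.interpolated = sorted(filled)
    data = pd.concat(pieces, ignore_index=True)
    return AbundanceTable(data[["treatment", "replicate", "day", "taxon_id", "abundance"]],
                          flags={"interpolated": sorted(filled)})


def prevalence_filter(
    table: AbundanceTable, min_presence: int = 5, report: QcReport | None = None
) -> AbundanceTable:
    """Keep a taxon iff some replicate has >= min_presence samples with it present."""
    d = table.data
    pres = d[d["abundance"] > 0]
    counts = pres.groupby(["taxon_id", "treatment", "replicate"]).size()
    keep = counts[counts >= min_presence].index.get_level_values("taxon_id").unique()
    out = d[d["taxon_id"].isin(keep)].reset_index(drop=True)
    if report is not None:
        report.retained_taxa = sorted(keep.tolist())
    return AbundanceTable(out, flags=dict(table.flags))


def calibrate_reads(
    reads: ReadTable,
    min_r: float = 0.7,
    min_reads: int = 350,
    min_presence: int = 5,
    interpolate: bool = True,
) -> tuple[AbundanceTable, QcReport]:
    """Full calibration pipeline: curves -> concentrations -> QC -> interpolation.

    Returns the calibrated, filtered, gap-filled abundance table and the
    QC report listing dropped samples, interpolated days and retained taxa.
    """
    report = QcReport()
    keys = ["treatment", "replicate", "day"]
    spike_g = reads.spike_reads.groupby(keys, sort=True)
    stats_rows, conc_rows = [], []
    for key, spikes in spike_g:
        sid = "{}_r{}_d{}".format(*key)
        taxa = reads.taxon_reads[
            (reads.taxon_reads[keys] == pd.Series(key, index=keys)).all(axis=1)
        ]
        total = int(taxa["reads"].sum())
        try:
            curve = fit_standard_curve(
                spikes["reads"].to_numpy(), spikes["known_nM"].to_numpy(), sid
            )
        except CalibrationError:
            stats_rows.append((sid, key, -np.inf, total))
            continue
        stats_rows.append((sid, key, curve.pearson_r, total))
        conc = calibrate_sample(taxa["reads"].to_numpy(), curve)
        for tid, c in zip(taxa["taxon_id"], conc):
            conc_rows.append((*key, tid, c))
    stats = pd.DataFrame(
        {
            "sample_id": [r[0] for r in stats_rows],
            "pearson_r": [r[2] for r in stats_rows],
            "total_reads": [r[3] for r in stats_rows],
        }
    )
    kept, qc = quality_filter(stats, min_r=min_r, min_reads=min_reads)
    report.dropped_low_r = qc.dropped_low_r
    report.dropped_low_reads = qc.dropped_low_reads
    kept_ids = set(kept["sample_id"])
    key_by_sid = {r[0]: r[1] for r in stats_rows}
    kept_keys = {key_by_sid[s] for s in kept_ids}
    conc = pd.DataFrame(conc_rows, columns=["treatment", "replicate", "day", "taxon_id", "abundance"])
    mask = conc.apply(lambda r: (r["treatment"], r["replicate"], r["day"]) in kept_keys, axis=1)
    conc = conc[mask].reset_index(drop=True)
    if conc.empty:
        raise CalibrationError("no samples survived quality filtering")
    table = AbundanceTable(conc)
    if interpolate:
        table = interpolate_missing(table, report)
    table = prevalence_filter(table, min_presence=min_presence, report=report)
    table.flags["qc_dropped"] = sorted(set(stats["sample_id"]) - kept_ids)
    return table, report
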