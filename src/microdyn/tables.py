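"""Long-format abundance tables shared by all analysis stages.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with one
row per (treatment, replicate, day, taxon) cell holding a 16S copy
concentration (nM).  :class:`AbundanceTable` is a thin wrapper adding the
pivots and normalizations every stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["treatment", "replicate", "day", "taxon_id", "abundance"]


@dataclass
class AbundanceTable:
    """Replicate x day x taxon grid of copy concentrations.

    Parameters
    ----------
    data : DataFrame
        Long-format table with columns ``treatment, replicate, day,
        taxon_id, abundance``.  Abundances are nonnegative copy
        concentrations (nM) after calibration, or raw simulator abundances.
    """

    data: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"abundance table missing columns: {missing}")
        dup = self.data.duplicated(subset=["treatment", "replicate", "day", "taxon_id"])
        if dup.any():
            rows = self.data.index[dup].tolist()[:10]
            raise ValueError(f"duplicate (replicate, day, taxon) rows at index {rows}")
        if (self.data["abundance"] < 0).any():
            raise ValueError("negative abundances in table")

    # -- accessors ---------------------------------------------------------
    @property
    def treatments(self) -> list:
        return sorted(self.data["treatment"].unique().tolist())

    def replicates(self, treatment) -> list:
        sub = self.data[self.data["treatment"] == treatment]
        return sorted(sub["replicate"].unique().tolist())

    @property
    def taxa(self) -> list:
        return sorted(self.data["taxon_id"].unique().tolist())

    def wide(self, treatment, replicate) -> pd.DataFrame:
        """Days x taxa matrix for a single replicate community."""
        sub = self.data[
            (self.data["treatment"] == treatment)
            & (self.data["replicate"] == replicate)
        ]
        w = sub.pivot(index="day", columns="taxon_id", values="abundance")
        return w.sort_index()

    def subset(self, treatment=None, replicates=None) -> "AbundanceTable":
        d = self.data
        if treatment is not None:
            d = d[d["treatment"] == treatment]
        if replicates is not None:
            d = d[d["replicate"].isin(list(replicates))]
        return AbundanceTable(d.reset_index(drop=True), flags=dict(self.flags))

    def relative(self) -> "AbundanceTable":
        """Per-sample relative abundances (all-zero samples stay zero)."""
        d = self.data.copy()
        totals = d.groupby(["treatment", "replicate", "day"])["abundance"].transform("sum")
        with np.errstate(invalid="ignore", divide="ignore"):
            d["abundance"] = np.where(totals > 0, d["abundance"] / totals, 0.0)
        return AbundanceTable(d, flags=dict(self.flags))

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(
            0,
            "sample_id",
            out["treatment"].astype(str)
            + "_r"
            + out["replicate"].astype(str)
            + "_d"
            + out["day"].astype(str),
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long(cls, data: pd.DataFrame) -> "AbundanceTable":
        return cls(data[COLUMNS].reset_index(drop=True))


def metadata_frame(table: AbundanceTable) -> pd.DataFrame:
    """Sample metadata (treatment, replicate, day) for a table."""
    meta = (
        table.data[["treatment", "replicate", "day"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    meta.insert(
        0,
        "sample_id",
        meta["treatment"].astype(str)
        + "_r"
        + meta["replicate"].astype(str)
        + "_d"
        + meta["day"].astype(str),
    )
    return meta
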