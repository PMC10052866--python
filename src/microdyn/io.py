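"""TSV/JSON readers and writers for tables, models and thresholds."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import PairwiseMaxEnt
from .simulate import ReadTable
from .tables import COLUMNS, AbundanceTable


def write_abundance(table: AbundanceTable, path, metadata_path=None) -> None:
    table.to_tsv(path)
    if metadata_path is not None:
        from .tables import metadata_frame

        metadata_frame(table).to_csv(metadata_path, sep="\t", index=False)


def read_abundance_table(path, metadata_path=None) -> AbundanceTable:
    """Read a long-format abundance TSV, validating the schema.

    Duplicate (replicate, day, taxon) rows are rejected; if a metadata TSV
    is given, every sample must appear in it.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    table = AbundanceTable(df[COLUMNS].copy())
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t")
        have = set(zip(meta["treatment"], meta["replicate"], meta["day"]))
        samples = set(
            zip(df["treatment"], df["replicate"], df["day"])
        )
        orphans = samples - have
        if orphans:
            raise ValueError(f"samples missing from metadata: {sorted(orphans)[:5]}")
    # flag day gaps (permitted pre-interpolation)
    gaps = []
    for (treat, rep), sub in df.groupby(["treatment", "replicate"]):
        days = np.sort(sub["day"].unique())
        if len(days) > 1 and not np.array_equal(days, np.arange(days[0], days[-1] + 1)):
            gaps.append((treat, rep))
    if gaps:
        table.flags["day_gaps"] = gaps
    return table


def write_reads(reads: ReadTable, taxon_path, spike_path) -> None:
    reads.taxon_reads.to_csv(taxon_path, sep="\t", index=False)
    reads.spike_reads.to_csv(spike_path, sep="\t", index=False)


def read_reads(taxon_path, spike_path) -> ReadTable:
    return ReadTable(
        pd.read_csv(taxon_path, sep="\t"),
        pd.read_csv(spike_path, sep="\t"),
    )


def write_maxent_model(model: PairwiseMaxEnt, taxon_ids, path) -> None:
    """Serialize a fitted model: taxa, h, upper-triangle J, diagnostics."""
    s = model.S_
    iu = np.triu_indices(s, k=1)
    payload = {
        "taxon_ids": list(taxon_ids),
        "h": model.h_.tolist(),
        "J_upper": model.J_[iu].tolist(),
        "n_iter": int(model.n_iter_),
        "max_abs_log_ratio": float(model.max_abs_log_ratio_),
        "converged": bool(model.converged_),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_maxent_model(path) -> tuple[PairwiseMaxEnt, list]:
    payload = json.loads(Path(path).read_text())
    h = np.asarray(payload["h"], dtype=float)
    s = len(h)
    J = np.zeros((s, s))
    iu = np.triu_indices(s, k=1)
    J[iu] = payload["J_upper"]
    J[(iu[1], iu[0])] = J[iu]
    model = PairwiseMaxEnt().set_parameters(h, J)
    model.n_iter_ = payload["n_iter"]
    model.max_abs_log_ratio_ = payload["max_abs_log_ratio"]
    model.converged_ = payload["converged"]
    return model, payload["taxon_ids"]
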