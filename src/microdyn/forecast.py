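"""Leave-one-replicate-out population forecasting and community assembly.

For each target replicate the reference state-space database is built from
the other replicates of the same treatment.  Per-taxon forecasts (simplex,
S-map with optimized theta, S-map with theta = 0, or a no-change null) are
scored by R^2 between predicted and observed abundance, then de-standardized
and compiled into predicted community compositions whose Bray-Curtis error
against the observed composition measures community-level skill.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import edm
from .metrics import bray_curtis
from .tables import AbundanceTable

METHODS = ("null", "simplex", "smap_opt", "smap_linear")


@dataclass
class ForecastConfig:
    horizons: tuple = (1, 2, 3, 4, 5, 6, 7)
    methods: tuple = ("null", "simplex", "smap_opt", "smap_linear")
    E_range: tuple = edm.E_RANGE
    theta_grid: tuple = edm.THETA_GRID
    fixed_E: int | None = None  # skip E selection when set

    def __post_init__(self) -> None:
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}")
        if any(p < 1 for p in self.horizons):
            raise ValueError("horizons must be >= 1")


@dataclass
class ForecastRun:
    predictions: pd.DataFrame  # treatment, target_replicate, taxon, day, p, method, E, theta, predicted, observed
    scale: pd.DataFrame  # replicate, taxon, mean, sd (z-transform inverse)
    skill: pd.DataFrame = field(default_factory=pd.DataFrame)


def _series_by_replicate(table: AbundanceTable, treatment, taxon) -> dict:
    out = {}
    for rep in table.replicates(treatment):
        wide = table.wide(treatment, rep)
        if taxon in wide.columns:
            out[rep] = wide[taxon].to_numpy(dtype=float)
    return out


def r_squared(pred, obs) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ss_tot = ((obs - obs.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0 if np.allclose(pred, obs) else -np.inf
    return float(1.0 - ((obs - pred) ** 2).sum() / ss_tot)


def run_population_forecasts(
    table: AbundanceTable,
    treatment,
    config: ForecastConfig | None = None,
    targets=None,
    qc_excluded: set | None = None,
) -> ForecastRun:
    """Forecast every taxon of every target replicate at each horizon.

    The reference database for a target replicate is built from all other
    replicates of the treatment (leave-one-replicate-out).  Null forecasts
    return the current value unchanged.  Days listed in ``qc_excluded``
    (as (replicate, day) pairs) are dropped from skill statistics.
    """
    config = config or ForecastConfig()
    reps = table.replicates(treatment)
    if len(reps) < 2:
        raise ValueError("leave-one-replicate-out forecasting needs >= 2 replicates")
    targets = list(targets) if targets is not None else reps
    qc_excluded = qc_excluded or set()
    taxa = sorted(
        table.data.loc[table.data["treatment"] == treatment, "taxon_id"].unique()
    )
    wides = {rep: table.wide(treatment, rep) for rep in reps}

    pred_rows = []
    scale_rows = []
    for target_rep in targets:
        refs = [r for r in reps if r != target_rep]
        assert target_rep not in refs
        wide_t = wides[target_rep]
        days = wide_t.index.to_numpy()
        for taxon in taxa:
            raw_t = wide_t[taxon].to_numpy(dtype=float)
            z_t, mu_t, sd_t, const_t = edm.zstandardize(raw_t)
            scale_rows.append((target_rep, taxon, mu_t, sd_t))
            # standardize each reference replicate within itself
            ref_series = {}
            for rep in refs:
                if taxon not in wides[rep].columns:
                    continue
                raw_r = wides[rep][taxon].to_numpy(dtype=float)
                z_r, _, _, const_r = edm.zstandardize(raw_r)
                if not const_r:
                    ref_series[rep] = z_r
            use_edm = bool(ref_series) and not const_t
            if use_edm and config.fixed_E is None:
                try:
                    E = edm.select_embedding_dimension(
                        z_t, ref_series, E_range=config.E_range, p=1
                    )
                except edm.EdmError:
                    use_edm = False
                    E = 1
            else:
                E = config.fixed_E or 1
            theta_opt = None
            if use_edm and ("smap_opt" in config.methods):
                theta_opt = edm.optimize_theta(
                    z_t, ref_series, E, grid=config.theta_grid, p=1
                )
            for p in config.horizons:
                # valid forecast times: embedding exists at t, observation at t+p
                try:
                    vecs, ts = edm.embed_series(z_t, E)
                except edm.EdmError:
                    continue
                ok = ts + p < len(z_t)
                if not ok.any():
                    continue
                vecs_ok, ts_ok = vecs[ok], ts[ok]
                obs_z = z_t[ts_ok + p]
                obs_raw = raw_t[ts_ok + p]
                for method in config.methods:
                    if method == "null":
                        pred_raw = raw_t[ts_ok]
                        theta, e_used = np.nan, np.nan
                    elif not use_edm:
                        continue
                    else:
                        ref = edm.Embedding.from_series(ref_series, E, p)
                        if method == "simplex":
                            model = edm.SimplexProjection().fit(ref.X, ref.y)
                            theta = np.nan
                        elif method == "smap_opt":
                            theta = theta_opt if theta_opt is not None else 0.0
                            model = edm.SMap(theta=theta).fit(ref.X, ref.y)
                        elif method == "smap_linear":
                            theta = 0.0
                            model = edm.SMap(theta=0.0).fit(ref.X, ref.y)
                        pred_z = model.predict(vecs_ok)
                        pred_raw = edm.destandardize(pred_z, mu_t, sd_t)
                        e_used = E
                    for t_i, pr, ob in zip(ts_ok, pred_raw, obs_raw):
                        day = int(days[t_i + p])
                        pred_rows.append(
                            (treatment, target_rep, taxon, day, p, method,
                             e_used, theta, pr, ob)
                        )
    predictions = pd.DataFrame(
        pred_rows,
        columns=["treatment", "target_replicate", "taxon", "day", "p",
                 "method", "E", "theta", "predicted", "observed"],
    )
    scale = pd.DataFrame(scale_rows, columns=["replicate", "taxon", "mean", "sd"])
    run = ForecastRun(predictions=predictions, scale=scale)
    run.skill = score_skill(run, qc_excluded=qc_excluded)
    return run


def score_skill(run: ForecastRun, qc_excluded: set | None = None) -> pd.DataFrame:
    """Per (target, taxon, p, method) R^2, excluding QC-dropped days."""
    qc_excluded = qc_excluded or set()
    d = run.predictions
    if qc_excluded:
        mask = [
            (rep, day) not in qc_excluded
            for rep, day in zip(d["target_replicate"], d["day"])
        ]
        d = d[mask]
    rows = []
    for key, sub in d.groupby(["treatment", "target_replicate", "taxon", "p", "method"]):
        rows.append((*key, r_squared(sub["predicted"], sub["observed"]), len(sub)))
    return pd.DataFrame(
        rows,
        columns=["treatment", "target_replicate", "taxon", "p", "method", "r2", "n_days"],
    )


def assemble_community_forecast(
    run: ForecastRun, method: str, p: int, target_replicate=None
) -> pd.DataFrame:
    """Compile per-taxon forecasts into predicted relative compositions.

    Negative de-standardized predictions are floored at 0 before
    renormalization.  Returns per-day Bray-Curtis error between predicted
    and observed compositions; a day whose predicted composition is all
    zero is flagged with NaN error.
    """
    d = run.predictions
    d = d[(d["method"] == method) & (d["p"] == p)]
    if target_replicate is not None:
        d = d[d["target_replicate"] == target_replicate]
    if d.empty:
        raise ValueError(f"no predictions for method={method!r}, p={p}")
    rows = []
    for (treat, rep, day), sub in d.groupby(["treatment", "target_replicate", "day"]):
        pred = np.maximum(sub["predicted"].to_numpy(dtype=float), 0.0)
        obs = np.maximum(sub["observed"].to_numpy(dtype=float), 0.0)
        if pred.sum() == 0 or obs.sum() == 0:
            rows.append((treat, rep, day, np.nan, True))
            continue
        err = bray_curtis(pred / pred.sum(), obs / obs.sum())
        rows.append((treat, rep, day, err, False))
    return pd.DataFrame(
        rows, columns=["treatment", "target_replicate", "day", "bc_error", "degenerate"]
    )


def reference_size_experiment(
    table: AbundanceTable,
    treatment,
    sizes=None,
    config: ForecastConfig | None = None,
    targets=None,
    taxa=None,
    p: int = 1,
) -> pd.DataFrame:
    """S-map skill as a function of reference-database size.

    For each target replicate and each size k, every C(R-1, k) subset of
    the other replicates serves as the reference; reports per
    (taxon, target, k, subset) R^2 of optimized-theta S-map forecasts.
    """
    config = config or ForecastConfig(methods=("smap_opt",))
    reps = table.replicates(treatment)
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates")
    targets = list(targets) if targets is not None else reps
    sizes = list(sizes) if sizes is not None else list(range(1, len(reps)))
    all_taxa = sorted(
        table.data.loc[table.data["treatment"] == treatment, "taxon_id"].unique()
    )
    taxa = list(taxa) if taxa is not None else all_taxa
    rows = []
    for target_rep in targets:
        others = [r for r in reps if r != target_rep]
        wide_t = table.wide(treatment, target_rep)
        for taxon in taxa:
            z_t, mu_t, sd_t, const_t = edm.zstandardize(wide_t[taxon].to_numpy(float))
            if const_t:
                continue
            z_refs = {}
            for rep in others:
                z_r, _, _, c = edm.zstandardize(
                    table.wide(treatment, rep)[taxon].to_numpy(float)
                )
                if not c:
                    z_refs[rep] = z_r
            for k in sizes:
                for subset in itertools.combinations(sorted(z_refs), k):
                    ref = {r: z_refs[r] for r in subset}
                    if config.fixed_E is None:
                        try:
                            E = edm.select_embedding_dimension(
                                z_t, ref, E_range=config.E_range, p=p
                            )
                        except edm.EdmError:
                            continue
                    else:
                        E = config.fixed_E
                    theta = edm.optimize_theta(z_t, ref, E, grid=config.theta_grid, p=p)
                    lib = edm.Embedding.from_series(ref, E, p)
                    vecs, ts = edm.embed_series(z_t, E)
                    ok = ts + p < len(z_t)
                    model = edm.SMap(theta=theta).fit(lib.X, lib.y)
                    pred = model.predict(vecs[ok])
                    r2 = r_squared(pred, z_t[ts[ok] + p])
                    rows.append((treatment, target_rep, taxon, k, ",".join(map(str, subset)), theta, E, r2))
    return pd.DataFrame(
        rows,
        columns=["treatment", "target_replicate", "taxon", "k", "subset", "theta", "E", "r2"],
    )
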