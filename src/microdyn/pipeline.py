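"""End-to-end pipeline: simulate -> calibrate -> metrics -> landscape ->
forecast -> stability -> signals, with per-stage artifacts and seeded
determinism throughout."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, edm, forecast, io, landscape, metrics, signals, stability
from .simulate import SpikeInSet, fixture_params, simulate_glv, simulate_reads
from .tables import AbundanceTable

log = logging.getLogger("microdyn")

STAGES = ("simulate", "calibrate", "metrics", "landscape", "forecast",
          "stability", "signals")


@dataclass
class RunConfig:
    """Flat configuration for the whole pipeline; YAML round-trippable."""

    out_dir: str = "microdyn_out"
    fixture: str = "bistable"
    input_abundance: str | None = None  # pre-calibrated table; skips simulate+calibrate
    seed: int = 0
    # simulation / sequencing
    n_replicates: int = 8
    n_days: int = 110
    reads_per_sample: int = 20_000
    # QC
    min_r: float = 0.7
    min_reads: int = 350
    min_presence: int = 5
    # metrics
    window: int = 5
    horizons: tuple = (1, 2, 3, 4, 5, 6, 7)
    signal_horizon: int = 7
    # landscape
    learning_rate: float = 0.1
    max_iter: int = 50_000
    tol: float = 1e-4
    n_walks: int = 1000
    signal_day_stride: int = 1
    # EDM
    E_range: tuple = tuple(range(1, 21))
    theta_grid: tuple = edm.THETA_GRID
    fixed_E: int | None = None
    forecast_methods: tuple = ("null", "simplex", "smap_opt", "smap_linear")
    jacobian_m: int = 8
    jacobian_theta: float = 1.0  # local weighting; 0 would give one global Jacobian
    stages: tuple = STAGES

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for k in ("horizons", "E_range", "theta_grid", "forecast_methods", "stages"):
            setattr(cfg, k, tuple(getattr(cfg, k)))
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the artifact directory.

    Every artifact directory is stamped with the config hash and seed; a
    fixed config and seed give byte-identical result tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed}
    (out / "run_info.json").write_text(json.dumps(stamp, indent=1))
    config.to_yaml(out / "config.yaml")
    stages = tuple(config.stages)
    table: AbundanceTable | None = None
    timings = {}

    def _run(stage, fn):
        nonlocal table
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # abort with stage name and context
            raise StageError(stage, exc) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", stage, timings[stage])

    # ------------------------------------------------------------- simulate
    def _simulate():
        nonlocal table
        params = fixture_params(
            config.fixture,
            n_replicates=config.n_replicates,
            n_days=config.n_days,
            seed=config.seed,
        )
        truth = simulate_glv(params, treatment=config.fixture)
        io.write_abundance(truth, out / "truth_abundance.tsv", out / "metadata.tsv")
        reads = simulate_reads(
            truth, SpikeInSet(), reads_per_sample=config.reads_per_sample,
            seed=config.seed + 1,
        )
        io.write_reads(reads, out / "taxon_reads.tsv", out / "spike_reads.tsv")
        table = truth

    # ------------------------------------------------------------ calibrate
    def _calibrate():
        nonlocal table
        reads = io.read_reads(out / "taxon_reads.tsv", out / "spike_reads.tsv")
        calibrated, report = calibration.calibrate_reads(
            reads, min_r=config.min_r, min_reads=config.min_reads,
            min_presence=config.min_presence,
        )
        calibrated.to_tsv(out / "calibrated_abundance.tsv")
        (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        table = calibrated

    def _load():
        nonlocal table
        if table is None:
            if config.input_abundance is not None:
                table = io.read_abundance_table(config.input_abundance)
            elif (out / "calibrated_abundance.tsv").exists():
                table = io.read_abundance_table(out / "calibrated_abundance.tsv")
            else:
                raise FileNotFoundError("no abundance table available; run earlier stages")

    # -------------------------------------------------------------- metrics
    def _metrics():
        _load()
        ab = pd.concat(
            [metrics.abruptness_table(table, p, window=config.window)
             for p in config.horizons],
            ignore_index=True,
        )
        ab.to_csv(out / "abruptness.tsv", sep="\t", index=False)
        metrics.diversity_table(table).to_csv(out / "diversity.tsv", sep="\t", index=False)

    # ------------------------------------------------------------ landscape
    def _landscape():
        _load()
        rows = []
        for treat in table.treatments:
            reps = table.replicates(treat)
            for target in reps:
                others = [r for r in reps if r != target]
                bcm = landscape.binarize(table, treatment=treat, replicates=others)
                model = landscape.PairwiseMaxEnt(
                    learning_rate=config.learning_rate,
                    max_iter=config.max_iter, tol=config.tol,
                ).fit(bcm)
                io.write_maxent_model(
                    model, bcm.taxon_ids, out / f"maxent_{treat}_r{target}.json"
                )
                wide = table.wide(treat, target)
                pres_all = wide[bcm.taxon_ids] > 0
                days = wide.index.to_numpy()[:: config.signal_day_stride]
                rng = np.random.default_rng(config.seed + 1000 + int(target))
                for day in days:
                    state = pres_all.loc[day].to_numpy().astype(np.int8)
                    gap = landscape.energy_gap(state, model)
                    ent = landscape.stable_state_entropy(
                        state, model, n_walks=config.n_walks, seed=rng
                    )
                    rows.append((treat, target, int(day), gap, ent))
        pd.DataFrame(
            rows, columns=["treatment", "replicate", "day",
                           "energy_gap", "stable_state_entropy"]
        ).to_csv(out / "landscape_signals.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- forecast
    def _forecast():
        _load()
        cfg = forecast.ForecastConfig(
            horizons=tuple(config.horizons), methods=tuple(config.forecast_methods),
            E_range=tuple(config.E_range), theta_grid=tuple(config.theta_grid),
            fixed_E=config.fixed_E,
        )
        runs = []
        for treat in table.treatments:
            run = forecast.run_population_forecasts(table, treat, cfg)
            runs.append(run)
            run.predictions.to_csv(out / f"forecast_{treat}.tsv", sep="\t", index=False)
            run.skill.to_csv(out / f"forecast_skill_{treat}.tsv", sep="\t", index=False)
            comm = forecast.assemble_community_forecast(
                run, method=cfg.methods[-1], p=config.signal_horizon
            )
            comm.to_csv(out / f"community_forecast_{treat}.tsv", sep="\t", index=False)

    # ------------------------------------------------------------ stability
    def _stability():
        _load()
        frames = []
        for treat in table.treatments:
            frames.append(
                stability.stability_table(
                    table, treat, m=config.jacobian_m, theta=config.jacobian_theta
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            out / "stability.tsv", sep="\t", index=False
        )

    # -------------------------------------------------------------- signals
    def _signals():
        _load()
        land = pd.read_csv(out / "landscape_signals.tsv", sep="\t")
        stab = pd.read_csv(out / "stability.tsv", sep="\t")
        idx = land.merge(stab[["treatment", "replicate", "day", "lyapunov", "structural"]],
                         on=["treatment", "replicate", "day"], how="outer")
        ab = pd.read_csv(out / "abruptness.tsv", sep="\t")
        series = signals.build_signal_series(idx, ab, p=config.signal_horizon)
        series.to_csv(out / "signal_series.tsv", sep="\t", index=False)
        reg = signals.regress_signal(series)
        reg.to_csv(out / "signal_regressions.tsv", sep="\t", index=False)
        thr_rows = []
        for col in signals.INDEX_COLUMNS:
            if col not in series:
                continue
            ok = series[col].notna()
            try:
                curve = signals.roc_analysis(series.loc[ok, col], series.loc[ok, "is_abrupt"])
            except signals.RocError as exc:
                log.warning("ROC skipped for %s: %s", col, exc)
                continue
            thr_rows.append(
                {"index": col, "auc": curve.auc,
                 "threshold": curve.youden_threshold, "youden_j": curve.youden_j}
            )
        (out / "thresholds.json").write_text(json.dumps(thr_rows, indent=1))

    fns = {
        "simulate": _simulate, "calibrate": _calibrate, "metrics": _metrics,
        "landscape": _landscape, "forecast": _forecast,
        "stability": _stability, "signals": _signals,
    }
    for stage in STAGES:
        if stage in stages and (stage not in ("simulate", "calibrate")
                                or config.input_abundance is None):
            _run(stage, fns[stage])
    (out / "timings.json").write_text(json.dumps(timings, indent=1))
    return out
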