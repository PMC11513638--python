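"""End-to-end orchestration: one call reproduces the full synthetic study.

``run_pipeline`` executes filter -> trait construction -> covariate
preparation -> model roster -> summaries, writes per-model posterior tables
(mode, median, 95% HPD per term), trend results and a machine-readable JSON
report of every estimate, and logs seeds, versions and timings.  Trait
covariates (neighbour counts, densities) are computed from the complete
nest map before any female-level filter, because removed focal females
still count as neighbours of the retained ones; the age partition and
standardization are computed on the analysed records.
"""

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

from . import __version__
from .animal_model import MCMCConfig, ModelSpec, fit_glmm_animal, fit_random_regression
from .errors import ConfigError
from .pedigree import read_pedigree
from .prep import prepare_model_table
from .simulate import TrueParams, default_study_params, simulate_dataset
from .summaries import (
    ReactionNormEstimates,
    dic,
    posterior_contrast,
    variance_decomposition,
)
from .traits import apply_study_filters, build_trait_table
from .trends import annual_mean_correlation, annual_trend

log = logging.getLogger("colonyqg")

MODEL_ROSTER = (
    "partitioned",
    "partitioned_extended",
    "intercept_rr_baseline",
    "rr_individual",
    "rr_genetic",
)

_PARTITIONED_FIXED = (
    "mean_age",
    "delta_age",
    "mean_age:delta_age",
    "year_std",
    "colony_density_std",
    "island_density_std",
)

REPORT_REQUIRED_KEYS = (
    "config_hash",
    "seed",
    "versions",
    "data",
    "pedigree",
    "trends",
    "models",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable to/from YAML or JSON."""

    out_dir: str = "colonyqg_run"
    seed: int = 0
    # data source: either paths to nest/pedigree CSVs, or simulation settings
    nests_path: str | None = None
    pedigree_path: str | None = None
    simulate: dict = field(default_factory=dict)  # kwargs of simulate_dataset
    truth: str | dict = "default_study"  # 'default_study', 'base', or TrueParams dict
    # trait options
    radius_m: float = 2.0
    window_days: int = 28
    filter_mode: str = "known_age"  # or 'presumed_dead'
    last_observation_year: int | None = None
    response_column: str = "count"  # 'count' (simulated) or 'neighbour_count'
    # model roster and chain settings
    models: tuple = ("partitioned", "intercept_rr_baseline", "rr_genetic")
    mcmc: dict = field(default_factory=dict)
    save_chains: bool = False

    def __post_init__(self):
        self.models = tuple(self.models)
        unknown = [m for m in self.models if m not in MODEL_ROSTER]
        if unknown:
            raise ConfigError(f"unknown model(s) in roster: {unknown}")
        if not self.models:
            raise ConfigError("model roster must be non-empty")
        if self.filter_mode == "presumed_dead" and self.last_observation_year is None:
            raise ConfigError("presumed_dead filtering requires last_observation_year")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _resolve_truth(config: RunConfig) -> TrueParams:
    if isinstance(config.truth, dict):
        d = dict(config.truth)
        for key in ("G2", "P2"):
            if key in d and d[key] is not None:
                d[key] = np.asarray(d[key], dtype=float)
        d.setdefault("seed", config.seed)
        return TrueParams(**d)
    if config.truth == "default_study":
        return default_study_params(seed=config.seed)
    if config.truth == "base":
        return TrueParams(seed=config.seed)
    raise ConfigError(f"unknown truth preset: {config.truth!r}")


def _load_data(config: RunConfig):
    if config.nests_path is not None:
        if config.pedigree_path is None:
            raise ConfigError("nests_path given without pedigree_path")
        nests = pd.read_csv(config.nests_path)
        pedigree = read_pedigree(config.pedigree_path)
        return nests, pedigree, None
    truth = _resolve_truth(config)
    sim = simulate_dataset(
        truth=truth,
        seed=config.seed,
        radius_m=config.radius_m,
        window_days=config.window_days,
        **config.simulate,
    )
    return sim.nests, sim.pedigree, sim


def _mcmc_config(config: RunConfig, offset: int) -> MCMCConfig:
    kwargs = dict(config.mcmc)
    kwargs.setdefault("seed", config.seed + 1000 * offset)
    return MCMCConfig(**kwargs)


def _summary_records(summary: pd.DataFrame) -> dict:
    return {
        str(k): {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
        for k, row in summary.iterrows()
    }


def _fit_one(name, table, A, config, offset):
    cfg = _mcmc_config(config, offset)
    response = config.response_column
    if name == "partitioned":
        spec = ModelSpec(response=response, fixed=_PARTITIONED_FIXED)
        return fit_glmm_animal(table, A, spec, cfg)
    if name == "partitioned_extended":
        spec = ModelSpec(
            response=response,
            fixed=_PARTITIONED_FIXED + ("laying_date_std", "wall_distance_std"),
        )
        return fit_glmm_animal(table, A, spec, cfg)
    if name == "intercept_rr_baseline":
        spec = ModelSpec(
            response=response,
            fixed=("age_std", "year_std", "colony_density_std", "island_density_std"),
            residual="by_age_class",
        )
        return fit_glmm_animal(table, A, spec, cfg)
    if name == "rr_individual":
        return fit_random_regression(table, A, "individual", cfg=cfg, response=response)
    if name == "rr_genetic":
        return fit_random_regression(table, A, "genetic+pe", cfg=cfg, response=response)
    raise ConfigError(f"unknown model: {name}")  # pragma: no cover


def validate_report(report: dict) -> None:
    """Check the stable report schema; raises ConfigError on violation."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ConfigError(f"report missing key(s): {missing}")
    for name, model in report["models"].items():
        for key in ("estimates", "dic"):
            if key not in model:
                raise ConfigError(f"model {name!r} report missing {key!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to disk)."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings = {}
    try:
        stage = "load"
        nests, pedigree, sim = _load_data(config)
        log.info(
            "loaded %d nest records, pedigree of %d (config %s, seed %d)",
            len(nests), len(pedigree), config.content_hash(), config.seed,
        )
        timings[stage] = time.time() - t0

        stage = "trait"
        t = time.time()
        base_cols = ["female_id", "year", "island", "x", "y", "laying_date", "age"]
        carried = [c for c in ("count",) if c in nests.columns]
        table = build_trait_table(
            nests[base_cols + carried],
            radius_m=config.radius_m,
            window_days=config.window_days,
        )
        n_before = len(table)
        table = apply_study_filters(
            table, config.filter_mode, config.last_observation_year
        )
        table, scalers = prepare_model_table(table)
        if config.response_column not in table.columns:
            raise ConfigError(
                f"response column {config.response_column!r} absent from trait table"
            )
        log.info("trait table: %d of %d records retained", len(table), n_before)
        timings[stage] = time.time() - t

        stage = "pedigree"
        t = time.time()
        pruned = pedigree.prune(table["female_id"].astype(str).unique())
        A = pruned.a_matrix()
        ped_stats = pruned.stats()
        timings[stage] = time.time() - t

        stage = "trends"
        t = time.time()
        trends = {
            "neighbours": annual_trend(
                table, "neighbours", count_column=config.response_column,
                seed=config.seed,
            ),
            "age": annual_trend(table, "age"),
            "laying_date": annual_trend(table, "laying_date"),
            "age_laying_correlation": annual_mean_correlation(table),
        }
        timings[stage] = time.time() - t

        models_report = {}
        for k, name in enumerate(config.models):
            stage = f"model:{name}"
            t = time.time()
            chains = _fit_one(name, table, A, config, offset=k)
            summary = chains.summary()
            summary.to_csv(out_dir / f"{name}_summary.csv")
            if config.save_chains:
                chains.save(out_dir / f"{name}_chains")
            entry = {"estimates": _summary_records(summary), "dic": dic(chains)}
            if name in ("partitioned", "partitioned_extended"):
                decomp = variance_decomposition(chains)
                entry["variance_decomposition"] = _summary_records(decomp.summary())
                contrast = posterior_contrast(
                    chains["beta:mean_age"], chains["beta:delta_age"]
                )
                entry["selective_disappearance"] = {
                    k2: (float(v) if isinstance(v, (int, float, np.floating)) else bool(v))
                    for k2, v in contrast.items()
                    if k2 != "samples"
                }
            if name == "rr_individual":
                entry["reaction_norm"] = _summary_records(
                    ReactionNormEstimates.from_chains(chains, "I").summary()
                )
            if name == "rr_genetic":
                entry["reaction_norm"] = {
                    **_summary_records(
                        ReactionNormEstimates.from_chains(chains, "A").summary()
                    ),
                    **_summary_records(
                        ReactionNormEstimates.from_chains(chains, "PE").summary()
                    ),
                }
            models_report[name] = entry
            timings[stage] = time.time() - t
            log.info("fitted %s in %.1f s (DIC %.1f)", name, timings[stage], entry["dic"])

        report = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "versions": {
                "colonyqg": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "data": {
                "n_obs": int(len(table)),
                "n_females": int(table["female_id"].nunique()),
                "n_years": int(table["year"].nunique()),
                "records_before_filter": int(n_before),
                "mean_count": float(table[config.response_column].mean()),
                "sd_count": float(table[config.response_column].std(ddof=0)),
                "mean_age": float(table["age"].mean()),
                "sd_age": float(table["age"].std(ddof=0)),
            },
            "pedigree": ped_stats,
            "trends": trends,
            "models": models_report,
        }
        if sim is not None:
            report["truth"] = json.loads(sim.truth.to_json())
        validate_report(report)
        table.to_csv(out_dir / "trait_table.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str)
        )
        log.info("pipeline complete in %.1f s; timings: %s", time.time() - t0, timings)
        return report
    except Exception as exc:
        stale = out_dir / "STALE"
        stale.write_text(f"pipeline aborted at stage {stage}: {exc}\n")
        log.error("pipeline aborted at stage %r: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
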