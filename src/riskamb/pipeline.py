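"""End-to-end run orchestration: simulate -> filter -> modelfree -> fit ->
compare -> correlate, with config, stable seeding and a reproducibility
manifest.

A run is fully determined by (config, seed): the global seed fans out to
stage-specific sub-seeds by stable hashing, so adding or re-running a stage
never perturbs another stage's randomness.  Each stage reads the previous
stage's CSVs from the output directory, which makes runs resumable and lets
a pipeline start from externally supplied choice data instead of the
simulator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, Marginal, simulate_cohort
from .comparison import compare_models
from .consistency import manipulation_checks, run_consistency_suite
from .filters import apply_exclusions
from .fitting import CV_GRID, fit_cohort, make_start_grid
from .io import load_dataset, write_table
from .modelfree import choice_proportions
from .trials import build_default_trialset

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "modelfree", "fit", "compare", "correlate")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    stages: tuple[str, ...] = ALL_STAGES
    cohort: CohortSpec = field(default_factory=CohortSpec)
    variant: str = "ordinal"
    compare_variants: tuple[str, ...] = ("ordinal", "rating")
    grid_step: float = 0.5
    cv_folds: int = 5
    #: when set, skip simulation and read these externally supplied tables
    input_paths: dict | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.variant not in ("ordinal", "rating"):
            raise ValueError(f"unknown model variant {self.variant!r}")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    cohort_raw = raw.pop("cohort", {})
    for dist_key in ("alpha_dist", "beta_dist", "gamma_dist"):
        if dist_key in cohort_raw and isinstance(cohort_raw[dist_key], dict):
            cohort_raw[dist_key] = Marginal(**cohort_raw[dist_key])
    cohort = CohortSpec(**cohort_raw)
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    if "compare_variants" in raw:
        raw["compare_variants"] = tuple(raw["compare_variants"])
    return RunConfig(cohort=cohort, **raw)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed; independent of stage ordering."""
    return int(
        np.random.default_rng(
            [int(seed) % (2**31), zlib.crc32(stage.encode())]
        ).integers(0, 2**31)
    )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dataset_paths(outdir: Path, config: RunConfig) -> dict:
    if config.input_paths:
        return dict(config.input_paths)
    return {
        name: outdir / f"{name}.csv"
        for name in ("trials", "choices", "ratings", "participants", "truth")
    }


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Stage failures abort the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed, skipped = [], [s for s in ALL_STAGES if s not in config.stages]
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            log.info("stage %s", stage)
            _STAGES[stage](config, outdir)
            completed.append(stage)
    except Exception as exc:
        _write_manifest(config, outdir, completed, skipped, error=f"{stage}: {exc}")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    _write_manifest(config, outdir, completed, skipped)
    return outdir


def _write_manifest(config, outdir, completed, skipped, error=None) -> None:
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": asdict(config),
        "stages_completed": completed,
        "stages_skipped": skipped,
        "error": error,
    }
    (Path(outdir) / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    trialset = build_default_trialset(stage_seed(config.seed, "trials"))
    spec = CohortSpec(
        **{**asdict(config.cohort), "seed": stage_seed(config.seed, "simulate")}
    )
    # asdict flattens Marginal dataclasses into dicts; rebuild them
    for key in ("alpha_dist", "beta_dist", "gamma_dist"):
        val = getattr(spec, key)
        if isinstance(val, dict):
            object.__setattr__(spec, key, Marginal(**val))
    tables = simulate_cohort(spec, trialset)
    write_table(trialset.to_frame(), outdir / "trials.csv")
    for name, df in tables.items():
        write_table(df, outdir / f"{name}.csv")


def _load(config: RunConfig, outdir: Path):
    paths = _dataset_paths(outdir, config)
    if "truth" in paths and not Path(paths["truth"]).exists():
        paths.pop("truth")
    return load_dataset(paths, strict=True)


def _stage_filter(config: RunConfig, outdir: Path) -> None:
    ds = _load(config, outdir)
    outcome = apply_exclusions(ds.choices, ds.participants, ds.trials)
    write_table(outcome.report, outdir / "exclusions.csv")
    write_table(outcome.analysis_choices, outdir / "analysis_choices.csv")
    write_table(outcome.modeling_choices, outdir / "modeling_choices.csv")
    log.info("exclusions by rule:\n%s", outcome.counts())


def _stage_modelfree(config: RunConfig, outdir: Path) -> None:
    ds = _load(config, outdir)
    analysis = pd.read_csv(outdir / "analysis_choices.csv")
    analysis["chose_lottery"] = analysis["chose_lottery"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    summary = choice_proportions(analysis, ds.trials)
    write_table(summary, outdir / "modelfree.csv")


def _read_choices(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["chose_lottery"] = df["chose_lottery"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    return df


def _stage_fit(config: RunConfig, outdir: Path) -> None:
    ds = _load(config, outdir)
    modeling = _read_choices(outdir / "modeling_choices.csv")
    grid = make_start_grid(step=config.grid_step)
    fits = fit_cohort(
        modeling, ds.trials, variant=config.variant, ratings=ds.ratings, grid=grid
    )
    write_table(fits, outdir / "fits.csv")


def _stage_compare(config: RunConfig, outdir: Path) -> None:
    ds = _load(config, outdir)
    modeling = _read_choices(outdir / "modeling_choices.csv")
    selection = compare_models(
        modeling,
        ds.trials,
        ds.ratings,
        variants=config.compare_variants,
        k=config.cv_folds,
        seed=stage_seed(config.seed, "compare"),
        grid=make_start_grid(step=config.grid_step),
        cv_grid=CV_GRID,
    )
    write_table(selection.table, outdir / "comparison.csv")
    (outdir / "selection.json").write_text(
        json.dumps(
            {"selected": selection.selected, "discordant": selection.discordant},
            indent=2,
        )
        + "\n"
    )


def _stage_correlate(config: RunConfig, outdir: Path) -> None:
    ds = _load(config, outdir)
    modelfree = pd.read_csv(outdir / "modelfree.csv")
    fits_path = outdir / "fits.csv"
    fits = pd.read_csv(fits_path) if fits_path.exists() else None
    correlations = run_consistency_suite(modelfree, fits)
    checks = manipulation_checks(modelfree, ds.ratings)
    write_table(correlations, outdir / "correlations.csv")
    write_table(checks, outdir / "checks.csv")


_STAGES = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "modelfree": _stage_modelfree,
    "fit": _stage_fit,
    "compare": _stage_compare,
    "correlate": _stage_correlate,
}
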