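"""Scenario orchestration: generation -> assays -> statistics -> report.

Each named scenario ties the stages into one reproducible run.  Stage seeds
are derived from the master seed by SHA-256 of ``"<seed>:<stage>"`` (first
four bytes, modulo 2^31), so adding a stage never perturbs the draws of the
others.  Logging goes to standard error as ``key=value`` lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agg6ma import class_mean_relative, relative_density_table
from .errors import ConfigurationError
from .lmpcr_assay import default_dpni_design, fold_change, simulate_assay
from .methylome_sim import (MethylationTrajectory, default_trajectories,
                            emit_modcalls, sample_pool)
from .survival import (expected_lifespan, intervention_profile, mean_lifespan,
                       percent_extension, simulate_cohort)
from .synthgenome import DEFAULT_SEED, build_genome, default_config

log = logging.getLogger(__name__)

SCENARIOS = ("assay_age_fold", "density_ratios", "methylation_slope",
             "lifespan_recovery")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed split from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class ScenarioConfig:
    seed: int
    scenario: str = "assay_age_fold"
    genotype: str = "wildtype"
    ages: list[int] | None = None
    molecules: int = 10_000
    reads: int = 20_000
    cohort_n: int = 120
    replicates: int = 20
    world_seed: int = DEFAULT_SEED
    outdir: str | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        for name in ("molecules", "reads", "cohort_n", "replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario config; unknown keys are rejected,
    missing keys take defaults (seed is mandatory)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
    if "seed" not in raw:
        raise ConfigurationError("config must set a seed")
    return ScenarioConfig(**raw)


def dump_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, float] = field(default_factory=dict)
    meta: dict[str, object] = field(default_factory=dict)


def _log_stage(stage: str, seed: int, started: float) -> None:
    log.info("stage=%s seed=%d elapsed=%.2fs", stage, seed, time.time() - started)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _active_families(build):
    return [fam.family_id for fam in build.family_index.values() if fam.active]


def _scenario_assay_age_fold(config: ScenarioConfig, bundle: ReportBundle) -> None:
    """Restriction-ligation assay at a young and an aged day for every
    active family; headline is the mean aged/young fold of relative 6mA."""
    build = build_genome(default_config(config.world_seed))
    traj = MethylationTrajectory.te_active()
    days = config.ages or [1, 11]
    young, old = min(days), max(days)
    rows, folds = [], []
    for fam in _active_families(build):
        design = default_dpni_design(build, fam)
        readouts = {}
        for day in (young, old):
            seed = stage_seed(config.seed, f"assay:{fam}:day{day}")
            t0 = time.time()
            pool = sample_pool(traj, day, config.genotype, config.molecules,
                               seed, locus=fam)
            readouts[day] = simulate_assay(pool, design)
            _log_stage(f"assay:{fam}:day{day}", seed, t0)
            rows.append((fam, day, readouts[day].target_signal,
                         readouts[day].control_signal,
                         readouts[day].relative_level))
        fold = fold_change(readouts[old], readouts[young])
        folds.append(fold)
        bundle.summary[f"fold_6ma_{fam}"] = fold
    bundle.tables["assay_readouts"] = pd.DataFrame(
        rows, columns=["family_id", "age_days", "target_signal",
                       "control_signal", "relative_level"])
    bundle.summary["fold_6ma"] = float(np.mean(folds))


def _scenario_density_ratios(config: ScenarioConfig, bundle: ReportBundle) -> None:
    """SMRT-style density analysis at a young and a mid-age day: per-class
    relative densities and the gene/TE ratio at each day."""
    build = build_genome(default_config(config.world_seed))
    trajectories = default_trajectories()
    families = list(build.family_index.values())
    days = config.ages or [1, 5]
    tables = []
    for day in days:
        seed = stage_seed(config.seed, f"modcalls:day{day}")
        t0 = time.time()
        calls = emit_modcalls(build, trajectories, day, config.genotype, seed)
        table = relative_density_table(calls, build.features, families)
        _log_stage(f"modcalls:day{day}", seed, t0)
        table.insert(0, "age_days", day)
        tables.append(table)
        te_mean = class_mean_relative(table, "te_family")
        bundle.summary[f"te_over_gene_day{day}"] = te_mean
        bundle.summary[f"gene_over_te_day{day}"] = 1.0 / te_mean
    bundle.tables["density"] = pd.concat(tables, ignore_index=True)


def _scenario_methylation_slope(config: ScenarioConfig, bundle: ReportBundle,
                                n_replicates: int = 5) -> None:
    """Relative 6mA level versus age in wild type and the long-lived
    insulin-pathway mutant; headline is the OLS slope ratio (expected 0.5)."""
    build = build_genome(default_config(config.world_seed))
    design = default_dpni_design(build, "Tc1-like")
    traj = MethylationTrajectory.te_active()
    days = config.ages or list(range(1, 12))
    rows = []
    for genotype in ("wildtype", "daf-2"):
        for rep in range(n_replicates):
            for day in days:
                seed = stage_seed(config.seed, f"slope:{genotype}:{rep}:{day}")
                pool = sample_pool(traj, day, genotype, config.molecules, seed)
                rows.append((genotype, rep, day,
                             simulate_assay(pool, design).relative_level))
    table = pd.DataFrame(rows, columns=["genotype", "replicate", "age_days",
                                        "relative_level"])
    slopes = {}
    for genotype, grp in table.groupby("genotype"):
        slopes[genotype] = float(np.polyfit(grp["age_days"],
                                            grp["relative_level"], 1)[0])
    bundle.tables["slope_levels"] = table
    bundle.summary["slope_wildtype"] = slopes["wildtype"]
    bundle.summary["slope_daf2"] = slopes["daf-2"]
    bundle.summary["slope_ratio_daf2"] = slopes["daf-2"] / slopes["wildtype"]


def _scenario_lifespan_recovery(config: ScenarioConfig, bundle: ReportBundle) -> None:
    """Replicated cohort pairs under the packaged intervention profiles;
    headlines are the recovered percent extensions and the daf-2 mean
    lifespan ratio."""
    control = intervention_profile("control")
    rows = []
    for name in ("te_rnai_single", "piwi_soma", "daf2"):
        profile = intervention_profile(name)
        extensions, ratios = [], []
        for rep in range(config.replicates):
            seed_c = stage_seed(config.seed, f"cohort:control:{name}:{rep}")
            seed_t = stage_seed(config.seed, f"cohort:{name}:{rep}")
            cohort_c = simulate_cohort(control, config.cohort_n, seed_c)
            cohort_t = simulate_cohort(profile, config.cohort_n, seed_t)
            ext = percent_extension(cohort_t, cohort_c)
            extensions.append(ext)
            ratios.append(mean_lifespan(cohort_t)[0] / mean_lifespan(cohort_c)[0])
            rows.append((name, rep, mean_lifespan(cohort_c)[0],
                         mean_lifespan(cohort_t)[0], ext))
        if name == "daf2":
            bundle.summary["daf2_lifespan_ratio"] = float(np.mean(ratios))
        else:
            bundle.summary[f"extension_{name}"] = float(np.mean(extensions))
    bundle.tables["lifespan"] = pd.DataFrame(
        rows, columns=["profile", "replicate", "control_mean", "treated_mean",
                       "percent_extension"])
    bundle.summary["expected_control_mean"] = expected_lifespan(control)


_SCENARIO_RUNNERS = {
    "assay_age_fold": _scenario_assay_age_fold,
    "density_ratios": _scenario_density_ratios,
    "methylation_slope": _scenario_methylation_slope,
    "lifespan_recovery": _scenario_lifespan_recovery,
}


def run_scenario(config: ScenarioConfig) -> ReportBundle:
    """Execute one named scenario; deterministic for a fixed config."""
    bundle = ReportBundle(meta={
        "version": __version__, "scenario": config.scenario,
        "seed": config.seed, "world_seed": config.world_seed,
    })
    t0 = time.time()
    try:
        _SCENARIO_RUNNERS[config.scenario](config, bundle)
    except Exception as exc:
        log.error("stage=%s status=failed cause=%r", config.scenario, exc)
        raise
    log.info("scenario=%s elapsed=%.2fs", config.scenario, time.time() - t0)
    return bundle


def write_report(bundle: ReportBundle, outdir: str | Path) -> dict[str, Path]:
    """Write per-stage TSV tables and a machine-readable summary JSON with
    stable column and key order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in bundle.tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths[name] = path
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump({"meta": bundle.meta,
                   "summary": {k: bundle.summary[k] for k in sorted(bundle.summary)}},
                  fh, indent=2, sort_keys=False)
        fh.write("\n")
    paths["summary"] = summary_path
    return paths
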