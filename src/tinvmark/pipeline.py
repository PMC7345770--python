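"""End-to-end orchestration: simulate/load -> profiles -> DEGs ->
consensus -> time-invariance -> features -> LOOCV -> stability report ->
external validation -> enrichment.

One :func:`run` call executes the whole discovery-and-evaluation flow on
either a synthetic experiment (with ground-truth recovery scoring) or a
directory of real study TSVs, writing every intermediate table plus a log
of all resolved settings so filter attrition is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import deg as degmod
from . import enrichment as enr
from . import evaluation as ev
from . import io as tio
from . import models as mdl
from . import simulate as sim  # noqa: F401 (bound before the package
# re-exports the simulate() function; keep submodule access via sim.*)
from .errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class StudyInput:
    """Paths of one real study's TSVs."""

    dataset_id: str
    platform: str
    expression_path: str
    metadata_path: str


@dataclass
class RunConfig:
    """Fully resolved settings for one pipeline run.

    Exactly one of ``simulation`` and ``studies`` must be given; ``seed``
    is mandatory and drives every stochastic component.
    """

    seed: int
    out_dir: str
    simulation: sim.SimulationConfig | None = None
    studies: list[StudyInput] = field(default_factory=list)
    labels_path: str | None = None
    genemap_path: str | None = None
    catalog_path: str | None = None
    alpha: float = 0.05
    fold_threshold: float = 1.5
    dose_group: str = "high"
    control_policy: str = "pooled"
    test_variant: str = "welch"
    direction_rule: str = "fold"
    required_exposures: tuple[str, ...] | None = None
    source_exposure: str | None = None
    algorithms: tuple[str, ...] = ("rf",)
    rf_trees: int | str = "auto"
    rf_tree_grid: tuple[int, ...] = mdl.DEFAULT_TREE_GRID

    def validate(self) -> "RunConfig":
        if (self.simulation is None) == (len(self.studies) == 0):
            raise ConfigurationError(
                "exactly one of simulation and studies must be specified"
            )
        if self.studies and self.labels_path is None:
            raise ConfigurationError("labels_path is required with real studies")
        unknown = set(self.algorithms) - set(mdl.ALGORITHMS)
        if unknown:
            raise ConfigurationError(f"unknown algorithm tag(s) {sorted(unknown)}")
        if isinstance(self.rf_trees, str) and self.rf_trees != "auto":
            raise ConfigurationError(
                f"rf_trees must be an integer or 'auto', got {self.rf_trees!r}"
            )
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("simulation") is not None:
            raw["simulation"] = sim.SimulationConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw["simulation"].items()
                }
            )
        raw["studies"] = [StudyInput(**s) for s in raw.get("studies", [])]
        for key in ("required_exposures", "algorithms", "rf_tree_grid"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        raw = asdict(self)
        if self.simulation is not None:
            raw["simulation"] = asdict(self.simulation)
        return raw


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    invariant_set: cns.BiomarkerSet
    modulation: cns.ModulationTable
    reports: dict[str, ev.StabilityReport]
    external: pd.DataFrame
    enrichment: pd.DataFrame | None
    recovery: dict | None
    consensus_by_exposure: dict[str, cns.BiomarkerSet]


def _discover(studies, labels, config) -> tuple[
    dict[str, dict[str, degmod.ChemicalProfileMatrix]],
    dict[str, list[pd.DataFrame]],
    dict[str, list[str]],
]:
    """Profiles and DEG tables for every dataset x exposure combination."""
    exposures = list(config.required_exposures)
    profiles: dict[str, dict[str, degmod.ChemicalProfileMatrix]] = {}
    deg_by_exposure: dict[str, list[pd.DataFrame]] = {e: [] for e in exposures}
    datasets_by_exposure: dict[str, list[str]] = {e: [] for e in exposures}
    for study in studies:
        profiles[study.dataset_id] = {}
        for exposure in exposures:
            if exposure not in set(study.samples["exposure_style"]):
                logger.info(
                    "discover: %s lacks exposure %s; skipped",
                    study.dataset_id, exposure,
                )
                continue
            prof = degmod.chemical_profiles(
                study,
                exposure,
                dose_group=config.dose_group,
                control_policy=config.control_policy,
                labels=labels,
            )
            profiles[study.dataset_id][exposure] = prof
            table = degmod.test_differential(
                prof,
                alpha=config.alpha,
                fold_threshold=config.fold_threshold,
                test_variant=config.test_variant,
            )
            deg_by_exposure[exposure].append(table)
            datasets_by_exposure[exposure].append(study.dataset_id)
    return profiles, deg_by_exposure, datasets_by_exposure


def _recovery_metrics(
    invariant_set: cns.BiomarkerSet, truth: sim.GroundTruth
) -> dict:
    recovered = set(invariant_set.time_invariant_subset)
    planted = set(truth.invariant_genes)
    variant = set(truth.variant_genes)
    tp = {
        g
        for g in recovered & planted
        if invariant_set.genes[g] == truth.invariant_genes[g]
    }
    precision = len(tp) / len(recovered) if recovered else float("nan")
    recall = len(tp) / len(planted) if planted else float("nan")
    return {
        "n_recovered": len(recovered),
        "n_planted": len(planted),
        "n_correct_direction": len(tp),
        "precision": precision,
        "recall": recall,
        "variant_genes_flagged": sorted(recovered & variant),
        "n_variant_flagged": len(recovered & variant),
    }


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; every stage error names its stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root = logging.getLogger("tinvmark")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, out)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()


def _run_stages(config: RunConfig, out: Path) -> RunResult:
    # --- inputs -----------------------------------------------------------
    truth: sim.GroundTruth | None = None
    if config.simulation is not None:
        sim_config = sim.SimulationConfig(
            **{**asdict(config.simulation), "seed": config.seed}
        )
        studies, truth = sim.simulate(sim_config)
        labels = pd.Series(truth.chemical_labels, name="class")
    else:
        labels = tio.read_labels(config.labels_path)
        studies = [
            tio.read_study(
                s.expression_path, s.metadata_path, s.dataset_id, s.platform
            )
            for s in config.studies
        ]
        if config.genemap_path is not None:
            genemap = tio.read_genemap(config.genemap_path)
            studies = [tio.map_to_genes(s, genemap) for s in studies]
    for study in studies:
        study.validate(labels=labels)

    all_exposures = list(
        dict.fromkeys(e for s in studies for e in s.exposure_styles)
    )
    if config.required_exposures is None:
        config.required_exposures = tuple(all_exposures)
    if config.source_exposure is None:
        # middle exposure by position, mirroring a mid-course selection
        config.source_exposure = config.required_exposures[
            (len(config.required_exposures) - 1) // 2
        ]
    if config.source_exposure not in config.required_exposures:
        raise ConfigurationError(
            f"source_exposure {config.source_exposure!r} not among required "
            f"exposures {config.required_exposures}"
        )
    with open(out / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    logger.info("run: resolved config written; exposures=%s source=%s",
                config.required_exposures, config.source_exposure)

    # --- profiles + DEGs --------------------------------------------------
    try:
        profiles, deg_by_exposure, datasets_by_exposure = _discover(
            studies, labels, config
        )
    except Exception as exc:
        raise PipelineError(f"stage deg: {exc}") from exc

    # --- consensus per exposure + invariance ------------------------------
    try:
        consensus_by_exposure = {
            exposure: cns.consensus_set(
                tables, name=f"consensus_{exposure}", source_exposure=exposure
            )
            for exposure, tables in deg_by_exposure.items()
            if tables
        }
        source_set = consensus_by_exposure[config.source_exposure]
        modulation = cns.cross_check(
            source_set,
            deg_by_exposure,
            config.required_exposures,
            rule=config.direction_rule,
            fold_threshold=config.fold_threshold,
            dataset_ids=datasets_by_exposure,
        )
    except KeyError as exc:
        raise PipelineError(
            f"stage consensus: no DEG tables at source exposure {exc}"
        ) from exc
    modulation.write(out / "modulation.tsv")
    invariant_set = cns.BiomarkerSet(
        name=f"time_invariant_{config.source_exposure}",
        genes={
            g: source_set.genes[g] for g in source_set.time_invariant_subset
        },
        source_exposure=config.source_exposure,
        time_invariant_subset=list(source_set.time_invariant_subset),
    )
    invariant_set.write(out / "invariant_set.tsv")
    for exposure, bset in consensus_by_exposure.items():
        bset.write(out / f"consensus_{exposure}.tsv")
    logger.info(
        "run: %d consensus genes at %s, %d time-invariant",
        len(source_set.genes), config.source_exposure, len(invariant_set.genes),
    )

    recovery = None
    if truth is not None:
        recovery = _recovery_metrics(source_set, truth)
        with open(out / "recovery.json", "w", encoding="utf-8") as fh:
            json.dump(recovery, fh, indent=2)

    # --- models + stability ----------------------------------------------
    reports: dict[str, ev.StabilityReport] = {}
    feature_cache: dict[tuple[str, str], mdl.FeatureTable] = {}
    if invariant_set.genes:
        for dataset_id, by_exposure in profiles.items():
            for exposure, prof in by_exposure.items():
                feature_cache[(dataset_id, exposure)] = mdl.build_features(
                    prof, invariant_set
                )
        for algorithm in config.algorithms:
            results = []
            for (dataset_id, exposure), features in feature_cache.items():
                params: dict = {}
                if algorithm == "rf":
                    if config.rf_trees == "auto":
                        params["n_trees"] = mdl.select_n_trees(
                            features, grid=config.rf_tree_grid, seed=config.seed
                        )
                    else:
                        params["n_trees"] = int(config.rf_trees)
                results.append(
                    mdl.loocv(features, algorithm, params=params, seed=config.seed)
                )
            if len(results) >= 2:
                reports[algorithm] = ev.aggregate(results)
                reports[algorithm].write_json(out / f"report_{algorithm}.json")
        rows = [
            ev.report_row(f"{invariant_set.name}/{alg}", rep)
            for alg, rep in reports.items()
        ]
        if rows:
            pd.DataFrame(rows).to_csv(out / "report.tsv", sep="\t", index=False)
    else:
        logger.info("run: empty invariant set; model stages skipped")

    # --- external validation ---------------------------------------------
    external_rows = []
    source_features = {
        ds: feature_cache[(ds, config.source_exposure)]
        for ds, _ in feature_cache
        if (ds, config.source_exposure) in feature_cache
    }
    rf_params = (
        {"n_trees": int(config.rf_trees)}
        if config.rf_trees != "auto"
        else None
    )
    for train_ds, train_ft in source_features.items():
        for test_ds, test_ft in source_features.items():
            if train_ds == test_ds:
                continue
            auc = ev.external_validate(
                train_ft, test_ft, algorithm="rf", params=rf_params,
                seed=config.seed,
            )
            external_rows.append(
                {"train_dataset": train_ds, "test_dataset": test_ds, "auc": auc}
            )
    external = pd.DataFrame(
        external_rows, columns=["train_dataset", "test_dataset", "auc"]
    )
    external.to_csv(out / "external.tsv", sep="\t", index=False)

    # --- enrichment -------------------------------------------------------
    enrichment = None
    if config.catalog_path is not None and invariant_set.genes:
        catalog = enr.read_catalog(config.catalog_path)
        enrichment = enr.enrich(set(invariant_set.genes), catalog)
        enrichment.to_csv(out / "enrich.tsv", sep="\t", index=False)

    return RunResult(
        out_dir=out,
        invariant_set=invariant_set,
        modulation=modulation,
        reports=reports,
        external=external,
        enrichment=enrichment,
        recovery=recovery,
        consensus_by_exposure=consensus_by_exposure,
    )


def discover_invariant_set(
    studies: Sequence[tio.ExpressionStudy],
    labels: pd.Series,
    source_exposure: str,
    required_exposures: Sequence[str],
    alpha: float = 0.05,
    fold_threshold: float = 1.5,
    dose_group: str = "high",
    control_policy: str = "pooled",
    test_variant: str = "welch",
    direction_rule: str = "fold",
) -> tuple[cns.BiomarkerSet, cns.ModulationTable]:
    """Library shortcut: studies -> time-invariant biomarker set.

    Runs profiles, DEG testing, per-exposure consensus at the source
    exposure and the cross-exposure invariance check, without touching the
    filesystem.
    """
    deg_by_exposure: dict[str, list[pd.DataFrame]] = {}
    for exposure in required_exposures:
        tables = []
        for study in studies:
            if exposure not in set(study.samples["exposure_style"]):
                continue
            prof = degmod.chemical_profiles(
                study, exposure, dose_group=dose_group,
                control_policy=control_policy, labels=labels,
            )
            tables.append(
                degmod.test_differential(
                    prof, alpha=alpha, fold_threshold=fold_threshold,
                    test_variant=test_variant,
                )
            )
        deg_by_exposure[exposure] = tables
    source_set = cns.consensus_set(
        deg_by_exposure[source_exposure],
        name=f"consensus_{source_exposure}",
        source_exposure=source_exposure,
    )
    modulation = cns.cross_check(
        source_set, deg_by_exposure, required_exposures,
        rule=direction_rule, fold_threshold=fold_threshold,
    )
    invariant = cns.BiomarkerSet(
        name=f"time_invariant_{source_exposure}",
        genes={g: source_set.genes[g] for g in source_set.time_invariant_subset},
        source_exposure=source_exposure,
        time_invariant_subset=list(source_set.time_invariant_subset),
    )
    return invariant, modulation
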