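"""Synthetic multi-dataset toxicogenomic experiment generator.

Emulates the joint structure of the public rat-liver archives this kind of
pipeline is run on: several datasets on two microarray ID spaces, chemicals
labelled NGHC (non-genotoxic hepatocarcinogen) or NHC (non-hepatocarcinogen)
at imbalanced ratios, a handful of exposure styles (1-day ... 28-day) in
biological triplicate, with planted signature genes whose regulation is
either constant-direction across exposure styles ("time-invariant") or
sign-flipping/transient ("time-variant"), plus additive per-dataset
per-gene offsets and i.i.d. Gaussian per-probe noise on the log2 scale.

The generator returns ground truth alongside the studies so that every
downstream stage (differential expression, consensus, invariance
filtering, modelling) is testable without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io import CONTROL_ID, ExpressionStudy, write_labels, write_study

UP = "+"
DOWN = "-"
NO_EFFECT = "0"

#: Built-in time-variant archetypes, cycled over planted variant genes:
#: a gene whose direction reverses at the last exposure, a gene responding
#: only at early exposures, and a gene responding only at late exposures.
VARIANT_ARCHETYPES = ("sign_flip", "early_only", "late_only")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic multi-dataset experiment.

    Counts are per dataset; ``effect_size``, ``noise_sd`` and
    ``dataset_shift_sd`` are in log2 units. The default effect size of
    0.585 log2 units is a 1.5-fold change, the conventional microarray
    effect threshold. The default class imbalance (26 NGHC : 62 NHC)
    matches the most balanced of the real archives this generator emulates.
    """

    n_genes: int = 2000
    n_datasets: int = 3
    platforms: tuple[str, ...] | None = None
    exposure_styles: tuple[str, ...] = ("1d", "3d", "1w", "14d", "28d")
    n_nghc: int = 26
    n_nhc: int = 62
    n_replicates: int = 3
    n_invariant_up: int = 10
    n_invariant_down: int = 10
    n_variant: int = 15
    effect_size: float = 0.585
    noise_sd: float = 0.4
    dataset_shift_sd: float = 0.2
    missing_probe_fraction: float = 0.05
    control_policy: str = "pooled"
    seed: int = 0

    def resolved_platforms(self) -> tuple[str, ...]:
        if self.platforms is not None:
            return self.platforms
        tags = ("affymetrix", "codelink")
        return tuple(tags[i % 2] for i in range(self.n_datasets))

    def validate(self) -> "SimulationConfig":
        counts = {
            "n_genes": self.n_genes,
            "n_datasets": self.n_datasets,
            "n_nghc": self.n_nghc,
            "n_nhc": self.n_nhc,
            "n_replicates": self.n_replicates,
            "n_invariant_up": self.n_invariant_up,
            "n_invariant_down": self.n_invariant_down,
            "n_variant": self.n_variant,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        for name in ("n_genes", "n_datasets", "n_replicates"):
            if counts[name] == 0:
                raise ConfigurationError(f"{name} must be >= 1, got 0")
        planted = self.n_invariant_up + self.n_invariant_down + self.n_variant
        if planted > self.n_genes:
            raise ConfigurationError(
                f"n_invariant_up + n_invariant_down + n_variant = {planted} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if len(self.exposure_styles) == 0:
            raise ConfigurationError("exposure_styles must be non-empty")
        if len(set(self.exposure_styles)) != len(self.exposure_styles):
            raise ConfigurationError(
                f"exposure_styles must be unique, got {self.exposure_styles}"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.dataset_shift_sd < 0:
            raise ConfigurationError(
                f"dataset_shift_sd must be >= 0, got {self.dataset_shift_sd}"
            )
        if not 0 <= self.missing_probe_fraction < 1:
            raise ConfigurationError(
                "missing_probe_fraction must be in [0, 1), got "
                f"{self.missing_probe_fraction}"
            )
        if self.control_policy not in ("pooled", "matched"):
            raise ConfigurationError(
                f"control_policy must be 'pooled' or 'matched', got "
                f"{self.control_policy!r}"
            )
        platforms = self.resolved_platforms()
        if len(platforms) != self.n_datasets:
            raise ConfigurationError(
                f"platforms must list one tag per dataset "
                f"({self.n_datasets}), got {len(platforms)}"
            )
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("platforms", "exposure_styles"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_yaml(self, path: Path | str) -> None:
        raw = asdict(self)
        raw["platforms"] = (
            list(self.platforms) if self.platforms is not None else None
        )
        raw["exposure_styles"] = list(self.exposure_styles)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted signal, kept for parameter-recovery checks.

    ``invariant_genes`` maps gene -> constant direction ("+"/"-");
    ``variant_genes`` maps gene -> per-exposure direction pattern with
    values in {"+", "-", "0"}; ``chemical_labels`` maps every chemical to
    its class (dataset-global).
    """

    invariant_genes: dict[str, str]
    variant_genes: dict[str, dict[str, str]]
    chemical_labels: dict[str, str]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "role": "invariant", "directions": d}
            for g, d in sorted(self.invariant_genes.items())
        ]
        rows += [
            {
                "gene": g,
                "role": "variant",
                "directions": ",".join(f"{e}:{c}" for e, c in pat.items()),
            }
            for g, pat in sorted(self.variant_genes.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "role", "directions"])


def _variant_pattern(
    archetype: str, base_dir: str, exposures: tuple[str, ...]
) -> dict[str, str]:
    m = len(exposures)
    flipped = DOWN if base_dir == UP else UP
    if archetype == "sign_flip":
        pat = {e: base_dir for e in exposures}
        pat[exposures[-1]] = flipped
    elif archetype == "early_only":
        cut = max(1, math.ceil(m / 2))
        pat = {e: (base_dir if i < cut else NO_EFFECT) for i, e in enumerate(exposures)}
    elif archetype == "late_only":
        cut = m // 2
        pat = {e: (base_dir if i >= cut else NO_EFFECT) for i, e in enumerate(exposures)}
    else:  # pragma: no cover - archetype list is fixed
        raise ConfigurationError(f"unknown variant archetype {archetype!r}")
    return pat


def simulate(config: SimulationConfig) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate one multi-dataset experiment plus its ground truth.

    Control samples are baseline + dataset offset + noise; NGHC-treated
    samples are additionally shifted by ±effect_size on the planted genes
    (per-exposure pattern for variant genes); NHC-treated samples carry no
    planted signal. Each platform's probe space omits a random
    ``missing_probe_fraction`` of genes. Identical seeds give bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    exposures = tuple(config.exposure_styles)
    platforms = config.resolved_platforms()

    width = max(5, len(str(n_genes - 1)))
    genes = np.array([f"g{i:0{width}d}" for i in range(n_genes)])

    order = rng.permutation(n_genes)
    n_up, n_down, n_var = (
        config.n_invariant_up,
        config.n_invariant_down,
        config.n_variant,
    )
    idx_up = np.sort(order[:n_up])
    idx_down = np.sort(order[n_up : n_up + n_down])
    idx_var = np.sort(order[n_up + n_down : n_up + n_down + n_var])

    invariant = {str(genes[i]): UP for i in idx_up}
    invariant.update({str(genes[i]): DOWN for i in idx_down})
    variant: dict[str, dict[str, str]] = {}
    for k, i in enumerate(idx_var):
        archetype = VARIANT_ARCHETYPES[k % len(VARIANT_ARCHETYPES)]
        base_dir = UP if k % 2 == 0 else DOWN
        variant[str(genes[i])] = _variant_pattern(archetype, base_dir, exposures)

    # Signed effect per (gene, exposure) in log2 units.
    effect = np.zeros((n_genes, len(exposures)))
    effect[idx_up, :] = config.effect_size
    effect[idx_down, :] = -config.effect_size
    sign = {UP: 1.0, DOWN: -1.0, NO_EFFECT: 0.0}
    for g, pattern in variant.items():
        gi = np.flatnonzero(genes == g)[0]
        for ei, e in enumerate(exposures):
            effect[gi, ei] = sign[pattern[e]] * config.effect_size

    baseline = rng.normal(8.0, 1.5, n_genes)

    # One probe-presence mask per platform tag; datasets sharing a
    # platform share the mask, mirroring a shared probe ID space.
    present: dict[str, np.ndarray] = {}
    for tag in dict.fromkeys(platforms):
        mask = rng.random(n_genes) >= config.missing_probe_fraction
        if not mask.any():
            mask[0] = True
        present[tag] = mask

    chemicals = [f"nghc{i:03d}" for i in range(config.n_nghc)] + [
        f"nhc{i:03d}" for i in range(config.n_nhc)
    ]
    chemical_labels = {
        c: ("NGHC" if c.startswith("nghc") else "NHC") for c in chemicals
    }

    studies: list[ExpressionStudy] = []
    for d in range(config.n_datasets):
        dataset_id = f"DS{d + 1}"
        platform = platforms[d]
        shift = rng.normal(0.0, config.dataset_shift_sd, n_genes)

        sample_ids: list[str] = []
        meta_rows: list[dict] = []
        col_effects: list[tuple[int, str | None]] = []  # (exposure idx, chem or None)
        for ei, exp in enumerate(exposures):
            if config.control_policy == "pooled":
                for r in range(config.n_replicates):
                    sid = f"{dataset_id}_{exp}_ctrl_r{r + 1}"
                    sample_ids.append(sid)
                    col_effects.append((ei, None))
                    meta_rows.append(
                        dict(
                            sample_id=sid,
                            chemical_id=CONTROL_ID,
                            exposure_style=exp,
                            dose_group="high",
                            replicate=r + 1,
                            is_control=True,
                        )
                    )
            for chem in chemicals:
                if config.control_policy == "matched":
                    for r in range(config.n_replicates):
                        sid = f"{dataset_id}_{exp}_{chem}_ctrl_r{r + 1}"
                        sample_ids.append(sid)
                        col_effects.append((ei, None))
                        meta_rows.append(
                            dict(
                                sample_id=sid,
                                chemical_id=chem,
                                exposure_style=exp,
                                dose_group="high",
                                replicate=r + 1,
                                is_control=True,
                            )
                        )
                for r in range(config.n_replicates):
                    sid = f"{dataset_id}_{exp}_{chem}_r{r + 1}"
                    sample_ids.append(sid)
                    col_effects.append((ei, chem))
                    meta_rows.append(
                        dict(
                            sample_id=sid,
                            chemical_id=chem,
                            exposure_style=exp,
                            dose_group="high",
                            replicate=r + 1,
                            is_control=False,
                        )
                    )

        n_samples = len(sample_ids)
        matrix = rng.normal(0.0, config.noise_sd, (n_genes, n_samples))
        matrix += (baseline + shift)[:, None]
        for j, (ei, chem) in enumerate(col_effects):
            if chem is not None and chemical_labels[chem] == "NGHC":
                matrix[:, j] += effect[:, ei]

        mask = present[platform]
        expr = pd.DataFrame(
            matrix[mask], index=pd.Index(genes[mask], name="probe_id"),
            columns=sample_ids,
        )
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        studies.append(ExpressionStudy(dataset_id, platform, expr, meta))

    truth = GroundTruth(invariant, variant, chemical_labels)
    return studies, truth


def write_simulation(
    out_dir: Path | str,
    studies: list[ExpressionStudy],
    truth: GroundTruth,
    config: SimulationConfig,
) -> Path:
    """Write studies, labels, ground truth and the config used to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for study in studies:
        write_study(
            study,
            out / f"{study.dataset_id}_expression.tsv",
            out / f"{study.dataset_id}_samples.tsv",
        )
    labels = pd.Series(truth.chemical_labels, name="class")
    write_labels(labels, out / "labels.tsv")
    truth.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    config.to_yaml(out / "sim_config.yaml")
    return out
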