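"""Tabular I/O contracts and validated in-memory studies.

All pipeline inputs are plain TSV files with mandatory headers:

``expression.tsv``
    First column: probe or gene identifier. Remaining columns: sample IDs.
    Values are log2 intensities.
``samples.tsv``
    Columns ``sample_id, chemical_id, exposure_style, dose_group,
    replicate, is_control``. Control samples carry ``chemical_id ==
    "CONTROL"`` under the pooled-control design, or the matched chemical's
    id under the matched design.
``labels.tsv``
    Columns ``chemical_id, class`` with class in {NGHC, NHC}.
``genemap.tsv``
    Columns ``platform, probe_id, gene_symbol``; a probe whose symbol (or
    id) is ``NA`` is treated as absent from that platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = (
    "sample_id",
    "chemical_id",
    "exposure_style",
    "dose_group",
    "replicate",
    "is_control",
)

CONTROL_ID = "CONTROL"
CLASS_POSITIVE = "NGHC"
CLASS_NEGATIVE = "NHC"
NA_TOKEN = "NA"


@dataclass
class ExpressionStudy:
    """One dataset: a log2 expression matrix plus sample metadata.

    Parameters
    ----------
    dataset_id
        Short dataset tag (e.g. ``"DMA"``).
    platform
        Probe-ID space of the array (e.g. ``"affymetrix"``, ``"codelink"``).
    expression
        Genes/probes (index) x samples (columns) matrix of log2 values.
    samples
        Per-sample metadata table indexed by ``sample_id`` with columns
        ``chemical_id, exposure_style, dose_group, replicate, is_control``.
    """

    dataset_id: str
    platform: str
    expression: pd.DataFrame
    samples: pd.DataFrame

    def validate(
        self,
        exposure_vocabulary: Sequence[str] | None = None,
        labels: pd.Series | None = None,
    ) -> "ExpressionStudy":
        """Check the study invariants; raise :class:`ValidationError` on failure."""
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"study {self.dataset_id}: duplicated sample_id(s): {dups}"
            )
        matrix_cols = set(self.expression.columns)
        meta_ids = set(self.samples.index)
        if matrix_cols != meta_ids:
            only_meta = sorted(meta_ids - matrix_cols)
            only_matrix = sorted(matrix_cols - meta_ids)
            raise ValidationError(
                f"study {self.dataset_id}: expression/metadata sample mismatch; "
                f"metadata-only={only_meta}, matrix-only={only_matrix}"
            )
        values = self.expression.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
            bad = self.expression.index[
                ~np.isfinite(self.expression.apply(pd.to_numeric, errors="coerce")).all(
                    axis=1
                )
            ].tolist()
            raise ValidationError(
                f"study {self.dataset_id}: non-finite or non-numeric values in rows {bad}"
            )
        if exposure_vocabulary is not None:
            seen = set(self.samples["exposure_style"])
            unknown = sorted(seen - set(exposure_vocabulary))
            if unknown:
                raise ValidationError(
                    f"study {self.dataset_id}: unknown exposure_style(s) {unknown}; "
                    f"allowed: {list(exposure_vocabulary)}"
                )
        if labels is not None:
            treated = self.samples.loc[~self.samples["is_control"], "chemical_id"]
            missing = sorted(set(treated) - set(labels.index))
            if missing:
                raise ValidationError(
                    f"study {self.dataset_id}: treated chemicals without a class "
                    f"label: {missing}"
                )
        return self

    @property
    def exposure_styles(self) -> list[str]:
        """Exposure styles present, in first-appearance order."""
        return list(dict.fromkeys(self.samples["exposure_style"]))


@dataclass
class GeneMap:
    """Probe-to-gene-symbol map across platforms.

    Rows of ``(platform, probe_id, gene_symbol)``; ``NA`` entries mean the
    gene has no probe on that platform and are dropped on load.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"platform", "probe_id", "gene_symbol"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"genemap: missing columns {sorted(missing)}")
        keep = (self.table["probe_id"] != NA_TOKEN) & (
            self.table["gene_symbol"] != NA_TOKEN
        )
        tab = self.table.loc[keep]
        if tab["gene_symbol"].eq("").any():
            raise ValidationError("genemap: empty gene_symbol")
        if tab.duplicated(["platform", "probe_id"]).any():
            dups = tab.loc[
                tab.duplicated(["platform", "probe_id"]), ["platform", "probe_id"]
            ].to_records(index=False).tolist()
            raise ValidationError(f"genemap: duplicated (platform, probe_id): {dups}")
        self.table = tab.reset_index(drop=True)

    def for_platform(self, platform: str) -> pd.Series:
        """Return probe_id -> gene_symbol for one platform."""
        sub = self.table[self.table["platform"] == platform]
        return sub.set_index("probe_id")["gene_symbol"]


def _read_header(path: Path | str) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return fh.readline().rstrip("\n").split("\t")


def read_expression(path: Path | str) -> pd.DataFrame:
    """Read an expression TSV; reject duplicated sample columns and
    rows containing non-numeric cells (error names the row)."""
    header = _read_header(path)
    sample_ids = header[1:]
    dup = [s for s in set(sample_ids) if sample_ids.count(s) > 1]
    if dup:
        raise ValidationError(f"{path}: duplicated sample_id column(s): {sorted(dup)}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.columns = sample_ids
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.index[~np.isfinite(numeric).all(axis=1)].tolist()
    if bad:
        raise ValidationError(f"{path}: non-numeric or non-finite cells in rows {bad}")
    if numeric.index.has_duplicates:
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated row identifier(s): {dups}")
    return numeric.astype(float)


def read_samples(path: Path | str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    meta["replicate"] = meta["replicate"].astype(int)
    truthy = {"1": True, "true": True, "0": False, "false": False}
    try:
        meta["is_control"] = [truthy[str(v).lower()] for v in meta["is_control"]]
    except KeyError as exc:
        raise ValidationError(f"{path}: unparseable is_control value {exc}") from exc
    return meta.set_index("sample_id")


def read_study(
    expression_path: Path | str,
    metadata_path: Path | str,
    dataset_id: str,
    platform: str,
    exposure_vocabulary: Sequence[str] | None = None,
) -> ExpressionStudy:
    """Assemble and validate a study from its expression and metadata TSVs."""
    expr = read_expression(expression_path)
    meta = read_samples(metadata_path)
    study = ExpressionStudy(dataset_id, platform, expr, meta)
    return study.validate(exposure_vocabulary=exposure_vocabulary)


def write_study(
    study: ExpressionStudy,
    expression_path: Path | str,
    metadata_path: Path | str,
) -> None:
    expr = study.expression.copy()
    expr.index.name = expr.index.name or "probe_id"
    expr.to_csv(expression_path, sep="\t", float_format="%.6f")
    meta = study.samples.reset_index()
    if meta.columns[0] != "sample_id":
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta = meta[list(SAMPLE_COLUMNS)]
    meta = meta.assign(is_control=meta["is_control"].astype(int))
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_labels(path: Path | str) -> pd.Series:
    """Read chemical class labels; values restricted to {NGHC, NHC}."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"chemical_id", "class"} - set(tab.columns)
    if missing:
        raise ValidationError(f"{path}: missing label columns {sorted(missing)}")
    if tab["chemical_id"].duplicated().any():
        dups = tab.loc[tab["chemical_id"].duplicated(), "chemical_id"].tolist()
        raise ValidationError(f"{path}: duplicated chemical_id(s): {dups}")
    bad = sorted(set(tab["class"]) - {CLASS_POSITIVE, CLASS_NEGATIVE})
    if bad:
        raise ValidationError(f"{path}: unknown class value(s) {bad}")
    return tab.set_index("chemical_id")["class"]


def write_labels(labels: pd.Series, path: Path | str) -> None:
    frame = labels.rename("class").rename_axis("chemical_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_genemap(path: Path | str) -> GeneMap:
    return GeneMap(pd.read_csv(path, sep="\t", dtype=str))


def map_to_genes(
    study: ExpressionStudy,
    genemap: GeneMap,
    collapse: str = "mean",
) -> ExpressionStudy:
    """Re-index probe rows to gene symbols, collapsing multi-probe genes.

    Probes with no mapping on the study's platform are dropped (count
    logged). ``collapse`` is one of ``mean``, ``median``, ``max``; the
    default ``mean`` is recorded in the log.
    """
    if collapse not in ("mean", "median", "max"):
        raise ValidationError(f"map_to_genes: unknown collapse statistic {collapse!r}")
    mapping = genemap.for_platform(study.platform)
    common = study.expression.index.intersection(mapping.index)
    if len(common) == 0:
        raise ValidationError(
            f"map_to_genes: no probe of study {study.dataset_id} maps to a gene "
            f"on platform {study.platform}"
        )
    dropped = len(study.expression.index) - len(common)
    logger.info(
        "map_to_genes: %s: %d probes mapped, %d unmapped probes dropped, "
        "collapse=%s",
        study.dataset_id,
        len(common),
        dropped,
        collapse,
    )
    mapped = study.expression.loc[common]
    grouped = mapped.groupby(mapping.loc[common].values)
    collapsed = getattr(grouped, collapse)()
    collapsed.index.name = "gene_symbol"
    return ExpressionStudy(
        study.dataset_id, study.platform, collapsed, study.samples.copy()
    )
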