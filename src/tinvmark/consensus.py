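"""Cross-dataset consensus biomarker sets and time-invariance filtering.

A *consensus biomarker* at one exposure style is a gene that is a DEG with
the same direction in every dataset at that exposure. Each consensus set
is then cross-checked against the other exposure styles: a gene whose
modulation call is the same signed direction at every required exposure is
*time-invariant*. Per-exposure calls use "+" (up in all contributing
datasets), "-" (down in all), "+/-" (datasets inconsistent or no direction
evidenced) and "absent" (gene not measured on any platform at that
exposure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

CALL_UP = "+"
CALL_DOWN = "-"
CALL_BOTH = "+/-"
CALL_ABSENT = "absent"
SIGNED_CALLS = (CALL_UP, CALL_DOWN)


@dataclass
class BiomarkerSet:
    """A named gene signature with per-gene directions."""

    name: str
    genes: dict[str, str]
    source_exposure: str | None = None
    time_invariant_subset: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.genes.items() if d not in SIGNED_CALLS}
        if bad:
            raise ValidationError(f"biomarker set {self.name}: bad directions {bad}")
        stray = set(self.time_invariant_subset) - set(self.genes)
        if stray:
            raise ValidationError(
                f"biomarker set {self.name}: time-invariant genes not in set: "
                f"{sorted(stray)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.genes),
                "direction": [self.genes[g] for g in self.genes],
                "time_invariant": [
                    int(g in set(self.time_invariant_subset)) for g in self.genes
                ],
            }
        )

    def write(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: Path | str, name: str | None = None) -> "BiomarkerSet":
        tab = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
        genes = dict(zip(tab["gene"], tab["direction"]))
        subset = (
            tab.loc[tab["time_invariant"].astype(bool), "gene"].tolist()
            if "time_invariant" in tab.columns
            else []
        )
        return cls(name or Path(path).stem, genes, time_invariant_subset=subset)


@dataclass
class ModulationTable:
    """Per-gene, per-exposure modulation calls plus time-invariance flags.

    ``calls`` is genes x exposure styles with values in
    {"+", "-", "+/-", "absent"}; ``provenance`` records, per exposure, the
    dataset ids that contributed a call.
    """

    calls: pd.DataFrame
    time_invariant: pd.Series
    required_exposures: tuple[str, ...]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.calls.copy()
        out["time_invariant"] = np.where(self.time_invariant, "Yes", "No")
        return out

    def write(self, path: Path | str) -> None:
        self.to_frame().rename_axis("gene").to_csv(path, sep="\t")


def consensus_set(
    deg_tables: Sequence[pd.DataFrame],
    min_datasets: int | None = None,
    name: str = "consensus",
    source_exposure: str | None = None,
) -> BiomarkerSet:
    """Intersect DEG calls across datasets at one exposure style.

    A gene qualifies when it is a DEG in at least ``min_datasets`` tables
    (default: all of them) and its direction is identical in every table
    where it is a DEG. An empty result is returned, not raised.
    """
    if len(deg_tables) < 1:
        raise ValidationError("consensus_set: need at least one DEG table")
    need = len(deg_tables) if min_datasets is None else min_datasets
    if need < 1 or need > len(deg_tables):
        raise ValidationError(
            f"consensus_set: min_datasets {need} outside 1..{len(deg_tables)}"
        )

    universe = deg_tables[0].index
    for tab in deg_tables[1:]:
        universe = universe.union(tab.index)
    if len(universe) == 0:
        raise ValidationError("consensus_set: empty gene universe")

    up = np.zeros(len(universe), dtype=int)
    down = np.zeros(len(universe), dtype=int)
    for tab in deg_tables:
        deg_up = (tab["is_deg"] & (tab["direction"] == CALL_UP)).reindex(
            universe, fill_value=False
        )
        deg_down = (tab["is_deg"] & (tab["direction"] == CALL_DOWN)).reindex(
            universe, fill_value=False
        )
        up += deg_up.to_numpy()
        down += deg_down.to_numpy()

    genes: dict[str, str] = {}
    for gene, n_up, n_down in zip(universe, up, down):
        if n_up >= need and n_down == 0:
            genes[gene] = CALL_UP
        elif n_down >= need and n_up == 0:
            genes[gene] = CALL_DOWN
    if not genes:
        logger.info("consensus_set %s: empty intersection", name)
    return BiomarkerSet(name, genes, source_exposure=source_exposure)


def _dataset_direction(
    delta: float, rule: str, log_fold: float
) -> str | None:
    """Direction evidenced by one dataset's delta, or None for no evidence."""
    if rule == "sign":
        if delta > 0:
            return CALL_UP
        if delta < 0:
            return CALL_DOWN
        return None  # exact tie: no direction evidenced
    # rule == "fold": a direction is evidenced only at >= the fold threshold
    if delta >= log_fold:
        return CALL_UP
    if delta <= -log_fold:
        return CALL_DOWN
    return None


def direction_calls(
    deg_tables: Sequence[pd.DataFrame],
    genes: Sequence[str],
    rule: str = "fold",
    fold_threshold: float = 1.5,
) -> pd.Series:
    """Aggregate per-dataset deltas into one modulation call per gene.

    Under the default ``rule="fold"`` a dataset evidences a direction only
    when its |delta| reaches log2(fold_threshold); under ``rule="sign"``
    any nonzero delta counts. Datasets evidencing conflicting directions,
    or no dataset evidencing any direction, yield "+/-"; a gene present in
    no table yields "absent". Significance is never re-required.
    """
    if rule not in ("fold", "sign"):
        raise ValidationError(f"direction_calls: unknown rule {rule!r}")
    log_fold = float(np.log2(fold_threshold))
    calls = {}
    for gene in genes:
        dirs: set[str] = set()
        present = False
        for tab in deg_tables:
            if gene not in tab.index:
                continue
            present = True
            d = _dataset_direction(float(tab.at[gene, "delta"]), rule, log_fold)
            if d is None:
                if rule == "sign":
                    dirs.add(CALL_BOTH)  # an exact zero delta is a tie
            else:
                dirs.add(d)
        if not present:
            calls[gene] = CALL_ABSENT
        elif dirs == {CALL_UP}:
            calls[gene] = CALL_UP
        elif dirs == {CALL_DOWN}:
            calls[gene] = CALL_DOWN
        else:
            calls[gene] = CALL_BOTH
    return pd.Series(calls, dtype=object)


def time_invariant_flags(
    calls: pd.DataFrame, required_exposures: Sequence[str]
) -> pd.Series:
    """Apply the time-invariance rule to a table of modulation calls.

    A gene is time-invariant iff its call at every required exposure style
    is a signed direction ("+" or "-") and all those calls are equal.
    """
    missing = [e for e in required_exposures if e not in calls.columns]
    if missing:
        raise ValidationError(
            f"time_invariant_flags: calls lack exposure column(s) {missing}"
        )
    sub = calls[list(required_exposures)]
    signed = sub.isin(SIGNED_CALLS).all(axis=1)
    constant = sub.nunique(axis=1) == 1
    return (signed & constant).rename("time_invariant")


def cross_check(
    consensus: BiomarkerSet,
    deg_by_exposure: Mapping[str, Sequence[pd.DataFrame]],
    required_exposures: Sequence[str],
    rule: str = "fold",
    fold_threshold: float = 1.5,
    dataset_ids: Mapping[str, Sequence[str]] | None = None,
) -> ModulationTable:
    """Cross-check a consensus set against the other exposure styles.

    Builds the modulation-call matrix for the set's genes over every
    exposure in ``deg_by_exposure`` and flags time-invariance over
    ``required_exposures``. A gene absent from every platform at a
    required exposure is called "absent" there and cannot be
    time-invariant.
    """
    missing = [e for e in required_exposures if e not in deg_by_exposure]
    if missing:
        raise ValidationError(
            f"cross_check: required exposure(s) {missing} not covered by "
            f"deg_by_exposure"
        )
    genes = list(consensus.genes)
    columns = {
        exposure: direction_calls(tables, genes, rule=rule,
                                  fold_threshold=fold_threshold)
        for exposure, tables in deg_by_exposure.items()
    }
    calls = pd.DataFrame(columns).reindex(genes)
    calls.index.name = "gene"
    flags = time_invariant_flags(calls, required_exposures)
    for gene in flags.index[~flags]:
        absent_at = [
            e for e in required_exposures if calls.at[gene, e] == CALL_ABSENT
        ]
        if absent_at:
            logger.info(
                "cross_check: %s not time-invariant (absent at %s)",
                gene,
                absent_at,
            )
    provenance = {
        exposure: list(dataset_ids.get(exposure, [])) if dataset_ids else []
        for exposure in deg_by_exposure
    }
    consensus.time_invariant_subset = list(flags.index[flags])
    return ModulationTable(
        calls, flags, tuple(required_exposures), provenance
    )


# ---------------------------------------------------------------------------
# Bundled reference: published short-term modulation calls for six rat-liver
# NGHC biomarker sets (consensus 1-day / 3-day / 1-week sets plus the
# published E5, F19 and U9 signatures), with the reported time-invariance
# verdicts. Used as a ground-truth check of the invariance rule.
# ---------------------------------------------------------------------------

REFERENCE_EXPOSURES = ("1d", "3d", "1w")


def load_reference_modulation() -> pd.DataFrame:
    """Load the bundled reference modulation table.

    Columns: ``set_name, gene, affymetrix_id, codelink_id, call_1d,
    call_3d, call_1w, time_invariant`` (the last as "Yes"/"No").
    """
    ref = resources.files("tinvmark.data").joinpath("reference_modulation.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def evaluate_reference_modulation(
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Re-derive the time-invariance verdict for every reference row.

    Returns the reference table with a ``computed`` column ("Yes"/"No")
    obtained by applying :func:`time_invariant_flags` to the encoded
    per-exposure calls, and an ``agrees`` boolean column.
    """
    ref = load_reference_modulation() if reference is None else reference.copy()
    calls = ref[[f"call_{e}" for e in REFERENCE_EXPOSURES]].copy()
    calls.columns = list(REFERENCE_EXPOSURES)
    flags = time_invariant_flags(calls, REFERENCE_EXPOSURES)
    ref["computed"] = np.where(flags, "Yes", "No")
    ref["agrees"] = ref["computed"] == ref["time_invariant"]
    return ref
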