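"""Per-chemical expression profiles and differential-expression calls.

The unit of replication is the chemical: replicate animals are averaged
into one treated-vs-control log2 ratio profile per chemical, and the
NGHC-vs-NHC comparison is then a per-gene two-sample t-test across
chemical profiles, combined with a fold-change filter on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError, ValidationError
from .io import CLASS_NEGATIVE, CLASS_POSITIVE, ExpressionStudy

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("p_value", "delta", "direction", "is_deg")


@dataclass
class ChemicalProfileMatrix:
    """Genes x chemicals matrix of treated-vs-control log2 ratios.

    One matrix per (dataset, exposure style); ``labels`` maps each
    chemical column to NGHC or NHC.
    """

    dataset_id: str
    exposure_style: str
    profiles: pd.DataFrame
    labels: pd.Series

    def validate(self) -> "ChemicalProfileMatrix":
        unlabelled = sorted(set(self.profiles.columns) - set(self.labels.index))
        if unlabelled:
            raise ValidationError(
                f"profiles {self.dataset_id}/{self.exposure_style}: chemicals "
                f"without a label: {unlabelled}"
            )
        counts = self.labels.loc[self.profiles.columns].value_counts()
        for cls in (CLASS_POSITIVE, CLASS_NEGATIVE):
            if counts.get(cls, 0) < 2:
                raise ValidationError(
                    f"profiles {self.dataset_id}/{self.exposure_style}: need >=2 "
                    f"chemicals of class {cls}, got {counts.get(cls, 0)}"
                )
        return self

    def class_columns(self, cls: str) -> list[str]:
        lab = self.labels.loc[self.profiles.columns]
        return [c for c in self.profiles.columns if lab[c] == cls]


def chemical_profiles(
    study: ExpressionStudy,
    exposure_style: str,
    dose_group: str = "high",
    control_policy: str = "pooled",
    labels: pd.Series | None = None,
) -> ChemicalProfileMatrix:
    """Average replicates into per-chemical log2 ratio profiles.

    For each chemical at the requested exposure style and dose group,
    profile = mean over treated replicates - mean over the applicable
    control replicates, per gene. ``control_policy`` chooses between
    controls pooled per (dataset, exposure) and per-chemical matched
    controls.
    """
    if control_policy not in ("pooled", "matched"):
        raise ValidationError(
            f"chemical_profiles: unknown control_policy {control_policy!r}"
        )
    meta = study.samples
    at_exposure = meta[meta["exposure_style"] == exposure_style]
    if at_exposure.empty:
        raise PipelineError(
            f"chemical_profiles: study {study.dataset_id} has no samples at "
            f"exposure {exposure_style!r}"
        )
    treated = at_exposure[
        (~at_exposure["is_control"]) & (at_exposure["dose_group"] == dose_group)
    ]
    controls = at_exposure[at_exposure["is_control"]]
    if treated.empty:
        raise PipelineError(
            f"chemical_profiles: study {study.dataset_id} has no treated samples "
            f"at ({exposure_style}, dose {dose_group})"
        )

    pooled_mean = None
    if control_policy == "pooled":
        if controls.empty:
            raise PipelineError(
                f"chemical_profiles: missing controls for "
                f"({study.dataset_id}, {exposure_style})"
            )
        pooled_mean = study.expression[controls.index].mean(axis=1)

    columns: dict[str, pd.Series] = {}
    for chem, group in treated.groupby("chemical_id", sort=True):
        treated_mean = study.expression[group.index].mean(axis=1)
        if control_policy == "matched":
            own = controls[controls["chemical_id"] == chem]
            if own.empty:
                raise PipelineError(
                    f"chemical_profiles: missing matched controls for chemical "
                    f"{chem} at ({study.dataset_id}, {exposure_style})"
                )
            control_mean = study.expression[own.index].mean(axis=1)
        else:
            control_mean = pooled_mean
        columns[str(chem)] = treated_mean - control_mean

    profiles = pd.DataFrame(columns)
    profiles.index.name = "gene"
    result = ChemicalProfileMatrix(
        study.dataset_id, exposure_style, profiles,
        labels if labels is not None else pd.Series(dtype=object),
    )
    if labels is not None:
        result.validate()
    return result


def test_differential(
    profiles: ChemicalProfileMatrix,
    alpha: float = 0.05,
    fold_threshold: float = 1.5,
    test_variant: str = "welch",
) -> pd.DataFrame:
    """Per-gene NGHC-vs-NHC t-test plus fold-change filter.

    Returns a DegTable: a frame indexed by gene with columns ``p_value``,
    ``delta`` (mean NGHC - mean NHC, log2), ``direction`` ("+"/"-") and
    ``is_deg`` (p < alpha and |delta| >= log2(fold_threshold)). A gene with
    zero variance in both groups and delta 0 gets p = 1. Welch's unequal-
    variance test is the default given the strong class imbalance;
    ``test_variant="student"`` gives the pooled-variance test.
    """
    if test_variant not in ("welch", "student"):
        raise ValidationError(f"test_differential: unknown variant {test_variant!r}")
    profiles.validate()
    pos = profiles.class_columns(CLASS_POSITIVE)
    neg = profiles.class_columns(CLASS_NEGATIVE)
    x = profiles.profiles[pos].to_numpy(float)
    y = profiles.profiles[neg].to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError(
            f"test_differential: non-finite profile values in "
            f"{profiles.dataset_id}/{profiles.exposure_style}"
        )

    delta = x.mean(axis=1) - y.mean(axis=1)
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # zero-variance genes trigger scipy precision warnings; they are
        # handled explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            x, y, axis=1, equal_var=(test_variant == "student")
        )
    # Degenerate genes: zero variance in both groups. Identical means carry
    # no evidence (p = 1); distinct constant groups are maximally separated.
    degenerate = np.isnan(p)
    p = np.where(degenerate, np.where(delta == 0.0, 1.0, 0.0), p)

    log_fold = np.log2(fold_threshold)
    direction = np.where(delta < 0, "-", "+")
    is_deg = (p < alpha) & (np.abs(delta) >= log_fold) & (delta != 0.0)

    table = pd.DataFrame(
        {
            "p_value": p,
            "delta": delta,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=profiles.profiles.index.copy(),
    )
    table.index.name = "gene"
    logger.info(
        "test_differential: %s/%s: %d/%d genes pass (alpha=%g, fold=%g, %s)",
        profiles.dataset_id,
        profiles.exposure_style,
        int(is_deg.sum()),
        len(table),
        alpha,
        fold_threshold,
        test_variant,
    )
    return table


def write_deg(table: pd.DataFrame, path: Path | str) -> None:
    out = table.copy()
    out["is_deg"] = out["is_deg"].astype(int)
    out.to_csv(path, sep="\t")


def read_deg(path: Path | str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(DEG_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing DEG columns {sorted(missing)}")
    table["is_deg"] = table["is_deg"].astype(bool)
    return table
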