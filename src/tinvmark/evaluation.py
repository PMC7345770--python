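"""Stability-aware aggregation of cross-validation AUCs, and external
validation across datasets.

A biomarker set is evaluated by running LOOCV in every dataset x exposure
combination; the resulting AUCs are summarized by their median and
interquartile range (IQR), and the source of the variance is attributed
with two coefficients of variation: C.V.d over per-dataset median AUCs and
C.V.e over per-exposure median AUCs (both as percentages, sample standard
deviation over mean). A model is called *stable* when IQR <= 0.05 and both
C.V.s are <= 5%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import CvResult, FeatureTable, _fit_and_score, auc_from_scores, make_classifier

#: Stability thresholds: IQR on the AUC scale, C.V.s in percent.
IQR_THRESHOLD = 0.05
CV_THRESHOLD_PCT = 5.0


@dataclass
class StabilityReport:
    """Median AUC, IQR, C.V.d, C.V.e and the stability verdict.

    Metadata fields record the numerical conventions: quartiles by linear
    interpolation between order statistics, per-group medians (not means)
    inside the C.V.s, and sample (n-1) standard deviations.
    """

    entries: list[CvResult]
    median_auc: float
    iqr: float
    cvd: float
    cve: float
    stable: bool
    quartile_rule: str = "linear"
    group_statistic: str = "median"

    def to_dict(self) -> dict:
        return {
            "median_auc": self.median_auc,
            "iqr": self.iqr,
            "cvd_pct": self.cvd,
            "cve_pct": self.cve,
            "stable": self.stable,
            "quartile_rule": self.quartile_rule,
            "group_statistic": self.group_statistic,
            "entries": [e.to_dict() for e in self.entries],
        }

    def write_json(self, path: Path | str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "StabilityReport":
        return cls(
            entries=[CvResult.from_dict(e) for e in raw["entries"]],
            median_auc=float(raw["median_auc"]),
            iqr=float(raw["iqr"]),
            cvd=float(raw["cvd_pct"]),
            cve=float(raw["cve_pct"]),
            stable=bool(raw["stable"]),
            quartile_rule=raw.get("quartile_rule", "linear"),
            group_statistic=raw.get("group_statistic", "median"),
        )

    @classmethod
    def read_json(cls, path: Path | str) -> "StabilityReport":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _cv_percent(group_values: Sequence[float]) -> float:
    """100 * sample sd / mean; zero when fewer than two groups."""
    values = np.asarray(list(group_values), dtype=float)
    if values.size < 2 or np.ptp(values) == 0.0:
        return 0.0
    return float(100.0 * values.std(ddof=1) / values.mean())


def aggregate(
    results: Sequence[CvResult],
    iqr_threshold: float = IQR_THRESHOLD,
    cv_threshold: float = CV_THRESHOLD_PCT,
) -> StabilityReport:
    """Summarize CvResults over dataset x exposure combinations.

    Median and IQR (Q3 - Q1, linear-interpolation quartiles) are taken
    over all entry AUCs; C.V.d and C.V.e are the coefficients of variation
    of per-dataset and per-exposure median AUCs.
    """
    if len(results) < 2:
        raise ValidationError("aggregate: need at least two CvResults")
    aucs = np.array([r.auc for r in results], dtype=float)
    q1, q3 = np.percentile(aucs, [25, 75])
    frame = pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in results],
            "exposure_style": [r.exposure_style for r in results],
            "auc": aucs,
        }
    )
    cvd = _cv_percent(frame.groupby("dataset_id")["auc"].median())
    cve = _cv_percent(frame.groupby("exposure_style")["auc"].median())
    iqr = float(q3 - q1)

    def within(value: float, bound: float) -> bool:
        # "<=" up to float representation error, so the verdict flips
        # exactly at the printed boundary
        return value <= bound or np.isclose(value, bound, rtol=1e-9, atol=1e-12)

    stable = bool(
        within(iqr, iqr_threshold)
        and within(cvd, cv_threshold)
        and within(cve, cv_threshold)
    )
    return StabilityReport(
        entries=list(results),
        median_auc=float(np.median(aucs)),
        iqr=iqr,
        cvd=cvd,
        cve=cve,
        stable=stable,
    )


def report_row(name: str, report: StabilityReport,
               short_term_median: float | None = None) -> dict:
    """One summary-table row for a signature."""
    return {
        "signature": name,
        "median_auc_short_term": short_term_median,
        "median_auc": report.median_auc,
        "iqr": report.iqr,
        "cvd_pct": report.cvd,
        "cve_pct": report.cve,
        "stable": report.stable,
    }


def external_validate(
    train: FeatureTable,
    test: FeatureTable,
    algorithm: str = "rf",
    params: Mapping | None = None,
    seed: int = 0,
) -> float:
    """Train once on one dataset's chemicals and score another's.

    Gene columns are intersected (platform restriction); an empty
    intersection or a single-class test set is an error.
    """
    train.validate()
    test.validate()
    shared = [g for g in train.X.columns if g in set(test.X.columns)]
    if not shared:
        raise ValidationError(
            f"external_validate: no shared biomarker genes between "
            f"{train.dataset_id} and {test.dataset_id}"
        )
    if test.y.nunique() < 2:
        raise ValidationError(
            f"external_validate: test set {test.dataset_id} has a single "
            "class; AUC undefined"
        )
    clf = make_classifier(algorithm, seed=seed, params=params)
    scores = _fit_and_score(
        clf,
        train.X[shared].to_numpy(float),
        train.y.to_numpy(object),
        test.X[shared].to_numpy(float),
    )
    return auc_from_scores(test.y, scores)
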