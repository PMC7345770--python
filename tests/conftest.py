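import numpy as np
import pandas as pd
import pytest

import tinvmark as tm


def build_study(
    values: np.ndarray,
    genes,
    sample_meta,
    dataset_id="DS1",
    platform="affymetrix",
) -> tm.ExpressionStudy:
    """Assemble a study from a matrix and a list of metadata dicts."""
    meta = pd.DataFrame(sample_meta).set_index("sample_id")
    expr = pd.DataFrame(values, index=pd.Index(genes, name="probe_id"),
                        columns=meta.index)
    return tm.ExpressionStudy(dataset_id, platform, expr, meta)


def sample_row(sid, chem, exposure, replicate=1, is_control=False, dose="high"):
    return dict(
        sample_id=sid,
        chemical_id=chem,
        exposure_style=exposure,
        dose_group=dose,
        replicate=replicate,
        is_control=is_control,
    )


@pytest.fixture
def tiny_study() -> tm.ExpressionStudy:
    """3 genes x 4 samples: one chemical (triplicate-free) plus one control."""
    meta = [
        sample_row("s1", "CONTROL", "1d", 1, True),
        sample_row("s2", "chemA", "1d", 1),
        sample_row("s3", "chemA", "1d", 2),
        sample_row("s4", "chemA", "1d", 3),
    ]
    values = np.array(
        [
            [2.0, 4.0, 5.0, 6.0],
            [3.0, 3.0, 3.0, 3.0],
            [1.0, 0.5, 1.5, 1.0],
        ]
    )
    return build_study(values, ["gA", "gB", "gC"], meta)


def profile_matrix(values, genes, chemicals, labels_map,
                   dataset_id="DS1", exposure="3d") -> tm.ChemicalProfileMatrix:
    profiles = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=pd.Index(genes, name="gene"),
        columns=chemicals,
    )
    return tm.ChemicalProfileMatrix(
        dataset_id, exposure, profiles, pd.Series(labels_map)
    )


@pytest.fixture
def separable_features() -> tm.FeatureTable:
    """One feature, NGHC at +2 and NHC at -2, ten chemicals per class."""
    chems = [f"p{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
    X = pd.DataFrame(
        {"gene1": [2.0] * 10 + [-2.0] * 10}, index=pd.Index(chems, name="chemical")
    )
    y = pd.Series(["NGHC"] * 10 + ["NHC"] * 10, index=X.index)
    return tm.FeatureTable(X, y, "DS1", "3d")


def make_deg_table(rows: dict) -> pd.DataFrame:
    """rows: gene -> (p_value, delta). is_deg derived from the standard rule."""
    genes = list(rows)
    p = np.array([rows[g][0] for g in genes])
    delta = np.array([rows[g][1] for g in genes])
    return pd.DataFrame(
        {
            "p_value": p,
            "delta": delta,
            "direction": np.where(delta < 0, "-", "+"),
            "is_deg": (p < 0.05) & (np.abs(delta) >= np.log2(1.5)) & (delta != 0),
        },
        index=pd.Index(genes, name="gene"),
    )


# Planted-signal settings used for parameter-recovery checks: three
# datasets on three short-term exposure styles, triplicates, ten
# constant-direction and ten transient/sign-flipping genes, a 1.0 log2
# effect over 0.3 log2 noise, 30 NGHC vs 100 NHC chemicals.
RECOVERY_CONFIG = tm.SimulationConfig(
    n_genes=2000,
    n_datasets=3,
    exposure_styles=("1d", "3d", "1w"),
    n_nghc=30,
    n_nhc=100,
    n_replicates=3,
    n_invariant_up=5,
    n_invariant_down=5,
    n_variant=10,
    effect_size=1.0,
    noise_sd=0.3,
    dataset_shift_sd=0.2,
    missing_probe_fraction=0.0,
    seed=1,
)


@pytest.fixture(scope="session")
def recovery_run():
    """One full discovery run at the parameter-recovery settings."""
    studies, truth = tm.simulate(RECOVERY_CONFIG)
    labels = pd.Series(truth.chemical_labels)
    invariant, modulation = tm.discover_invariant_set(
        studies, labels, "3d", ("1d", "3d", "1w")
    )
    return studies, truth, invariant, modulation
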