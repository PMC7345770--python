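"""Chemical profiles and the NGHC-vs-NHC differential-expression filter."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tinvmark as tm
from tinvmark.errors import PipelineError, ValidationError

from _oracles import welch_t_p
from conftest import build_study, profile_matrix, sample_row


def replicate_study(treated, controls, control_chem="CONTROL"):
    """One gene, one chemical: explicit treated/control replicate values."""
    meta, cols = [], []
    for i, v in enumerate(controls):
        meta.append(sample_row(f"c{i}", control_chem, "1d", i + 1, True))
        cols.append(v)
    for i, v in enumerate(treated):
        meta.append(sample_row(f"t{i}", "chemA", "1d", i + 1))
        cols.append(v)
    return build_study(np.array([cols]), ["gA"], meta)


def test_profile_is_mean_treated_minus_mean_control():
    study = replicate_study([4.0, 5.0, 6.0], [2.0, 2.0, 2.0])
    prof = tm.chemical_profiles(study, "1d")
    assert prof.profiles.loc["gA", "chemA"] == pytest.approx(3.0)


def test_identical_treated_and_control_gives_zero_profile():
    study = replicate_study([2.5, 2.5, 2.5], [2.5, 2.5, 2.5])
    prof = tm.chemical_profiles(study, "1d")
    assert (prof.profiles.to_numpy() == 0).all()


def test_missing_controls_error_names_the_cell():
    study = replicate_study([1.0], [2.0])
    with pytest.raises(PipelineError, match="chemA"):
        tm.chemical_profiles(study, "1d", control_policy="matched")


def test_pooled_equals_matched_when_each_chemical_owns_the_pool():
    """Per-chemical controls identical to the pool: both policies agree."""
    rng = np.random.default_rng(3)
    control_vals = rng.normal(5, 1, size=(4, 2))  # 4 genes, 2 control reps
    meta, cols = [], []
    for r in range(2):
        meta.append(sample_row(f"cA{r}", "chemA", "1d", r + 1, True))
        cols.append(control_vals[:, r])
        meta.append(sample_row(f"cB{r}", "chemB", "1d", r + 1, True))
        cols.append(control_vals[:, r])
    for chem in ("chemA", "chemB"):
        for r in range(3):
            meta.append(sample_row(f"t{chem}{r}", chem, "1d", r + 1))
            cols.append(rng.normal(5, 1, 4))
    study = build_study(np.column_stack(cols), list("wxyz"), meta)
    pooled = tm.chemical_profiles(study, "1d", control_policy="pooled")
    matched = tm.chemical_profiles(study, "1d", control_policy="matched")
    pd.testing.assert_frame_equal(pooled.profiles, matched.profiles)


def test_forced_separation_is_deg_up():
    rng = np.random.default_rng(0)
    jitter = rng.normal(0, 1e-3, size=(1, 8))
    prof = profile_matrix(
        np.array([[2.0] * 4 + [0.0] * 4]) + jitter,
        ["gA"],
        [f"c{i}" for i in range(8)],
        {f"c{i}": ("NGHC" if i < 4 else "NHC") for i in range(8)},
    )
    table = tm.test_differential(prof)
    assert bool(table.at["gA", "is_deg"])
    assert table.at["gA", "direction"] == "+"


def test_identical_group_distributions_not_deg():
    prof = profile_matrix(
        np.tile([1.0, 2.0, 1.0, 2.0], (3, 1)),
        ["gA", "gB", "gC"],
        ["c0", "c1", "c2", "c3"],
        {"c0": "NGHC", "c1": "NGHC", "c2": "NHC", "c3": "NHC"},
    )
    table = tm.test_differential(prof)
    assert not table["is_deg"].any()


def test_zero_variance_identical_groups_p_is_one():
    prof = profile_matrix(
        np.ones((1, 6)),
        ["gA"],
        [f"c{i}" for i in range(6)],
        {f"c{i}": ("NGHC" if i < 3 else "NHC") for i in range(6)},
    )
    table = tm.test_differential(prof)
    assert table.at["gA", "p_value"] == 1.0
    assert not bool(table.at["gA", "is_deg"])


def test_small_class_errors():
    prof = profile_matrix(
        np.ones((1, 3)),
        ["gA"],
        ["c0", "c1", "c2"],
        {"c0": "NGHC", "c1": "NHC", "c2": "NHC"},
    )
    with pytest.raises(ValidationError, match="NGHC"):
        tm.test_differential(prof)


def random_profiles(seed, n_genes=50, n_pos=6, n_neg=14):
    rng = np.random.default_rng(seed)
    chems = [f"c{i}" for i in range(n_pos + n_neg)]
    labels = {c: ("NGHC" if i < n_pos else "NHC") for i, c in enumerate(chems)}
    values = rng.normal(0, 1, size=(n_genes, n_pos + n_neg))
    values[: n_genes // 2, :n_pos] += rng.normal(0, 1, size=(n_genes // 2, 1))
    return profile_matrix(values, [f"g{i}" for i in range(n_genes)], chems, labels)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_welch_p_values_match_textbook_oracle(seed):
    prof = random_profiles(seed)
    table = tm.test_differential(prof, test_variant="welch")
    pos = prof.class_columns("NGHC")
    neg = prof.class_columns("NHC")
    for gene in prof.profiles.index:
        x = prof.profiles.loc[gene, pos].tolist()
        y = prof.profiles.loc[gene, neg].tolist()
        _, p_expected = welch_t_p(x, y)
        assert abs(table.at[gene, "p_value"] - p_expected) < 1e-10
        assert table.at[gene, "delta"] == pytest.approx(
            np.mean(x) - np.mean(y), abs=1e-12
        )


def test_null_type_one_rate_within_binomial_bounds():
    """With no planted effect the p<0.05 rate stays near nominal."""
    config = tm.SimulationConfig(
        n_genes=2000,
        n_datasets=1,
        exposure_styles=("1d",),
        n_nghc=15,
        n_nhc=40,
        n_variant=0,
        n_invariant_up=0,
        n_invariant_down=0,
        effect_size=0.0,
        noise_sd=0.3,
        missing_probe_fraction=0.0,
        seed=11,
    )
    studies, truth = tm.simulate(config)
    prof = tm.chemical_profiles(
        studies[0], "1d", labels=pd.Series(truth.chemical_labels)
    )
    table = tm.test_differential(prof)
    rate = (table["p_value"] < 0.05).mean()
    half_width = 2.576 * np.sqrt(0.05 * 0.95 / len(table))
    assert 0.05 - half_width < rate < 0.05 + half_width
    # and essentially nothing survives the fold-change filter
    assert table["is_deg"].mean() < 0.01


def test_deg_monotone_in_alpha_and_fold():
    prof = random_profiles(5)
    base = tm.test_differential(prof, alpha=0.05, fold_threshold=1.5)
    stricter_alpha = tm.test_differential(prof, alpha=0.01, fold_threshold=1.5)
    stricter_fold = tm.test_differential(prof, alpha=0.05, fold_threshold=2.0)
    assert set(stricter_alpha.index[stricter_alpha["is_deg"]]) <= set(
        base.index[base["is_deg"]]
    )
    assert set(stricter_fold.index[stricter_fold["is_deg"]]) <= set(
        base.index[base["is_deg"]]
    )


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    shift=st.floats(-5, 5, allow_nan=False),
    perm_seed=st.integers(0, 2**16),
)
def test_invariant_to_column_order_and_constant_shift(shift, perm_seed):
    prof = random_profiles(9, n_genes=10)
    base = tm.test_differential(prof)
    rng = np.random.default_rng(perm_seed)
    order = rng.permutation(prof.profiles.columns)
    shuffled = tm.ChemicalProfileMatrix(
        prof.dataset_id,
        prof.exposure_style,
        prof.profiles[order] + shift,
        prof.labels,
    )
    table = tm.test_differential(shuffled)
    np.testing.assert_allclose(
        table["p_value"], base["p_value"], rtol=1e-9, atol=1e-12
    )
    pd.testing.assert_series_equal(table["is_deg"], base["is_deg"])


def test_deg_table_round_trip(tmp_path):
    from tinvmark.deg import read_deg, write_deg

    table = tm.test_differential(random_profiles(2))
    write_deg(table, tmp_path / "deg.tsv")
    back = read_deg(tmp_path / "deg.tsv")
    np.testing.assert_allclose(back["p_value"], table["p_value"], atol=1e-9)
    assert (back["is_deg"] == table["is_deg"]).all()
    assert (back["direction"] == table["direction"]).all()
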