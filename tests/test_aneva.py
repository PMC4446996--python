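import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epifst import (
    ANEVA,
    ValidationError,
    aneva_table,
    effective_sample_size,
    min_epi_fst,
    permutation_test,
    variance_components,
)
from epifst.aneva import _exhaustive_assignments

from conftest import random_instance


# ---------------------------------------------------------------------------
# variance components


@pytest.mark.parametrize(
    "values, labels, expected",
    [
        # constant shift between species, no within variation
        ([1, 1, 1, 3, 3, 3], ["A"] * 3 + ["B"] * 3,
         dict(ss_between=6, ss_within=0, n0=3, s2=0, s2_alpha=2, epi_fst=1.0)),
        # constant everywhere: everything zero, statistic undefined
        ([1, 1, 1, 1], ["A", "A", "B", "B"],
         dict(ss_between=0, ss_within=0, s2=0, s2_alpha=0, epi_fst=math.nan)),
        # hand-worked balanced case
        ([0, 2, 4, 6], ["A", "A", "B", "B"],
         dict(ss_between=16, ss_within=4, s2=2, n0=2, s2_alpha=7, epi_fst=7 / 9)),
        # equal means with within variation: the attainable minimum -1/(n0-1)
        ([0, 2, 1, 1], ["A", "A", "B", "B"],
         dict(ss_between=0, ss_within=2, s2=1, n0=2, s2_alpha=-0.5, epi_fst=-1.0)),
    ],
)
def test_variance_components_hand_algebra(values, labels, expected):
    vc = variance_components(values, labels)
    for field, want in expected.items():
        got = getattr(vc, field)
        if isinstance(want, float) and math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, rel=1e-12)


def test_variance_components_rejects_bad_designs():
    with pytest.raises(ValidationError, match="2 species"):
        variance_components([1, 2, 3], ["A", "A", "A"])
    with pytest.raises(ValidationError, match="fewer than 2"):
        variance_components([1, 2, 3], ["A", "A", "B"])


def test_oracle_equivalence_statsmodels():
    """SS/MS/df agree with an independent one-way ANOVA implementation."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(7)
    for _ in range(40):
        values, labels = random_instance(rng)
        vc = variance_components(values, labels)
        tab = sm.stats.anova_lm(
            ols("y ~ C(g)", pd.DataFrame({"y": values, "g": labels})).fit()
        )
        assert vc.ss_between == pytest.approx(tab["sum_sq"].iloc[0], rel=1e-9)
        assert vc.ss_within == pytest.approx(tab["sum_sq"].iloc[1], rel=1e-9)
        assert vc.df_between == tab["df"].iloc[0]
        assert vc.df_within == tab["df"].iloc[1]
        assert vc.ms_between == pytest.approx(tab["mean_sq"].iloc[0], rel=1e-9)


def test_effective_sample_size_unbalanced():
    # 11 + 4 samples: (15 - (121+16)/15) / 1 = 88/15
    assert effective_sample_size([11, 4]) == pytest.approx(88 / 15, rel=1e-12)
    # balanced designs give the common group size
    assert effective_sample_size([5, 5, 5]) == pytest.approx(5.0)


def test_n0_override_changes_s2_alpha():
    vc = variance_components([0, 2, 1, 1], ["A", "A", "B", "B"], n0=6.0)
    assert vc.n0 == 6.0
    assert vc.epi_fst == pytest.approx(-0.2)


@given(
    st.lists(st.floats(-50, 50), min_size=4, max_size=12),
    st.floats(0.1, 10),
    st.floats(-100, 100),
)
def test_epifst_location_scale_invariant(values, a, b):
    """epi-FST is unchanged by y -> a*y + b (all SS scale by a^2)."""
    n = len(values)
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    vc = variance_components(values, labels)
    vc2 = variance_components(a * np.asarray(values) + b, labels)
    # skip near-degenerate cases where the statistic itself is ill-conditioned
    if vc.defined and vc.s2_alpha + vc.s2 > 1e-3 * max(vc.s2, vc.ms_between, 1e-9):
        assert vc2.epi_fst == pytest.approx(vc.epi_fst, abs=1e-6)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=60)
def test_ss_conservation_and_bounds(seed):
    """SS_between + SS_within equals the directly computed total SS, and a
    defined epi-FST obeys -1/(n0-1) <= fst <= 1, hitting 1 iff SS_within=0
    with SS_between>0."""
    rng = np.random.default_rng(seed)
    values, labels = random_instance(rng)
    vc = variance_components(values, labels)
    total = float(((values - values.mean()) ** 2).sum())
    assert vc.ss_between + vc.ss_within == pytest.approx(total, rel=1e-9, abs=1e-12)
    if vc.defined:
        assert min_epi_fst(vc.n0) - 1e-12 <= vc.epi_fst <= 1 + 1e-12
        if vc.ss_within == 0 and vc.ss_between > 0:
            assert vc.epi_fst == pytest.approx(1.0)
        else:
            assert vc.epi_fst < 1


# ---------------------------------------------------------------------------
# minimum epi-FST


def test_min_epi_fst_values_and_limit():
    assert min_epi_fst(6) == pytest.approx(-0.2, abs=1e-15)
    assert min_epi_fst(2) == -1.0
    grid = np.logspace(0.5, 6, 30)
    mins = [min_epi_fst(n) for n in grid]
    assert all(b > a for a, b in zip(mins, mins[1:]))  # monotone toward 0
    assert abs(min_epi_fst(1e6)) < 1e-5
    with pytest.raises(ValueError):
        min_epi_fst(1.0)


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_constant_data_undefined():
    pr = permutation_test([2, 2, 2, 2], ["A", "A", "B", "B"], n_perm=50, seed=1)
    assert not pr.observed_defined
    assert pr.p_value == 1.0


def test_permutation_exhaustive_matches_manual_enumeration():
    """p on A=[0,0], B=[10,10] equals the enumerated tail with +1 correction:
    2 of the 6 assignments reproduce a perfect split (fst=1)."""
    pr = permutation_test([0, 0, 10, 10], ["A", "A", "B", "B"], exhaustive=True)
    assert pr.n_permutations == 6
    assert pr.n_as_extreme == 2
    assert pr.p_value == pytest.approx(3 / 7)


def test_exhaustive_assignment_count_multinomial():
    # 7 samples into groups (3, 2, 2): 7!/(3!2!2!) = 210 assignments
    assert len(_exhaustive_assignments(7, np.array([3, 2, 2]))) == 210


def test_permutation_reproducible_and_seed_sensitive():
    rng = np.random.default_rng(3)
    y = rng.normal(size=10)
    labels = ["A"] * 6 + ["B"] * 4
    a = permutation_test(y, labels, n_perm=200, seed=9)
    b = permutation_test(y, labels, n_perm=200, seed=9)
    assert a == b


def test_permutation_converges_to_exhaustive_tail():
    rng = np.random.default_rng(12)
    y = rng.normal(size=9)
    labels = ["A"] * 5 + ["B"] * 4
    exact = permutation_test(y, labels, exhaustive=True)
    approx = permutation_test(y, labels, n_perm=4000, seed=0)
    p = exact.n_as_extreme / exact.n_permutations
    se = math.sqrt(p * (1 - p) / 4000)
    assert abs(approx.p_value - exact.p_value) < 4 * se + 2 / exact.n_permutations


# ---------------------------------------------------------------------------
# table / model / results


def test_aneva_table_contract(primate_pm):
    pm, _ = primate_pm
    tab = aneva_table(pm, species=["human", "chimp"], n_perm=0)
    assert len(tab) == pm.n_peaks
    total = tab["ss_between"] + tab["ss_within"]
    sub = pm.subset_species(["human", "chimp"])
    direct = ((sub.densities - sub.densities.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    np.testing.assert_allclose(total, direct, rtol=1e-9)
    # macaque samples excluded: group-mean columns only for requested species
    assert "mean_macaque" not in tab.columns
    assert {"mean_human", "mean_chimp"} <= set(tab.columns)
    np.testing.assert_allclose(tab["n0"], 88 / 15)


def test_model_fit_results_surface(primate_pm):
    pm, _ = primate_pm
    model = ANEVA.from_peak_matrix(pm, species=["human", "chimp"])
    res = model.fit(n_perm=99, seed=4)
    t = res.table
    assert {"epi_fst", "p_value", "p_adjusted", "n_as_extreme"} <= set(t.columns)
    defined = t["fst_defined"]
    assert ((t.loc[defined, "p_value"] > 0) & (t.loc[defined, "p_value"] <= 1)).all()
    # p = (r+1)/(n+1) identity
    np.testing.assert_allclose(
        t.loc[defined, "p_value"], (t.loc[defined, "n_as_extreme"] + 1) / 100
    )
    assert "epi-FST" in res.summary()
    # same seed reproduces identical permutation outcomes
    res2 = model.fit(n_perm=99, seed=4)
    pd.testing.assert_frame_equal(res.table, res2.table)


def test_from_dataframe_matches_file_path(toy_pm):
    model = ANEVA.from_dataframe(toy_pm.to_frame(), toy_pm.metadata.table)
    res = model.fit(n_perm=0)
    vc = variance_components(toy_pm.densities[0], toy_pm.species_labels())
    assert res.table.loc[0, "epi_fst"] == pytest.approx(vc.epi_fst)


def test_unknown_species_label_rejected(toy_pm):
    with pytest.raises(ValidationError, match="gorilla"):
        aneva_table(toy_pm, species=["human", "gorilla"])
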