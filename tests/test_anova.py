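"""From-scratch repeated-measures ANOVA vs independent implementations."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cylgrip import anova as ra
from cylgrip.errors import (
    IncompleteDesignError,
    InsufficientDataError,
    MissingCellError,
)
from cylgrip.synthetic_hand import default_cohort_spec, simulate_cohort


def make_long(Y, factors, subject="subject", dv="y"):
    """(n, k1, ..., km) array -> long DataFrame with string levels."""
    n = Y.shape[0]
    rows = []
    for s in range(n):
        for idx in np.ndindex(*Y.shape[1:]):
            row = {subject: s, dv: Y[(s, *idx)]}
            for (name, _), i in zip(factors, idx):
                row[name] = f"{name}{i}"
            rows.append(row)
    return pd.DataFrame(rows)


def null_dataset(rng, n=10, shape=(3, 4, 3), names=("A", "B", "C")):
    Y = rng.normal(size=(n, *shape)) + rng.normal(size=(n,) + (1,) * len(shape))
    return make_long(Y, [(nm, k) for nm, k in zip(names, shape)])


# ---------------------------------------------------------------------------
# degrees of freedom

def test_three_way_design_dfs():
    dfs = ra.anova_dfs([3, 4, 3], 10)
    assert dfs["A:B:C"]["df"] == 12
    assert dfs["B"] == {"df": 3, "df_error": 27}
    assert dfs["A"] == {"df": 2, "df_error": 18}


def test_two_way_and_minimal_design_dfs():
    dfs = ra.anova_dfs([3, 4], 10)
    assert dfs["A:B"] == {"df": 6, "df_error": 54}
    assert dfs["A"] == {"df": 2, "df_error": 18}
    assert ra.anova_dfs([2], 2)["A"] == {"df": 1, "df_error": 1}


# ---------------------------------------------------------------------------
# the table itself

def test_constant_response_flags_undefined_f():
    df = make_long(np.full((4, 3), 7.0), [("A", 3)])
    res = ra.rm_anova(df, "y", ["A"], "subject")
    row = res.table.iloc[0]
    assert row["ss"] == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(row["F"]) and np.isnan(row["p_value"])
    assert "undefined" in row["note"]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_ss_decomposition_is_exact(seed):
    rng = np.random.default_rng(seed)
    df = null_dataset(rng, n=6, shape=(2, 3), names=("A", "B"))
    res = ra.rm_anova(df, "y", ["A", "B"], "subject", correction="none")
    total = (res.table["ss"].sum() + res.table["error_ss"].sum()
             + res.subject_ss)
    assert total == pytest.approx(res.ss_total, rel=1e-10)


def test_unbalanced_data_rejected():
    rng = np.random.default_rng(0)
    df = null_dataset(rng, n=5, shape=(3,), names=("A",))
    with pytest.raises(IncompleteDesignError):
        ra.rm_anova(df.iloc[:-1], "y", ["A"], "subject")


@pytest.mark.parametrize("seed", [101, 102, 103])
def test_three_way_table_matches_r_aov(seed):
    from cylgrip.validation import reference_rm_anova

    coh = simulate_cohort(default_cohort_spec(seed=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ra.rm_anova(coh, "angle_deg",
                          ["diameter_mm", "finger", "joint"], "subject",
                          correction="none")
    ref = reference_rm_anova(coh, "angle_deg",
                             ["diameter_mm", "finger", "joint"], "subject")
    mine = res.table.set_index("source")
    for _, r in ref.iterrows():
        m = mine.loc[r["source"]]
        for col_m, col_r in [("ss", "ss"), ("F", "F"),
                             ("p_value", "p_value"), ("df", "df")]:
            assert m[col_m] == pytest.approx(r[col_r], rel=1e-8), r["source"]


# ---------------------------------------------------------------------------
# sphericity and the GG correction

def test_two_level_factor_sphericity_is_vacuous():
    rng = np.random.default_rng(1)
    df = null_dataset(rng, n=8, shape=(2,), names=("A",))
    sp = ra.mauchly_test(df, "y", ["A"], "subject")
    assert sp.mauchly_w == 1.0 and sp.epsilon_gg == 1.0
    assert sp.df == 0 and not sp.testable


def test_mauchly_near_one_under_compound_symmetry():
    rng = np.random.default_rng(2)
    n, k = 200, 4
    Y = rng.normal(size=(n, k)) + 2.0 * rng.normal(size=(n, 1))
    df = make_long(Y, [("A", k)])
    sp = ra.mauchly_test(df, "y", ["A"], "subject")
    assert sp.testable
    assert sp.mauchly_w > 0.9
    assert sp.epsilon_gg > 0.95


def test_mauchly_p_uniform_under_spherical_null():
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(300):
        Y = rng.normal(size=(20, 3))
        sp = ra.mauchly_test(make_long(Y, [("A", 3)]), "y", ["A"], "subject")
        ps.append(sp.p_value)
    # rejection rate near the nominal level
    assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.09


@pytest.mark.parametrize("seed", [5, 6])
def test_mauchly_and_epsilon_match_pingouin(seed):
    import pingouin as pg

    rng = np.random.default_rng(seed)
    n, k = 12, 4
    Y = rng.normal(size=(n, k)) * np.array([1.0, 2.0, 0.5, 1.5])
    Y += rng.normal(size=(n, 1))
    df = make_long(Y, [("A", k)])
    sp = ra.mauchly_test(df, "y", ["A"], "subject")
    ref = pg.sphericity(df, dv="y", within="A", subject="subject")
    eps = pg.epsilon(df, dv="y", within="A", subject="subject", correction="gg")
    assert sp.mauchly_w == pytest.approx(ref.W, rel=1e-8)
    assert sp.chi_square == pytest.approx(ref.chi2, rel=1e-8)
    assert sp.p_value == pytest.approx(ref.pval, rel=1e-8)
    assert sp.epsilon_gg == pytest.approx(eps, rel=1e-8)


def test_singular_contrast_covariance_reported_as_boundary():
    rng = np.random.default_rng(4)
    coh = simulate_cohort(default_cohort_spec(seed=4))
    with pytest.warns(UserWarning, match="singular"):
        sp = ra.mauchly_test(coh, "angle_deg",
                             ["diameter_mm", "finger", "joint"], "subject",
                             effect=["diameter_mm", "finger", "joint"])
    assert sp.mauchly_w == 0.0 and not sp.testable
    assert 1.0 / 12 <= sp.epsilon_gg <= 1.0


def test_gg_correction_never_decreases_p_in_rejection_region():
    """Shrinking both df by epsilon <= 1 is conservative wherever the
    uncorrected test is anywhere near rejection (for F in the deep null
    bulk, i.e. F well below 1, the two survival curves cross, so the
    guarantee is asserted where significance decisions live)."""
    rng = np.random.default_rng(8)
    checked = 0
    while checked < 5:
        Y = rng.normal(size=(9, 4)) * np.array([0.3, 1.0, 2.0, 3.0])
        Y += np.array([0.0, 1.0, 2.0, 0.5])  # real effect
        df = make_long(Y, [("A", 4)])
        p_none = ra.rm_anova(df, "y", ["A"], "subject",
                             correction="none").table.iloc[0]["p_value"]
        if p_none >= 0.2:
            continue
        p_gg = ra.rm_anova(df, "y", ["A"], "subject",
                           correction="gg").table.iloc[0]["p_value"]
        assert p_gg >= p_none - 1e-12
        checked += 1


def test_corrected_df_scales_by_epsilon():
    rng = np.random.default_rng(9)
    Y = rng.normal(size=(10, 3)) * np.array([0.2, 1.0, 3.0])
    df = make_long(Y, [("A", 3)])
    res = ra.rm_anova(df, "y", ["A"], "subject", correction="gg")
    row = res.table.iloc[0]
    assert row["correction"] == "greenhouse_geisser"
    assert row["df"] == pytest.approx(2 * row["epsilon"])
    assert row["ms"] == pytest.approx(row["ss"] / row["df"], rel=1e-9)


# ---------------------------------------------------------------------------
# follow-up tests

def test_simple_main_effects_equal_subset_anova():
    coh = simulate_cohort(default_cohort_spec(seed=21))
    sme = ra.simple_main_effects(coh, "angle_deg", "diameter_mm", "subject",
                                 by=["finger", "joint"])
    assert len(sme) == 4 * 3  # one table per fixed combination
    sub = coh[(coh.finger == "ring") & (coh.joint == "PIP")]
    direct = ra.rm_anova(sub, "angle_deg", ["diameter_mm"], "subject")
    row = sme[(sme.finger == "ring") & (sme.joint == "PIP")].iloc[0]
    assert row["F"] == pytest.approx(direct.table.iloc[0]["F"], rel=1e-10)
    assert row["p_value"] == pytest.approx(direct.table.iloc[0]["p_value"],
                                           rel=1e-10)


def test_simple_main_effects_missing_combination_raises():
    coh = simulate_cohort(default_cohort_spec(seed=21))
    with pytest.raises(MissingCellError):
        ra.simple_main_effects(coh, "angle_deg", "diameter_mm", "subject",
                               by=["finger", "joint"],
                               fixed={"finger": "thumb", "joint": "PIP"})


def test_identical_cell_means_give_near_zero_f():
    rng = np.random.default_rng(30)
    n, k = 2000, 3
    Y = rng.normal(size=(n, k))  # exchangeable: no target effect
    df = make_long(Y, [("A", k)])
    res = ra.rm_anova(df, "y", ["A"], "subject", correction="none")
    assert res.table.iloc[0]["F"] < 5  # O(1), not diverging


def test_bonferroni_adjustment_and_direction_strings():
    coh = simulate_cohort(default_cohort_spec(seed=33))
    pw = ra.bonferroni_pairwise(coh, "angle_deg", "diameter_mm", "subject",
                                by=["finger", "joint"])
    assert len(pw) == 12 * 3  # 12 combinations x 3 diameter pairs
    for row in pw.itertuples():
        assert row.m == 3
        assert row.p_bonferroni == pytest.approx(min(1.0, 3 * row.p_raw))
        if row.significant:
            hi = row.level_a if row.mean_diff > 0 else row.level_b
            assert str(hi) == row.direction.split(" > ")[0]
        else:
            assert row.direction == ""


def test_bonferroni_global_family_multiplier():
    coh = simulate_cohort(default_cohort_spec(seed=33))
    pw = ra.bonferroni_pairwise(coh, "angle_deg", "diameter_mm", "subject",
                                by=["finger", "joint"], family="global")
    assert (pw["m"] == 36).all()


def test_bonferroni_pooled_error_method_runs():
    coh = simulate_cohort(default_cohort_spec(seed=33))
    pw = ra.bonferroni_pairwise(coh, "angle_deg", "diameter_mm", "subject",
                                by=[], method="pooled")
    assert len(pw) == 3
    assert (pw["df"] == 18).all()  # pooled one-way error df


def test_pairwise_insufficient_subjects_rejected():
    df = make_long(np.zeros((1, 3)), [("A", 3)])
    with pytest.raises(InsufficientDataError):
        ra.bonferroni_pairwise(df, "y", "A", "subject")


def test_p_value_formatting_matches_reporting_convention():
    assert ra.format_p(0.0002) == "<0.0005"
    assert ra.format_p(0.011) == "0.011"
    assert ra.format_p(float("nan")) == "undefined"
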