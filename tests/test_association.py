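"""Association layer: representatives, linear models, ANOVA, Tukey-Kramer
and multiplicity control against closed forms and statsmodels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from metmodnet.association import (
    module_group_anova,
    module_representatives,
    module_trait_lm,
    per_metabolite_group_test,
)
from metmodnet.io import TraitTable
from metmodnet.network import GREY, ModuleAssignment
from metmodnet.simulate import simulate_cohort
from metmodnet.stats import adjust_pvalues, one_way_anova, studentized_range_sf, tukey_kramer

from conftest import small_config, toy_meta, toy_matrix


@pytest.fixture(scope="module")
def cohort_no_noise():
    cfg = small_config(
        seed=21, n_high_cv=0, n_forced_high_missing=0, missing_rate=0.0, outlier_rate=0.0
    )
    return simulate_cohort(cfg)


def _truth_assignment(matrix, truth):
    labels = pd.Series(
        ["blue" if truth.module_of[m] == 0 else GREY for m in matrix.metabolite_ids],
        index=matrix.values.index,
    )
    return ModuleAssignment(labels, "baseline")


# -- representatives -----------------------------------------------------------


def test_identical_metabolite_module_measures_perfectly_correlated():
    meta = toy_meta(n_subjects=8)
    ids = meta.sample_ids(role="experimental")
    rng = np.random.default_rng(0)
    x = rng.normal(size=len(ids))
    mat = toy_matrix(np.vstack([x, x, x]), sample_ids=ids, log_scale=True)
    labels = pd.Series(["blue"] * 3, index=mat.values.index)
    reps = module_representatives(mat.values, ModuleAssignment(labels), meta, include_grey=False)
    r = np.corrcoef(reps.eigen["blue"], reps.zmean["blue"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)


def test_single_metabolite_module_equals_zscores():
    meta = toy_meta(n_subjects=10)
    ids = meta.sample_ids(role="experimental")
    rng = np.random.default_rng(1)
    x = rng.normal(size=len(ids))
    mat = toy_matrix(x[None, :], sample_ids=ids, log_scale=True)
    labels = pd.Series(["blue"], index=mat.values.index)
    reps = module_representatives(mat.values, ModuleAssignment(labels), meta, include_grey=False)
    base_ids = meta.sample_ids(role="experimental", timepoint="baseline")
    xb = mat.values.loc[:, base_ids].to_numpy()[0]
    z = (xb - xb.mean()) / xb.std(ddof=1)
    np.testing.assert_allclose(reps.zmean["blue"].to_numpy(), z, atol=1e-10)
    np.testing.assert_allclose(reps.eigen["blue"].to_numpy(), z, atol=1e-10)


def test_mean_zscore_matches_brute_force(cohort_no_noise):
    matrix, meta, _, _, truth = cohort_no_noise
    vals = np.log2(matrix.values)
    assign = _truth_assignment(matrix, truth)
    reps = module_representatives(vals, assign, meta, include_grey=False)
    base_ids = meta.sample_ids(role="experimental", timepoint="baseline")
    members = assign.members("blue")
    X = vals.loc[members, base_ids].to_numpy()
    z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    np.testing.assert_allclose(reps.zmean["blue"].to_numpy(), z.mean(axis=0), atol=1e-12)


# -- linear models -------------------------------------------------------------


def test_trait_copy_of_module_zscore_gives_beta_one(cohort_no_noise):
    matrix, meta, _, _, truth = cohort_no_noise
    vals = np.log2(matrix.values)
    reps = module_representatives(vals, _truth_assignment(matrix, truth), meta, include_grey=False)
    traits = TraitTable(pd.DataFrame({"copycat": reps.zmean["blue"]}))
    res = module_trait_lm(reps, traits)
    row = res[(res["measure"] == "zscore") & (res["trait"] == "copycat")].iloc[0]
    assert row["beta"] == pytest.approx(1.0, abs=1e-10)
    assert row["p"] < 1e-20


def test_standardized_beta_equals_pearson_r(cohort_no_noise):
    matrix, meta, traits, _, truth = cohort_no_noise
    vals = np.log2(matrix.values)
    reps = module_representatives(vals, _truth_assignment(matrix, truth), meta, include_grey=False)
    res = module_trait_lm(reps, traits)
    for _, row in res[res["measure"] == "eigenmetabolite"].head(5).iterrows():
        x = reps.eigen[row["module"]].to_numpy()
        y = traits.df.loc[reps.eigen.index, row["trait"]].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        assert row["beta"] == pytest.approx(r, abs=1e-12)
        assert -1 <= row["beta"] <= 1


def test_group_coded_trait_vanishes_under_group_adjustment(cohort_no_noise):
    matrix, meta, _, _, truth = cohort_no_noise
    vals = np.log2(matrix.values)
    reps = module_representatives(vals, _truth_assignment(matrix, truth), meta, include_grey=False)
    exp = meta.experimental().drop_duplicates("subject_id").set_index("subject_id")
    # group-mean-coded trait aligned with the planted endurance module shift
    group_mean = {"control": 0.0, "bodybuilding": 0.0, "endurance": 1.0, "sprint": 0.0}
    trait_vals = np.array([group_mean[exp.loc[s, "group"]] for s in reps.eigen.index], dtype=float)
    traits = TraitTable(pd.DataFrame({"groupy": trait_vals}, index=reps.eigen.index))
    unadj = module_trait_lm(reps, traits, meta, adjust_for_group=False)
    adj = module_trait_lm(reps, traits, meta, adjust_for_group=True)
    # module 0 is planted with an endurance shift, so unadjusted association exists
    p_un = unadj[(unadj["measure"] == "eigenmetabolite") & (unadj["module"] == "blue")]["p"].iloc[0]
    p_ad = adj[(adj["measure"] == "eigenmetabolite") & (adj["module"] == "blue")]["p"].iloc[0]
    beta_ad = adj[(adj["measure"] == "eigenmetabolite") & (adj["module"] == "blue")]["beta"].iloc[0]
    assert p_un < 0.05
    assert p_ad > 0.05
    assert abs(beta_ad) < abs(
        unadj[(unadj["measure"] == "eigenmetabolite") & (unadj["module"] == "blue")]["beta"].iloc[0]
    )


def test_constant_trait_marked_untestable(cohort_no_noise):
    matrix, meta, _, _, truth = cohort_no_noise
    vals = np.log2(matrix.values)
    reps = module_representatives(vals, _truth_assignment(matrix, truth), meta, include_grey=False)
    traits = TraitTable(pd.DataFrame({"flat": np.zeros(len(reps.eigen))}, index=reps.eigen.index))
    res = module_trait_lm(reps, traits)
    assert not res["testable"].any()
    assert res["p"].isna().all()


# -- ANOVA / Tukey -------------------------------------------------------------


def test_anova_f_matches_hand_computation():
    groups = [
        np.array([1.0, 2.0, 3.0]),
        np.array([2.0, 3.0, 4.0]),
        np.array([6.0, 7.0, 8.0]),
    ]
    f, p = one_way_anova(groups)
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_hand = (ss_between / 2) / (ss_within / 6)
    assert f == pytest.approx(f_hand, abs=1e-10)
    assert p == pytest.approx(sps.f.sf(f_hand, 2, 6), abs=1e-12)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 12)
    f, p_f = one_way_anova([a, b])
    t, p_t = sps.ttest_ind(a, b, equal_var=True)
    assert f == pytest.approx(t**2, rel=1e-12)
    assert p_f == pytest.approx(p_t, rel=1e-12)


def test_tukey_kramer_matches_statsmodels():
    rng = np.random.default_rng(3)
    data = {
        "a": rng.normal(0, 1, 11),
        "b": rng.normal(0.8, 1, 9),
        "c": rng.normal(-0.3, 1, 8),
        "d": rng.normal(0.2, 1, 7),
    }
    ours = tukey_kramer(data, exact=True)
    flat = np.concatenate(list(data.values()))
    labels = np.concatenate([[g] * len(v) for g, v in data.items()])
    sm_res = pairwise_tukeyhsd(flat, labels, alpha=0.05)
    sm_pairs = {
        (str(row[0]), str(row[1])): (float(row[2]), float(p))
        for row, p in zip(sm_res._results_table.data[1:], sm_res.pvalues)
    }
    for _, row in ours.iterrows():
        diff_ref, p_ref = sm_pairs[(row["group1"], row["group2"])]
        # the summary table prints g2-g1 rounded to 4 decimals
        assert -row["meandiff"] == pytest.approx(diff_ref, abs=1e-3)
        assert row["p_tukey"] == pytest.approx(p_ref, abs=1e-6)


def test_tukey_spline_matches_exact_quadrature():
    rng = np.random.default_rng(4)
    for q in rng.uniform(0.2, 10, 12):
        exact = sps.studentized_range.sf(q, 4, 31)
        fast = studentized_range_sf(q, 4, 31)
        assert fast == pytest.approx(exact, rel=1e-4, abs=1e-12)


def test_tukey_protects_against_unadjusted_pairwise():
    rng = np.random.default_rng(5)
    data = {g: rng.normal(i * 0.3, 1, 8) for i, g in enumerate("abcd")}
    tk = tukey_kramer(data)
    for _, row in tk.iterrows():
        t, p_unadj = sps.ttest_ind(data[row["group1"]], data[row["group2"]], equal_var=True)
        assert row["p_tukey"] >= p_unadj - 1e-10


def test_module_group_anova_detects_planted_shift(cohort_no_noise):
    matrix, meta, _, _, truth = cohort_no_noise
    vals = np.log2(matrix.values)
    reps = module_representatives(vals, _truth_assignment(matrix, truth), meta, include_grey=False)
    anova, pairs = module_group_anova(reps, meta, posthoc=True)
    row = anova[anova["module"] == "blue"].iloc[0]
    assert row["p"] < 0.05 / 6  # planted 1.5-SD endurance shift, this seed
    sig_pairs = pairs[(pairs["module"] == "blue") & (pairs["p_tukey"] < 0.05)]
    assert all("endurance" in (r["group1"], r["group2"]) for _, r in sig_pairs.iterrows())


# -- per-metabolite tests -------------------------------------------------------


def test_planted_single_metabolite_shift_is_bonferroni_significant():
    rng = np.random.default_rng(6)
    meta = toy_meta(n_subjects=32, groups=("control", "bodybuilding", "endurance", "sprint"))
    ids = meta.sample_ids(role="experimental", timepoint="baseline")
    groups = meta.group_of()
    n_met = 120
    X = rng.normal(0, 1, size=(n_met, len(ids)))
    shift = np.array([3.0 if groups[s] == "endurance" else 0.0 for s in ids])
    X[0] += shift
    mat = toy_matrix(X, sample_ids=ids, log_scale=True)
    res, _ = per_metabolite_group_test(mat.values, meta, posthoc=False)
    assert bool(res.iloc[0]["significant_bonferroni"])
    null_bonf = res.iloc[1:]["significant_bonferroni"].sum()
    assert null_bonf == 0


def test_adjust_pvalues_hand_cases():
    assert adjust_pvalues([0.01], "bh")[0] == pytest.approx(0.01)
    assert adjust_pvalues([0.01], "bonferroni")[0] == pytest.approx(0.01)
    np.testing.assert_allclose(
        adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04, 0.04, 0.04, 0.04]
    )
    assert adjust_pvalues([0.03] * 857, "bonferroni")[0] == 1.0
    # adjusted >= raw always
    rng = np.random.default_rng(7)
    p = rng.uniform(size=50)
    for method in ("bh", "bonferroni"):
        assert (adjust_pvalues(p, method) >= p - 1e-12).all()
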