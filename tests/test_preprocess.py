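"""QC chain: each stage against hand or brute-force oracles, plus the
conservation invariants of the full chain."""

import numpy as np
import pandas as pd
import pytest

from metmodnet import preprocess
from metmodnet.io import IonCountMatrix, SampleMeta
from metmodnet.preprocess import (
    QCError,
    QCParams,
    QCReport,
    batch_median_normalize,
    cv_filter,
    flag_sample_outliers,
    iqr_outlier_removal,
    knn_impute,
    log2_transform,
    missingness_filter,
    replicate_cv,
    run_qc,
)
from metmodnet.simulate import simulate_cohort

from conftest import small_config, toy_matrix, toy_meta


# -- sample outlier flagging -------------------------------------------------


def test_uniform_missingness_flags_nothing():
    vals = np.ones((10, 5))
    vals[0, :] = np.nan  # 10% missing in every sample
    flagged, _, _ = flag_sample_outliers(toy_matrix(vals))
    assert flagged == []


def test_extreme_sample_flagged():
    rng = np.random.default_rng(0)
    n_met, n_samp = 100, 70
    vals = rng.lognormal(10, 1, (n_met, n_samp))
    # 69 samples at 10% missing, 1 sample at 90%
    for j in range(69):
        vals[rng.choice(n_met, 10, replace=False), j] = np.nan
    vals[rng.choice(n_met, 90, replace=False), 69] = np.nan
    mat = toy_matrix(vals)
    flagged, frac, thr = flag_sample_outliers(mat)
    assert flagged == [mat.sample_ids[69]]
    # oracle: threshold recomputed directly
    f = np.isnan(vals).mean(axis=0)
    assert thr == pytest.approx(f.mean() + 5 * f.std(ddof=1))


def test_single_sample_errors():
    with pytest.raises(QCError):
        flag_sample_outliers(toy_matrix(np.ones((3, 1))))


# -- batch median normalization ----------------------------------------------


def _norm_fixture():
    meta = toy_meta(n_subjects=2, n_ref=4)
    # columns: s0_base s0_post s1_base s1_post ref0..ref3
    vals = np.array([[6.0, 8.0, 10.0, 12.0, 2.0, 2.0, 2.0, 2.0]])
    mat = toy_matrix(vals, met_ids=["m0"], sample_ids=[s for s in meta.df["sample_id"]])
    return mat, meta


def test_constant_reference_divides_through():
    mat, meta = _norm_fixture()
    out = batch_median_normalize(mat, meta)
    assert out.values.loc["m0", "s0_base"] == pytest.approx(3.0)


def test_two_batches_remove_batch_effect():
    rows = []
    for i, batch in ((0, "batch1"), (1, "batch2")):
        rows.append((f"s{i}_base", f"subj{i}", "experimental", "control", "baseline", batch))
        for r in range(2):
            rows.append((f"{batch}_ref{r}", "", "reference_serum", "", "", batch))
    meta = SampleMeta(pd.DataFrame(rows, columns=list(SampleMeta.COLUMNS)))
    ids = [r[0] for r in rows]
    vals = np.array([[2.0, 2.0, 2.0, 4.0, 4.0, 4.0]])
    mat = toy_matrix(vals, met_ids=["m0"], sample_ids=ids)
    out = batch_median_normalize(mat, meta)
    assert out.values.loc["m0", "s0_base"] == pytest.approx(1.0)
    assert out.values.loc["m0", "s1_base"] == pytest.approx(1.0)


def test_normalized_reference_median_is_one_and_idempotent(small_cohort):
    matrix, meta, *_ = small_cohort
    out = batch_median_normalize(matrix, meta)
    batch_of = meta.batch_of()
    ref = set(meta.sample_ids(role="reference_serum"))
    for batch in sorted(set(meta.df["batch"])):
        cols = [c for c in out.sample_ids if c in ref and batch_of[c] == batch]
        med = out.values.loc[:, cols].median(axis=1, skipna=True).dropna()
        np.testing.assert_allclose(med.to_numpy(), 1.0)
    again = batch_median_normalize(out, meta)
    pd.testing.assert_frame_equal(again.values, out.values)


def test_missing_references_left_unscaled_and_flagged():
    mat, meta = _norm_fixture()
    vals = mat.values.copy()
    vals.loc["m0", ["ref0", "ref1", "ref2", "ref3"]] = np.nan
    report = QCReport()
    out = batch_median_normalize(IonCountMatrix(vals), meta, report)
    assert out.values.loc["m0", "s0_base"] == 6.0
    assert ("m0", "batch1") in report.unscaled


# -- CV filter ---------------------------------------------------------------


def test_cv_zero_for_constant_replicates():
    mat, meta = _norm_fixture()
    cv = replicate_cv(mat, meta)
    assert cv["m0"] == 0.0


def test_cv_hand_computed_case_excluded_at_25():
    meta = toy_meta(n_subjects=1, n_ref=4)
    reps = [0.5, 1.0, 1.5, 1.0]
    vals = np.array([[1.0, 1.0] + reps])
    mat = toy_matrix(vals, met_ids=["m0"], sample_ids=list(meta.df["sample_id"]))
    cv = replicate_cv(mat, meta)
    expected = 100 * np.std(reps, ddof=1) / np.mean(reps)
    assert cv["m0"] == pytest.approx(expected)
    assert cv["m0"] == pytest.approx(40.8, abs=0.1)
    out = cv_filter(mat, meta, threshold_pct=25.0)
    assert out.metabolite_ids == []


def test_cv_filter_keeps_quiet_metabolites(small_cohort):
    matrix, meta, _, _, truth = small_cohort
    normed = batch_median_normalize(matrix, meta)
    report = QCReport()
    out = cv_filter(normed, meta, 25.0, report=report)
    assert set(report.cv_excluded) == set(truth.high_cv)
    assert len(out.metabolite_ids) == matrix.shape[0] - len(truth.high_cv)


# -- missingness filter --------------------------------------------------------


def test_missingness_boundary_is_strict():
    vals = np.ones((2, 70))
    vals[0, :21] = np.nan  # exactly 30%: retained
    vals[1, :22] = np.nan  # 31.4%: removed
    out = missingness_filter(toy_matrix(vals), threshold=0.30)
    assert out.metabolite_ids == ["m0"]


# -- log2 ----------------------------------------------------------------------


def test_log2_values_and_missing_preserved():
    vals = np.array([[8.0, 1.0], [2.0, np.nan]])
    out = log2_transform(toy_matrix(vals))
    assert out.values.iloc[0, 0] == 3.0
    assert out.values.iloc[0, 1] == 0.0
    assert np.isnan(out.values.iloc[1, 1])
    assert out.log_scale


def test_log2_zero_errors_with_location():
    with pytest.raises(QCError, match="m1.*s0"):
        log2_transform(toy_matrix(np.array([[2.0], [0.0]])))


# -- kNN imputation ------------------------------------------------------------


def brute_force_knn(X: np.ndarray, k: int) -> np.ndarray:
    """Independent reference imputer: literal per-cell loops."""
    n_met, n_samp = X.shape
    out = X.copy()
    for i in range(n_met):
        for j in range(n_samp):
            if not np.isnan(X[i, j]):
                continue
            cand = []
            for u in range(n_met):
                if u == i or np.isnan(X[u, j]):
                    continue
                both = ~np.isnan(X[i]) & ~np.isnan(X[u])
                if both.sum() == 0:
                    continue
                d = np.sqrt((n_samp / both.sum()) * ((X[i, both] - X[u, both]) ** 2).sum())
                cand.append((d, u))
            if not cand:
                out[i, j] = np.nanmean(X[i])
                continue
            cand.sort(key=lambda t: (t[0], t[1]))
            donors = [u for _, u in cand[:k]]
            out[i, j] = X[donors, j].mean()
    return out


def test_knn_identity_without_missing():
    mat = toy_matrix(np.random.default_rng(0).normal(size=(5, 4)), log_scale=True)
    out = knn_impute(mat, k=2)
    pd.testing.assert_frame_equal(out.values, mat.values)


def test_knn_duplicate_row_toy():
    # metabolite A duplicates B except one missing cell; k=1 must copy B
    X = np.array(
        [
            [1.0, 2.0, np.nan, 4.0],
            [1.0, 2.0, 3.0, 4.0],
            [9.0, 8.0, 7.0, 6.0],
        ]
    )
    out = knn_impute(toy_matrix(X, log_scale=True), k=1)
    assert out.values.iloc[0, 2] == 3.0


def test_knn_matches_brute_force_on_random_fixture():
    rng = np.random.default_rng(42)
    X = rng.normal(10, 2, size=(30, 20))
    X[rng.random((30, 20)) < 0.15] = np.nan
    assert (~np.isnan(X)).all(axis=1).sum() > 0  # ensure solvable
    out = knn_impute(toy_matrix(X, log_scale=True), k=10)
    expected = brute_force_knn(X, 10)
    np.testing.assert_allclose(out.values.to_numpy(), expected, rtol=1e-10)


def test_knn_never_alters_observed_and_stays_in_donor_range():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, size=(25, 12))
    mask = rng.random((25, 12)) < 0.1
    X[mask] = np.nan
    out = knn_impute(toy_matrix(X, log_scale=True), k=5).values.to_numpy()
    np.testing.assert_array_equal(out[~mask], X[~mask])
    col_min, col_max = np.nanmin(X, axis=0), np.nanmax(X, axis=0)
    for i, j in zip(*np.where(mask)):
        assert col_min[j] - 1e-12 <= out[i, j] <= col_max[j] + 1e-12


def test_knn_all_missing_metabolite_errors():
    X = np.array([[np.nan, np.nan], [1.0, 2.0]])
    with pytest.raises(QCError, match="zero observed"):
        knn_impute(toy_matrix(X, log_scale=True), k=1)


# -- IQR outlier removal -------------------------------------------------------


def test_iqr_all_equal_removes_nothing():
    meta = toy_meta(n_subjects=3, n_ref=2)
    ids = meta.sample_ids(role="experimental")
    mat = toy_matrix(np.ones((2, len(ids))), sample_ids=ids, log_scale=True)
    out = iqr_outlier_removal(mat, meta)
    assert not out.values.isna().any().any()


def test_iqr_zero_iqr_spike_blanks_both_timepoints():
    meta = toy_meta(n_subjects=35, n_ref=2)
    ids = meta.sample_ids(role="experimental")  # 70 wells
    vals = np.zeros((1, 70))
    vals[0, 5] = 10.0  # s2_post has the spike -> s2_base blanked too
    report = QCReport()
    out = iqr_outlier_removal(toy_matrix(vals, sample_ids=ids, log_scale=True), meta, report=report)
    spiked = ids[5]
    subj = meta.subject_of()[spiked]
    partner = [s for s in ids if meta.subject_of()[s] == subj and s != spiked][0]
    assert report.iqr_flagged_points == [("m0", spiked)]
    assert np.isnan(out.values.loc["m0", spiked])
    assert np.isnan(out.values.loc["m0", partner])


def test_iqr_removes_even_number_per_subject(small_cohort):
    matrix, meta, *_ = small_cohort
    clean, report = run_qc(matrix, meta)
    removed = pd.DataFrame(report.iqr_removed_cells, columns=["m", "s"])
    assert not removed.empty  # the fixture plants ~0.5% outlier cells
    subj = meta.subject_of()
    removed["subject"] = [subj[s] for s in removed["s"]]
    counts = removed.groupby(["m", "subject"]).size()
    assert (counts == 2).all()


# -- full chain ----------------------------------------------------------------


def test_clean_cohort_passes_untouched(clean_cohort):
    matrix, meta, *_ = clean_cohort
    clean, report = run_qc(matrix, meta)
    assert report.flagged_samples == []
    assert report.cv_excluded == []
    assert report.missingness_excluded == []
    assert clean.shape[0] == matrix.shape[0]


def test_counts_conserve_through_qc(small_cohort):
    matrix, meta, _, _, truth = small_cohort
    clean, report = run_qc(matrix, meta)
    assert (
        report.n_input_metabolites
        == report.n_retained_metabolites + len(report.cv_excluded) + len(report.missingness_excluded)
    )
    assert set(report.cv_excluded) == set(truth.high_cv)
    assert set(report.missingness_excluded) == set(truth.forced_high_missing)
    assert not clean.values.isna().any().any()
    assert clean.shape[1] == 70


def test_iqr_before_imputation_switch(small_cohort):
    matrix, meta, *_ = small_cohort
    clean, report = run_qc(matrix, meta, QCParams(iqr_on_unimputed=True))
    assert not clean.values.isna().any().any()
    assert report.n_retained_metabolites == clean.shape[0]


def test_cv_and_missingness_exclusions_disjoint(small_cohort):
    matrix, meta, *_ = small_cohort
    _, report = run_qc(matrix, meta)
    assert not set(report.cv_excluded) & set(report.missingness_excluded)
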