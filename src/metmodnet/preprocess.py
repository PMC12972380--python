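"""Quality control and preprocessing of raw ion-count matrices.

The chain, in fixed order: sample-missingness outlier check, batch-median
normalization against reference-serum aliquots, coefficient-of-variation
filter, missingness filter, log2 transform, k-nearest-neighbour
imputation, +/- 3*IQR outlier-point removal (blanking both timepoints of
an affected subject), and re-imputation.  Every exclusion is recorded in
a :class:`QCReport`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import IonCountMatrix, SampleMeta


class QCError(ValueError):
    pass


@dataclasses.dataclass
class QCParams:
    cv_max_pct: float = 25.0
    miss_max: float = 0.30
    knn_k: int = 10
    iqr_multiplier: float = 3.0
    sample_sd_mult: float = 5.0
    cv_per_batch: bool = False      # aggregate per-batch CVs by max instead of pooling
    iqr_on_unimputed: bool = False  # compute IQR statistics before the first imputation


@dataclasses.dataclass
class QCReport:
    """Bookkeeping of every QC decision; counts conserve at each stage."""

    sample_missingness: dict[str, float] = dataclasses.field(default_factory=dict)
    sample_threshold: float = float("nan")
    flagged_samples: list[str] = dataclasses.field(default_factory=list)
    unscaled: list[tuple[str, str]] = dataclasses.field(default_factory=list)  # (metabolite, batch)
    cv_pct: dict[str, float] = dataclasses.field(default_factory=dict)
    cv_excluded: list[str] = dataclasses.field(default_factory=list)
    missingness_excluded: list[str] = dataclasses.field(default_factory=list)
    iqr_flagged_points: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    iqr_removed_cells: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    n_input_metabolites: int = 0
    n_retained_metabolites: int = 0

    def summary(self) -> pd.DataFrame:
        rows = [
            ("input_metabolites", self.n_input_metabolites),
            ("flagged_samples", len(self.flagged_samples)),
            ("cv_excluded", len(self.cv_excluded)),
            ("missingness_excluded", len(self.missingness_excluded)),
            ("iqr_flagged_points", len(self.iqr_flagged_points)),
            ("iqr_removed_cells", len(self.iqr_removed_cells)),
            ("retained_metabolites", self.n_retained_metabolites),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------


def flag_sample_outliers(
    matrix: IonCountMatrix,
    meta: SampleMeta | None = None,
    sd_mult: float = 5.0,
) -> tuple[list[str], dict[str, float], float]:
    """Samples whose missingness exceeds mean + ``sd_mult`` * SD (n-1 SD).

    Returns (flagged sample ids, per-sample missingness, threshold).
    """
    cols = matrix.sample_ids if meta is None else [
        s for s in matrix.sample_ids if s in set(meta.sample_ids(role="experimental"))
    ]
    if len(cols) < 2:
        raise QCError("need >= 2 samples to define a missingness outlier threshold")
    frac = matrix.values.loc[:, cols].isna().mean(axis=0)
    thr = float(frac.mean() + sd_mult * frac.std(ddof=1))
    flagged = frac.index[frac > thr].tolist()
    return flagged, frac.to_dict(), thr


def batch_median_normalize(
    matrix: IonCountMatrix,
    meta: SampleMeta,
    report: QCReport | None = None,
    reference_role: str = "reference_serum",
) -> IonCountMatrix:
    """Divide each value by the per-(metabolite, batch) median of the
    reference aliquots of that batch.

    Metabolite/batch combinations with no usable reference value are left
    unscaled and flagged in the report.
    """
    if matrix.log_scale:
        raise QCError("batch-median normalization operates on raw ion counts")
    values = matrix.values.copy()
    batch_of = meta.batch_of()
    ref_ids = set(meta.sample_ids(role=reference_role))
    for batch in sorted(set(batch_of[list(values.columns)])):
        batch_cols = [c for c in values.columns if batch_of.get(c) == batch]
        ref_cols = [c for c in batch_cols if c in ref_ids]
        if not ref_cols:
            raise QCError(f"batch '{batch}' has no {reference_role} wells")
        med = values.loc[:, ref_cols].median(axis=1, skipna=True)
        usable = med.notna() & (med > 0)
        scale = med.where(usable, 1.0)
        values.loc[:, batch_cols] = values.loc[:, batch_cols].div(scale, axis=0)
        if report is not None:
            report.unscaled.extend((m, batch) for m in values.index[~usable])
    return IonCountMatrix(values, log_scale=False)


def replicate_cv(
    matrix: IonCountMatrix,
    meta: SampleMeta,
    replicate_role: str = "reference_serum",
    per_batch: bool = False,
) -> pd.Series:
    """Percent CV (100*sd/mean, n-1 SD) per metabolite over replicate wells.

    Pooled across batches by default; ``per_batch`` aggregates per-batch
    CVs by their maximum.  NaN where fewer than 2 replicate values are
    present or the mean is zero.
    """
    rep_cols = [s for s in matrix.sample_ids if s in set(meta.sample_ids(role=replicate_role))]
    if not rep_cols:
        raise QCError(f"no {replicate_role} wells available for CV computation")

    def _cv(df: pd.DataFrame) -> pd.Series:
        n = df.notna().sum(axis=1)
        mean = df.mean(axis=1, skipna=True)
        sd = df.std(axis=1, ddof=1, skipna=True)
        cv = 100.0 * sd / mean
        cv[(n < 2) | (mean == 0)] = np.nan
        return cv

    sub = matrix.values.loc[:, rep_cols]
    if not per_batch:
        return _cv(sub)
    batch_of = meta.batch_of()
    per = [
        _cv(sub.loc[:, [c for c in rep_cols if batch_of[c] == b]])
        for b in sorted(set(batch_of[rep_cols]))
    ]
    return pd.concat(per, axis=1).max(axis=1)


def cv_filter(
    matrix: IonCountMatrix,
    meta: SampleMeta,
    threshold_pct: float = 25.0,
    replicate_role: str = "reference_serum",
    per_batch: bool = False,
    report: QCReport | None = None,
) -> IonCountMatrix:
    """Drop metabolites whose replicate CV exceeds ``threshold_pct`` (or is
    undefined)."""
    cv = replicate_cv(matrix, meta, replicate_role, per_batch)
    excluded = cv.index[(cv > threshold_pct) | cv.isna()].tolist()
    if report is not None:
        report.cv_pct = cv.to_dict()
        report.cv_excluded = excluded
    keep = [m for m in matrix.metabolite_ids if m not in set(excluded)]
    return matrix.subset_metabolites(keep)


def missingness_filter(
    matrix: IonCountMatrix,
    meta: SampleMeta | None = None,
    threshold: float = 0.30,
    report: QCReport | None = None,
) -> IonCountMatrix:
    """Drop metabolites missing in strictly more than ``threshold`` of the
    experimental samples."""
    cols = matrix.sample_ids if meta is None else [
        s for s in matrix.sample_ids if s in set(meta.sample_ids(role="experimental"))
    ]
    frac = matrix.values.loc[:, cols].isna().mean(axis=1)
    excluded = frac.index[frac > threshold].tolist()
    if report is not None:
        report.missingness_excluded = excluded
    keep = [m for m in matrix.metabolite_ids if m not in set(excluded)]
    return matrix.subset_metabolites(keep)


def log2_transform(matrix: IonCountMatrix) -> IonCountMatrix:
    """Cell-wise log2; zero or negative values are a domain error."""
    vals = matrix.values
    bad = (vals <= 0)
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise QCError(
            f"non-positive value at metabolite '{vals.index[i]}', "
            f"sample '{vals.columns[j]}' cannot be log2 transformed"
        )
    return IonCountMatrix(np.log2(vals), log_scale=True)


def _pairwise_rescaled_distances(X: np.ndarray) -> np.ndarray:
    """Metabolite x metabolite Euclidean distance over jointly observed
    samples, rescaled by the overlap count (nan-Euclidean convention)."""
    M = (~np.isnan(X)).astype(float)
    A = np.where(np.isnan(X), 0.0, X)
    Q = A * A
    overlap = M @ M.T
    cross = A @ A.T
    sq = Q @ M.T + M @ Q.T - 2.0 * cross
    n_samp = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = sq * (n_samp / overlap)
    d2[overlap == 0] = np.inf
    d2 = np.maximum(d2, 0.0)
    return np.sqrt(d2)


def knn_impute(matrix: IonCountMatrix, k: int = 10) -> IonCountMatrix:
    """Fill each missing cell with the mean of the k nearest metabolites.

    Nearness is Euclidean distance over jointly observed samples, rescaled
    by the overlap count; donors are restricted to metabolites observed in
    the target sample.  Fewer than k donors: use all; none: fall back to
    the metabolite's own observed mean.  Ties break by row order.
    """
    X = matrix.values.to_numpy(copy=True)
    obs = ~np.isnan(X)
    if (obs.sum(axis=1) == 0).any():
        empty = matrix.values.index[obs.sum(axis=1) == 0].tolist()
        raise QCError(f"metabolite(s) with zero observed values: {empty}")
    if not np.isnan(X).any():
        return matrix.copy()
    D = _pairwise_rescaled_distances(X)
    np.fill_diagonal(D, np.inf)
    row_means = np.nanmean(X, axis=1)
    out = X.copy()
    for j in range(X.shape[1]):
        miss_rows = np.where(~obs[:, j])[0]
        if miss_rows.size == 0:
            continue
        donors = np.where(obs[:, j])[0]
        for i in miss_rows:
            d = D[i, donors]
            finite = np.isfinite(d)
            cand = donors[finite]
            if cand.size == 0:
                out[i, j] = row_means[i]
                continue
            order = np.argsort(d[finite], kind="stable")[: min(k, cand.size)]
            out[i, j] = X[cand[order], j].mean()
    return IonCountMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        log_scale=matrix.log_scale,
    )


def iqr_outlier_removal(
    matrix: IonCountMatrix,
    meta: SampleMeta,
    multiplier: float = 3.0,
    report: QCReport | None = None,
) -> IonCountMatrix:
    """Blank data points outside median +/- ``multiplier`` * IQR.

    Statistics are computed per metabolite over all experimental samples
    (both timepoints, linear-interpolation quantiles).  For each flagged
    (metabolite, subject), both of that subject's timepoint cells are set
    missing.  Boundary values (exactly on a bound) are retained.
    """
    exp_ids = [s for s in matrix.sample_ids if s in set(meta.sample_ids(role="experimental"))]
    vals = matrix.values.copy()
    sub = vals.loc[:, exp_ids]
    med = sub.median(axis=1, skipna=True)
    q1 = sub.quantile(0.25, axis=1, interpolation="linear")
    q3 = sub.quantile(0.75, axis=1, interpolation="linear")
    iqr = q3 - q1
    lo = med - multiplier * iqr
    hi = med + multiplier * iqr
    outside = sub.lt(lo, axis=0) | sub.gt(hi, axis=0)

    subject_of = meta.subject_of()
    samples_of_subject: dict[str, list[str]] = {}
    for s in exp_ids:
        samples_of_subject.setdefault(subject_of[s], []).append(s)

    flagged: list[tuple[str, str]] = []
    removed: set[tuple[str, str]] = set()
    rows, cols = np.where(outside.to_numpy())
    for r, c in zip(rows, cols):
        m, s = outside.index[r], outside.columns[c]
        flagged.append((m, s))
        for sib in samples_of_subject[subject_of[s]]:
            removed.add((m, sib))
    for m, s in removed:
        vals.loc[m, s] = np.nan
    if report is not None:
        report.iqr_flagged_points = flagged
        report.iqr_removed_cells = sorted(removed)
    return IonCountMatrix(vals, log_scale=matrix.log_scale)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def run_qc(
    matrix: IonCountMatrix,
    meta: SampleMeta,
    params: QCParams | None = None,
) -> tuple[IonCountMatrix, QCReport]:
    """Run the full QC chain and return the analysis-ready log2 matrix.

    Order: sample-outlier check -> batch normalization -> CV filter ->
    missingness filter -> restriction to experimental samples -> log2 ->
    kNN imputation -> IQR outlier removal -> re-imputation.
    """
    p = params or QCParams()
    report = QCReport(n_input_metabolites=matrix.shape[0])

    flagged, frac, thr = flag_sample_outliers(matrix, meta, p.sample_sd_mult)
    report.flagged_samples = flagged
    report.sample_missingness = frac
    report.sample_threshold = thr
    if flagged:
        keep = [s for s in matrix.sample_ids if s not in set(flagged)]
        matrix = matrix.subset_samples(keep)

    matrix = batch_median_normalize(matrix, meta, report)
    matrix = cv_filter(matrix, meta, p.cv_max_pct, per_batch=p.cv_per_batch, report=report)
    matrix = missingness_filter(matrix, meta, p.miss_max, report=report)

    exp_ids = [s for s in matrix.sample_ids if s in set(meta.sample_ids(role="experimental"))]
    matrix = matrix.subset_samples(exp_ids)
    matrix = log2_transform(matrix)

    if p.iqr_on_unimputed:
        matrix = iqr_outlier_removal(matrix, meta, p.iqr_multiplier, report)
        matrix = knn_impute(matrix, p.knn_k)
    else:
        matrix = knn_impute(matrix, p.knn_k)
        matrix = iqr_outlier_removal(matrix, meta, p.iqr_multiplier, report)
        matrix = knn_impute(matrix, p.knn_k)

    report.n_retained_metabolites = matrix.shape[0]
    return matrix, report
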