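"""Exercise-response analysis.

Per metabolite: paired t-tests baseline vs post (over all subjects and
within each athlete group), per-subject log2 fold changes, a two-tier
significance rule (tier 1: overall p below a Bonferroni threshold;
tier 2: additionally nominal significance in every group), and a
group-specific response ANOVA on the fold changes with pairwise
contrasts.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SampleMeta
from .stats import adjust_pvalues, one_way_anova, paired_t, tukey_kramer


class ResponseError(ValueError):
    pass


def _pairing(meta: SampleMeta, columns) -> pd.DataFrame:
    """Subjects with both timepoints present in the matrix columns."""
    exp = meta.experimental()
    present = exp[exp["sample_id"].isin(set(columns))]
    wide = present.pivot(index="subject_id", columns="timepoint", values="sample_id")
    if "baseline" not in wide.columns or "post" not in wide.columns:
        raise ResponseError("need both baseline and post samples")
    wide = wide.dropna(subset=["baseline", "post"])
    group_of = exp.drop_duplicates("subject_id").set_index("subject_id")["group"]
    wide["group"] = [group_of[s] for s in wide.index]
    return wide


def log2_fold_changes(
    values: pd.DataFrame,
    meta: SampleMeta,
    exclude: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Per-(metabolite, subject) log2 fold change, post minus baseline.

    ``values`` must be on the log2 scale.  ``exclude`` lists
    (metabolite_id, sample_id) cells blanked by QC; the corresponding
    subject pair is dropped listwise for that metabolite.
    """
    pairing = _pairing(meta, values.columns)
    base = values.loc[:, pairing["baseline"]].to_numpy(dtype=float)
    post = values.loc[:, pairing["post"]].to_numpy(dtype=float)
    fc = post - base
    if exclude:
        met_pos = {m: i for i, m in enumerate(values.index)}
        col_of_sample = {}
        for j, subj in enumerate(pairing.index):
            col_of_sample[pairing["baseline"].iloc[j]] = j
            col_of_sample[pairing["post"].iloc[j]] = j
        for m, s in exclude:
            if m in met_pos and s in col_of_sample:
                fc[met_pos[m], col_of_sample[s]] = np.nan
    return pd.DataFrame(fc, index=values.index, columns=pairing.index)


def paired_tests(
    values: pd.DataFrame,
    meta: SampleMeta,
    alpha_overall: float | None = None,
    alpha_group: float = 0.05,
    exclude: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Two-sided paired t-tests per metabolite, overall and per group.

    tier1: overall p < ``alpha_overall`` (default 0.05 / n_metabolites,
    the exact quotient).  tier2: tier1 and p < ``alpha_group`` in every
    group with a testable stratum (strata with < 2 complete pairs are
    untestable and excluded from the flags).
    """
    if alpha_overall is None:
        alpha_overall = 0.05 / values.shape[0]
    pairing = _pairing(meta, values.columns)
    fc = log2_fold_changes(values, meta, exclude)
    groups = sorted(set(pairing["group"]))
    rows = []
    for m in values.index:
        d = fc.loc[m].to_numpy(dtype=float)
        t_all, p_all, n_all = _one_sample_t(d)
        rec = {
            "metabolite_id": m,
            "log2fc_mean": float(np.nanmean(d)) if np.isfinite(d).any() else np.nan,
            "t_overall": t_all,
            "p_overall": p_all,
            "n_pairs": n_all,
        }
        group_ps = []
        for g in groups:
            dg = d[(pairing["group"] == g).to_numpy()]
            t_g, p_g, n_g = _one_sample_t(dg)
            rec[f"log2fc_mean_{g}"] = float(np.nanmean(dg)) if np.isfinite(dg).any() else np.nan
            rec[f"t_{g}"] = t_g
            rec[f"p_{g}"] = p_g
            rec[f"n_{g}"] = n_g
            if n_g >= 2:
                group_ps.append(p_g)
        tier1 = bool(np.isfinite(p_all) and p_all < alpha_overall)
        tier2 = bool(tier1 and group_ps and all(p < alpha_group for p in group_ps))
        rec["tier1"] = tier1
        rec["tier2"] = tier2
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["alpha_overall"] = alpha_overall
    out.attrs["alpha_group"] = alpha_group
    return out


def _one_sample_t(d: np.ndarray) -> tuple[float, float, int]:
    """One-sample t on paired differences == paired t on (baseline, post)."""
    d = d[~np.isnan(d)]
    return paired_t(np.zeros_like(d), d)


def response_anova(
    fold_changes: pd.DataFrame,
    meta: SampleMeta,
    posthoc: bool = True,
    paired: pd.DataFrame | None = None,
    alpha: float = 0.05,
    pairwise_method: str = "tukey",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA (log2 fold change ~ group) per metabolite.

    ``differential``: ANOVA p < alpha.  ``differential_and_changed``:
    differential and nominally significant paired change in >= 1 group
    (requires the ``paired`` table from :func:`paired_tests`).
    Pairwise contrasts use Tukey-Kramer by default; ``welch`` switches to
    unadjusted Welch t-tests.
    """
    exp = meta.experimental().drop_duplicates("subject_id")
    group_of = exp.set_index("subject_id")["group"]
    groups = sorted(set(group_of[fold_changes.columns]))
    cols_by_group = {
        g: [s for s in fold_changes.columns if group_of[s] == g] for g in groups
    }
    rows, pair_rows = [], []
    for m in fold_changes.index:
        by_group = {
            g: fold_changes.loc[m, cols].to_numpy(dtype=float)
            for g, cols in cols_by_group.items()
        }
        by_group = {g: v[~np.isnan(v)] for g, v in by_group.items()}
        testable = {g: v for g, v in by_group.items() if len(v) >= 2}
        if len(testable) < 2:
            rows.append((m, np.nan, np.nan))
            continue
        f, p = one_way_anova(list(testable.values()))
        rows.append((m, f, p))
        if posthoc and np.isfinite(p):
            if pairwise_method == "tukey":
                tk = tukey_kramer(testable)
            else:
                tk = _welch_pairs(testable)
            tk.insert(0, "metabolite_id", m)
            pair_rows.append(tk)
    out = pd.DataFrame(rows, columns=["metabolite_id", "F_response", "p_response"])
    out["p_response_fdr"] = adjust_pvalues(out["p_response"], "bh")
    out["differential"] = out["p_response"] < alpha
    if paired is not None:
        group_p_cols = [c for c in paired.columns if c.startswith("p_") and c not in ("p_overall",)]
        changed = (paired[group_p_cols] < alpha).any(axis=1)
        changed.index = paired["metabolite_id"]
        out["differential_and_changed"] = out["differential"] & out["metabolite_id"].map(changed).fillna(False)
    pairs = pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame(
        columns=["metabolite_id", "group1", "group2", "meandiff", "q", "p_tukey"]
    )
    return out, pairs


def _welch_pairs(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    from itertools import combinations

    from scipy import stats as sps

    rows = []
    for a, b in combinations(groups, 2):
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append((a, b, float(groups[a].mean() - groups[b].mean()), float(t), float(p)))
    return pd.DataFrame(rows, columns=["group1", "group2", "meandiff", "q", "p_tukey"])


def run_response(
    values: pd.DataFrame,
    meta: SampleMeta,
    exclude: Iterable[tuple[str, str]] = (),
    alpha_overall: float | None = None,
    alpha_group: float = 0.05,
    pairwise_method: str = "tukey",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tests + response ANOVA merged into one table per metabolite."""
    paired = paired_tests(values, meta, alpha_overall, alpha_group, exclude)
    fc = log2_fold_changes(values, meta, exclude)
    anova, pairs = response_anova(fc, meta, True, paired, alpha_group, pairwise_method)
    merged = paired.merge(anova, on="metabolite_id", how="left")
    merged.attrs.update(paired.attrs)
    return merged, pairs
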