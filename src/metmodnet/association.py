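"""Module- and metabolite-level association with traits and group membership.

Module representatives (eigenmetabolite and mean z-score, baseline) feed
linear models against the cohort traits and a one-way ANOVA against the
athlete group, with Tukey-Kramer post-hoc contrasts and Bonferroni/BH
multiplicity control.  A per-metabolite group ANOVA covers metabolites
outside the robust modules.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import SampleMeta, TraitTable
from .network import GREY, ModuleAssignment, eigenmetabolite
from .stats import adjust_pvalues, one_way_anova, tukey_kramer


class AssociationError(ValueError):
    pass


@dataclasses.dataclass
class ModuleRepresentatives:
    """Per-subject module summaries computed at one timepoint.

    ``eigen``: subjects x modules PC1 scores; ``zmean``: subjects x modules
    mean metabolite z-scores.  Signs are aligned so the two measures
    correlate positively within each module.
    """

    eigen: pd.DataFrame
    zmean: pd.DataFrame
    variance_explained: dict[str, float]
    timepoint: str = "baseline"

    @property
    def modules(self) -> list[str]:
        return list(self.eigen.columns)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subj in self.eigen.index:
            for mod in self.eigen.columns:
                rows.append((subj, mod, self.eigen.loc[subj, mod], self.zmean.loc[subj, mod]))
        return pd.DataFrame(rows, columns=["subject_id", "module", "eigenmetabolite", "mean_zscore"])


def module_representatives(
    values: pd.DataFrame,
    assignment: ModuleAssignment,
    meta: SampleMeta,
    timepoint: str = "baseline",
    include_grey: bool = True,
) -> ModuleRepresentatives:
    """Eigenmetabolite (PC1) and mean z-score per subject per module.

    ``values`` is the QC'd log2 matrix (metabolites x samples); only the
    requested timepoint's experimental samples enter.
    """
    samp = [
        s for s in values.columns
        if s in set(meta.sample_ids(role="experimental", timepoint=timepoint))
    ]
    if len(samp) < 3:
        raise AssociationError("need >= 3 samples for module representatives")
    sub = values.loc[:, samp]
    subject_of = meta.subject_of()
    subjects = [subject_of[s] for s in samp]

    labels = assignment.module_labels()
    if include_grey and GREY in set(assignment.labels):
        labels = labels + [GREY]

    eig_cols, z_cols, varexp = {}, {}, {}
    for lab in labels:
        members = [m for m in assignment.members(lab) if m in sub.index]
        if not members:
            continue
        e = eigenmetabolite(sub, _restrict(assignment, sub.index), lab)
        X = sub.loc[members].to_numpy()
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        zmean = ((X - mean) / sd).mean(axis=0)
        eig_cols[lab] = e.scores.to_numpy()
        z_cols[lab] = zmean
        varexp[lab] = e.variance_explained

    idx = pd.Index(subjects, name="subject_id")
    return ModuleRepresentatives(
        eigen=pd.DataFrame(eig_cols, index=idx),
        zmean=pd.DataFrame(z_cols, index=idx),
        variance_explained=varexp,
        timepoint=timepoint,
    )


def _restrict(assignment: ModuleAssignment, metabolite_ids) -> ModuleAssignment:
    keep = [m for m in assignment.metabolite_ids if m in set(metabolite_ids)]
    return ModuleAssignment(assignment.labels.loc[keep], assignment.timepoint)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def module_trait_lm(
    reps: ModuleRepresentatives,
    traits: TraitTable,
    meta: SampleMeta | None = None,
    adjust_for_group: bool = False,
) -> pd.DataFrame:
    """Linear model trait ~ representative per (module, trait).

    Both variables are z-scored, so the slope of the simple model equals
    the Pearson correlation.  ``adjust_for_group`` adds athlete-group
    indicators (control as reference).  Both representative measures are
    reported; eigenmetabolite p-values carry the default significance
    column, z-score betas the effect direction.  BH-FDR is applied across
    the modules x traits family per measure.
    """
    if adjust_for_group and meta is None:
        raise AssociationError("group adjustment requires sample metadata")
    group_of_subject = None
    if adjust_for_group:
        exp = meta.experimental().drop_duplicates("subject_id")
        group_of_subject = exp.set_index("subject_id")["group"]

    rows = []
    for measure, table in (("eigenmetabolite", reps.eigen), ("zscore", reps.zmean)):
        for mod in table.columns:
            for trait in traits.trait_names:
                shared = [s for s in table.index if s in traits.df.index]
                x = table.loc[shared, mod].to_numpy(dtype=float)
                y = traits.df.loc[shared, trait].to_numpy(dtype=float)
                ok = ~np.isnan(y)
                x, y = x[ok], y[ok]
                used = [s for s, o in zip(shared, ok) if o]
                if len(y) < 3 or y.std(ddof=1) == 0 or x.std(ddof=1) == 0:
                    rows.append((mod, trait, measure, np.nan, np.nan, len(y), False))
                    continue
                X = _zscore(x)[:, None]
                if adjust_for_group:
                    dummies = pd.get_dummies(
                        pd.Categorical(
                            [group_of_subject[s] for s in used],
                            categories=["control", "bodybuilding", "endurance", "sprint"],
                        ),
                        drop_first=True,
                    ).to_numpy(dtype=float)
                    X = np.column_stack([X, dummies])
                model = sm.OLS(_zscore(y), sm.add_constant(X)).fit()
                rows.append(
                    (mod, trait, measure, float(model.params[1]), float(model.pvalues[1]), len(y), True)
                )
    out = pd.DataFrame(
        rows, columns=["module", "trait", "measure", "beta", "p", "n", "testable"]
    )
    out["group_adjusted"] = adjust_for_group
    for measure in ("eigenmetabolite", "zscore"):
        mask = out["measure"] == measure
        out.loc[mask, "p_fdr"] = adjust_pvalues(out.loc[mask, "p"], "bh")
        out.loc[mask, "p_bonferroni"] = adjust_pvalues(out.loc[mask, "p"], "bonferroni")
    return out


def module_group_anova(
    reps: ModuleRepresentatives,
    meta: SampleMeta,
    posthoc: bool = True,
    measure: str = "eigenmetabolite",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA of each module representative on athlete group.

    Returns (anova table, Tukey-Kramer pairwise table).  The module-level
    Bonferroni threshold 0.05 / n_modules is reported alongside.
    """
    table = reps.eigen if measure == "eigenmetabolite" else reps.zmean
    exp = meta.experimental().drop_duplicates("subject_id")
    group_of = exp.set_index("subject_id")["group"]
    n_modules = table.shape[1]
    rows, pair_rows = [], []
    for mod in table.columns:
        by_group = {
            g: table.loc[[s for s in table.index if group_of[s] == g], mod].to_numpy()
            for g in sorted(set(group_of))
        }
        if sum(len(v) >= 2 for v in by_group.values()) < 2:
            raise AssociationError("need >= 2 groups with >= 2 subjects each")
        f, p = one_way_anova(list(by_group.values()))
        rows.append((mod, f, p, 0.05 / n_modules, p < 0.05 / n_modules))
        if posthoc and np.isfinite(p):
            tk = tukey_kramer(by_group)
            tk.insert(0, "module", mod)
            pair_rows.append(tk)
    anova = pd.DataFrame(
        rows, columns=["module", "F", "p", "bonferroni_threshold", "significant_bonferroni"]
    )
    pairs = pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame(
        columns=["module", "group1", "group2", "meandiff", "q", "p_tukey"]
    )
    return anova, pairs


def per_metabolite_group_test(
    values: pd.DataFrame,
    meta: SampleMeta,
    timepoint: str = "baseline",
    posthoc: bool = True,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-metabolite one-way group ANOVA at one timepoint.

    Bonferroni and BH-FDR columns are computed across the metabolite
    family.  Tukey-Kramer pairs are reported for every testable metabolite.
    """
    samp = [
        s for s in values.columns
        if s in set(meta.sample_ids(role="experimental", timepoint=timepoint))
    ]
    group_of = meta.group_of()
    groups = sorted(set(group_of[samp]))
    cols_by_group = {g: [s for s in samp if group_of[s] == g] for g in groups}
    rows, pair_rows = [], []
    for m in values.index:
        by_group = {g: values.loc[m, cols].to_numpy(dtype=float) for g, cols in cols_by_group.items()}
        f, p = one_way_anova(list(by_group.values()))
        rows.append((m, f, p))
        if posthoc and np.isfinite(p):
            tk = tukey_kramer(by_group)
            tk.insert(0, "metabolite_id", m)
            pair_rows.append(tk)
    out = pd.DataFrame(rows, columns=["metabolite_id", "F", "p"])
    out["p_bonferroni"] = adjust_pvalues(out["p"], "bonferroni")
    out["p_fdr"] = adjust_pvalues(out["p"], "bh")
    out["significant_bonferroni"] = out["p_bonferroni"] < alpha
    out["significant_fdr"] = out["p_fdr"] < alpha
    pairs = pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame(
        columns=["metabolite_id", "group1", "group2", "meandiff", "q", "p_tukey"]
    )
    return out, pairs
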