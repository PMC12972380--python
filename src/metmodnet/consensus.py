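"""Consensus refinement of baseline vs post-exercise module assignments.

Modules detected independently at the two timepoints are matched by
maximal set overlap; each consensus module keeps only the metabolites
assigned to the matched pair at both timepoints.  This is a plain
set-intersection notion of consensus, not the calibrated-TOM machinery
used elsewhere in the literature.
"""

from __future__ import annotations

import dataclasses
from itertools import permutations

import pandas as pd
from scipy.stats import hypergeom

from .network import GREY, ModuleAssignment


class ConsensusError(ValueError):
    pass


@dataclasses.dataclass
class ModuleMatch:
    """One-to-one matching of baseline to post module labels."""

    pairs: list[tuple[str, str]]            # (baseline label, post label)
    overlap: dict[tuple[str, str], int]
    jaccard: dict[tuple[str, str], float]
    p_hypergeom: dict[tuple[str, str], float]
    unmatched_baseline: list[str]
    unmatched_post: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (b, p, self.overlap[(b, p)], self.jaccard[(b, p)], self.p_hypergeom[(b, p)])
            for b, p in self.pairs
        ]
        return pd.DataFrame(
            rows, columns=["baseline", "post", "overlap", "jaccard", "p_hypergeom"]
        )


def _overlap_stats(set_b: set, set_p: set, universe: int):
    inter = len(set_b & set_p)
    union = len(set_b | set_p)
    jac = inter / union if union else 0.0
    # upper tail: P(X >= inter), X ~ Hypergeom(universe, |B|, |P|)
    p = float(hypergeom.sf(inter - 1, universe, len(set_b), len(set_p)))
    return inter, jac, p


def match_modules(
    base: ModuleAssignment,
    post: ModuleAssignment,
    exhaustive: bool = False,
) -> ModuleMatch:
    """Match non-grey modules across timepoints by maximal pairwise overlap.

    Greedy descent on intersection size (ties broken by larger Jaccard,
    then label order); ``exhaustive`` switches to the optimal assignment
    (total overlap maximized) for problems up to 8x8.
    """
    if set(base.metabolite_ids) != set(post.metabolite_ids):
        raise ConsensusError("baseline and post assignments cover different metabolites")
    universe = len(base.metabolite_ids)
    b_mods = {lab: set(base.members(lab)) for lab in base.module_labels()}
    p_mods = {lab: set(post.members(lab)) for lab in post.module_labels()}

    overlap, jaccard, pval = {}, {}, {}
    for bl, bs in b_mods.items():
        for pl, ps in p_mods.items():
            inter, jac, p = _overlap_stats(bs, ps, universe)
            overlap[(bl, pl)] = inter
            jaccard[(bl, pl)] = jac
            pval[(bl, pl)] = p

    pairs: list[tuple[str, str]] = []
    if exhaustive and len(b_mods) <= 8 and len(p_mods) <= 8:
        b_labels, p_labels = list(b_mods), list(p_mods)
        best, best_total = [], -1
        if len(b_labels) <= len(p_labels):
            for perm in permutations(p_labels, len(b_labels)):
                cand = list(zip(b_labels, perm))
                total = sum(overlap[c] for c in cand)
                if total > best_total:
                    best, best_total = cand, total
        else:
            for perm in permutations(b_labels, len(p_labels)):
                cand = list(zip(perm, p_labels))
                total = sum(overlap[c] for c in cand)
                if total > best_total:
                    best, best_total = cand, total
        pairs = [c for c in best if overlap[c] >= 1]
    else:
        remaining_b, remaining_p = set(b_mods), set(p_mods)
        candidates = sorted(
            overlap,
            key=lambda c: (-overlap[c], -jaccard[c], c),
        )
        for bl, pl in candidates:
            if overlap[(bl, pl)] < 1:
                continue
            if bl in remaining_b and pl in remaining_p:
                pairs.append((bl, pl))
                remaining_b.discard(bl)
                remaining_p.discard(pl)

    matched_b = {b for b, _ in pairs}
    matched_p = {p for _, p in pairs}
    return ModuleMatch(
        pairs=pairs,
        overlap=overlap,
        jaccard=jaccard,
        p_hypergeom=pval,
        unmatched_baseline=sorted(set(b_mods) - matched_b),
        unmatched_post=sorted(set(p_mods) - matched_p),
    )


def consensus_refine(
    base: ModuleAssignment,
    post: ModuleAssignment,
    match: ModuleMatch | None = None,
    drop_unstable: bool = True,
) -> ModuleAssignment:
    """Consensus modules: intersection of each matched pair's membership.

    Metabolites assigned differently at the two timepoints are dropped
    from module analyses (``drop_unstable=True``, default) or pushed to
    grey.  Consensus grey = grey at baseline AND grey at post.
    """
    if match is None:
        match = match_modules(base, post)
    labels = {}
    for bl, pl in match.pairs:
        for m in set(base.members(bl)) & set(post.members(pl)):
            labels[m] = bl
    for m in set(base.members(GREY)) & set(post.members(GREY)):
        labels[m] = GREY
    if drop_unstable:
        index = [m for m in base.metabolite_ids if m in labels]
        values = [labels[m] for m in index]
    else:
        index = base.metabolite_ids
        values = [labels.get(m, GREY) for m in index]
    return ModuleAssignment(pd.Series(values, index=pd.Index(index)), timepoint="consensus")


def consensus_frame(
    base: ModuleAssignment, post: ModuleAssignment, consensus: ModuleAssignment
) -> pd.DataFrame:
    """Long-form table: metabolite, consensus module, per-timepoint labels."""
    rows = []
    for m in consensus.metabolite_ids:
        rows.append(
            (m, consensus.labels[m], base.labels.get(m, ""), post.labels.get(m, ""))
        )
    return pd.DataFrame(rows, columns=["metabolite_id", "consensus_module", "in_baseline", "in_post"])
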