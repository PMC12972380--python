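"""Unsigned weighted correlation network construction and module detection.

Implements the soft-thresholded correlation network from first principles:
adjacency a_ij = |cor(x_i, x_j)|**beta, topological overlap similarity,
average-linkage hierarchical clustering of 1 - TOM, and a dynamic tree-cut
style module detection (static cut at 99% of the dendrogram height range
followed by gap-controlled recursive branch splitting, minimum module
size, and a grey label for unassigned metabolites).  Modules are named by
the conventional size-ordered colour sequence.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

GREY = "grey"

#: conventional module colour sequence (largest module first)
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

#: deep-split sensitivity ladder: minimum normalized merge-height gap that
#: justifies splitting a branch into two modules (larger = fewer modules)
_MIN_GAP = {0: 0.27, 1: 0.2025, 2: 0.135, 3: 0.0675, 4: 0.0375}


class NetworkError(ValueError):
    pass


@dataclasses.dataclass
class NetworkParams:
    soft_power: float = 6.0
    network_type: str = "unsigned"
    min_module_size: int = 30
    merge_height: float = 0.25
    deep_split: int = 2
    linkage: str = "average"
    cut_height_frac: float = 0.99  # static cut at this fraction of the height range

    def validate(self) -> None:
        if self.soft_power <= 0:
            raise NetworkError("soft_power must be > 0")
        if self.min_module_size < 2:
            raise NetworkError("min_module_size must be >= 2")
        if self.network_type != "unsigned":
            raise NetworkError("only unsigned networks are implemented")
        if self.deep_split not in _MIN_GAP:
            raise NetworkError("deep_split must be an integer 0-4")


@dataclasses.dataclass
class ModuleAssignment:
    """metabolite id -> colour label ('grey' = unassigned)."""

    labels: pd.Series  # index metabolite_id, values colour strings
    timepoint: str = ""

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.labels.index)

    def members(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def module_labels(self) -> list[str]:
        """Non-grey labels, largest module first."""
        counts = self.labels[self.labels != GREY].value_counts()
        return counts.index.tolist()

    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metabolite_id": self.labels.index, "module": self.labels.to_numpy()}
        )


@dataclasses.dataclass
class Eigenmetabolite:
    """Per-sample module summary: PC1 of the standardized member matrix."""

    module: str
    scores: pd.Series          # index sample_id, mean 0
    variance_explained: float


# ---------------------------------------------------------------------------


def adjacency(values: pd.DataFrame, params: NetworkParams | None = None) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |cor|**beta.

    ``values``: metabolite x sample log-scale matrix, fully observed,
    >= 3 samples.  Pearson correlation across samples.
    """
    p = params or NetworkParams()
    p.validate()
    if values.shape[1] < 3:
        raise NetworkError("need >= 3 samples to estimate correlations")
    if values.isna().any().any():
        raise NetworkError("adjacency requires a fully imputed matrix")
    X = values.to_numpy()
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = values.index[sd == 0].tolist()
        raise NetworkError(f"zero-variance metabolite(s): {bad}")
    C = np.corrcoef(X)
    A = np.abs(np.clip(C, -1.0, 1.0)) ** p.soft_power
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=values.index, columns=values.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u != i, j and connectivity k_i = sum_{u != i} a_iu; diagonal 1.
    """
    A = adj.to_numpy(dtype=float)
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # includes u = i and u = j terms, both zero since diag(A) = 0
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (shared + A) / (kmin + 1.0 - A)
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


def _size_ordered_labels(clusters: list[list[int]], n: int, ids) -> pd.Series:
    order = sorted(range(len(clusters)), key=lambda c: (-len(clusters[c]), min(clusters[c])))
    labels = np.array([GREY] * n, dtype=object)
    for rank, c in enumerate(order):
        color = COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE) else f"module{rank + 1}"
        labels[clusters[c]] = color
    return pd.Series(labels, index=ids)


def cluster_and_cut(
    dissimilarity: pd.DataFrame,
    params: NetworkParams | None = None,
    timepoint: str = "",
) -> ModuleAssignment:
    """Average-linkage clustering of a dissimilarity + dynamic branch cut.

    Branch candidates come from a static cut at ``cut_height_frac`` of the
    dendrogram height range; each candidate subtree is then recursively
    split wherever both child branches hold >= min_module_size leaves and
    the merge sits a deep_split-controlled gap above both children.
    Branches below the minimum size dissolve into 'grey'.
    """
    p = params or NetworkParams()
    p.validate()
    ids = dissimilarity.index
    n = len(ids)
    if n < p.min_module_size:
        return ModuleAssignment(pd.Series([GREY] * n, index=ids), timepoint)
    D = dissimilarity.to_numpy(dtype=float)
    Z = linkage(squareform(D, checks=False), method=p.linkage)
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    span = max(hmax - hmin, 1e-300)
    cut_h = hmin + p.cut_height_frac * span
    root = to_tree(Z)
    min_gap = _MIN_GAP[p.deep_split]

    def norm(h: float) -> float:
        return (h - hmin) / span

    def split(node) -> list:
        if node.is_leaf():
            return [node]
        a, b = node.get_left(), node.get_right()
        if a.count >= p.min_module_size and b.count >= p.min_module_size:
            gap_a = norm(node.dist) - norm(a.dist if not a.is_leaf() else hmin)
            gap_b = norm(node.dist) - norm(b.dist if not b.is_leaf() else hmin)
            if gap_a >= min_gap and gap_b >= min_gap:
                return split(a) + split(b)
        return [node]

    # collect the static-cut subtrees, then refine each recursively
    forest: list = []

    def collect(node) -> None:
        if node.dist <= cut_h or node.is_leaf():
            forest.append(node)
        else:
            collect(node.get_left())
            collect(node.get_right())

    collect(root)
    clusters: list[list[int]] = []
    for sub in forest:
        for terminal in split(sub):
            leaves = terminal.pre_order(lambda x: x.id)
            if len(leaves) >= p.min_module_size:
                clusters.append(leaves)
    return ModuleAssignment(_size_ordered_labels(clusters, n, ids), timepoint)


def eigenmetabolite(
    values: pd.DataFrame,
    assignment: ModuleAssignment,
    module_label: str,
) -> Eigenmetabolite:
    """PC1 scores of a module's z-scored metabolite sub-matrix.

    Scores have mean 0 and are sign-oriented to correlate positively with
    the module's mean z-score profile.
    """
    members = assignment.members(module_label)
    if not members:
        raise NetworkError(f"module '{module_label}' is empty")
    sub = values.loc[members]
    if sub.shape[1] < 2:
        raise NetworkError("eigenmetabolite requires >= 2 samples")
    X = sub.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xz = (X - mean) / sd
    U, S, Vt = np.linalg.svd(Xz, full_matrices=False)
    scores = S[0] * Vt[0]
    total = float((S**2).sum())
    var_explained = float(S[0] ** 2 / total) if total > 0 else 0.0
    mean_z = Xz.mean(axis=0)
    if np.dot(scores, mean_z) < 0:
        scores = -scores
    return Eigenmetabolite(
        module=module_label,
        scores=pd.Series(scores - scores.mean(), index=sub.columns),
        variance_explained=var_explained,
    )


def module_eigenmetabolites(
    values: pd.DataFrame, assignment: ModuleAssignment, include_grey: bool = False
) -> dict[str, Eigenmetabolite]:
    labels = assignment.module_labels()
    if include_grey and GREY in set(assignment.labels):
        labels = labels + [GREY]
    return {lab: eigenmetabolite(values, assignment, lab) for lab in labels}


def merge_close_modules(
    assignment: ModuleAssignment,
    values: pd.DataFrame,
    merge_height: float = 0.25,
) -> ModuleAssignment:
    """Iteratively merge modules whose eigenmetabolites correlate >= 1 - merge_height."""
    labels = assignment.labels.copy()
    while True:
        current = ModuleAssignment(labels, assignment.timepoint)
        mods = current.module_labels()
        if len(mods) < 2:
            break
        eig = {m: eigenmetabolite(values, current, m).scores for m in mods}
        best, best_cor = None, 1.0 - merge_height
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                c = float(np.corrcoef(eig[mods[i]], eig[mods[j]])[0, 1])
                if c >= best_cor:
                    best, best_cor = (mods[i], mods[j]), c
        if best is None:
            break
        labels[labels == best[1]] = best[0]
    # relabel by new sizes
    current = ModuleAssignment(labels, assignment.timepoint)
    clusters = []
    idx = {m: i for i, m in enumerate(labels.index)}
    for lab in current.module_labels():
        clusters.append([idx[m] for m in current.members(lab)])
    return ModuleAssignment(
        _size_ordered_labels(clusters, len(labels), labels.index), assignment.timepoint
    )


def kme(values: pd.DataFrame, assignment: ModuleAssignment) -> pd.Series:
    """Correlation of each metabolite with its own module eigenmetabolite
    (NaN for grey metabolites)."""
    out = pd.Series(np.nan, index=assignment.labels.index)
    for lab in assignment.module_labels():
        eig = eigenmetabolite(values, assignment, lab).scores.to_numpy()
        for m in assignment.members(lab):
            x = values.loc[m].to_numpy()
            if x.std(ddof=1) > 0:
                out[m] = float(np.corrcoef(x, eig)[0, 1])
    return out


def detect_modules(
    values: pd.DataFrame,
    params: NetworkParams | None = None,
    timepoint: str = "",
    merge: bool = True,
) -> ModuleAssignment:
    """Full one-step pipeline: adjacency -> TOM -> clustering -> merge."""
    p = params or NetworkParams()
    A = adjacency(values, p)
    T = tom_similarity(A)
    assignment = cluster_and_cut(1.0 - T, p, timepoint)
    if merge and assignment.module_labels():
        assignment = merge_close_modules(assignment, values, p.merge_height)
    return assignment


def soft_power_scan(
    values: pd.DataFrame, powers: Sequence[float] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12)
) -> pd.DataFrame:
    """Diagnostic scale-free-fit scan: R^2 of log10 p(k) vs log10 k per power."""
    rows = []
    base = np.abs(np.corrcoef(values.to_numpy()))
    np.fill_diagonal(base, 0.0)
    for beta in powers:
        k = (base**beta).sum(axis=1)
        hist, edges = np.histogram(k, bins=10)
        centers = (edges[:-1] + edges[1:]) / 2
        keep = (hist > 0) & (centers > 0)
        if keep.sum() < 3:
            rows.append((beta, np.nan, float(k.mean())))
            continue
        x = np.log10(centers[keep])
        y = np.log10(hist[keep] / hist.sum())
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append((beta, r2, float(k.mean())))
    return pd.DataFrame(rows, columns=["power", "scale_free_r2", "mean_connectivity"])
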