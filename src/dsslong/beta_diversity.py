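"""Phylogenetic beta diversity and its downstream tests.

The distance kernel is generalized UniFrac:

    d^(alpha)(A, B) = sum_i b_i (p_i + q_i)^alpha |p_i - q_i| / (p_i + q_i)
                      -----------------------------------------------------
                      sum_i b_i (p_i + q_i)^alpha

over tree branches i with length b_i and clade proportions p_i, q_i of the
two samples. alpha moderates the weight of abundant lineages: alpha=1 is
normalized weighted UniFrac, alpha=0.5 (the default) the half-moderated
variant usually recommended for detecting changes in moderately abundant
lineages.

Ordination is nonmetric MDS (SMACOF majorization with isotonic regression
on distance ranks, Kruskal stress-1, best of several random starts), and
group separation is tested with PERMANOVA/ADONIS on the Gower-centered
distance matrix with a label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from sklearn.manifold import MDS

from .cohort_io import CohortValidationError, FeatureTable
from .community_metrics import to_relative_abundance
from .stats_core import permutation_pvalue

__all__ = [
    "gunifrac",
    "nmds",
    "adonis",
    "baseline_distance",
    "OrdinationResult",
    "PermanovaResult",
    "branch_profile",
]


def branch_profile(tree: TreeNode, feature_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch leaf-membership matrix.

    Returns ``(lengths, membership)`` where ``membership[i, j]`` is 1 if
    feature j lies below branch i. Clade proportions for a sample with
    relative abundances ``ra`` are then ``membership @ ra``.
    """
    col = {f: j for j, f in enumerate(feature_ids)}
    lengths = []
    rows = []
    node_vec: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(col))
            if node.name in col:
                vec[col[node.name]] = 1.0
        else:
            vec = np.zeros(len(col))
            for child in node.children:
                vec += node_vec.pop(id(child))
        node_vec[id(node)] = vec
        if node.parent is not None and node.length is not None:
            lengths.append(node.length)
            rows.append(vec)
    return np.asarray(lengths, dtype=float), np.asarray(rows)


def gunifrac(table, tree: TreeNode, alpha: float = 0.5,
             validate: bool = True) -> DistanceMatrix:
    """Generalized UniFrac distances between all sample pairs.

    ``table`` may be a :class:`FeatureTable` (converted to relative
    abundances) or an already-normalized samples x features DataFrame.
    Branches with zero combined abundance in a pair are excluded from both
    sums; identical samples get distance 0, samples with disjoint support 1.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if isinstance(table, FeatureTable):
        ra_df = to_relative_abundance(table)
    else:
        ra_df = pd.DataFrame(table)
        sums = ra_df.to_numpy().sum(axis=1)
        if (sums <= 0).any():
            raise CohortValidationError("sample with zero total abundance")
    sample_ids = list(ra_df.index.astype(str))
    feature_ids = list(ra_df.columns.astype(str))
    if validate:
        leaves = {t.name for t in tree.tips()}
        present = ra_df.to_numpy().sum(axis=0) > 0
        orphans = [f for f, keep in zip(feature_ids, present) if keep and f not in leaves]
        if orphans:
            raise CohortValidationError(f"features missing from tree: {orphans[:5]}")
    lengths, member = branch_profile(tree, feature_ids)
    ra = ra_df.to_numpy(dtype=float)
    ra = ra / ra.sum(axis=1, keepdims=True)
    P = member @ ra.T  # branches x samples clade proportions
    n = len(sample_ids)
    D = np.zeros((n, n))
    for i in range(n):
        pi = P[:, i]
        for j in range(i + 1, n):
            qj = P[:, j]
            tot = pi + qj
            mask = tot > 0
            w = lengths[mask] * tot[mask] ** alpha
            frac = np.abs(pi[mask] - qj[mask]) / tot[mask]
            denom = w.sum()
            D[i, j] = D[j, i] = float((w * frac).sum() / denom) if denom > 0 else 0.0
    return DistanceMatrix(D, ids=sample_ids)


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS embedding: centered coordinates and the final Kruskal stress-1."""

    sample_ids: tuple
    coordinates: np.ndarray  # n x k, centered at the origin
    stress: float
    k: int
    seed: int | None
    restarts: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids), columns=cols)


def nmds(dm: DistanceMatrix, k: int = 2, seed: int | None = None,
         restarts: int = 10, max_iter: int = 500, tol: float = 1e-9) -> OrdinationResult:
    """Nonmetric MDS of a distance matrix, best stress over random restarts."""
    n = len(dm.ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    data = np.asarray(dm.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite distances")
    model = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        n_init=restarts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(data)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return OrdinationResult(tuple(dm.ids), coords, float(model.stress_), k, seed, restarts)


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based multivariate ANOVA: R2, pseudo-F, permutation p."""

    r2: float
    pseudo_f: float
    p: float
    n_perm: int
    df_between: int
    df_within: int


def _group_ss(G: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    # tr(H G) for the one-way hat matrix: sum over groups of block-sum / n_g
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += G[np.ix_(idx, idx)].sum() / idx.size
    return ss


def adonis(dm: DistanceMatrix, grouping, n_perm: int = 999,
           seed: int | None = None) -> PermanovaResult:
    """PERMANOVA (ADONIS) on a distance matrix with freely permuted labels.

    The total sum of squares is the trace of the Gower-centered matrix
    G = -1/2 J D^2 J; the between-group SS is tr(HGH) for the one-way
    design hat matrix. p uses the (1 + #{null >= obs}) / (1 + B) rule.
    """
    labels = np.asarray(list(grouping))
    n = len(dm.ids)
    if labels.size != n:
        raise ValueError("grouping length must match the distance matrix")
    groups = np.unique(labels)
    a = groups.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    D2 = np.asarray(dm.data, dtype=float) ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ D2 @ J
    ss_total = float(np.trace(G))
    ss_between = _group_ss(G, labels, groups)
    ss_within = ss_total - ss_between
    df_b, df_w = a - 1, n - a
    pseudo_f = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total
    rng = np.random.default_rng(seed)
    null_f = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        ssb = _group_ss(G, perm, groups)
        null_f[b] = (ssb / df_b) / ((ss_total - ssb) / df_w)
    p = permutation_pvalue(pseudo_f, null_f)
    return PermanovaResult(float(r2), float(pseudo_f), p, n_perm, df_b, df_w)


def baseline_distance(dm: DistanceMatrix, baseline_ids) -> pd.Series:
    """Mean distance of every sample to the baseline set.

    The baseline is typically the day-0 samples of the 0%-dose group; a
    baseline sample's zero self-distance is excluded from its own mean.
    """
    baseline = [str(b) for b in baseline_ids]
    if not baseline:
        raise ValueError("empty baseline")
    ids = list(dm.ids)
    missing = set(baseline) - set(ids)
    if missing:
        raise ValueError(f"baseline samples not in distance matrix: {sorted(missing)}")
    data = np.asarray(dm.data)
    b_idx = np.array([ids.index(b) for b in baseline])
    out = {}
    for i, s in enumerate(ids):
        cols = b_idx[b_idx != i]
        if cols.size == 0:
            out[s] = np.nan
        else:
            out[s] = float(data[i, cols].mean())
    return pd.Series(out, name="baseline_distance")
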