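"""Between-sample (beta) diversity: weighted UniFrac, PCoA ordination, ANOSIM.

Weighted UniFrac measures phylogenetic dissimilarity between two communities
as sum_b l_b * |p_Ab - p_Bb| over tree branches, where l_b is the branch
length and p_Ab the fraction of sample A's reads descending from branch b.
The raw (unnormalized) form is the default; the normalized form divides by
sum_j d_j (p_Aj + p_Bj) over tips, with d_j the root-to-tip distance, and is
bounded by 1.

ANOSIM is the rank-based permutation test of Clarke (1993): R contrasts mean
between-group vs within-group distance ranks; significance comes from group
label permutation. PCoA is classical metric scaling (Gower double centering).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .exceptions import (
    DesignError,
    EmptySampleError,
    GroupingError,
    LabelError,
)
from .io import DistanceMatrix, OtuTable, RootedTree, logger


# ---------------------------------------------------------------------------
# Weighted UniFrac
# ---------------------------------------------------------------------------

def _branch_profile(table: OtuTable, tree: RootedTree):
    """Per-branch relative-abundance profiles for every sample.

    Returns (branch_lengths, P, tip_depths, T) where P[s, b] is the fraction
    of sample s's reads descending from branch b, and T[s, j] the tip-level
    fractions with tip_depths[j] the root-to-tip distances (used by the
    normalized form).
    """
    col = {o: j for j, o in enumerate(table.otu_ids)}
    totals = table.sample_totals().astype(float)
    if np.any(totals == 0):
        raise EmptySampleError("sample with zero total count")
    rel = table.counts / totals[:, None]

    used = {o for j, o in enumerate(table.otu_ids) if table.counts[:, j].any()}
    tip_labels = {
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon
    }
    missing = used - tip_labels
    if missing:
        raise LabelError(f"OTUs with counts absent from tree: {sorted(missing)}")

    n = table.n_samples
    lengths, profiles = [], []
    tip_depth, tip_rel = [], []
    subtree: dict[int, np.ndarray] = {}
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            vec = (
                rel[:, col[label]]
                if label in col
                else np.zeros(n)
            )
            tip_depth.append(depth[id(node)])
            tip_rel.append(vec)
        else:
            vec = np.sum([subtree.pop(id(c)) for c in node.child_nodes()], axis=0)
        subtree[id(node)] = vec
        if node is not tree.seed_node:
            lengths.append(node.edge.length or 0.0)
            profiles.append(vec)
    return (
        np.asarray(lengths),
        np.asarray(profiles).T,  # samples x branches
        np.asarray(tip_depth),
        np.asarray(tip_rel).T,  # samples x tips
    )


def weighted_unifrac(
    table: OtuTable,
    tree: RootedTree,
    sample_a: str,
    sample_b: str,
    normalized: bool = False,
) -> float:
    """Weighted UniFrac between two samples of a count table (raw by default)."""
    lengths, prof, tip_d, tip_p = _branch_profile(table, tree)
    ia = table.sample_ids.index(sample_a)
    ib = table.sample_ids.index(sample_b)
    raw = float(np.sum(lengths * np.abs(prof[ia] - prof[ib])))
    if not normalized:
        return raw
    norm = float(np.sum(tip_d * (tip_p[ia] + tip_p[ib])))
    return raw / norm if norm > 0 else 0.0


def unifrac_matrix(
    table: OtuTable, tree: RootedTree, normalized: bool = False
) -> DistanceMatrix:
    """All pairwise weighted UniFrac values as a DistanceMatrix."""
    lengths, prof, tip_d, tip_p = _branch_profile(table, tree)
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(prof[i + 1:] - prof[i])  # remaining samples x branches
        raw = diff @ lengths
        if normalized:
            norm = (tip_p[i + 1:] + tip_p[i]) @ tip_d
            raw = np.divide(raw, norm, out=np.zeros_like(raw), where=norm > 0)
        out[i, i + 1:] = raw
        out[i + 1:, i] = raw
    return DistanceMatrix(table.sample_ids, out)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    """Analysis-of-similarities outcome: R in [-1, 1], permutation p."""

    R: float
    p: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(
    dist: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """One-way ANOSIM of a distance matrix against a grouping.

    Distances are ranked with mid-ranks for ties;
    R = (mean between-group rank - mean within-group rank) / (M/2),
    M = n(n-1)/2. The p-value uses group-label permutation with the add-one
    convention, so p is never exactly 0.
    """
    missing = set(dist.labels) - groups.keys()
    if missing:
        raise GroupingError(f"samples without a group: {sorted(missing)}")
    labels = np.array([groups[s] for s in dist.labels])
    uniq, sizes = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DesignError("ANOSIM needs at least 2 groups")
    if sizes.min() < 2:
        small = [g for g, c in zip(uniq, sizes) if c < 2]
        raise DesignError(f"groups of size 1 not allowed: {small}")
    if sizes.min() < 5:
        logger.warning(
            "ANOSIM group sizes %s below 5; permutation p has limited resolution",
            dict(zip(uniq.tolist(), sizes.tolist())),
        )
    n = len(dist)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(dist.condensed())  # mid-ranks
    denom = (n * (n - 1) // 2) / 2.0
    r_obs = _anosim_r(ranks, labels[iu] == labels[ju], denom)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu] == perm[ju], denom) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(R=r_obs, p=p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcoaResult:
    """Classical-scaling ordination of a distance matrix.

    ``eigenvalues`` holds the full spectrum, non-increasing, negative values
    reported verbatim; coordinates and proportion_explained cover the
    positive eigenvalues only.
    """

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis by Gower double centering.

    B = -1/2 J D^2 J with J the centering matrix; coordinates are the
    eigenvectors of B scaled by sqrt of their (positive) eigenvalues.
    Negative eigenvalues, which arise from non-Euclidean distances, are
    reported but not corrected.
    """
    d = dist.values
    n = len(dist)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval.max(initial=0.0)), 1.0))
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total_pos = eigval[pos].sum()
    prop = eigval[pos] / total_pos if total_pos > 0 else eigval[pos]
    return PcoaResult(
        sample_ids=dist.labels,
        coordinates=coords,
        eigenvalues=eigval,
        proportion_explained=prop,
    )
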