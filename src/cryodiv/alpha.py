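"""Within-sample (alpha) diversity indices.

Implements the classical index panel for amplicon surveys: observed richness,
Shannon diversity H = -sum p_i ln p_i (nats by default), bias-corrected Chao1
richness, Berger-Parker dominance d = N_max/N, Good's coverage C = 1 - F1/N,
and Faith's phylogenetic diversity (total branch length spanned by the taxa
present, including the path to the root).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping

import numpy as np

from .exceptions import EmptySampleError, GroupingError, LabelError
from .io import OtuTable, RootedTree


def _positive(counts) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise EmptySampleError("index undefined for an all-zero count vector")
    return counts


def observed_otus(counts) -> int:
    """Number of OTUs with a positive count."""
    return int(_positive(counts).size)


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive counts.

    Natural log by default; pass ``base`` (e.g. 2) for other conventions.
    """
    counts = _positive(counts)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1 - 1) / (2(F2 + 1)).

    F1 and F2 are the singleton and doubleton counts. The bias-corrected
    form is defined even when no doubletons are present.
    """
    counts = _positive(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return counts.size + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def berger_parker(counts) -> float:
    """Berger-Parker dominance: relative abundance of the most abundant OTU."""
    counts = _positive(counts)
    return float(counts.max() / counts.sum())


def goods_coverage(counts) -> float:
    """Good's coverage C = 1 - F1/N: estimated fraction of the community
    represented by sampled OTUs (F1 singletons, N total reads)."""
    counts = _positive(counts)
    f1 = int((counts == 1).sum())
    return 1.0 - f1 / counts.sum()


def faith_pd(
    present_otus: Iterable[str], tree: RootedTree, rooted: bool = True
) -> float:
    """Faith's phylogenetic diversity of a set of tree tips.

    Sum of branch lengths of the minimal subtree connecting the present tips.
    With ``rooted=True`` (default) the subtree includes the path to the root,
    so even a single tip has positive PD; with ``rooted=False`` only branches
    between present tips count.
    """
    present = set(present_otus)
    if not present:
        return 0.0
    tip_nodes = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon
    }
    missing = present - tip_nodes.keys()
    if missing:
        raise LabelError(f"labels not in tree: {sorted(missing)}")
    covered = set()
    for label in present:
        node = tip_nodes[label]
        while node is not None and node not in covered:
            covered.add(node)
            node = node.parent_node
    total = 0.0
    for node in covered:
        if node is tree.seed_node:
            continue
        if not rooted:
            # count only edges whose subtree splits the present set off
            below = {
                leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon
            } & present
            if len(below) == len(present):
                continue
        total += node.edge.length or 0.0
    return total


@dataclass(frozen=True)
class AlphaSummary:
    """Per-sample (or group-mean) index panel; PD in branch-length units."""

    observed_otus: float
    shannon: float
    chao1: float
    berger_parker: float
    goods_coverage: float
    faith_pd: float


def sample_alpha(
    counts, otu_ids: Iterable[str], tree: RootedTree | None = None
) -> AlphaSummary:
    """All indices for one count vector; PD is NaN without a tree."""
    counts = np.asarray(counts)
    if tree is not None:
        present = [o for o, c in zip(otu_ids, counts) if c > 0]
        pd_value = faith_pd(present, tree)
    else:
        pd_value = float("nan")
    return AlphaSummary(
        observed_otus=float(observed_otus(counts)),
        shannon=shannon(counts),
        chao1=chao1(counts),
        berger_parker=berger_parker(counts),
        goods_coverage=goods_coverage(counts),
        faith_pd=pd_value,
    )


def alpha_summary(
    table: OtuTable,
    tree: RootedTree | None,
    groups: Mapping[str, str],
) -> dict[str, AlphaSummary]:
    """Per-sample indices averaged (unweighted) within each group.

    ``groups`` maps every sample id to a group label (e.g. ice / soil).
    """
    missing = set(table.sample_ids) - groups.keys()
    if missing:
        raise GroupingError(f"samples without a group: {sorted(missing)}")
    per_group: dict[str, list[AlphaSummary]] = {}
    for sid, row in zip(table.sample_ids, table.counts):
        per_group.setdefault(groups[sid], []).append(
            sample_alpha(row, table.otu_ids, tree)
        )
    out = {}
    for g, summaries in per_group.items():
        out[g] = AlphaSummary(**{
            f.name: float(np.mean([getattr(s, f.name) for s in summaries]))
            for f in fields(AlphaSummary)
        })
    return out
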