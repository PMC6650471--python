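"""OTU definition and rarefaction.

Sequences are binned into operational taxonomic units (OTUs) by average-
neighbor (group-average / UPGMA-criterion) agglomerative clustering of a
pairwise distance matrix, conventionally at a 0.03 distance cutoff (97%
identity). Count tables are rarefied by subsampling without replacement
(multivariate hypergeometric), which is consistent with the closed-form
expected-richness curve implemented alongside.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import DataError, DepthError, EmptySampleError
from .io import DistanceMatrix, OtuTable

#: conventional species-level cutoff: 97% identity = 0.03 distance
DEFAULT_CUTOFF = 0.03


@dataclass(frozen=True)
class OtuAssignment:
    """label -> OTU index (0..K-1) at a given distance cutoff."""

    assignment: dict[str, int]
    cutoff: float

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def members(self) -> list[list[str]]:
        """OTU member lists, indexed by OTU."""
        out: list[list[str]] = [[] for _ in range(self.n_otus)]
        for label, k in self.assignment.items():
            out[k].append(label)
        for group in out:
            group.sort()
        return out


def cluster_average_neighbor(
    dist: DistanceMatrix, cutoff: float = DEFAULT_CUTOFF
) -> OtuAssignment:
    """Average-neighbor clustering of a distance matrix at a distance cutoff.

    Clusters are merged agglomeratively while the minimum average between-
    cluster distance (arithmetic mean over all cross-cluster pairs of the
    original matrix) is at or below ``cutoff``. Ties are broken by the
    lexicographically lowest label pair, so the partition is deterministic.

    Parameters
    ----------
    dist
        Pairwise sequence distances (e.g. 1 - identity).
    cutoff
        Maximum average between-cluster distance allowed in a merge;
        0.03 corresponds to the conventional 97% identity OTU definition.

    Returns
    -------
    OtuAssignment mapping every label to an OTU index. OTUs are numbered by
    their lexicographically smallest member.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise DataError(f"cutoff {cutoff} outside [0, 1]")
    labels = dist.labels
    d = dist.values
    if np.any(np.isnan(d)):
        raise DataError("distance matrix contains NaN")
    # clusters as index sets; average distance recomputed from the original
    # matrix (group average), which the Lance-Williams update reproduces
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    while len(clusters) > 1:
        best = None  # (avg_dist, tie_key, a, b)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                block = d[np.ix_(clusters[a], clusters[b])]
                avg = float(block.mean())
                key = tuple(sorted(
                    (min(labels[i] for i in clusters[a]),
                     min(labels[i] for i in clusters[b]))
                ))
                if best is None or (avg, key) < (best[0], best[1]):
                    best = (avg, key, a, b)
        if best is None or best[0] > cutoff:
            break
        _, _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    clusters.sort(key=lambda c: min(labels[i] for i in c))
    assignment = {labels[i]: k for k, c in enumerate(clusters) for i in c}
    return OtuAssignment(assignment, cutoff)


def rarefy_table(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Draws are multivariate hypergeometric per sample, reproducible under
    ``seed``. OTUs that end up with zero counts in every sample are retained
    (column set unchanged) so tables stay alignable across depths.
    """
    if depth < 1:
        raise DepthError(f"depth must be positive, got {depth}")
    totals = table.sample_totals()
    if np.any(totals < depth):
        short = [s for s, t in zip(table.sample_ids, totals) if t < depth]
        raise DepthError(
            f"depth {depth} exceeds sample totals for {short} "
            f"(min total {totals.min()})"
        )
    rng = np.random.default_rng(seed)
    out = np.vstack([
        rng.multivariate_hypergeometric(row, depth) for row in table.counts
    ])
    return OtuTable(table.sample_ids, table.otu_ids, out)


def expected_rarefaction_richness(counts: np.ndarray, depth: int) -> float:
    """Analytic expected OTU richness of a subsample of size ``depth``.

    E[S_depth] = sum_i [1 - C(N - N_i, depth) / C(N, depth)] where N_i are
    the OTU counts and N their total; the hypergeometric probability that
    OTU i is entirely missed. Computed in log space for large counts.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise EmptySampleError("no positive counts")
    n_total = int(counts.sum())
    if depth < 1 or depth > n_total:
        raise DepthError(f"depth {depth} outside [1, {n_total}]")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = n_total - counts
    p_missed = np.zeros(counts.shape)
    ok = rest >= depth  # OTUs with N_i > N - depth can never be missed
    p_missed[ok] = np.exp(log_comb(rest[ok], depth) - log_comb(n_total, depth))
    return float(np.sum(1.0 - p_missed))


def rarefaction_curve(
    counts: np.ndarray, depths: np.ndarray | None = None, n_points: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Expected-richness curve over a grid of depths (for plotting/TSV output)."""
    counts = np.asarray(counts)
    n_total = int(counts.sum())
    if depths is None:
        depths = np.unique(np.linspace(1, n_total, n_points).astype(int))
    richness = np.array([
        expected_rarefaction_richness(counts, int(d)) for d in depths
    ])
    return np.asarray(depths), richness
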