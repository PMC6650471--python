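"""Isolation-by-distance analysis for georeferenced sequence sets.

The chain: an uncorrected genetic distance (p-distance) matrix from an
alignment, a great-circle geographic distance matrix from site coordinates,
a global Mantel test between the two, and a Mantel correlogram whose number
of distance classes follows Sturge's rule, each class tested by permutation
with a Bonferroni correction.

A positive global Mantel r means genetic divergence increases with
geographic separation (isolation by distance); a flat correlogram indicates
dispersal strong enough to erase spatial structure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    ComparabilityError,
    DataError,
    DegenerateError,
    DesignError,
    LabelError,
    MappingError,
)
from .io import Alignment, DistanceMatrix, GeoSites

#: IUGG mean Earth radius, km.
MEAN_EARTH_RADIUS_KM = 6371.0088
#: International (Hayford 1924) ellipsoid equatorial radius, km; the
#: convention used by some older geographic-distance routines.
INTERNATIONAL_ELLIPSOID_RADIUS_KM = 6378.388

_VALID = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def genetic_distance_matrix(
    aln: Alignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Uncorrected p-distance matrix: mismatches / compared sites per pair.

    Sites where either sequence carries a gap or an ambiguity code are
    excluded pair by pair (``deletion="pairwise"``, default) or globally
    (``deletion="complete"``). U is treated as T.
    """
    if len(aln) < 2:
        raise DesignError("need at least 2 sequences")
    if deletion not in ("pairwise", "complete"):
        raise DataError(f"unknown deletion mode {deletion!r}")
    n, length = len(aln), aln.n_sites
    codes = np.full((n, length), -1, dtype=np.int8)
    for i, seq in enumerate(aln.sequences):
        for j, ch in enumerate(seq):
            codes[i, j] = _VALID.get(ch, -1)
    valid = codes >= 0
    if deletion == "complete":
        keep = valid.all(axis=0)
        codes, valid = codes[:, keep], valid[:, keep]
    out = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        comparable = both.sum(axis=1)
        zero = np.flatnonzero(comparable == 0)
        if zero.size:
            j = i + 1 + zero[0]
            raise ComparabilityError(
                f"{aln.seq_ids[i]!r} and {aln.seq_ids[j]!r} share no "
                "comparable sites"
            )
        mism = ((codes[i] != codes[i + 1:]) & both).sum(axis=1)
        out[i, i + 1:] = out[i + 1:, i] = mism / comparable
    return DistanceMatrix(aln.seq_ids, out)


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float,
    radius_km: float = MEAN_EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance between two points in decimal degrees."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance_matrix(
    sites: GeoSites,
    membership: Mapping[str, str],
    radius_km: float = MEAN_EARTH_RADIUS_KM,
) -> DistanceMatrix:
    """Great-circle distances (km) between the sites of each sequence pair.

    ``membership`` maps sequence ids to site ids; its order fixes the matrix
    label order. Same-site pairs get distance 0.
    """
    unmapped = [s for s, site in membership.items() if site not in sites]
    if unmapped:
        raise MappingError(f"sequences mapped to unknown sites: {unmapped}")
    seq_ids = list(membership)
    site_ids = list(sites.site_ids)
    idx = {s: i for i, s in enumerate(site_ids)}
    m = len(site_ids)
    site_d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = haversine_km(*sites[site_ids[i]], *sites[site_ids[j]], radius_km)
            site_d[i, j] = site_d[j, i] = d
    which = np.array([idx[membership[s]] for s in seq_ids])
    return DistanceMatrix(seq_ids, site_d[np.ix_(which, which)])


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    tail: str


def _aligned_values(dx: DistanceMatrix, dy: DistanceMatrix) -> np.ndarray:
    if dx.labels == dy.labels:
        return dy.values
    if set(dx.labels) != set(dy.labels):
        raise LabelError("distance matrices have different label sets")
    order = [dy.labels.index(lab) for lab in dx.labels]
    return dy.values[np.ix_(order, order)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    return float((xc @ yc) / denom) if denom > 0 else float("nan")


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
    tail: str = "positive",
) -> MantelResult:
    """Mantel test: Pearson correlation between two distance matrices.

    r is computed over the n(n-1)/2 unordered pairs; the null distribution
    comes from simultaneous row/column permutation of ``dy``. ``tail`` is
    "positive" (default; the isolation-by-distance direction), "negative",
    or "two-sided". The add-one convention keeps p > 0.
    """
    if len(dx) < 3:
        raise DesignError("Mantel test needs at least 3 objects")
    if tail not in ("positive", "negative", "two-sided"):
        raise DataError(f"unknown tail {tail!r}")
    yv = _aligned_values(dx, dy)
    n = len(dx)
    iu = np.triu_indices(n, k=1)
    x, y = dx.values[iu], yv[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateError("zero variance in off-diagonal distances")
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        r_perm = _pearson(x, yv[np.ix_(p, p)][iu])
        if tail == "positive":
            hits += r_perm >= r_obs
        elif tail == "negative":
            hits += r_perm <= r_obs
        else:
            hits += abs(r_perm) >= abs(r_obs)
    return MantelResult(
        r=r_obs,
        p=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        tail=tail,
    )


# ---------------------------------------------------------------------------
# Mantel correlogram
# ---------------------------------------------------------------------------

def sturges_classes(n_pairs: int) -> int:
    """Sturge's rule for the number of distance classes: ceil(1 + log2(m))."""
    if n_pairs < 1:
        raise DataError(f"n_pairs must be >= 1, got {n_pairs}")
    return math.ceil(1.0 + math.log2(n_pairs))


@dataclass(frozen=True)
class CorrelogramClass:
    """One distance class of a Mantel correlogram.

    ``r`` is sign-flipped relative to the raw Mantel statistic on the binary
    class-membership matrix, so positive r means pairs in the class are more
    genetically similar than average (positive spatial autocorrelation).
    Empty classes carry n_pairs = 0 and NaN statistics.
    """

    index: int
    lower_km: float
    upper_km: float
    midpoint_km: float
    n_pairs: int
    r: float
    p_raw: float
    p_bonferroni: float
    significant: bool


def mantel_correlogram(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[CorrelogramClass]:
    """Mantel correlogram over Sturge's-rule equal-width distance classes.

    Geographic distances are partitioned into k = ceil(1 + log2(m))
    equal-width classes spanning (0, max]; zero-distance (same-site) pairs
    join the first class so every pair is classified. Each class is tested
    by a Mantel permutation test of the genetic matrix against the binary
    class-membership matrix, one-tailed in the direction of the observed
    statistic, and Bonferroni-corrected by the number of classes k.
    """
    if len(d_gen) < 4:
        raise DesignError("correlogram needs at least 4 objects")
    geo = _aligned_values(d_gen, d_geo)
    n = len(d_gen)
    iu = np.triu_indices(n, k=1)
    g, e = d_gen.values[iu], geo[iu]
    if np.ptp(g) == 0:
        raise DegenerateError("zero variance in genetic distances")
    m = g.size
    k = sturges_classes(m)
    dmax = float(e.max())
    if dmax <= 0:
        raise DegenerateError("all geographic distances are zero")
    width = dmax / k
    # class index 1..k; upper-closed bins, zero-distance pairs into class 1
    cls = np.clip(np.ceil(e / width).astype(int), 1, k)

    rng = np.random.default_rng(seed)
    out = []
    for ci in range(1, k + 1):
        member = (cls == ci).astype(float)
        n_pairs = int(member.sum())
        lower, upper = (ci - 1) * width, ci * width
        mid = (lower + upper) / 2.0
        if n_pairs == 0 or n_pairs == m:
            out.append(CorrelogramClass(
                index=ci, lower_km=lower, upper_km=upper, midpoint_km=mid,
                n_pairs=n_pairs, r=float("nan"), p_raw=float("nan"),
                p_bonferroni=float("nan"), significant=False,
            ))
            continue
        r_obs = -_pearson(g, member)
        hits = 0
        for _ in range(n_permutations):
            p = rng.permutation(n)
            r_perm = -_pearson(d_gen.values[np.ix_(p, p)][iu], member)
            if r_obs >= 0:
                hits += r_perm >= r_obs
            else:
                hits += r_perm <= r_obs
        p_raw = (1 + hits) / (1 + n_permutations)
        p_bonf = min(1.0, k * p_raw)
        out.append(CorrelogramClass(
            index=ci, lower_km=lower, upper_km=upper, midpoint_km=mid,
            n_pairs=n_pairs, r=r_obs, p_raw=p_raw, p_bonferroni=p_bonf,
            significant=p_bonf <= alpha,
        ))
    return out


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IbdResult:
    mantel: MantelResult
    correlogram: list[CorrelogramClass]
    metadata: dict


def ibd_analysis(
    aln: Alignment,
    sites: GeoSites,
    membership: Mapping[str, str],
    n_permutations: int = 1000,
    seed: int | None = None,
    radius_km: float = MEAN_EARTH_RADIUS_KM,
    tail: str = "positive",
) -> IbdResult:
    """Full isolation-by-distance analysis of an aligned, georeferenced clade.

    Builds the genetic and geographic matrices, runs the global Mantel test
    and the per-class Mantel correlogram, and reports run metadata.
    """
    missing = [s for s in aln.seq_ids if s not in membership]
    if missing:
        raise MappingError(f"sequences without a site: {missing}")
    ordered = {s: membership[s] for s in aln.seq_ids}
    d_gen = genetic_distance_matrix(aln)
    d_geo = geographic_distance_matrix(sites, ordered, radius_km)
    global_test = mantel(d_gen, d_geo, n_permutations, seed, tail)
    classes = mantel_correlogram(
        d_gen, d_geo, n_permutations,
        None if seed is None else seed + 1,
    )
    meta = {
        "n_sequences": len(aln),
        "n_sites": len({ordered[s] for s in aln.seq_ids}),
        "n_pairs": d_gen.n_pairs,
        "max_distance_km": float(d_geo.values.max()),
        "n_classes": len(classes),
        "radius_km": radius_km,
    }
    return IbdResult(mantel=global_test, correlogram=classes, metadata=meta)


def plot_correlogram(classes: Sequence[CorrelogramClass], path: str) -> None:
    """Save a correlogram plot: Mantel r vs class midpoint, filled squares
    marking Bonferroni-significant classes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mids = [c.midpoint_km for c in classes if c.n_pairs > 0]
    rs = [c.r for c in classes if c.n_pairs > 0]
    sig = [c.significant for c in classes if c.n_pairs > 0]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.plot(mids, rs, "-", color="black", lw=1)
    for x, y, s in zip(mids, rs, sig):
        ax.plot(x, y, "s", mfc="black" if s else "white", mec="black", ms=7)
    ax.set_xlabel("geographic distance class midpoint (km)")
    ax.set_ylabel("Mantel r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
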