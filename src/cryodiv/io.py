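"""Domain types and readers/writers for the standard formats the pipeline touches.

The pipeline's currency is a handful of small validated containers:

* :class:`Alignment` -- equal-length sequences (FASTA in/out).
* :class:`OtuTable` -- non-negative integer counts, samples x OTUs (TSV).
* :class:`GeoSites` -- georeferenced sites in decimal degrees (CSV).
* :class:`MatchTable` -- per-OTU best database hit identity and the thermal
  environments of its close matches (TSV).
* :class:`DistanceMatrix` -- symmetric, zero-diagonal, non-negative (PHYLIP/TSV).
* rooted phylogenies with branch lengths, held as :class:`dendropy.Tree`
  (Newick in/out).

All tabular files are UTF-8 and tab-separated; lines starting with ``#`` are
comments. Parsers never silently drop records: every record either lands in
the returned object or raises.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import (
    AlignmentError,
    DataError,
    FormatError,
    RangeError,
    VocabularyError,
)

logger = logging.getLogger("cryodiv")

#: Controlled vocabulary for thermal environments of database matches.
ENVIRONMENTS = frozenset({"cold", "temperate"})

#: Symmetry tolerance for distance matrices.
SYMMETRY_TOL = 1e-12


def configure_logging(level: str = "INFO") -> None:
    """Configure the package logger once, CLI-style (stderr, terse format)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """Equal-length sequences over nucleotide symbols (gaps/ambiguity allowed)."""

    seq_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.sequences) or not self.seq_ids:
            raise FormatError("alignment needs at least one (id, sequence) pair")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            dupes = {s for s in self.seq_ids if self.seq_ids.count(s) > 1}
            raise FormatError(f"duplicate sequence ids: {sorted(dupes)}")
        length = len(self.sequences[0])
        if length < 1:
            raise AlignmentError(f"record {self.seq_ids[0]!r} has empty sequence")
        for sid, seq in zip(self.seq_ids, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(seq)}, expected {length}"
                )

    def __len__(self) -> int:
        return len(self.seq_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True, eq=False)
class OtuTable:
    """Sample-by-OTU count table; the unit of diversity analysis.

    Rows are samples, columns are OTUs; counts are non-negative integers and
    every sample retains at least one positive count.
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise FormatError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids")
        if counts.size and np.any(counts.sum(axis=1) == 0):
            empty = [s for s, t in zip(self.sample_ids, counts.sum(axis=1)) if t == 0]
            raise FormatError(f"samples with zero total counts: {empty}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        from .exceptions import LabelError

        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise LabelError(f"unknown sample {sample_id!r}") from None
        return self.counts[i]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )


@dataclass(frozen=True)
class GeoSites:
    """site_id -> (latitude, longitude) in decimal degrees."""

    coords: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for sid, (lat, lon) in self.coords.items():
            if not -90.0 <= lat <= 90.0:
                raise RangeError(f"site {sid!r}: latitude {lat} outside [-90, 90]")
            if not -180.0 < lon <= 180.0:
                raise RangeError(f"site {sid!r}: longitude {lon} outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, site_id: str) -> tuple[float, float]:
        return self.coords[site_id]

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.coords

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(self.coords)


@dataclass(frozen=True)
class MatchRecord:
    """Best-hit summary for one OTU against a reference database.

    ``match_environments`` lists the thermal environments of every database
    entry matching at >= 97% identity; it may be empty only when the best hit
    itself falls below 97%.
    """

    otu_id: str
    n_sequences: int
    best_identity_pct: float
    match_environments: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise FormatError(f"OTU {self.otu_id!r}: n_sequences must be >= 1")
        if not 0.0 <= self.best_identity_pct <= 100.0:
            raise RangeError(
                f"OTU {self.otu_id!r}: identity {self.best_identity_pct} outside [0, 100]"
            )
        bad = set(self.match_environments) - ENVIRONMENTS
        if bad:
            raise VocabularyError(
                f"OTU {self.otu_id!r}: unknown environment labels {sorted(bad)}; "
                f"allowed: {sorted(ENVIRONMENTS)}"
            )
        if self.best_identity_pct >= 97.0 and not self.match_environments:
            raise DataError(
                f"OTU {self.otu_id!r}: identity >= 97% requires at least one "
                "match environment"
            )


@dataclass(frozen=True)
class MatchTable:
    records: tuple[MatchRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.otu_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate OTU ids in match table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal and unique labels.

    The common currency of beta diversity and Mantel analyses.
    """

    __slots__ = ("labels", "values")

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        labels = tuple(labels)
        n = len(labels)
        if len(set(labels)) != n:
            raise FormatError("duplicate labels in distance matrix")
        if values.shape != (n, n):
            raise FormatError(f"matrix shape {values.shape} does not match {n} labels")
        if np.any(np.isnan(values)):
            raise DataError("distance matrix contains NaN")
        if np.any(np.diag(values) != 0.0):
            raise DataError("distance matrix diagonal must be exactly zero")
        if np.any(values < 0):
            raise DataError("distances must be non-negative")
        if np.max(np.abs(values - values.T), initial=0.0) > SYMMETRY_TOL:
            raise DataError(f"matrix not symmetric within {SYMMETRY_TOL}")
        self.labels = labels
        self.values = 0.5 * (values + values.T)  # exact symmetry

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        n = len(self.labels)
        return n * (n - 1) // 2

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])


RootedTree = dendropy.Tree  # alias: rooted phylogeny with branch lengths


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; residues are uppercased, order preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(ids, seqs)


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", **kwargs)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a TSV count table: header row of OTU ids, first column sample ids."""
    df = _read_table(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or missing cells")
    try:
        counts = df.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer cell ({exc})") from exc
    if (df.to_numpy(dtype=float) != counts).any():
        raise FormatError(f"{path}: non-integer counts")
    return OtuTable(
        tuple(str(s) for s in df.index),
        tuple(str(o) for o in df.columns),
        counts,
    )


def read_newick(path: str | Path) -> RootedTree:
    """Read a rooted Newick tree with branch lengths.

    Missing branch lengths are set to 0 with a warning: phylogenetic diversity
    and UniFrac sum branch lengths, and a silent default other than zero would
    bias those sums.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"{path}: not parseable as Newick ({exc})") from exc
    return validate_tree(tree, source=str(path))


def validate_tree(tree: RootedTree, source: str = "<tree>") -> RootedTree:
    """Enforce tree invariants: unique tips, non-negative lengths, no missing lengths."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{source}: duplicate tip labels")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise DataError(f"{source}: negative branch length {edge.length}")
    if n_missing:
        logger.warning("%s: %d missing branch length(s) set to 0", source, n_missing)
    return tree


def read_sites(path: str | Path) -> GeoSites:
    """Read a CSV site table with columns site_id, lat, lon (decimal degrees)."""
    df = _read_table(path, sep=",")
    required = {"site_id", "lat", "lon"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    ids = df["site_id"].astype(str)
    if ids.duplicated().any():
        raise FormatError(f"{path}: duplicate site ids")
    coords = {
        sid: (float(lat), float(lon))
        for sid, lat, lon in zip(ids, df["lat"], df["lon"])
    }
    return GeoSites(coords)


def read_match_table(path: str | Path) -> MatchTable:
    """Read a TSV match table: otu_id, n_sequences, best_identity_pct,
    match_environments (semicolon-separated; empty allowed below 97%)."""
    df = _read_table(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"otu_id", "n_sequences", "best_identity_pct", "match_environments"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        envs = frozenset(
            e.strip() for e in str(row.match_environments).split(";") if e.strip()
        )
        records.append(
            MatchRecord(
                otu_id=str(row.otu_id),
                n_sequences=int(row.n_sequences),
                best_identity_pct=float(row.best_identity_pct),
                match_environments=envs,
            )
        )
    return MatchTable(tuple(records))


def read_membership(path: str | Path) -> dict[str, str]:
    """Read a TSV seq_id -> site_id mapping."""
    df = _read_table(path, sep="\t", dtype=str)
    if not {"seq_id", "site_id"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns ['seq_id', 'site_id']")
    if df["seq_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate seq_ids")
    return dict(zip(df["seq_id"], df["site_id"]))


def read_phylip_distances(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP distance matrix, square or lower-triangular."""
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise FormatError(f"{path}: first line must be the taxon count") from None
    rows = lines[1:]
    if len(rows) != n:
        raise FormatError(f"{path}: expected {n} rows, found {len(rows)}")
    labels, mat = [], np.zeros((n, n))
    lower = None
    for i, row in enumerate(rows):
        parts = row.split()
        labels.append(parts[0])
        vals = [float(v) for v in parts[1:]]
        if lower is None:
            lower = len(vals) != n
        if lower:
            if len(vals) != i:
                raise FormatError(f"{path}: row {i} has {len(vals)} values, expected {i}")
            mat[i, :i] = vals
            mat[:i, i] = vals
        else:
            if len(vals) != n:
                raise FormatError(f"{path}: row {i} has {len(vals)} values, expected {n}")
            mat[i] = vals
    return DistanceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# Writers (each round-trips exactly through its reader)
# ---------------------------------------------------------------------------

def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.seq_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def write_newick(tree: RootedTree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_sites(sites: GeoSites, path: str | Path) -> None:
    pd.DataFrame(
        [(sid, lat, lon) for sid, (lat, lon) in sites.coords.items()],
        columns=["site_id", "lat", "lon"],
    ).to_csv(path, index=False)


def write_match_table(matches: MatchTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.otu_id, r.n_sequences, r.best_identity_pct,
             ";".join(sorted(r.match_environments)))
            for r in matches
        ],
        columns=["otu_id", "n_sequences", "best_identity_pct", "match_environments"],
    ).to_csv(path, sep="\t", index=False)


def write_membership(membership: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        list(membership.items()), columns=["seq_id", "site_id"]
    ).to_csv(path, sep="\t", index=False)


def write_phylip_distances(dist: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dist)}\n")
        for label, row in zip(dist.labels, dist.values):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_distance_tsv(dist: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(
        dist.values, index=list(dist.labels), columns=list(dist.labels)
    ).to_csv(path, sep="\t", index_label="label")


# ---------------------------------------------------------------------------
# Coordinate helper
# ---------------------------------------------------------------------------

_DDM_RE = re.compile(
    r"^\s*([NSEW])\s*(\d{1,3})\s+(\d{1,2}(?:[.,]\s*\d+)?)\s*[′']?\s*$",
    re.IGNORECASE,
)


def ddm_to_decimal(text: str) -> float:
    """Convert a degrees-decimal-minutes string to decimal degrees.

    Accepts field-notebook style strings such as ``"S 03 04.839'"`` or
    ``"E 037 21.628'"``; south and west are negative. Spaces after the decimal
    comma/point (an OCR artifact in transcribed coordinates) are tolerated.
    """
    m = _DDM_RE.match(text)
    if not m:
        raise FormatError(f"cannot parse coordinate {text!r}")
    hemi, deg, minutes = m.group(1).upper(), int(m.group(2)), m.group(3)
    minutes = float(minutes.replace(",", ".").replace(" ", ""))
    if minutes >= 60:
        raise RangeError(f"minutes {minutes} >= 60 in {text!r}")
    value = deg + minutes / 60.0
    if hemi in "SW":
        value = -value
    limit = 90.0 if hemi in "NS" else 180.0
    if abs(value) > limit:
        raise RangeError(f"{text!r}: {value} exceeds +/-{limit}")
    return value
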