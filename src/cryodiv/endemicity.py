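"""Environmental classification of OTUs (modified Herbold scheme).

An OTU whose best database hit is at >= 97% identity is *non-endemic* and is
subdivided by the thermal provenance of all its close (>= 97%) matches:
cryophilic (all from perennially cold environments), non-cryophilic (all
temperate), or polythermal/cosmopolitan (both). OTUs without a close match
are *endemic*: subnovel for best identity in [95.5, 97), novel in
[88.5, 95.5). Best identities below 88.5% fall outside the scheme and are
reported as unclassified rather than silently binned.

Only OTUs represented by at least 2 sequences are classified, screening out
likely sequencing artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .exceptions import DataError, RangeError
from .io import MatchTable, logger

NON_ENDEMIC_MIN = 97.0
SUBNOVEL_MIN = 95.5
NOVEL_MIN = 88.5

CATEGORIES = (
    "cryophilic",
    "non_cryophilic",
    "polythermal_cosmopolitan",
    "subnovel",
    "novel",
    "unclassified",
)

_TIER = {
    "cryophilic": "non_endemic",
    "non_cryophilic": "non_endemic",
    "polythermal_cosmopolitan": "non_endemic",
    "subnovel": "endemic",
    "novel": "endemic",
    "unclassified": "unclassified",
}


@dataclass(frozen=True)
class EndemicityClass:
    category: str
    tier: str


@dataclass(frozen=True)
class ClassificationSummary:
    """Category counts over the classifiable OTUs of a match table."""

    counts: dict[str, int]
    n_endemic: int
    n_non_endemic: int
    pct_cosmopolitan_of_non_endemic: float

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def filter_classifiable(matches: MatchTable, min_seqs: int = 2) -> MatchTable:
    """Keep only OTUs represented by at least ``min_seqs`` sequences."""
    return MatchTable(
        tuple(r for r in matches if r.n_sequences >= min_seqs)
    )


def classify_otu(
    best_identity_pct: float, match_environments: Iterable[str]
) -> EndemicityClass:
    """Classify one OTU from its best-hit identity and close-match environments.

    The 97% boundary itself counts as non-endemic (closed from below), so the
    endemic and non-endemic rules partition the identity line; the same
    closure applies at 95.5 and 88.5.
    """
    if not 0.0 <= best_identity_pct <= 100.0:
        raise RangeError(f"identity {best_identity_pct} outside [0, 100]")
    envs = set(match_environments)
    if best_identity_pct >= NON_ENDEMIC_MIN:
        if not envs:
            raise DataError(
                "non-endemic OTU (identity >= 97%) with no match environments"
            )
        if envs == {"cold"}:
            cat = "cryophilic"
        elif envs == {"temperate"}:
            cat = "non_cryophilic"
        else:
            cat = "polythermal_cosmopolitan"
    elif best_identity_pct >= SUBNOVEL_MIN:
        cat = "subnovel"
    elif best_identity_pct >= NOVEL_MIN:
        cat = "novel"
    else:
        logger.warning(
            "best identity %.2f%% below %.1f%%: outside the classification "
            "scheme, reported as unclassified",
            best_identity_pct, NOVEL_MIN,
        )
        cat = "unclassified"
    return EndemicityClass(category=cat, tier=_TIER[cat])


def classify_dataset(
    matches: MatchTable, min_seqs: int = 2
) -> tuple[dict[str, EndemicityClass], ClassificationSummary]:
    """Classify every classifiable OTU and summarize category counts.

    Returns (per-OTU classes, summary). The cosmopolitan percentage is kept
    unrounded; report text conventionally rounds it to a whole percent.
    """
    kept = filter_classifiable(matches, min_seqs)
    per_otu = {
        r.otu_id: classify_otu(r.best_identity_pct, r.match_environments)
        for r in kept
    }
    counts = {c: 0 for c in CATEGORIES}
    for cls in per_otu.values():
        counts[cls.category] += 1
    n_non_endemic = sum(counts[c] for c in CATEGORIES if _TIER[c] == "non_endemic")
    n_endemic = sum(counts[c] for c in CATEGORIES if _TIER[c] == "endemic")
    pct = (
        100.0 * counts["polythermal_cosmopolitan"] / n_non_endemic
        if n_non_endemic
        else 0.0
    )
    return per_otu, ClassificationSummary(
        counts=counts,
        n_endemic=n_endemic,
        n_non_endemic=n_non_endemic,
        pct_cosmopolitan_of_non_endemic=pct,
    )
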