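"""Domain architectures of sigma70 proteins.

A protein's architecture is the N->C ordered sequence of its (non-overlapping)
domain hits, written with ``*`` separators, e.g. ``r1_2*r2*r3*r4``.  The
domain vocabulary splits into six *essential* sigma70 domains (r1_2, r2, r3,
r4, r4_2 and ECF) with a canonical N->C rank, and an open set of *accessory*
domains (DUF6596, NB-ARC, TPR_MalT, WD40, ...).  Restricting an architecture
to the essential vocabulary yields its *core pattern*; the positions of
accessory domains relative to the core (N-terminal, C-terminal, both sides,
or internal) drive family numbering downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hits import DomainHit

__all__ = [
    "DomainVocabulary",
    "DomainToken",
    "Architecture",
    "CoreDecomposition",
    "SizeMetrics",
    "load_profile_aliases",
    "build_architecture",
    "decompose",
    "architecture_census",
    "size_metrics",
    "architectures_to_frame",
]


def load_profile_aliases(path: str | Path | None = None) -> dict[str, str]:
    """Load the long-profile-name -> short-token alias table.

    Ships as ``data/profile_aliases.tsv``; pass a path to extend or replace
    it.  Profiles absent from the table keep their own name as token (this is
    how accessory profiles like DUF6596 pass through unchanged).
    """
    if path is None:
        src = resources.files("sig70arch").joinpath("data/profile_aliases.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["profile"].astype(str), df["token"].astype(str)))


DEFAULT_ALIASES: dict[str, str] = load_profile_aliases()

#: Canonical N->C rank of the essential domains.  r4 and r4_2 share one rank
#: (r4_2 is a variant of r4); ECF stands alone at the end of the order.
ESSENTIAL_RANK: dict[str, int] = {
    "r1_2": 1,
    "r2": 2,
    "r3": 3,
    "r4": 4,
    "r4_2": 4,
    "ECF": 5,
}


@dataclass(frozen=True)
class DomainVocabulary:
    """The essential/accessory split of domain tokens.

    ``essential`` is a closed ordered set with canonical ranks; everything
    else is accessory (an open set — unseen tokens are accessory by
    definition, so classification stays total on novel genomes).
    """

    essential: tuple[str, ...] = ("r1_2", "r2", "r3", "r4", "r4_2", "ECF")
    ranks: Mapping[str, int] = field(default_factory=lambda: dict(ESSENTIAL_RANK))

    def __post_init__(self) -> None:
        missing = [t for t in self.essential if t not in self.ranks]
        if missing:
            raise ValueError(f"essential tokens without a rank: {missing}")

    def is_essential(self, token: str) -> bool:
        return token in self.essential

    def rank(self, token: str) -> int:
        return self.ranks[token]


DEFAULT_VOCABULARY = DomainVocabulary()


@dataclass(frozen=True, slots=True)
class DomainToken:
    """One positioned domain in an architecture (short token + coordinates)."""

    token: str
    ali_start: int
    ali_end: int

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class Architecture:
    """N->C ordered domain composition of one protein."""

    protein_id: str
    tokens: tuple[DomainToken, ...]
    protein_length: int
    genome_id: str = ""

    def __post_init__(self) -> None:
        starts = [t.ali_start for t in self.tokens]
        if starts != sorted(starts):
            raise ValueError(f"{self.protein_id}: tokens not ordered by ali_start")
        if self.tokens and self.protein_length < max(t.ali_end for t in self.tokens):
            raise ValueError(
                f"{self.protein_id}: protein_length {self.protein_length} shorter "
                f"than last domain end"
            )

    @property
    def string(self) -> str:
        """The ``*``-joined architecture string, e.g. ``r1_2*r2*r3*r4``."""
        return "*".join(t.token for t in self.tokens)

    def token_names(self) -> tuple[str, ...]:
        return tuple(t.token for t in self.tokens)


@dataclass(frozen=True)
class CoreDecomposition:
    """An architecture split into essential core pattern + accessory placement.

    ``ad_placement`` is one of ``none``, ``N``, ``C``, ``both`` or
    ``internal``; accessory domains strictly between two essential domains
    (never observed in the cyanobacterial cohort, where accessory domains sit
    exclusively at the protein extremities) are accepted but flagged via
    ``warnings``.
    """

    core_pattern: tuple[str, ...]
    ad_placement: str
    accessory: tuple[tuple[str, str], ...]  # (token, side) with side in N/C/internal
    warnings: tuple[str, ...] = ()

    @property
    def core_string(self) -> str:
        return "*".join(self.core_pattern)


@dataclass(frozen=True)
class SizeMetrics:
    protein_length: int
    essential_span_sum: int
    coverage_fraction: float


def build_architecture(
    hits: Sequence[DomainHit],
    protein_length: int | None = None,
    aliases: Mapping[str, str] | None = None,
) -> Architecture:
    """Assemble an :class:`Architecture` from resolved (non-overlapping) hits.

    ``protein_length`` defaults to the length recorded on the hits (the
    domtblout ``tlen`` column) and must be at least the last domain end.
    Overlapping input is a contract violation — run
    :func:`sig70arch.hits.resolve_overlaps` first.
    """
    if not hits:
        raise ValueError("no domains: cannot build an architecture from zero hits")
    alias = DEFAULT_ALIASES if aliases is None else aliases
    ordered = sorted(hits, key=lambda h: (h.ali_start, h.ali_end))
    for a, b in zip(ordered, ordered[1:]):
        if b.ali_start <= a.ali_end:
            raise ValueError(
                f"{a.protein_id}: overlapping hits {a.profile}@{a.ali_start}-{a.ali_end} "
                f"and {b.profile}@{b.ali_start}-{b.ali_end}; resolve overlaps first"
            )
    if protein_length is None:
        known = [h.protein_length for h in ordered if h.protein_length is not None]
        protein_length = max(known) if known else ordered[-1].ali_end
    tokens = tuple(
        DomainToken(alias.get(h.profile, h.profile), h.ali_start, h.ali_end)
        for h in ordered
    )
    return Architecture(
        protein_id=ordered[0].protein_id,
        tokens=tokens,
        protein_length=int(protein_length),
        genome_id=ordered[0].genome_id,
    )


def decompose(
    arch: Architecture,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> CoreDecomposition:
    """Split an architecture into essential core pattern and accessory placement."""
    names = arch.token_names()
    ess_idx = [i for i, t in enumerate(names) if vocab.is_essential(t)]
    if not ess_idx:
        raise ValueError(
            f"unclassifiable: no essential domain in architecture {arch.string!r}"
        )
    first, last = ess_idx[0], ess_idx[-1]
    core = tuple(names[i] for i in ess_idx)
    accessory: list[tuple[str, str]] = []
    warnings: list[str] = []
    for i, t in enumerate(names):
        if vocab.is_essential(t):
            continue
        if i < first:
            accessory.append((t, "N"))
        elif i > last:
            accessory.append((t, "C"))
        else:
            accessory.append((t, "internal"))
            warnings.append(
                f"{arch.protein_id}: accessory domain {t} internal to the core"
            )
    sides = {side for _, side in accessory}
    if not accessory:
        placement = "none"
    elif "internal" in sides:
        placement = "internal"
    elif sides == {"N"}:
        placement = "N"
    elif sides == {"C"}:
        placement = "C"
    else:
        placement = "both"
    return CoreDecomposition(
        core_pattern=core,
        ad_placement=placement,
        accessory=tuple(accessory),
        warnings=tuple(warnings),
    )


def architecture_census(architectures: Iterable[Architecture]) -> pd.DataFrame:
    """Count distinct architecture strings; rows sorted lexicographically."""
    counts: dict[str, int] = {}
    for a in architectures:
        counts[a.string] = counts.get(a.string, 0) + 1
    return pd.DataFrame(
        {"pattern": sorted(counts), "count": [counts[p] for p in sorted(counts)]}
    )


def size_metrics(
    arch: Architecture,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> SizeMetrics:
    """Protein length, summed essential-domain span, and essential coverage.

    Tokens are disjoint by construction, so the essential span is a plain sum
    of per-domain lengths and coverage lies in (0, 1] whenever at least one
    essential domain is present.
    """
    span = sum(t.length for t in arch.tokens if vocab.is_essential(t.token))
    return SizeMetrics(
        protein_length=arch.protein_length,
        essential_span_sum=span,
        coverage_fraction=span / arch.protein_length,
    )


def architectures_to_frame(
    architectures: Iterable[Architecture],
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Tabulate architectures (one row per protein) for TSV export."""
    rows = []
    for a in architectures:
        d = decompose(a, vocab)
        m = size_metrics(a, vocab)
        rows.append(
            {
                "genome_id": a.genome_id,
                "protein_id": a.protein_id,
                "architecture_string": a.string,
                "core_pattern": d.core_string,
                "ad_placement": d.ad_placement,
                "protein_length": m.protein_length,
                "essential_span_sum": m.essential_span_sum,
                "coverage": m.coverage_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "protein_id",
            "architecture_string",
            "core_pattern",
            "ad_placement",
            "protein_length",
            "essential_span_sum",
            "coverage",
        ],
    )
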