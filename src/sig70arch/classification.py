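"""Clan/family classification and standardized nomenclature of sigma70 units.

A *clan* is the set of homologs sharing the same set of essential domains;
twelve primary clans (A-L) are registered with defined canonical core
patterns, plus the miscellaneous clan Z for undetermined essential-domain
sets.  Within a clan, a *family* is fixed by the core pattern and the
placement of accessory domains (AD):

* canonical core: index 1 (no AD), 2 (N-terminal AD), 3 (C-terminal AD),
  4 (AD on both sides);
* the k-th registered non-canonical core pattern of the clan owns the index
  block 4k+1 .. 4k+4 with the same placement offsets (5-8 for the first,
  9-12 for the second, and so on).

Each homolog then receives the standardized name ``Sig<clan>.<index>.<n>``
where ``n`` numbers the homologs of that family within one genome, assigned
deterministically from a configurable ordering key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .architecture import (
    Architecture,
    CoreDecomposition,
    DEFAULT_VOCABULARY,
    DomainVocabulary,
    decompose,
)

__all__ = [
    "ClanFamilyRegistry",
    "FamilyId",
    "SigmaUnit",
    "is_canonical",
    "assign_clan",
    "assign_family",
    "classify_architecture",
    "classify_cohort",
    "assign_unit_names",
]

_PLACEMENT_OFFSET = {"none": 1, "N": 2, "C": 3, "both": 4, "internal": 4}
_CLAN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXY"  # Z reserved for miscellaneous


@dataclass(frozen=True, order=True)
class FamilyId:
    """A family: clan letter plus positive index (``index <= 4`` iff canonical core)."""

    clan: str
    index: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("family index must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.clan}.{self.index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class SigmaUnit:
    """One classified sigma70 homolog with its standardized unit name."""

    genome_id: str
    protein_id: str
    family: FamilyId
    unit_suffix: int
    name: str


@dataclass
class ClanFamilyRegistry:
    """Clan table (letter -> essential set + canonical pattern) and the
    per-clan append-only lists of registered non-canonical core patterns.

    The shipped registry lives in ``data/clans.yaml`` and is editable;
    ``auto_extend`` operations may register new non-canonical patterns (and,
    optionally, new clans) during classification, always by appending, so
    that numbering never shifts for previously seen patterns.
    """

    essential_sets: dict[str, frozenset[str]]
    canonical: dict[str, tuple[str, ...]]
    noncanonical: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    @classmethod
    def default(cls, path: str | Path | None = None) -> "ClanFamilyRegistry":
        """Load the shipped registry (or one from ``path``)."""
        if path is None:
            src = resources.files("sig70arch").joinpath("data/clans.yaml")
            with resources.as_file(src) as p:
                raw = yaml.safe_load(p.read_text())
        else:
            raw = yaml.safe_load(Path(path).read_text())
        essential_sets: dict[str, frozenset[str]] = {}
        canonical: dict[str, tuple[str, ...]] = {}
        for letter, entry in raw["clans"].items():
            essential_sets[str(letter)] = frozenset(entry["essential"])
            canonical[str(letter)] = tuple(entry["canonical"])
        noncanonical = {
            str(letter): [tuple(p) for p in patterns]
            for letter, patterns in (raw.get("noncanonical") or {}).items()
        }
        reg = cls(essential_sets=essential_sets, canonical=canonical, noncanonical=noncanonical)
        reg._check()
        return reg

    def _check(self) -> None:
        seen: dict[frozenset[str], str] = {}
        for letter, s in self.essential_sets.items():
            if s in seen:
                raise ValueError(f"clans {seen[s]} and {letter} share an essential set")
            seen[s] = letter
            canon = self.canonical[letter]
            if frozenset(canon) != s or len(canon) != len(s):
                raise ValueError(f"clan {letter}: canonical pattern inconsistent with set")

    @property
    def primary_clans(self) -> list[str]:
        return sorted(self.essential_sets)

    def clan_for_set(self, domains: frozenset[str]) -> str | None:
        for letter, s in self.essential_sets.items():
            if s == domains:
                return letter
        return None

    def _next_letter(self) -> str:
        for letter in _CLAN_LETTERS:
            if letter not in self.essential_sets:
                return letter
        raise RuntimeError("clan letters exhausted")

    def register_clan(self, domains: frozenset[str], vocab: DomainVocabulary) -> str:
        """Register a new primary clan for an unseen essential-domain set."""
        letter = self._next_letter()
        self.essential_sets[letter] = domains
        # canonical order: by rank, name as tie-break (r4/r4_2 share a rank)
        self.canonical[letter] = tuple(sorted(domains, key=lambda t: (vocab.rank(t), t)))
        return letter

    def noncanonical_slot(self, clan: str, pattern: tuple[str, ...], register: bool = True) -> int:
        """1-based slot k of a non-canonical core pattern within its clan.

        Unseen patterns are appended when ``register`` is true (the default),
        keeping numbering append-only and therefore stable.
        """
        patterns = self.noncanonical.setdefault(clan, [])
        for k, p in enumerate(patterns, start=1):
            if p == pattern:
                return k
        if not register:
            raise KeyError(f"unregistered non-canonical pattern {pattern} in clan {clan}")
        patterns.append(pattern)
        return len(patterns)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "clans": {
                letter: {
                    "essential": sorted(self.essential_sets[letter]),
                    "canonical": list(self.canonical[letter]),
                }
                for letter in sorted(self.essential_sets)
            },
            "noncanonical": {
                letter: [list(p) for p in patterns]
                for letter, patterns in self.noncanonical.items()
                if patterns
            },
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def is_canonical(
    core_pattern: Sequence[str],
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> bool:
    """True iff every essential domain of the pattern appears exactly once and
    the tokens follow the canonical N->C rank order.

    r4 and r4_2 share one canonical rank, so a pattern carrying both is
    non-canonical (no strict order exists between them).
    """
    pattern = tuple(core_pattern)
    if not pattern:
        raise ValueError("empty core pattern")
    if len(set(pattern)) != len(pattern):
        return False
    ranks = [vocab.rank(t) for t in pattern]
    return all(a < b for a, b in zip(ranks, ranks[1:])) or len(ranks) == 1


def assign_clan(
    core_pattern: Sequence[str],
    registry: ClanFamilyRegistry,
    auto_extend: bool = False,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> str:
    """Clan letter for a core pattern: the primary clan whose essential-domain
    set equals the pattern's set; otherwise a freshly registered letter when
    ``auto_extend`` is on, else the miscellaneous clan ``Z``."""
    domains = frozenset(core_pattern)
    if not domains:
        raise ValueError("empty core pattern")
    letter = registry.clan_for_set(domains)
    if letter is not None:
        return letter
    if auto_extend:
        return registry.register_clan(domains, vocab)
    return "Z"


def assign_family(
    decomp: CoreDecomposition,
    registry: ClanFamilyRegistry,
    auto_extend: bool = False,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> FamilyId:
    """Family of a decomposed architecture.

    Base index 0 for the clan's canonical core, 4k for its k-th registered
    non-canonical core; plus 1/2/3/4 for AD placement none/N/C/both.  Internal
    accessory domains map to the both-sides class (4) so classification stays
    total.  Patterns routed to clan Z are always treated as non-canonical
    (Z has no defined core), yielding Z.5+, Z.9+, ...
    """
    clan = assign_clan(decomp.core_pattern, registry, auto_extend=auto_extend, vocab=vocab)
    pattern = decomp.core_pattern
    if clan != "Z" and pattern == registry.canonical.get(clan):
        base = 0
    else:
        base = 4 * registry.noncanonical_slot(clan, pattern)
    return FamilyId(clan=clan, index=base + _PLACEMENT_OFFSET[decomp.ad_placement])


def classify_architecture(
    arch: Architecture,
    registry: ClanFamilyRegistry | None = None,
    auto_extend: bool = False,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> tuple[FamilyId, CoreDecomposition]:
    """Decompose and classify one architecture in a single call."""
    if registry is None:
        registry = ClanFamilyRegistry.default()
    d = decompose(arch, vocab)
    return assign_family(d, registry, auto_extend=auto_extend, vocab=vocab), d


def classify_cohort(
    architectures: Iterable[Architecture],
    registry: ClanFamilyRegistry | None = None,
    auto_extend: bool = False,
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Classify a cohort of architectures into a tidy table.

    Architectures are processed in a deterministic order (genome id, protein
    id) so that any on-the-fly registration of non-canonical patterns is
    reproducible.  Returns one row per protein with clan, family index,
    family label, core pattern and AD placement.
    """
    if registry is None:
        registry = ClanFamilyRegistry.default()
    rows = []
    for arch in sorted(architectures, key=lambda a: (a.genome_id, a.protein_id)):
        fam, d = classify_architecture(arch, registry, auto_extend=auto_extend, vocab=vocab)
        rows.append(
            {
                "genome_id": arch.genome_id,
                "protein_id": arch.protein_id,
                "clan": fam.clan,
                "family_index": fam.index,
                "family": fam.label,
                "core_pattern": d.core_string,
                "ad_placement": d.ad_placement,
                "architecture_string": arch.string,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "protein_id",
            "clan",
            "family_index",
            "family",
            "core_pattern",
            "ad_placement",
            "architecture_string",
        ],
    )


def assign_unit_names(
    classified: pd.DataFrame,
    order_by: Sequence[str] = ("protein_id",),
) -> pd.DataFrame:
    """Assign deterministic per-genome unit suffixes and render unit names.

    Within each (genome, family) group, suffixes run 1..n following
    ``order_by`` (default: protein id; pass e.g. ``("replicon", "start",
    "protein_id")`` when gene coordinates are available).  The historical
    practice of numbering units arbitrarily is replaced by this deterministic
    key so reruns produce identical names.
    """
    if classified.empty:
        out = classified.copy()
        out["unit_suffix"] = pd.Series(dtype=int)
        out["name"] = pd.Series(dtype=str)
        return out
    dup = classified.duplicated(subset=["genome_id", "protein_id"])
    if dup.any():
        offenders = classified.loc[dup, ["genome_id", "protein_id"]]
        raise ValueError(
            f"duplicate protein ids within a genome: {offenders.to_dict('records')}"
        )
    out = classified.sort_values(
        ["genome_id", "clan", "family_index", *order_by], kind="mergesort"
    ).copy()
    out["unit_suffix"] = out.groupby(["genome_id", "clan", "family_index"]).cumcount() + 1
    out["name"] = (
        "Sig"
        + out["clan"].astype(str)
        + "."
        + out["family_index"].astype(str)
        + "."
        + out["unit_suffix"].astype(str)
    )
    return out.reset_index(drop=True)
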