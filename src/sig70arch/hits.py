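"""Ingestion of profile-HMM domain hits.

Sigma70 homolog detection starts from per-domain alignments of Pfam-style
domain profiles (Sigma70_r1_2, Sigma70_r2, ... plus accessory profiles such as
DUF6596) against protein sequences.  This module reads HMMER3 per-domain
tabular output (``domtblout``), keeps hits whose per-domain bit score clears
the profile's gathering (trusted) cutoff, resolves overlapping hits so that
each residue is claimed by at most one domain, and applies the seed-domain
requisite that defines a putative sigma70 homolog.

Coordinates are 1-based inclusive amino-acid positions, the HMMER convention.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

__all__ = [
    "DomainHit",
    "ThresholdTable",
    "DomtbloutParseError",
    "DEFAULT_SEED_PROFILES",
    "parse_domtblout",
    "filter_by_threshold",
    "resolve_overlaps",
    "require_seed_domain",
    "hits_to_frame",
    "frame_to_hits",
    "write_hits_tsv",
    "read_hits_tsv",
]

#: The seven representative seed profiles; a protein qualifies as a putative
#: sigma70 homolog only if at least one surviving hit comes from this set.
DEFAULT_SEED_PROFILES: frozenset[str] = frozenset(
    {
        "Sigma70_r1_1",
        "Sigma70_r1_2",
        "Sigma70_r2",
        "Sigma70_r3",
        "Sigma70_r4",
        "Sigma70_r4_2",
        "Sigma70_ECF",
    }
)

HIT_COLUMNS = [
    "genome_id",
    "protein_id",
    "profile",
    "ali_start",
    "ali_end",
    "bit_score",
    "e_value",
]

_GENOME_RE = re.compile(r"genome=(\S+)")


class DomtbloutParseError(ValueError):
    """Raised for a malformed domtblout line; carries the 1-based line number."""

    def __init__(self, line_number: int, reason: str):
        self.line_number = line_number
        super().__init__(f"domtblout line {line_number}: {reason}")


@dataclass(frozen=True, slots=True)
class DomainHit:
    """One profile-HMM alignment of a domain profile to a protein region.

    ``bit_score`` and ``e_value`` are the per-domain (independent) values;
    ``ali_start``/``ali_end`` are the alignment coordinates on the protein,
    1-based inclusive.  ``protein_length`` is carried along when known (the
    domtblout ``tlen`` column) so downstream architecture building does not
    require the FASTA.
    """

    protein_id: str
    profile: str
    ali_start: int
    ali_end: int
    bit_score: float
    e_value: float
    genome_id: str = ""
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if not self.profile:
            raise ValueError("profile must be a non-empty token")
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"invalid coordinates {self.ali_start}..{self.ali_end} "
                f"for {self.protein_id}/{self.profile}"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def length(self) -> int:
        """Alignment length in residues (inclusive coordinates)."""
        return self.ali_end - self.ali_start + 1

    def overlap_length(self, other: "DomainHit") -> int:
        """Number of residues shared with ``other`` (0 if disjoint)."""
        lo = max(self.ali_start, other.ali_start)
        hi = min(self.ali_end, other.ali_end)
        return max(0, hi - lo + 1)


@dataclass
class ThresholdTable:
    """Per-profile trusted bit-score cutoffs (sequence level, domain level).

    The domain-level cutoff is the one enforced by :func:`filter_by_threshold`;
    the sequence-level cutoff is recorded for completeness but not applied by
    default, since per-domain records do not carry the full-sequence score.
    ``default`` supplies cutoffs for profiles absent from the table; if it is
    ``None``, querying an unknown profile raises :class:`KeyError`.
    """

    cutoffs: dict[str, tuple[float, float]]
    default: tuple[float, float] | None = None

    def _lookup(self, profile: str) -> tuple[float, float]:
        try:
            return self.cutoffs[profile]
        except KeyError:
            if self.default is not None:
                return self.default
            raise KeyError(
                f"no trusted threshold for profile {profile!r} and no default policy"
            ) from None

    def sequence_cutoff(self, profile: str) -> float:
        return self._lookup(profile)[0]

    def domain_cutoff(self, profile: str) -> float:
        return self._lookup(profile)[1]

    @classmethod
    def from_tsv(cls, source: str | Path | TextIO, default: tuple[float, float] | None = None) -> "ThresholdTable":
        """Read a 3-column TSV: profile, sequence cutoff, domain cutoff."""
        df = pd.read_csv(source, sep="\t", comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        cutoffs = {
            str(row.iloc[0]): (float(row.iloc[1]), float(row.iloc[2]))
            for _, row in df.iterrows()
        }
        return cls(cutoffs=cutoffs, default=default)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"profile": p, "seq_cutoff": s, "dom_cutoff": d}
            for p, (s, d) in sorted(self.cutoffs.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_domtblout(
    stream: str | Path | TextIO | Iterable[str],
    genome_id: str = "",
) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output into :class:`DomainHit` records.

    Uses the per-domain alignment coordinates (``ali from``/``ali to``), the
    per-domain bit score and the independent E-value (``i-Evalue``) columns;
    input order is preserved.  Lines starting with ``#`` are comments.  If the
    free-text description field contains a ``genome=<id>`` token it overrides
    the ``genome_id`` argument (the synthetic generator uses this to keep one
    hit table for a whole cohort).
    """
    if isinstance(stream, (str, Path)):
        if isinstance(stream, str) and "\n" in stream:
            lines: Iterable[str] = io.StringIO(stream)
        else:
            lines = open(stream, "rt", encoding="utf-8")
    else:
        lines = stream

    hits: list[DomainHit] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 22:
            raise DomtbloutParseError(
                lineno, f"expected >= 22 whitespace-delimited fields, got {len(parts)}"
            )
        description = " ".join(parts[22:])
        try:
            tlen = int(parts[2])
            i_evalue = float(parts[12])
            dom_score = float(parts[13])
            ali_from = int(parts[17])
            ali_to = int(parts[18])
        except ValueError as exc:
            raise DomtbloutParseError(lineno, f"non-numeric field: {exc}") from None
        m = _GENOME_RE.search(description)
        gid = m.group(1) if m else genome_id
        try:
            hit = DomainHit(
                protein_id=parts[0],
                profile=parts[3],
                ali_start=ali_from,
                ali_end=ali_to,
                bit_score=dom_score,
                e_value=i_evalue,
                genome_id=gid,
                protein_length=tlen if tlen > 0 else None,
            )
        except ValueError as exc:
            raise DomtbloutParseError(lineno, str(exc)) from None
        hits.append(hit)
    if hasattr(lines, "close") and not isinstance(stream, io.StringIO):
        try:
            lines.close()  # type: ignore[union-attr]
        except Exception:
            pass
    return hits


def filter_by_threshold(
    hits: Sequence[DomainHit],
    thresholds: ThresholdTable,
    comparator: str = ">=",
) -> list[DomainHit]:
    """Keep hits whose domain bit score clears the profile's trusted cutoff.

    ``comparator`` is ``">="`` (Pfam gathering cutoffs are curated as
    inclusive bounds; the default) or ``">"`` (strict).  Order is preserved,
    and the operation is idempotent.  Unknown profiles raise ``KeyError``
    unless the table declares a default.
    """
    if comparator not in (">=", ">"):
        raise ValueError(f"comparator must be '>=' or '>', got {comparator!r}")
    keep: list[DomainHit] = []
    for h in hits:
        cutoff = thresholds.domain_cutoff(h.profile)
        ok = h.bit_score >= cutoff if comparator == ">=" else h.bit_score > cutoff
        if ok:
            keep.append(h)
    return keep


def _selection_key(h: DomainHit) -> tuple:
    # longest first, then best (smallest) E-value, then leftmost, then name
    return (-h.length, h.e_value, h.ali_start, h.profile)


def _conflicts(a: DomainHit, b: DomainHit, min_overlap_frac: float) -> bool:
    ov = a.overlap_length(b)
    if ov == 0:
        return False
    return ov > min_overlap_frac * min(a.length, b.length)


def resolve_overlaps(
    hits: Sequence[DomainHit],
    min_overlap_frac: float = 0.0,
) -> list[DomainHit]:
    """Resolve overlapping domain hits on one protein.

    When domains overlap, the longest ones with the best E-values win: hits
    are sorted by (length descending, E-value ascending, start ascending,
    profile name ascending) and accepted greedily if they do not overlap any
    previously accepted hit.  With the default ``min_overlap_frac`` of 0, any
    shared residue is a conflict; a positive fraction tolerates overlaps up to
    that fraction of the shorter hit.  Output is sorted by ``ali_start`` and
    is pairwise disjoint, and the result is independent of input order.
    """
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"resolve_overlaps expects one protein, got {sorted(protein_ids)}")
    accepted: list[DomainHit] = []
    for h in sorted(hits, key=_selection_key):
        if not any(_conflicts(h, a, min_overlap_frac) for a in accepted):
            accepted.append(h)
    accepted.sort(key=lambda h: (h.ali_start, h.ali_end, h.profile))
    return accepted


def require_seed_domain(
    hits: Iterable[DomainHit],
    seed_profiles: Iterable[str] = DEFAULT_SEED_PROFILES,
) -> bool:
    """True iff at least one hit's profile belongs to the seed set.

    The seed set defaults to the seven representative sigma70 profiles; pass
    ``{"DUF6596"}`` to run the accessory-domain survey mode instead.
    """
    seeds = frozenset(seed_profiles)
    if not seeds:
        raise ValueError("seed_profiles must be non-empty")
    return any(h.profile in seeds for h in hits)


# ---------------------------------------------------------------------------
# tabular round-trips

def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": h.genome_id,
            "protein_id": h.protein_id,
            "profile": h.profile,
            "ali_start": h.ali_start,
            "ali_end": h.ali_end,
            "bit_score": h.bit_score,
            "e_value": h.e_value,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(df: pd.DataFrame) -> list[DomainHit]:
    return [
        DomainHit(
            protein_id=str(r.protein_id),
            profile=str(r.profile),
            ali_start=int(r.ali_start),
            ali_end=int(r.ali_end),
            bit_score=float(r.bit_score),
            e_value=float(r.e_value),
            genome_id=str(r.genome_id) if not pd.isna(r.genome_id) else "",
        )
        for r in df.itertuples(index=False)
    ]


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    return frame_to_hits(pd.read_csv(path, sep="\t", keep_default_na=False))
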