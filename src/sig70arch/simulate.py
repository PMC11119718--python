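"""Synthetic cohort generator with planted sigma70 architectures.

Every other module of the package consumes standard inputs (FASTA proteomes,
HMMER3 domtblout hit tables, a threshold TSV, genome metadata); this module
fabricates all four, with a truth table of planted family labels, so the
whole pipeline is testable without any genome download.

The generator emulates the statistical structure of a cyanobacterial cohort:
per-genome homolog counts averaging ~12 with ~90% of genomes between 5 and
17, heterocyst-forming (H) genomes larger and richer overall and enriched in
the A.1, A.5, C.1, J.1 and K.1 families, the ECF-only L.1 family absent from
H genomes, and A.1/F.1 present in every genome.  Protein sequences are random
residues of realistic lengths (A-family proteins ~350 aa); the pipeline
consumes domain hits, not alignments, so sequence content is irrelevant.
Decoy hits — sub-threshold matches and overlapping shorter matches — exercise
the threshold filter and the overlap resolver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hits import DomainHit, ThresholdTable

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "default_paper_like_spec"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: short token -> Pfam-style profile name used in the hit tables
TOKEN_TO_PROFILE = {
    "r1_1": "Sigma70_r1_1",
    "r1_2": "Sigma70_r1_2",
    "ner": "Sigma70_ner",
    "r2": "Sigma70_r2",
    "r3": "Sigma70_r3",
    "r4": "Sigma70_r4",
    "r4_2": "Sigma70_r4_2",
    "ECF": "Sigma70_ECF",
}

#: mean and sd of the emitted domain lengths (aa); chosen so a full
#: r1_2*r2*r3*r4 protein lands near 350 aa and an ECF-only protein near 200.
DOMAIN_LENGTHS: dict[str, tuple[float, float]] = {
    "r1_2": (70, 8),
    "r2": (68, 7),
    "r3": (50, 5),
    "r4": (55, 5),
    "r4_2": (45, 5),
    "ECF": (165, 12),
    "_accessory": (65, 12),
}

ACCESSORY_PROFILES = [
    ("DUF6596", 0.50),
    ("NB-ARC", 0.10),
    ("WD40", 0.10),
    ("zf-C4_ClpX", 0.08),
    ("Ank_2", 0.07),
    ("TPR_MalT", 0.05),
    ("AAA_35", 0.05),
    ("CRISPR_Cas6", 0.05),
]

#: family label -> (core tokens, accessory placement)
FAMILY_LAYOUTS: dict[str, tuple[tuple[str, ...], str]] = {
    "A.1": (("r1_2", "r2", "r3", "r4"), "none"),
    "A.5": (("r1_2", "r3", "r2", "r3", "r4"), "none"),
    "B.1": (("r1_2", "r2", "r4"), "none"),
    "C.1": (("r2", "r3", "r4"), "none"),
    "D.1": (("r2", "r3", "r4_2"), "none"),
    "E.1": (("r2", "r4"), "none"),
    "F.1": (("r2", "r4_2"), "none"),
    "F.2": (("r2", "r4_2"), "N"),
    "F.3": (("r2", "r4_2"), "C"),
    "F.4": (("r2", "r4_2"), "both"),
    "H.1": (("r2",), "none"),
    "H.3": (("r2",), "C"),
    "J.1": (("r4",), "none"),
    "K.1": (("r4_2",), "none"),
    "K.3": (("r4_2",), "C"),
    "L.1": (("ECF",), "none"),
}

_UF_MEANS = {
    "A.1": 2.5, "A.5": 0.3, "B.1": 0.8, "C.1": 0.6, "D.1": 0.3, "E.1": 1.5,
    "F.1": 2.0, "F.3": 0.3, "H.1": 1.0, "H.3": 0.2, "J.1": 0.5, "K.1": 0.5,
    "K.3": 0.2, "L.1": 0.6,
}
_H_MEANS = {
    "A.1": 3.5, "A.5": 1.0, "B.1": 0.5, "C.1": 1.5, "D.1": 0.4, "E.1": 0.5,
    "F.1": 2.0, "F.3": 0.5, "H.1": 0.6, "H.3": 0.2, "J.1": 1.2, "K.1": 1.3,
    "K.3": 0.6, "L.1": 0.0,
}

_DEFAULT_ORDERS = {
    "U": [("Synechococcales", 0.65), ("Chroococcales", 0.35)],
    "F": [("Oscillatoriales", 0.70), ("Pseudanabaenales", 0.30)],
    "H": [("Nostocales", 1.0)],
}

_CDS_BASE = {"U": (2800.0, 600.0), "F": (3200.0, 600.0), "H": (4800.0, 700.0)}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; the seed is mandatory.

    ``family_means`` gives, per morphotype, the expected homolog count per
    family (Poisson-distributed; families in ``guaranteed_families`` are
    planted as 1 + Poisson(mean - 1) so every genome carries at least one).
    Decoy rates are per-protein probabilities of an extra sub-threshold hit
    and of an extra overlapping (shorter, worse-E-value) hit.
    """

    seed: int
    n_genomes: dict[str, int] = field(
        default_factory=lambda: {"U": 90, "F": 44, "H": 66}
    )
    family_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "U": dict(_UF_MEANS),
            "F": dict(_UF_MEANS),
            "H": dict(_H_MEANS),
        }
    )
    guaranteed_families: tuple[str, ...] = ("A.1", "F.1")
    orders: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_ORDERS.items()}
    )
    cds_base: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_CDS_BASE)
    )
    cds_per_homolog: float = 120.0
    decoy_subthreshold_rate: float = 0.2
    decoy_overlap_rate: float = 0.15
    score_margin_scale: float = 15.0
    clade: str = "Cyanobacteria"

    def validate(self) -> None:
        for morph, means in self.family_means.items():
            for fam, mean in means.items():
                if fam not in FAMILY_LAYOUTS:
                    raise ValueError(f"family {fam!r} has no planted layout")
                if mean < 0:
                    raise ValueError(f"negative mean for {fam} in {morph}")
        for rate in (self.decoy_subthreshold_rate, self.decoy_overlap_rate):
            if rate < 0:
                raise ValueError("decoy rates must be >= 0")
        for fam in self.guaranteed_families:
            if fam not in FAMILY_LAYOUTS:
                raise ValueError(f"guaranteed family {fam!r} has no layout")


@dataclass
class SyntheticCohort:
    """Generated inputs plus the planted truth table."""

    fasta_text: str
    domtblout_text: str
    thresholds: ThresholdTable
    genomes: pd.DataFrame  # genome_id, order, morphotype, cds_count, clade
    truth: pd.DataFrame  # genome_id, protein_id, family, clan, family_index
    hits: list[DomainHit]  # true + decoy hits, as parsed from domtblout_text

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.faa",
            "domtblout": out / "hits.domtblout",
            "thresholds": out / "thresholds.tsv",
            "genomes": out / "genomes.tsv",
            "truth": out / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["domtblout"].write_text(self.domtblout_text)
        self.thresholds.to_tsv(paths["thresholds"])
        self.genomes.to_csv(paths["genomes"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def default_thresholds() -> ThresholdTable:
    profiles = list(TOKEN_TO_PROFILE.values()) + [p for p, _ in ACCESSORY_PROFILES]
    return ThresholdTable(cutoffs={p: (22.0, 22.0) for p in profiles})


def default_paper_like_spec(seed: int) -> CohortSpec:
    """The cohort conditions the generator emulates by default: 200 genomes
    at the phylum's U/F/H mix, ~12 homologs per genome on average with ~90%
    of genomes between 5 and 17, H genomes larger and enriched as described
    in the module docstring."""
    return CohortSpec(seed=seed)


def _weighted_choice(rng: np.random.Generator, items: list[tuple[str, float]]) -> str:
    names = [n for n, _ in items]
    w = np.array([x for _, x in items], dtype=float)
    return str(rng.choice(names, p=w / w.sum()))


def _domain_length(rng: np.random.Generator, token: str) -> int:
    mean, sd = DOMAIN_LENGTHS.get(token, DOMAIN_LENGTHS["_accessory"])
    return max(20, int(round(rng.normal(mean, sd))))


def _score_and_evalue(
    rng: np.random.Generator, cutoff: float, margin_scale: float
) -> tuple[float, float]:
    score = cutoff + 2.0 + float(rng.exponential(margin_scale))
    e_value = float(10.0 ** (-(0.30 * score) + rng.normal(0, 0.5)))
    return round(score, 1), max(e_value, 1e-290)


def _protein_tokens(
    rng: np.random.Generator, family: str
) -> list[str]:
    core, placement = FAMILY_LAYOUTS[family]
    tokens = list(core)
    if placement in ("N", "both"):
        tokens.insert(0, _weighted_choice(rng, ACCESSORY_PROFILES))
    if placement in ("C", "both"):
        tokens.append(_weighted_choice(rng, ACCESSORY_PROFILES))
    return tokens


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    thresholds = default_thresholds()

    fasta_chunks: list[str] = []
    dom_lines: list[str] = [
        "# target name        accession   tlen query name           accession   qlen"
        "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
        "  from    to  from    to  acc description of target"
    ]
    genome_rows = []
    truth_rows = []
    all_hits: list[DomainHit] = []

    gi = 0
    for morph in ("U", "F", "H"):
        for _ in range(spec.n_genomes.get(morph, 0)):
            gi += 1
            gid = f"G{gi:04d}"
            order = _weighted_choice(rng, spec.orders[morph])
            means = spec.family_means[morph]
            fam_counts: dict[str, int] = {}
            for fam in sorted(means):
                mean = means[fam]
                if fam in spec.guaranteed_families:
                    n = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
                elif mean > 0:
                    n = int(rng.poisson(mean))
                else:
                    n = 0
                if n:
                    fam_counts[fam] = n
            pj = 0
            total = 0
            for fam in sorted(fam_counts):
                for _copy in range(fam_counts[fam]):
                    pj += 1
                    total += 1
                    pid = f"{gid}_P{pj:03d}"
                    _emit_protein(
                        rng, spec, thresholds, gid, pid, fam,
                        fasta_chunks, dom_lines, truth_rows, all_hits,
                    )
            cds_mean, cds_sd = spec.cds_base[morph]
            cds = int(
                max(500, round(cds_mean + spec.cds_per_homolog * total + rng.normal(0, cds_sd)))
            )
            genome_rows.append(
                {
                    "genome_id": gid,
                    "order": order,
                    "morphotype": morph,
                    "cds_count": cds,
                    "clade": spec.clade,
                }
            )

    genomes = pd.DataFrame(
        genome_rows, columns=["genome_id", "order", "morphotype", "cds_count", "clade"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["genome_id", "protein_id", "family", "clan", "family_index"]
    )
    return SyntheticCohort(
        fasta_text="".join(fasta_chunks),
        domtblout_text="\n".join(dom_lines) + "\n",
        thresholds=thresholds,
        genomes=genomes,
        truth=truth,
        hits=all_hits,
    )


def _emit_protein(
    rng: np.random.Generator,
    spec: CohortSpec,
    thresholds: ThresholdTable,
    gid: str,
    pid: str,
    family: str,
    fasta_chunks: list[str],
    dom_lines: list[str],
    truth_rows: list[dict],
    all_hits: list[DomainHit],
) -> None:
    tokens = _protein_tokens(rng, family)
    # lay domains N->C with linkers
    spans: list[tuple[str, int, int]] = []
    pos = 1 + int(rng.integers(3, 25))
    for tok in tokens:
        length = _domain_length(rng, tok)
        spans.append((tok, pos, pos + length - 1))
        pos = pos + length + int(rng.integers(6, 30))
    protein_length = spans[-1][2] + int(rng.integers(3, 30))

    seq = "".join(rng.choice(AMINO_ACIDS, size=protein_length))
    fasta_chunks.append(f">{pid} genome={gid} family={family}\n")
    for k in range(0, protein_length, 60):
        fasta_chunks.append(seq[k : k + 60] + "\n")

    hits: list[DomainHit] = []
    for tok, start, end in spans:
        profile = TOKEN_TO_PROFILE.get(tok, tok)
        cutoff = thresholds.domain_cutoff(profile)
        score, ev = _score_and_evalue(rng, cutoff, spec.score_margin_scale)
        hits.append(
            DomainHit(pid, profile, start, end, score, ev, gid, protein_length)
        )
    true_hits = list(hits)
    # decoy: sub-threshold hit (1-5 bits below the cutoff), random location
    if rng.random() < spec.decoy_subthreshold_rate:
        profile = _weighted_choice(rng, ACCESSORY_PROFILES)
        cutoff = thresholds.domain_cutoff(profile)
        length = _domain_length(rng, "_accessory")
        start = int(rng.integers(1, max(2, protein_length - length)))
        score = round(cutoff - float(rng.uniform(1.0, 5.0)), 1)
        hits.append(
            DomainHit(pid, profile, start, min(start + length - 1, protein_length),
                      score, 0.01, gid, protein_length)
        )
    # decoy: above-threshold hit nested inside a true hit, strictly shorter
    # and with a worse E-value, so overlap resolution must discard it
    if rng.random() < spec.decoy_overlap_rate:
        tok, start, end = spans[int(rng.integers(0, len(spans)))]
        true_len = end - start + 1
        if true_len > 24:
            profile = _weighted_choice(rng, ACCESSORY_PROFILES)
            cutoff = thresholds.domain_cutoff(profile)
            d_len = int(rng.integers(15, true_len - 5))
            d_start = start + int(rng.integers(0, true_len - d_len))
            score = round(cutoff + float(rng.uniform(0.5, 4.0)), 1)
            matching = [h for h in true_hits if h.ali_start == start and h.ali_end == end]
            worse_ev = min(1.0, matching[0].e_value * 10 ** float(rng.uniform(2, 6)))
            hits.append(
                DomainHit(pid, profile, d_start, d_start + d_len - 1,
                          score, worse_ev, gid, protein_length)
            )
    n = len(hits)
    for k, h in enumerate(hits, start=1):
        dom_lines.append(_domtblout_line(h, k, n))
    all_hits.extend(hits)

    from .classification import FamilyId  # local import to avoid cycles at load

    clan, idx = family.split(".")
    truth_rows.append(
        {
            "genome_id": gid,
            "protein_id": pid,
            "family": FamilyId(clan, int(idx)).label,
            "clan": clan,
            "family_index": int(idx),
        }
    )


def _domtblout_line(h: DomainHit, k: int, n: int) -> str:
    qlen = h.length
    seq_score = h.bit_score  # single-domain proteins dominate; close enough
    fields = [
        h.protein_id, "-", str(h.protein_length or h.ali_end), h.profile, "-",
        str(qlen), f"{h.e_value:.2g}", f"{seq_score:.1f}", "0.1",
        str(k), str(n), f"{h.e_value:.2g}", f"{h.e_value:.2g}",
        f"{h.bit_score:.1f}", "0.1", "1", str(qlen),
        str(h.ali_start), str(h.ali_end), str(max(1, h.ali_start - 3)),
        str(h.ali_end + 3), "0.90", f"genome={h.genome_id}",
    ]
    return " ".join(fields)
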