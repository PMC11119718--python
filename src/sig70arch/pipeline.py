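"""End-to-end orchestration: hits -> architectures -> classification -> stats.

:func:`run_pipeline` wires the stages together, writes the standard TSV
artifacts plus a run manifest (package version, configuration hash, seed),
and returns the in-memory results for library callers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import (
    Architecture,
    DEFAULT_VOCABULARY,
    architectures_to_frame,
    build_architecture,
)
from .classification import ClanFamilyRegistry, assign_unit_names, classify_cohort
from .hits import (
    DEFAULT_SEED_PROFILES,
    ThresholdTable,
    filter_by_threshold,
    parse_domtblout,
    require_seed_domain,
    resolve_overlaps,
    write_hits_tsv,
)

logger = logging.getLogger("sig70arch")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "proteins_from_hits"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    domtblout: Path
    thresholds: Path
    out_dir: Path
    genomes: Path | None = None
    fasta: Path | None = None
    registry: Path | None = None
    seed_profiles: tuple[str, ...] = tuple(sorted(DEFAULT_SEED_PROFILES))
    threshold_comparator: str = ">="
    min_overlap_frac: float = 0.0
    auto_extend_clans: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    architectures: list[Architecture]
    classified: pd.DataFrame  # named units table
    counts: pd.DataFrame | None
    artifacts: dict[str, Path] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _read_fasta_lengths(path: Path) -> dict[str, int]:
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def proteins_from_hits(
    hits,
    thresholds: ThresholdTable,
    seed_profiles=DEFAULT_SEED_PROFILES,
    comparator: str = ">=",
    min_overlap_frac: float = 0.0,
    lengths: dict[str, int] | None = None,
    require_seed: bool = True,
) -> list[Architecture]:
    """Filter, resolve and assemble architectures for every qualifying protein.

    Proteins whose surviving hits contain no seed-set profile are dropped
    when ``require_seed`` is true (the homolog requisite); pass
    ``require_seed=False`` to keep every protein with any surviving hit
    (survey mode over all domain-carrying proteins).
    """
    kept = filter_by_threshold(hits, thresholds, comparator=comparator)
    by_protein: dict[str, list] = {}
    for h in kept:
        by_protein.setdefault(h.protein_id, []).append(h)
    architectures = []
    for pid in sorted(by_protein):
        resolved = resolve_overlaps(by_protein[pid], min_overlap_frac=min_overlap_frac)
        if require_seed and not require_seed_domain(resolved, seed_profiles):
            continue
        if not resolved:
            continue
        length = lengths.get(pid) if lengths else None
        architectures.append(build_architecture(resolved, protein_length=length))
    return architectures


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute ingest -> architecture -> classify -> name -> counts.

    Writes ``hits_resolved.tsv``, ``architectures.tsv``,
    ``classification.tsv``, ``counts.tsv`` (when genome metadata is given)
    and ``manifest.json`` into ``config.out_dir``.  Any stage failure is
    re-raised with a stage tag.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    warnings: list[str] = []

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("ingest")
    try:
        hits = parse_domtblout(Path(config.domtblout))
        thresholds = ThresholdTable.from_tsv(Path(config.thresholds))
        lengths = _read_fasta_lengths(Path(config.fasta)) if config.fasta else None
        architectures = proteins_from_hits(
            hits,
            thresholds,
            seed_profiles=frozenset(config.seed_profiles),
            comparator=config.threshold_comparator,
            min_overlap_frac=config.min_overlap_frac,
            lengths=lengths,
        )
        resolved_all = [h for a in architectures for h in _arch_hits(a)]
        current = stage("write-hits")
        artifacts["hits_resolved"] = out / "hits_resolved.tsv"
        pd.DataFrame(resolved_all).to_csv(artifacts["hits_resolved"], sep="\t", index=False)

        current = stage("architecture")
        arch_df = architectures_to_frame(architectures)
        artifacts["architectures"] = out / "architectures.tsv"
        arch_df.to_csv(artifacts["architectures"], sep="\t", index=False)

        current = stage("classify")
        registry = ClanFamilyRegistry.default(config.registry)
        classified = classify_cohort(
            architectures, registry, auto_extend=config.auto_extend_clans
        )
        named = assign_unit_names(classified)
        artifacts["classification"] = out / "classification.tsv"
        named.to_csv(artifacts["classification"], sep="\t", index=False)

        counts = None
        if config.genomes is not None:
            current = stage("distribute")
            genomes = pd.read_csv(Path(config.genomes), sep="\t")
            from .cohort import build_count_matrix

            matrix = build_count_matrix(named, genomes)
            counts = matrix.counts
            artifacts["counts"] = out / "counts.tsv"
            counts.to_csv(artifacts["counts"], sep="\t")

        current = stage("manifest")
        manifest = {
            "package": "sig70arch",
            "version": __version__,
            "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_proteins": len(architectures),
            "n_genomes": int(named["genome_id"].nunique()) if not named.empty else 0,
            "warnings": warnings,
        }
        artifacts["manifest"] = out / "manifest.json"
        artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    return PipelineResult(
        architectures=architectures,
        classified=named,
        counts=counts,
        artifacts=artifacts,
        warnings=warnings,
    )


def _arch_hits(arch: Architecture) -> list[dict]:
    return [
        {
            "genome_id": arch.genome_id,
            "protein_id": arch.protein_id,
            "token": t.token,
            "ali_start": t.ali_start,
            "ali_end": t.ali_end,
        }
        for t in arch.tokens
    ]
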