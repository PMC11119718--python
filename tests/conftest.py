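import numpy as np
import pytest

from sig70arch.architecture import Architecture, DomainToken
from sig70arch.hits import DomainHit


@pytest.fixture
def make_architecture():
    """Factory: architecture from a token list, with plausible coordinates."""

    def _make(tokens, protein_id="P1", genome_id="G1", start=10, length=50, gap=15,
              tail=25):
        toks = []
        pos = start
        for t in tokens:
            toks.append(DomainToken(t, pos, pos + length - 1))
            pos += length + gap
        return Architecture(
            protein_id=protein_id,
            tokens=tuple(toks),
            protein_length=pos - gap - 1 + tail,
            genome_id=genome_id,
        )

    return _make


@pytest.fixture
def make_hit():
    """Factory for DomainHit records with defaults."""

    def _make(profile="Sigma70_r2", start=10, end=80, score=40.0, e_value=1e-10,
              protein_id="P1", genome_id="G1", protein_length=None):
        return DomainHit(
            protein_id=protein_id,
            profile=profile,
            ali_start=start,
            ali_end=end,
            bit_score=score,
            e_value=e_value,
            genome_id=genome_id,
            protein_length=protein_length,
        )

    return _make


def random_hit_instance(rng: np.random.Generator, n_hits: int, protein_id="P1"):
    """Random overlapping hit sets for oracle comparisons."""
    profiles = ["Sigma70_r2", "Sigma70_r3", "Sigma70_r4", "DUF6596", "WD40", "NB-ARC"]
    hits = []
    for _ in range(n_hits):
        start = int(rng.integers(1, 300))
        length = int(rng.integers(10, 120))
        hits.append(
            DomainHit(
                protein_id=protein_id,
                profile=str(rng.choice(profiles)),
                ali_start=start,
                ali_end=start + length - 1,
                bit_score=float(np.round(rng.uniform(20, 80), 1)),
                e_value=float(10.0 ** rng.uniform(-40, -2)),
                genome_id="G1",
            )
        )
    return hits
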