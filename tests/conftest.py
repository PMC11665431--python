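"""Shared fixtures: independent oracles, synthetic tables, random sequences."""

import itertools
import random

import pytest

from codongc.seqio import CodingSequence
from codongc.usage import CodonUsageTable, UsageEntry

# standard genetic code, written out independently of the package's
# Biopython-backed translation so codon-family logic can be cross-checked
GENETIC_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AAS[_i]

FAMILIES = {}
for _codon, _aa in GENETIC_CODE.items():
    FAMILIES.setdefault(_aa, []).append(_codon)


def oracle_windowed_gc(bases: str, site: int) -> float:
    """Brute-force 21-base counter with explicit edge referencing."""
    L = len(bases) // 3
    c = min(max(site, 4), L - 3)
    window = bases[3 * (c - 4): 3 * (c + 3)]
    assert len(window) == 21
    return 100.0 * (window.count("G") + window.count("C")) / 21.0


def oracle_translate(bases: str) -> str:
    return "".join(GENETIC_CODE[bases[i: i + 3]] for i in range(0, len(bases), 3))


def random_cds(rng: random.Random, codons: int, name: str = "rnd") -> CodingSequence:
    return CodingSequence(
        name, "".join(rng.choice("ACGT") for _ in range(3 * codons))
    )


def make_uniform_table() -> CodonUsageTable:
    """Synthetic table: each amino acid's codons at fraction 1/k, uniform
    per-thousand (1000/64 each)."""
    entries = {}
    for codon, aa in GENETIC_CODE.items():
        k = len(FAMILIES[aa])
        entries[codon] = UsageEntry(codon, aa, 1.0 / k, 1000.0 / 64)
    return CodonUsageTable("uniform_synthetic", entries)


def uniform_table_text() -> str:
    lines = ["# organism: uniform_synthetic"]
    for codon in sorted(GENETIC_CODE):
        aa = GENETIC_CODE[codon]
        k = len(FAMILIES[aa])
        lines.append(f"{codon} {aa} {1.0 / k:.4f} {1000.0 / 64:.4f}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def uniform_table() -> CodonUsageTable:
    return make_uniform_table()


@pytest.fixture
def poly_ala20() -> CodingSequence:
    return CodingSequence("poly_ala", "GCA" * 20)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260927)
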