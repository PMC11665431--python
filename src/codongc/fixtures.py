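"""Seeded synthetic coding sequences with controllable local-GC structure.

Test and demonstration tooling: the generator *chooses the protein* to suit
a requested GC shape (GC-rich codon families such as Ala/Gly/Pro/Arg for
high regions, GC-poor families such as Lys/Ile/Asn/Phe for low regions) and
can plant literal motifs — restriction sites, repeats, hairpin arms — at
requested base positions. Sequences it emits are valid coding sequences but
are in no sense designed genes; do not mistake fixtures for design output.
Equal specs and seeds give byte-identical sequences.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .seqio import CodingSequence

# codon pools by GC count of the codon (0, 1, 2 or 3 of 3 bases)
POOL_GC0 = ["AAA", "ATT", "TTT", "AAT", "ATA", "TAT"]  # Lys/Ile/Phe/Asn/Ile/Tyr
POOL_GC1 = ["GAT", "ACA", "GTT", "TGT", "CAA", "TTG"]  # Asp/Thr/Val/Cys/Gln/Leu
POOL_GC2 = ["GAC", "GCT", "TGC", "AGC", "CCT", "GGA"]  # Asp/Ala/Cys/Ser/Pro/Gly
POOL_GC3 = ["GCG", "GGC", "CCG", "CGG", "GCC", "GGG"]  # Ala/Gly/Pro/Arg/Ala/Gly

LEVEL_POOLS = {"low": POOL_GC0, "mid": POOL_GC1 + POOL_GC2, "high": POOL_GC3}


class FixtureError(ValueError):
    """Raised on infeasible fixture specifications."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic CDS.

    shape: list of ((first_site, last_site), level) with level one of
    'low' | 'mid' | 'high'; unshaped sites default to 'mid'.
    planted_patterns: list of (kind_label, payload_bases, 1-based base
    position); payloads overwrite the generated bases verbatim.
    """

    protein_length: int
    shape: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    planted_patterns: list[tuple[str, str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < 7:
            raise FixtureError("protein_length must be >= 7")
        claimed: list[tuple[int, int]] = []
        for (a, b), level in self.shape:
            if level not in LEVEL_POOLS:
                raise FixtureError(f"unknown GC level {level!r}")
            if not (1 <= a <= b <= self.protein_length):
                raise FixtureError(f"shape range {a}..{b} out of bounds")
            if any(a <= y and x <= b for x, y in claimed):
                raise FixtureError(f"overlapping shape range {a}..{b}")
            claimed.append((a, b))
        spans: list[tuple[int, int]] = []
        for kind, payload, pos in self.planted_patterns:
            if any(ch not in "ACGT" for ch in payload.upper()):
                raise FixtureError(f"planted payload {payload!r} is not plain DNA")
            end = pos + len(payload) - 1
            if not (1 <= pos and end <= 3 * self.protein_length):
                raise FixtureError(f"planted pattern {kind!r} at {pos} out of bounds")
            if any(pos <= y and x <= end for x, y in spans):
                raise FixtureError(f"planted pattern {kind!r} collides with another")
            spans.append((pos, end))


def generate(spec: FixtureSpec) -> CodingSequence:
    """Deterministically realize a :class:`FixtureSpec`."""
    rng = random.Random(spec.seed)
    levels = ["mid"] * spec.protein_length
    for (a, b), level in spec.shape:
        for s in range(a, b + 1):
            levels[s - 1] = level
    codons = [rng.choice(LEVEL_POOLS[lvl]) for lvl in levels]
    bases = list("".join(codons))
    for _, payload, pos in spec.planted_patterns:
        bases[pos - 1: pos - 1 + len(payload)] = payload.upper()
    name = f"fixture_L{spec.protein_length}_seed{spec.seed}"
    return CodingSequence(name, "".join(bases))


def generate_profile_like(values: list[float], seed: int = 0) -> CodingSequence:
    """A CDS whose windowed-GC profile tracks a per-site target curve.

    Greedy with error diffusion: each codon's GC count (0-3) follows the
    local target while a running error term corrects quantization drift.
    For smooth targets within [20, 80] the achieved interior profile stays
    within about +/-15 percentage points of the target; extreme targets
    saturate at the all-AT / all-GC codon pools.
    """
    L = len(values)
    if L < 7:
        raise FixtureError("need at least 7 target values")
    if any(not 0 <= v <= 100 for v in values):
        raise FixtureError("target values must lie in [0, 100]")
    rng = random.Random(seed)
    pools = {0: POOL_GC0, 1: POOL_GC1, 2: POOL_GC2, 3: POOL_GC3}
    codons: list[str] = []
    carry = 0.0
    for v in values:
        want = 3.0 * v / 100.0 + carry
        count = min(3, max(0, round(want)))
        carry = want - count
        codons.append(rng.choice(pools[count]))
    return CodingSequence(f"profile_like_seed{seed}", "".join(codons))
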