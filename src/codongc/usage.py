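"""Codon-usage frequency tables.

A table maps each of the 64 codons to its amino acid, its *fraction* (the
share of that codon within its synonymous family, summing to 1 per family)
and its *per-thousand* frequency (occurrences per 1000 codons genome-wide).
Fractions drive the choice of replacement codons during editing: a frequent
codon of the host organism is preferred so expression is not compromised.

File dialect: one whitespace-separated entry per line,
``CODON AA FRACTION PER_THOUSAND``; '#' starts a comment; an optional
``# organism: <name>`` header names the organism. RNA codons (U) and
lowercase are accepted. This mirrors the layout of the public codon-usage
compilations (Kazusa-style) that such tables are transcribed from.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import translate_codon

FRACTION_TOL = 0.02  # published tables round fractions to 2 decimals
PER_THOUSAND_TOL = 10.0

ALL_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)  # 64, lexicographic


class UsageTableError(ValueError):
    """Raised when a codon-usage table file violates the contract."""


@dataclass(frozen=True)
class UsageEntry:
    codon: str
    amino_acid: str
    fraction: float
    per_thousand: float


@dataclass(frozen=True)
class CodonUsageTable:
    """Organism-labelled map codon -> (amino acid, fraction, per-thousand)."""

    organism: str
    entries: dict[str, UsageEntry]

    def __post_init__(self) -> None:
        _validate_entries(self.entries)

    def __getitem__(self, codon: str) -> UsageEntry:
        return self.entries[_normalize_codon(codon)]

    def fraction(self, codon: str) -> float:
        return self[codon].fraction

    def family(self, amino_acid: str) -> list[UsageEntry]:
        """All entries for one amino acid (or '*')."""
        return [e for e in self.entries.values() if e.amino_acid == amino_acid]


def _normalize_codon(codon: str) -> str:
    c = codon.strip().upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise UsageTableError(f"invalid codon string {codon!r}")
    return c


def _validate_entries(entries: dict[str, UsageEntry]) -> None:
    missing = [c for c in ALL_CODONS if c not in entries]
    if missing:
        raise UsageTableError(
            f"incomplete table ({len(entries)}/64): missing {', '.join(missing)}"
        )
    for codon, e in entries.items():
        expected = translate_codon(codon)
        if e.amino_acid != expected:
            raise UsageTableError(
                f"codon {codon} listed as {e.amino_acid!r} but encodes "
                f"{expected!r} under the standard genetic code"
            )
        if not 0.0 <= e.fraction <= 1.0:
            raise UsageTableError(f"fraction for {codon} outside [0,1]: {e.fraction}")
        if e.per_thousand < 0:
            raise UsageTableError(f"negative per-thousand for {codon}")
    by_aa: dict[str, float] = {}
    for e in entries.values():
        by_aa[e.amino_acid] = by_aa.get(e.amino_acid, 0.0) + e.fraction
    for aa, total in sorted(by_aa.items()):
        if abs(total - 1.0) > FRACTION_TOL + 1e-9:
            raise UsageTableError(
                f"fractions for amino acid {aa!r} sum to {total:.3f}, "
                f"expected 1 ± {FRACTION_TOL}"
            )
    grand = sum(e.per_thousand for e in entries.values())
    if abs(grand - 1000.0) > PER_THOUSAND_TOL:
        raise UsageTableError(
            f"per-thousand values total {grand:.1f}, expected 1000 ± "
            f"{PER_THOUSAND_TOL:g}"
        )


def parse_usage_table(path: str | Path) -> CodonUsageTable:
    """Parse and validate a codon-usage table file."""
    path = Path(path)
    organism = path.stem
    entries: dict[str, UsageEntry] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("organism:"):
                organism = body.split(":", 1)[1].strip()
            continue
        fields = stripped.split()
        if len(fields) != 4:
            raise UsageTableError(
                f"{path}:{lineno}: malformed line (expected 4 fields, "
                f"got {len(fields)}): {stripped!r}"
            )
        codon_raw, aa, frac_s, pt_s = fields
        codon = _normalize_codon(codon_raw)
        if codon in entries:
            raise UsageTableError(f"{path}:{lineno}: duplicate codon {codon}")
        try:
            fraction, per_thousand = float(frac_s), float(pt_s)
        except ValueError as exc:
            raise UsageTableError(
                f"{path}:{lineno}: non-numeric field in {stripped!r}"
            ) from exc
        entries[codon] = UsageEntry(codon, aa.upper(), fraction, per_thousand)
    return CodonUsageTable(organism, entries)


def serialize_usage_table(table: CodonUsageTable, path: str | Path) -> None:
    """Write the canonical dialect: fractions to 2 decimals, per-thousand to 1."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# organism: {table.organism}\n")
        fh.write("# codon  aa  fraction  per_thousand\n")
        for codon in ALL_CODONS:
            e = table.entries[codon]
            fh.write(f"{codon} {e.amino_acid} {e.fraction:.2f} {e.per_thousand:.1f}\n")


def synonymous_alternatives(
    table: CodonUsageTable, codon: str
) -> list[UsageEntry]:
    """All codons of the query's synonymous family, the query included.

    Sorted by fraction descending; ties broken by lexicographic codon order
    so output is deterministic.
    """
    entry = table[codon]
    fam = table.family(entry.amino_acid)
    return sorted(fam, key=lambda e: (-e.fraction, e.codon))


def available_tables() -> list[str]:
    """Keys of the organism tables bundled with the package."""
    root = resources.files("codongc") / "data" / "usage"
    return sorted(p.name[:-4] for p in root.iterdir() if p.name.endswith(".txt"))


def builtin_table(name: str = "e_coli") -> CodonUsageTable:
    """Load a bundled organism table; *Escherichia coli* is the default host."""
    root = resources.files("codongc") / "data" / "usage"
    target = root / f"{name}.txt"
    if not target.is_file():
        raise UsageTableError(
            f"unknown organism {name!r}; available: {', '.join(available_tables())}"
        )
    with resources.as_file(target) as p:
        table = parse_usage_table(p)
    return table
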