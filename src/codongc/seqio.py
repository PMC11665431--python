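"""Reading, validating, writing and transforming coding sequences.

A coding sequence (CDS) here is the sense strand of a protein-coding gene,
read in frame: its length is a multiple of 3 and every triplet is one codon.
All user-facing coordinates are 1-based codon sites; slicing internally is
0-based half-open, the usual Python convention.

FASTA parsing/writing and translation delegate to Biopython; validation is
deliberately strict (ACGT only after normalization) because the windowed GC
statistic is undefined over ambiguity codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

#: Minimum codon count: one full 7-codon window must fit.
MIN_CODONS = 7

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised when an input sequence violates the CDS contract."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated DNA coding sequence with codon-indexed access.

    Attributes
    ----------
    identifier:
        Free-text name (FASTA header without the leading ``>``).
    bases:
        Uppercase DNA over {A, C, G, T}; length is ``3 * codon_count``.
    """

    identifier: str
    bases: str

    def __post_init__(self) -> None:
        bad = next((i for i, b in enumerate(self.bases) if b not in "ACGT"), None)
        if bad is not None:
            raise SequenceError(
                f"invalid character {self.bases[bad]!r} at position {bad + 1}"
            )
        if len(self.bases) % 3 != 0:
            raise SequenceError(
                f"not a codon-complete CDS: length {len(self.bases)} "
                "is not divisible by 3"
            )
        if len(self.bases) < 3 * MIN_CODONS:
            raise SequenceError(
                f"sequence too short: {len(self.bases) // 3} codons, "
                f"need at least {MIN_CODONS} for one full window"
            )

    @property
    def codon_count(self) -> int:
        """Number of codons L."""
        return len(self.bases) // 3

    def codon(self, site: int) -> str:
        """Codon at 1-based site ``site`` (1..L)."""
        if not 1 <= site <= self.codon_count:
            raise SequenceError(
                f"codon site {site} out of range 1..{self.codon_count}"
            )
        return self.bases[3 * (site - 1): 3 * site]

    def codons(self) -> list[str]:
        """All codons in order."""
        return [self.bases[i: i + 3] for i in range(0, len(self.bases), 3)]

    def with_codon(self, site: int, new_codon: str) -> "CodingSequence":
        """Copy of this sequence with ``site`` replaced by ``new_codon``."""
        self.codon(site)  # range check
        i = 3 * (site - 1)
        return CodingSequence(self.identifier, self.bases[:i] + new_codon + self.bases[i + 3:])


@dataclass(frozen=True)
class ProteinSequence:
    """Translated product; one-letter codes, '*' for stop."""

    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def _normalize(raw: str) -> str:
    return "".join(raw.split()).upper().replace("U", "T")


def read_coding_sequence(path: str | Path) -> CodingSequence:
    """Read a single-record FASTA or headerless sequence text file.

    Lowercase and RNA (U) input are accepted and normalized; whitespace is
    stripped. Rejects multi-record FASTA, non-triplet lengths, ambiguity
    codes, and sequences shorter than 7 codons.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(path, "fasta"))
        if len(records) > 1:
            raise SequenceError(
                f"multiple records ({len(records)}) in {path}; expected exactly one"
            )
        if not records:
            raise SequenceError(f"no sequence record found in {path}")
        identifier = records[0].description
        raw = str(records[0].seq)
    else:
        identifier = path.stem
        raw = text
    bases = _normalize(raw)
    if not bases:
        raise SequenceError(f"no sequence data in {path}")
    # Pre-check characters on the normalized string so the error position is
    # meaningful before the triplet-length check fires.
    for i, b in enumerate(bases):
        if b not in "ACGT":
            raise SequenceError(f"invalid character {b!r} at position {i + 1}")
    return CodingSequence(identifier, bases)


def write_fasta(seq: CodingSequence, path: str | Path, *, width: int = 60) -> None:
    """Write a single-record FASTA, 60 bases per line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{seq.identifier}\n")
        for i in range(0, len(seq.bases), width):
            fh.write(seq.bases[i: i + width] + "\n")


def translate(seq: CodingSequence) -> ProteinSequence:
    """Translate under the standard genetic code (table 1); stops as '*'.

    Internal stop codons are allowed (a warning is logged) so partially
    edited or deliberately unusual fixtures can still be profiled.
    """
    residues = str(Seq(seq.bases).translate(table=1))
    internal = residues[:-1].find("*")
    if internal != -1:
        log.warning(
            "internal stop codon at codon site %d of %s", internal + 1, seq.identifier
        )
    return ProteinSequence(residues)


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or '*') for a single codon, table 1."""
    if len(codon) != 3 or any(b not in "ACGT" for b in codon.upper()):
        raise SequenceError(f"invalid codon {codon!r}")
    return str(Seq(codon.upper()).translate(table=1))


def reverse_complement(bases: str) -> str:
    """Reverse complement of a plain A/C/G/T string."""
    up = bases.upper()
    if any(b not in "ACGT" for b in up):
        bad = next(b for b in up if b not in "ACGT")
        raise SequenceError(f"invalid character {bad!r} in sequence")
    return up.translate(_COMPLEMENT)[::-1]
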