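"""Synonymous codon editing with a chronological change log.

An :class:`EditSession` holds the original sequence, the current edited
state and an ordered log of substitutions. Every substitution must be
synonymous (same amino acid under the standard code, stop codons forming
their own family), so the encoded protein is invariant by construction;
each log record snapshots the windowed GC at the edited site before and
after the change, matching the per-change plot updates of interactive use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .gcprofile import windowed_gc
from .seqio import CodingSequence, SequenceError, translate_codon, write_fasta

log = logging.getLogger(__name__)


class EditError(ValueError):
    """Raised on invalid substitutions or session operations."""


@dataclass(frozen=True)
class ChangeRecord:
    site: int
    amino_acid: str
    old_codon: str
    new_codon: str
    gc_before: float
    gc_after: float


@dataclass
class EditSession:
    """Original sequence, current state, and the ordered change log."""

    original: CodingSequence
    current: CodingSequence = None  # type: ignore[assignment]
    changes: list[ChangeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.current is None:
            self.current = self.original


def new_session(seq: CodingSequence) -> EditSession:
    return EditSession(original=seq)


def apply_substitution(session: EditSession, site: int, new_codon: str) -> EditSession:
    """Substitute the codon at ``site`` (1-based) with a synonymous codon.

    Appends a :class:`ChangeRecord`; substituting a codon with itself is a
    logged no-op. A later substitution at the same site appends a second
    record — the log is chronological, never coalesced.
    """
    new_codon = new_codon.strip().upper().replace("U", "T")
    try:
        new_aa = translate_codon(new_codon)
    except SequenceError as exc:
        raise EditError(str(exc)) from exc
    old_codon = session.current.codon(site)  # raises on bad site
    old_aa = translate_codon(old_codon)
    if new_aa != old_aa:
        raise EditError(
            f"non-synonymous substitution at site {site}: "
            f"{old_codon} ({old_aa}) -> {new_codon} ({new_aa})"
        )
    if new_codon == old_codon:
        log.warning("site %d: substituting %s with itself; no change", site, old_codon)
        return session
    gc_before = windowed_gc(session.current, site)
    session.current = session.current.with_codon(site, new_codon)
    gc_after = windowed_gc(session.current, site)
    session.changes.append(
        ChangeRecord(site, old_aa, old_codon, new_codon, gc_before, gc_after)
    )
    return session


def undo_last(session: EditSession) -> EditSession:
    """Revert the most recent substitution."""
    if not session.changes:
        raise EditError("nothing to undo: change log is empty")
    last = session.changes.pop()
    session.current = session.current.with_codon(last.site, last.old_codon)
    return session


def replay(original: CodingSequence, changes: list[ChangeRecord]) -> CodingSequence:
    """Apply a change log to the original sequence; reproduces `current`."""
    seq = original
    for ch in changes:
        seq = seq.with_codon(ch.site, ch.new_codon)
    return seq


def export_changes(session: EditSession, path: str | Path) -> None:
    """Changed-codons TSV: site, amino acid, old/new codon, GC before/after."""
    with Path(path).open("w") as fh:
        fh.write("site\taa\told_codon\tnew_codon\tgc_before\tgc_after\n")
        for ch in session.changes:
            fh.write(
                f"{ch.site}\t{ch.amino_acid}\t{ch.old_codon}\t{ch.new_codon}\t"
                f"{ch.gc_before:.2f}\t{ch.gc_after:.2f}\n"
            )


def save_optimized(session: EditSession, path: str | Path) -> None:
    """Write the current sequence as FASTA, identifier suffixed '_optimized'."""
    out = CodingSequence(
        session.current.identifier.rstrip() + "_optimized", session.current.bases
    )
    write_fasta(out, path)
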