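"""Post-edit sanity scans: restriction sites, repeats, palindromes, hairpins.

Sequences destined for gene synthesis or subcloning should be screened for
unwanted restriction sites, tandem repeats, reverse-complement palindromes
and inverted repeats (hairpin-formers). The detectors here are deliberately
exact-match and self-contained: no mismatch tolerance, pure functions of
(sequence, parameters), with 1-based inclusive base coordinates throughout.
That trades some sensitivity against dedicated scanners for fully testable,
deterministic behaviour.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import CodingSequence, reverse_complement

#: IUPAC nucleotide ambiguity codes -> the base set each denotes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class CheckError(ValueError):
    """Raised on invalid scan parameters or patterns."""


@dataclass(frozen=True)
class PatternHit:
    """One restriction-site match, 1-based inclusive base coordinates.

    ``matched`` is the recognition string as read on the hit strand: for
    minus-strand hits it is the reverse complement of the plus-strand slice.
    """

    name: str
    start: int
    end: int
    matched: str
    strand: str  # "plus" | "minus"


@dataclass(frozen=True)
class RepeatHit:
    """One repeat feature. For tandem repeats ``unit_or_arm`` is the repeat
    unit and ``copies_or_loop`` the copy number; for inverted repeats it is
    the left arm and the loop length; for palindromes the full span and 0."""

    kind: str  # "tandem" | "inverted" | "palindrome"
    start: int
    end: int
    unit_or_arm: str
    copies_or_loop: int


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a character-class regex."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise CheckError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def reverse_complement_iupac(pattern: str) -> str:
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise CheckError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def _find_all(regex: str, text: str):
    """Overlapping match starts (0-based)."""
    return [m.start() for m in re.finditer(f"(?=({regex}))", text)]


def scan_restriction_sites(
    seq: CodingSequence, enzymes: list[tuple[str, str]]
) -> list[PatternHit]:
    """Exact IUPAC-pattern matches on both strands, in plus coordinates.

    A site that matches at the same span on both strands (a palindromic
    recognition site) is reported once, on the plus strand.
    """
    hits: list[PatternHit] = []
    for name, pattern in enzymes:
        plus_re = iupac_regex(pattern)
        minus_re = iupac_regex(reverse_complement_iupac(pattern))
        n = len(pattern)
        plus_spans = set()
        for s in _find_all(plus_re, seq.bases):
            plus_spans.add(s)
            hits.append(
                PatternHit(name, s + 1, s + n, seq.bases[s: s + n], "plus")
            )
        for s in _find_all(minus_re, seq.bases):
            if s in plus_spans:
                continue  # palindromic site: collapse to the plus-strand hit
            hits.append(
                PatternHit(
                    name, s + 1, s + n,
                    reverse_complement(seq.bases[s: s + n]), "minus",
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.name, h.strand))
    return hits


def find_palindromes(seq: CodingSequence, min_len: int = 8) -> list[RepeatHit]:
    """Maximal reverse-complement palindromic spans of length >= min_len.

    Spans nested inside a longer reported span are suppressed. Biological
    palindromes have even length, so min_len must be even.
    """
    if min_len % 2 != 0 or min_len < 4:
        raise CheckError("min_len must be an even integer >= 4")
    bases = seq.bases
    n = len(bases)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    spans: list[tuple[int, int]] = []  # 0-based [start, end) of maximal spans
    for center in range(1, n):  # center between center-1 and center
        l, r = center - 1, center
        while l >= 0 and r < n and bases[l] == comp[bases[r]]:
            l -= 1
            r += 1
        length = r - (l + 1)
        if length >= min_len:
            spans.append((l + 1, r))
    # suppress spans contained in another reported span
    keep = [
        (s, e) for s, e in spans
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in spans)
    ]
    keep.sort()
    return [
        RepeatHit("palindrome", s + 1, e, bases[s:e], 0) for s, e in keep
    ]


def _primitive(unit: str) -> bool:
    """True if the unit is not itself a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_tandem_repeats(
    seq: CodingSequence, min_unit: int = 3, min_copies: int = 3
) -> list[RepeatHit]:
    """Maximal runs unit^k with primitive unit, |unit| >= min_unit, k >= min_copies.

    Each run is reported once at its leftmost phase with its smallest
    primitive unit; the span covers whole copies only.
    """
    if min_unit < 2 or min_copies < 2:
        raise CheckError("min_unit and min_copies must each be >= 2")
    bases = seq.bases
    n = len(bases)
    found: dict[tuple[int, int], tuple[int, str, int]] = {}  # span -> (u, unit, k)
    for u in range(min_unit, n // min_copies + 1):
        i = 0
        while i + u * min_copies <= n:
            unit = bases[i: i + u]
            if not _primitive(unit):
                i += 1
                continue
            k = 1
            while bases[i + u * k: i + u * (k + 1)] == unit:
                k += 1
            if k >= min_copies:
                # leftmost phase only: skip if the same run extends left
                if i >= u and bases[i - u: i] == unit:
                    i += 1
                    continue
                span = (i, i + u * k)
                if span not in found or u < found[span][0]:
                    found[span] = (u, unit, k)
                i += u * k  # jump past the run for this unit length
            else:
                i += 1
    hits = [
        RepeatHit("tandem", s + 1, e, unit, k)
        for (s, e), (u, unit, k) in found.items()
    ]
    # drop runs fully contained in a longer reported run
    hits = [
        h for h in hits
        if not any(
            (o.start <= h.start and h.end <= o.end) and o is not h for o in hits
        )
    ]
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def find_inverted_repeats(
    seq: CodingSequence, min_arm: int = 8, max_loop: int = 60
) -> list[RepeatHit]:
    """Exact inverted repeats: an arm whose reverse complement recurs
    downstream after a loop of at most ``max_loop`` bases.

    Arms are maximal for each (center, loop) pair; hits whose span is nested
    inside another hit's span are suppressed. A zero-loop inverted repeat is
    a palindrome and is reported here too.
    """
    if min_arm < 6 or max_loop < 0:
        raise CheckError("min_arm must be >= 6 and max_loop >= 0")
    bases = seq.bases
    n = len(bases)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    raw: list[tuple[int, int, int, int]] = []  # (start0, end0, arm_len, loop)
    for p in range(1, n):  # p = first base after the left arm
        for g in range(0, max_loop + 1):
            l, r = p - 1, p + g
            if r >= n:
                break
            arm = 0
            while l >= 0 and r < n and bases[l] == comp[bases[r]]:
                arm += 1
                l -= 1
                r += 1
            if arm >= min_arm:
                raw.append((l + 1, r, arm, g))
    # one hit per span: prefer the longest arm, then the shortest loop
    best: dict[tuple[int, int], tuple[int, int]] = {}
    for s, e, arm, g in raw:
        cur = best.get((s, e))
        if cur is None or (arm, -g) > (cur[0], -cur[1]):
            best[(s, e)] = (arm, g)
    keep = sorted(
        span for span in best
        if not any(
            o[0] <= span[0] and span[1] <= o[1] and o != span for o in best
        )
    )
    return [
        RepeatHit("inverted", s + 1, e, bases[s: s + best[(s, e)][0]], best[(s, e)][1])
        for s, e in keep
    ]


def load_enzymes(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Enzyme pattern file: lines ``NAME IUPAC_PATTERN``, '#' comments.

    With no path, the bundled list of common cloning enzymes is returned.
    """
    if path is None:
        ref = resources.files("codongc") / "data" / "enzymes.txt"
        text = ref.read_text()
        source = "<bundled>"
    else:
        text = Path(path).read_text()
        source = str(path)
    enzymes: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 2:
            raise CheckError(
                f"{source}:{lineno}: expected 'NAME PATTERN', got {stripped!r}"
            )
        name, pattern = fields
        iupac_regex(pattern)  # validates characters
        enzymes.append((name, pattern.upper()))
    return enzymes


def run_all_checks(
    seq: CodingSequence,
    enzymes: list[tuple[str, str]] | None = None,
    *,
    palindrome_min_len: int = 8,
    tandem_min_unit: int = 3,
    tandem_min_copies: int = 3,
    inverted_min_arm: int = 8,
    inverted_max_loop: int = 60,
) -> list[PatternHit | RepeatHit]:
    """All scans with their defaults; restriction hits first, then repeats."""
    if enzymes is None:
        enzymes = load_enzymes()
    out: list[PatternHit | RepeatHit] = []
    out.extend(scan_restriction_sites(seq, enzymes))
    out.extend(find_tandem_repeats(seq, tandem_min_unit, tandem_min_copies))
    out.extend(find_palindromes(seq, palindrome_min_len))
    out.extend(find_inverted_repeats(seq, inverted_min_arm, inverted_max_loop))
    return out


def export_check_report(
    hits: list[PatternHit | RepeatHit], path: str | Path
) -> None:
    """Combined TSV: ``kind name start end detail``."""
    with Path(path).open("w") as fh:
        fh.write("kind\tname\tstart\tend\tdetail\n")
        for h in hits:
            if isinstance(h, PatternHit):
                fh.write(
                    f"restriction\t{h.name}\t{h.start}\t{h.end}\t"
                    f"{h.matched}/{h.strand}\n"
                )
            else:
                detail = (
                    f"{h.unit_or_arm}x{h.copies_or_loop}"
                    if h.kind == "tandem"
                    else f"{h.unit_or_arm}/loop={h.copies_or_loop}"
                    if h.kind == "inverted"
                    else h.unit_or_arm
                )
                fh.write(f"{h.kind}\t-\t{h.start}\t{h.end}\t{detail}\n")
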