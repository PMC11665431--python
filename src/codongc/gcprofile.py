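"""Per-codon sliding-window GC profiling.

The central statistic: for each codon site, the GC content of the 21 bases
formed by the codon itself plus its three flanking codons on each side
(a 7-codon window). Sites 1-3 take the value of site 4 and the last three
sites take the value of site L-3, since no full window fits there; these
edge sites act as references rather than measurements.

Values are computed in full precision; rounding to two decimals happens
only at presentation (site tables, TSV export, reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import CodingSequence, translate

WINDOW_CODONS = 7
WINDOW_BASES = 21
FLANK = 3  # codons on each side of the central codon


class ProfileError(ValueError):
    """Raised on invalid profiling requests."""


@dataclass(frozen=True)
class GCProfile:
    """Windowed GC percentages for every codon site of one CDS.

    ``values`` is indexed 0-based internally; use :meth:`at` for the 1-based
    codon-site view used in every report. ``mean_gc`` is the GC content of
    the whole CDS — the horizontal reference line in plots.
    """

    values: np.ndarray
    mean_gc: float
    window_codons: int = WINDOW_CODONS
    window_bases: int = WINDOW_BASES

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        self.values.setflags(write=False)

    @property
    def codon_count(self) -> int:
        return len(self.values)

    def at(self, site: int) -> float:
        """Value at 1-based codon site."""
        if not 1 <= site <= len(self.values):
            raise ProfileError(f"site {site} out of range 1..{len(self.values)}")
        return float(self.values[site - 1])


@dataclass(frozen=True)
class SiteRecord:
    """One row of the per-site table: site, residue, codon, windowed GC."""

    site: int
    amino_acid: str
    codon: str
    gc_percent: float  # rounded to 2 decimals for presentation


@dataclass(frozen=True)
class ProfileComparison:
    """Read-only pairing of two profiles of synonymous sequences.

    ``delta`` is profile2 − profile1 per site; each sequence keeps its own
    mean line.
    """

    seq1: CodingSequence
    seq2: CodingSequence
    profile1: GCProfile
    profile2: GCProfile
    delta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        d = self.profile2.values - self.profile1.values
        d.setflags(write=False)
        object.__setattr__(self, "delta", d)


def _is_gc(bases: str) -> np.ndarray:
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return (arr == ord("G")) | (arr == ord("C"))


def _codon_gc_counts(seq: CodingSequence) -> np.ndarray:
    return _is_gc(seq.bases).reshape(-1, 3).sum(axis=1)


def windowed_gc(seq: CodingSequence, site: int) -> float:
    """Windowed GC percentage at a 1-based codon site.

    For interior sites (4..L-3): 100 × (G/C count over codons site−3..site+3)
    / 21. Edge sites return the site-4 / site-(L−3) reference value.
    """
    L = seq.codon_count
    if not 1 <= site <= L:
        raise ProfileError(f"site {site} out of range 1..{L}")
    if site < 1 + FLANK + 1:  # sites 1..3
        site = FLANK + 1
    elif site > L - FLANK:  # sites L-2..L
        site = L - FLANK
    start = 3 * (site - 1 - FLANK)
    window = seq.bases[start: start + WINDOW_BASES]
    return 100.0 * sum(b in "GC" for b in window) / WINDOW_BASES


def profile(seq: CodingSequence) -> GCProfile:
    """Full windowed-GC profile plus the sequence-wide mean GC."""
    counts = _codon_gc_counts(seq)
    L = len(counts)
    # sliding 7-codon sums over interior sites via cumulative sums
    csum = np.concatenate(([0], np.cumsum(counts)))
    interior = csum[WINDOW_CODONS:] - csum[:-WINDOW_CODONS]  # length L-6
    values = np.empty(L, dtype=float)
    values[FLANK: L - FLANK] = 100.0 * interior / WINDOW_BASES
    values[:FLANK] = values[FLANK]
    values[L - FLANK:] = values[L - FLANK - 1]
    mean_gc = 100.0 * counts.sum() / (3 * L)
    return GCProfile(values=values, mean_gc=float(mean_gc))


def site_table(seq: CodingSequence) -> list[SiteRecord]:
    """Per-site records (site, amino acid, codon, GC%), site ascending."""
    prof = profile(seq)
    residues = translate(seq).residues
    return [
        SiteRecord(i + 1, residues[i], codon, round(float(prof.values[i]), 2))
        for i, codon in enumerate(seq.codons())
    ]


def export_site_table(seq: CodingSequence, path: str | Path) -> None:
    """TSV export: ``site aa codon gc_percent`` with 2-decimal GC."""
    rows = site_table(seq)
    with Path(path).open("w") as fh:
        fh.write("site\taa\tcodon\tgc_percent\n")
        for r in rows:
            fh.write(f"{r.site}\t{r.amino_acid}\t{r.codon}\t{r.gc_percent:.2f}\n")


def find_extrema(
    p: GCProfile, threshold: float = 15.0
) -> list[tuple[int, float, str]]:
    """Local peaks and valleys relative to the sequence mean.

    A peak (valley) is a maximal run of consecutive sites with value at
    least ``threshold`` percentage points above (below) ``mean_gc``; each
    run is reported at its extreme site, earliest site on ties. Output is
    interleaved in site order.
    """
    if threshold < 0:
        raise ProfileError("threshold must be non-negative")
    out: list[tuple[int, float, str]] = []
    kinds = np.zeros(len(p.values), dtype=int)
    kinds[p.values >= p.mean_gc + threshold] = 1
    kinds[p.values <= p.mean_gc - threshold] = -1
    i = 0
    while i < len(kinds):
        if kinds[i] == 0:
            i += 1
            continue
        j = i
        while j < len(kinds) and kinds[j] == kinds[i]:
            j += 1
        run = p.values[i:j]
        rel = int(np.argmax(run) if kinds[i] == 1 else np.argmin(run))
        out.append(
            (i + rel + 1, float(run[rel]), "peak" if kinds[i] == 1 else "valley")
        )
        i = j
    return out


def compare_profiles(seq1: CodingSequence, seq2: CodingSequence) -> ProfileComparison:
    """Site-aligned comparison of two sequences encoding the same protein."""
    p1, p2 = translate(seq1).residues, translate(seq2).residues
    if len(p1) != len(p2):
        mismatch = min(len(p1), len(p2)) + 1
        raise ProfileError(
            "sequences do not encode the same protein "
            f"(first mismatch at site {mismatch})"
        )
    for i, (a, b) in enumerate(zip(p1, p2)):
        if a != b:
            raise ProfileError(
                f"sequences do not encode the same protein (first mismatch at site {i + 1})"
            )
    return ProfileComparison(seq1, seq2, profile(seq1), profile(seq2))


def export_comparison(cmp: ProfileComparison, path: str | Path) -> None:
    """TSV export: ``site aa codon_1 gc_1 codon_2 gc_2 delta``."""
    residues = translate(cmp.seq1).residues
    c1, c2 = cmp.seq1.codons(), cmp.seq2.codons()
    with Path(path).open("w") as fh:
        fh.write("site\taa\tcodon_1\tgc_1\tcodon_2\tgc_2\tdelta\n")
        for i in range(cmp.profile1.codon_count):
            fh.write(
                f"{i + 1}\t{residues[i]}\t{c1[i]}\t{cmp.profile1.values[i]:.2f}\t"
                f"{c2[i]}\t{cmp.profile2.values[i]:.2f}\t{cmp.delta[i]:+.2f}\n"
            )


def plot_profiles(
    seqs: list[tuple[str, CodingSequence]], path: str | Path
) -> None:
    """Static line plot: x = codon site, y = windowed GC%, one line per
    sequence, dashed horizontal line at each sequence's mean GC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for label, seq in seqs:
        p = profile(seq)
        sites = np.arange(1, p.codon_count + 1)
        (line,) = ax.plot(sites, p.values, label=f"{label} (mean {p.mean_gc:.1f}%)")
        ax.axhline(p.mean_gc, color=line.get_color(), linestyle="--", linewidth=0.8)
    ax.set_xlabel("codon site")
    ax.set_ylabel("windowed GC (%)")
    ax.set_ylim(-2, 102)
    ax.legend(loc="best", fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
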