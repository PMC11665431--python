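"""Automated local-GC flattening by greedy synonymous substitution.

Subcloning primers anneal poorly where local GC strays outside roughly
40-60%, so the goal is a profile that stays inside user bounds. The loop
repeatedly targets the worst out-of-bounds site, scores every synonymous
single-codon swap inside that site's 7-codon window by how much it reduces
the profile's total out-of-bounds deviation, and applies the best strictly
improving swap. Candidate codons below a minimum usage fraction are
excluded so rare codons are never introduced. Greedy, deterministic, and
guaranteed to terminate (total deviation lives on a finite lattice and
strictly decreases); no optimality claim is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import editing
from .gcprofile import FLANK, GCProfile, profile
from .seqio import CodingSequence
from .usage import CodonUsageTable, synonymous_alternatives


class FlattenError(ValueError):
    """Raised on invalid flattening configuration."""


@dataclass(frozen=True)
class FlattenConfig:
    """Bounds and limits for the flattening loop.

    lo, hi:
        Acceptable windowed-GC band in percent, closed interval; defaults
        40-60, the usual primer-design comfort zone.
    min_fraction:
        Smallest codon-usage fraction an introduced codon may have
        (default 0.05, excluding rare codons); set 0 to allow any synonym.
    max_changes:
        Cap on the number of substitutions; None means unlimited.
    """

    lo: float = 40.0
    hi: float = 60.0
    min_fraction: float = 0.05
    max_changes: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi <= 100:
            raise FlattenError(f"invalid bounds [{self.lo}, {self.hi}]")
        if not 0 <= self.min_fraction < 1:
            raise FlattenError(f"invalid min_fraction {self.min_fraction}")
        if self.max_changes is not None and self.max_changes < 0:
            raise FlattenError("max_changes must be non-negative")


def violations(
    p: GCProfile, lo: float, hi: float
) -> list[tuple[int, float, str]]:
    """Sites whose value falls outside the closed band [lo, hi], ascending."""
    out = []
    for i, v in enumerate(p.values):
        if v < lo:
            out.append((i + 1, float(v), "low"))
        elif v > hi:
            out.append((i + 1, float(v), "high"))
    return out


def _deviations(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.maximum(lo - values, 0.0) + np.maximum(values - hi, 0.0)


def _total_deviation(seq: CodingSequence, lo: float, hi: float) -> float:
    return float(_deviations(profile(seq).values, lo, hi).sum())


def flatten(
    seq: CodingSequence,
    table: CodonUsageTable,
    cfg: FlattenConfig = FlattenConfig(),
) -> tuple[editing.EditSession, list[tuple[int, float, str]]]:
    """Flatten local GC into [cfg.lo, cfg.hi] by greedy synonymous swaps.

    Returns the edit session (original, edited sequence, change log) and the
    report of sites still violating the bounds, with their values.
    """
    session = editing.new_session(seq)
    L = seq.codon_count
    while cfg.max_changes is None or len(session.changes) < cfg.max_changes:
        current = session.current
        prof = profile(current)
        dev = _deviations(prof.values, cfg.lo, cfg.hi)
        if not dev.any():
            break
        total_now = float(dev.sum())
        # violating sites, worst first; earliest site wins ties
        order = sorted(range(L), key=lambda i: (-dev[i], i))
        best = None  # (reduction, -fraction, codon, window_site)
        for site0 in order:
            if dev[site0] == 0:
                break
            lo_w = max(1, site0 + 1 - FLANK)
            hi_w = min(L, site0 + 1 + FLANK)
            for wsite in range(lo_w, hi_w + 1):
                old = current.codon(wsite)
                for alt in synonymous_alternatives(table, old):
                    if alt.codon == old or alt.fraction < cfg.min_fraction:
                        continue
                    trial = current.with_codon(wsite, alt.codon)
                    reduction = total_now - _total_deviation(trial, cfg.lo, cfg.hi)
                    if reduction <= 1e-9:
                        continue
                    key = (-reduction, -alt.fraction, alt.codon, wsite)
                    if best is None or key < best[0]:
                        best = (key, wsite, alt.codon)
            if best is not None:
                break  # the worst fixable site is handled; rescan after swap
        if best is None:
            break
        _, wsite, codon = best
        editing.apply_substitution(session, wsite, codon)
    report = violations(profile(session.current), cfg.lo, cfg.hi)
    return session, report


def export_report(
    report: list[tuple[int, float, str]], path
) -> None:
    """Unresolved-sites TSV: ``site value side``."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("site\tvalue\tside\n")
        for site, value, side in report:
            fh.write(f"{site}\t{value:.2f}\t{side}\n")
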