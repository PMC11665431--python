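# codongc

Codon-resolution sliding-window GC profiling and synonymous codon editing
for gene synthesis and subcloning.

## The problem

Subcloning primers anneal through local base pairing, so their melting
behaviour depends on the GC content of the stretch they bind — comfortable
primers sit around 40–60% GC. A coding sequence that is fine on average can
still contain short GC peaks or valleys where no good primer exists and PCR
fails. Because the genetic code is redundant, such regions can usually be
repaired without touching the protein: swap codons for synonymous ones that
are common in the expression host.

`codongc` makes that workflow scriptable:

- **Windowed GC profile.** For codon site *i* of a CDS with *L* codons, the
  statistic is

  GC(i) = 100 · (#G + #C among the 21 bases of codons *i*−3 … *i*+3) / 21,
  for 4 ≤ *i* ≤ *L*−3,

  i.e. the GC content of a fixed 7-codon (21-base) window centred on the
  codon. Sites 1–3 take the value at site 4 and the last three sites the
  value at site *L*−3, since no full window fits there. The sequence-wide
  mean GC serves as the reference line.
- **Synonymous editing** with a chronological change log, per-change GC
  snapshots, undo, and protein-preservation guaranteed by construction.
- **Codon-usage tables** (bundled: *E. coli* as default host, human,
  budding yeast; plus a validated text format for custom organisms) that
  rank replacement codons by usage fraction.
- **Automated flattening**: a deterministic greedy loop that drives every
  window into user bounds where single synonymous swaps can do so, and
  reports the residual sites where they cannot.
- **Post-edit checks**: restriction sites (IUPAC patterns, both strands),
  tandem repeats, reverse-complement palindromes and inverted repeats.

## Worked example

```python
from codongc import find_extrema, profile
from codongc.fixtures import FixtureSpec, generate

seq = generate(FixtureSpec(protein_length=60, shape=[((25, 35), "high")], seed=7))
prof = profile(seq)
print(f"mean GC of the whole CDS: {prof.mean_gc:.2f}%")
for site, value, kind in find_extrema(prof, threshold=15):
    print(f"  {kind} at codon site {site}: {value:.2f}%")
```

prints

```
mean GC of the whole CDS: 57.78%
  peak at codon site 28: 100.00%
```

— a 60-codon gene whose overall GC looks unremarkable but which carries a
stretch (codon sites ~25–35) where every base of the 21-base window is G or
C; primers there would be unusable. Flattening it against the *E. coli*
table (`examples/03_flatten_local_gc.py`) applies 16 synonymous swaps,
cuts the out-of-bounds sites from 21 to 7 and prints the sites that remain
stuck: an alanine/arginine/glycine-rich island whose every codon must keep
at least two G/C bases, so no synonymous choice can reach 60% — the report
makes that residual explicit instead of hiding it.

The same workflow is available from a shell:

```sh
codongc profile gene.fasta --out sites.tsv --plot profile.png
codongc edit gene.fasta 5:GCG 12:GCT --out edited.fasta --log changes.tsv
codongc flatten gene.fasta --lo 40 --hi 60 --out flat.fasta --report residual.tsv
codongc check flat.fasta --out report.tsv
codongc compare gene.fasta flat.fasta --out cmp.tsv
codongc tables list
```

Each `examples/0*.py` script is a runnable narrative for one capability.

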