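"""Automatically flatten local GC into the 40-60% primer-design band.

Generates a gene with a GC-rich island, then lets the greedy optimizer pick
synonymous swaps (preferring frequent E. coli codons) until every 21-base
window sits inside the bounds or no single swap helps any further.
"""

from codongc import FlattenConfig, builtin_table, flatten, profile, translate, violations
from codongc.fixtures import FixtureSpec, generate

seq = generate(FixtureSpec(protein_length=50, shape=[((20, 30), "high")], seed=11))
table = builtin_table("e_coli")

before = violations(profile(seq), 40, 60)
session, residual = flatten(seq, table, FlattenConfig(lo=40, hi=60))

print(f"out-of-bounds sites before: {len(before)}, after: {len(residual)}")
print(f"substitutions applied: {len(session.changes)}")
for rec in session.changes[:5]:
    print(f"  site {rec.site}: {rec.old_codon} -> {rec.new_codon} "
          f"({rec.gc_before:.1f}% -> {rec.gc_after:.1f}%)")
if len(session.changes) > 5:
    print(f"  ... and {len(session.changes) - 5} more")
assert translate(session.current).residues == translate(seq).residues
print("protein preserved; residual sites (if any) are infeasible for single swaps:")
for site, value, side in residual:
    print(f"  site {site}: {value:.2f}% ({side})")
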