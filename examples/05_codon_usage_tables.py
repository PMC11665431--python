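"""Inspect codon-usage tables and synonymous alternatives.

Loads the bundled E. coli table and lists, for a few codons, the synonymous
family sorted by usage fraction — the same ordering the editor and the
flattener use when proposing replacement codons.
"""

from codongc import builtin_table, synonymous_alternatives
from codongc.usage import available_tables

print("bundled organisms:", ", ".join(available_tables()))
table = builtin_table("e_coli")
print(f"host: {table.organism}")

for codon in ("CTG", "GCA", "CGT"):
    entry = table[codon]
    print(f"\n{codon} ({entry.amino_acid}), family by fraction:")
    for alt in synonymous_alternatives(table, codon):
        marker = " <- query" if alt.codon == codon else ""
        print(f"  {alt.codon}  fraction {alt.fraction:.2f}  "
              f"per-thousand {alt.per_thousand:.1f}{marker}")
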