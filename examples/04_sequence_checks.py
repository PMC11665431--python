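"""Post-edit sanity checks: restriction sites, repeats, palindromes, hairpins.

Plants an EcoRI site, a CTG tandem repeat and an inverted-repeat pair in a
random background, then recovers each with the bundled scanners. These are
the screens worth running on any sequence before ordering synthesis.
"""

from codongc import checks
from codongc.fixtures import FixtureSpec, generate

seq = generate(FixtureSpec(
    protein_length=50,
    planted_patterns=[
        ("EcoRI site", "GAATTC", 10),
        ("tandem repeat", "A" + "CTG" * 4 + "T", 60),
        ("hairpin arms", "GGCGCA" + "TTAT" + "TGCGCC", 100),
    ],
    seed=13,
))

for hit in checks.scan_restriction_sites(seq, checks.load_enzymes()):
    print(f"restriction {hit.name}: bases {hit.start}-{hit.end} ({hit.strand})")
for hit in checks.find_tandem_repeats(seq, min_unit=3, min_copies=3):
    print(f"tandem: {hit.unit_or_arm} x{hit.copies_or_loop} at {hit.start}-{hit.end}")
for hit in checks.find_palindromes(seq, min_len=6):
    print(f"palindrome: {hit.unit_or_arm} at {hit.start}-{hit.end}")
for hit in checks.find_inverted_repeats(seq, min_arm=6, max_loop=10):
    print(f"inverted repeat: arm {hit.unit_or_arm}, loop {hit.copies_or_loop}, "
          f"at {hit.start}-{hit.end}")
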