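"""Pattern and repeat scans: planted-motif recovery and self-verification."""

import pytest

from codongc import checks
from codongc.checks import CheckError
from codongc.fixtures import FixtureSpec, generate
from codongc.seqio import CodingSequence, reverse_complement

from conftest import random_cds


def pad(core: str, name: str = "p", left: str = "AAA", total_codons: int = 12) -> CodingSequence:
    """Embed a motif after `left` in an A-padding, codon-complete sequence."""
    bases = left + core
    bases += "A" * (3 * total_codons - len(bases))
    return CodingSequence(name, bases)


class TestScanRestrictionSites:
    def test_palindromic_site_collapses_to_one_plus_hit(self):
        seq = pad("GAATTC")
        hits = checks.scan_restriction_sites(seq, [("EcoRI", "GAATTC")])
        assert len(hits) == 1
        h = hits[0]
        assert (h.name, h.start, h.end, h.matched, h.strand) == (
            "EcoRI", 4, 9, "GAATTC", "plus"
        )

    def test_absent_pattern_gives_no_hits(self):
        seq = pad("GAATTC")
        assert checks.scan_restriction_sites(seq, [("Acc65I", "GGTACC")]) == []

    def test_iupac_ambiguity_expansion(self):
        seq = CodingSequence("p", "AAAGAATTCAAAGGATTCAAAAAAAAA")
        hits = checks.scan_restriction_sites(seq, [("amb", "GRATTC")])
        assert [(h.start, h.matched) for h in hits] == [(4, "GAATTC"), (13, "GGATTC")]

    def test_minus_strand_hit_in_plus_coordinates(self):
        # BamHI site GGATCC on the minus strand appears as GGATCC in the
        # reverse complement; plant its reverse complement on the plus strand
        seq = pad(reverse_complement("GGATCA"))  # non-palindromic probe
        hits = checks.scan_restriction_sites(seq, [("probe", "GGATCA")])
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "minus"
        assert h.matched == "GGATCA"
        assert reverse_complement(seq.bases[h.start - 1: h.end]) == h.matched

    def test_minus_hits_map_to_plus_hits_of_reverse_complement(self, rng):
        seq = random_cds(rng, 60)
        pattern = ("probe", "GGATCA")
        fwd = checks.scan_restriction_sites(seq, [pattern])
        rc_seq = CodingSequence("rc", reverse_complement(seq.bases))
        rev = checks.scan_restriction_sites(rc_seq, [pattern])
        n = len(seq.bases)
        mapped = sorted(
            (n - h.end + 1, n - h.start + 1) for h in rev if h.strand == "plus"
        )
        minus = sorted((h.start, h.end) for h in fwd if h.strand == "minus")
        assert minus == mapped

    def test_invalid_iupac_character_rejected(self):
        seq = pad("GAATTC")
        with pytest.raises(CheckError, match="invalid IUPAC"):
            checks.scan_restriction_sites(seq, [("bad", "GAAT7C")])

    def test_hits_round_trip_coordinates(self, rng):
        seq = random_cds(rng, 80)
        for h in checks.scan_restriction_sites(seq, checks.load_enzymes()):
            slice_ = seq.bases[h.start - 1: h.end]
            assert h.matched == (
                slice_ if h.strand == "plus" else reverse_complement(slice_)
            )


class TestFindPalindromes:
    def test_ecoRI_span_found(self):
        seq = pad("GAATTC")
        hits = checks.find_palindromes(seq, min_len=6)
        assert any(
            (h.start, h.end, h.unit_or_arm) == (4, 9, "GAATTC") for h in hits
        )

    def test_homopolymer_has_none(self):
        seq = CodingSequence("h", "AAA" * 10)
        assert checks.find_palindromes(seq, min_len=4) == []

    def test_odd_min_len_rejected(self):
        with pytest.raises(CheckError, match="even"):
            checks.find_palindromes(CodingSequence("h", "AAA" * 10), min_len=5)

    def test_reported_spans_self_verify_and_are_maximal(self, rng):
        seq = random_cds(rng, 100)
        hits = checks.find_palindromes(seq, min_len=6)
        spans = [(h.start, h.end) for h in hits]
        for h in hits:
            span = seq.bases[h.start - 1: h.end]
            assert span == reverse_complement(span)
            assert len(span) >= 6 and len(span) % 2 == 0
            # no reported span nested inside another reported span
            assert not any(
                (s <= h.start and h.end <= e) and (s, e) != (h.start, h.end)
                for s, e in spans
            )


class TestFindTandemRepeats:
    def test_acg_times_three(self):
        seq = pad("ACGACGACG", total_codons=14)
        hits = checks.find_tandem_repeats(seq, min_unit=3, min_copies=3)
        assert any(
            (h.unit_or_arm, h.copies_or_loop) == ("ACG", 3) for h in hits
        )

    def test_incomplete_copy_not_counted(self):
        seq = pad("ACGTACGA", left="TTT", total_codons=14)
        hits = checks.find_tandem_repeats(seq, min_unit=3, min_copies=2)
        assert not any(h.unit_or_arm == "ACGT" for h in hits)

    def test_planted_ctg_run_in_random_background(self, rng):
        fix = generate(
            FixtureSpec(protein_length=40,
                        planted_patterns=[("tandem", "CTG" * 4, 31)], seed=9)
        )
        hits = checks.find_tandem_repeats(fix, min_unit=3, min_copies=3)
        match = [h for h in hits if h.unit_or_arm == "CTG" and h.start <= 31]
        assert match and match[0].copies_or_loop >= 4

    def test_span_equals_unit_times_copies(self, rng):
        seq = random_cds(rng, 120)
        for h in checks.find_tandem_repeats(seq, min_unit=2, min_copies=2):
            unit, k = h.unit_or_arm, h.copies_or_loop
            assert h.end - h.start + 1 == len(unit) * k
            assert seq.bases[h.start - 1: h.end] == unit * k

    def test_parameter_bounds(self):
        seq = CodingSequence("h", "AAA" * 10)
        with pytest.raises(CheckError):
            checks.find_tandem_repeats(seq, min_unit=1, min_copies=2)


class TestFindInvertedRepeats:
    def test_planted_arm_and_mate(self):
        seq = pad("GGGGGG" + "AT" + "CCCCCC", total_codons=12)
        hits = checks.find_inverted_repeats(seq, min_arm=6, max_loop=10)
        assert len(hits) >= 1
        h = hits[0]
        assert len(h.unit_or_arm) >= 6

    def test_homopolymer_has_none(self):
        seq = CodingSequence("h", "AAA" * 20)
        assert checks.find_inverted_repeats(seq, min_arm=6, max_loop=10) == []

    def test_arms_self_verify(self, rng):
        seq = random_cds(rng, 100)
        for h in checks.find_inverted_repeats(seq, min_arm=6, max_loop=20):
            arm = h.unit_or_arm
            loop = h.copies_or_loop
            span = seq.bases[h.start - 1: h.end]
            a = len(arm)
            assert span[:a] == arm
            assert span[a + loop:] == reverse_complement(arm)
            assert len(span) == 2 * a + loop


class TestReportAndEnzymeIO:
    def test_bundled_enzyme_list_loads(self):
        enzymes = checks.load_enzymes()
        names = [n for n, _ in enzymes]
        assert "EcoRI" in names and ("EcoRI", "GAATTC") in enzymes

    def test_bad_enzyme_file_reports_line(self, tmp_path):
        p = tmp_path / "enz.txt"
        p.write_text("EcoRI GAATTC\nBad\n")
        with pytest.raises(CheckError, match=":2"):
            checks.load_enzymes(p)

    def test_combined_report_tsv(self, tmp_path):
        seq = pad("GAATTC")
        hits = checks.run_all_checks(seq, [("EcoRI", "GAATTC")],
                                     palindrome_min_len=6, inverted_min_arm=6,
                                     inverted_max_loop=10)
        out = tmp_path / "report.tsv"
        checks.export_check_report(hits, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "kind\tname\tstart\tend\tdetail"
        assert any(line.startswith("restriction\tEcoRI\t4\t9") for line in lines)
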