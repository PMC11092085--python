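"""Read QC, locus/haplotype classification, categorisation, unit counting."""

import numpy as np
import pytest

from nanofshd.feature_library import build_allele_sequence
from nanofshd.local_align import AlignmentHit, FeatureScanner, ReadScan
from nanofshd.read_typing import (
    ReadTyping,
    categorize_read,
    classify_chromosome,
    classify_haplotype,
    count_d4z4_units,
    filter_reads,
    type_read,
)

from conftest import mutate_subs


class FakeRead:
    def __init__(self, length, quality):
        self.length = length
        self.mean_quality = quality


class TestFilterReads:
    def test_short_high_quality_read_removed(self):
        assert filter_reads([FakeRead(499, 20)]) == []

    def test_boundary_read_kept(self):
        # the filter removes quality < 9 and length < 500, so a read at
        # exactly (500, Q9) survives
        kept = filter_reads([FakeRead(500, 9)])
        assert len(kept) == 1

    def test_partition(self, rng):
        reads = [
            FakeRead(int(rng.integers(100, 2000)), float(rng.uniform(5, 20)))
            for _ in range(100)
        ]
        kept = filter_reads(reads)
        removed = [r for r in reads if r not in kept]
        assert len(kept) + len(removed) == len(reads)
        assert all(r.length >= 500 and r.mean_quality >= 9 for r in kept)


def _hit(feature, locus, hap, start, end, bits, cov=1.0):
    return AlignmentHit(
        feature=feature, read_id="r", read_start=start, read_end=end,
        strand="+", raw_score=bits, bitscore=bits, identity=0.95,
        feature_coverage=cov, locus=locus, haplotype=hap,
    )


def _scan(hits, length=10000):
    return ReadScan(read_id="r", strand="+", hits=hits, read_length=length)


class TestClassification:
    def test_tied_scores_are_ambiguous(self):
        scan = _scan([
            _hit("D4Z4", "4q", "none", 0, 3300, 200),
            _hit("D4Z4", "10q", "none", 0, 3300, 200),
        ])
        assert classify_chromosome(scan) == "ambiguous"

    def test_no_hits_unclassified(self):
        assert classify_chromosome(_scan([])) == "unclassified"

    def test_margin_respected(self):
        scan = _scan([
            _hit("D4Z4", "4q", "none", 0, 3300, 209),
            _hit("D4Z4", "10q", "none", 0, 3300, 200),
        ])
        assert classify_chromosome(scan, margin_bits=10) == "ambiguous"
        assert classify_chromosome(scan, margin_bits=5) == "4q"

    def test_haplotype_from_better_plam(self):
        scan = _scan([
            _hit("pLAM_A", "4q", "A", 100, 600, 300),
            _hit("pLAM_B", "4q", "B", 100, 600, 150),
        ])
        assert classify_haplotype(scan, "4q") == "A"

    def test_haplotype_none_without_plam_or_on_tie(self):
        assert classify_haplotype(_scan([]), "4q") == "none"
        tie = _scan([
            _hit("pLAM_A", "4q", "A", 100, 600, 200),
            _hit("pLAM_B", "4q", "B", 100, 600, 200),
        ])
        assert classify_haplotype(tie, "4q") == "none"


class TestCountUnits:
    def test_counts_full_coverage_hits_only(self):
        scan = _scan([
            _hit("D4Z4", "4q", "none", 0, 3300, 200, cov=1.0),
            _hit("D4Z4", "4q", "none", 3300, 6600, 200, cov=0.95),
            _hit("D4Z4", "4q", "none", 6600, 8000, 90, cov=0.4),  # edge unit
        ])
        assert count_d4z4_units(scan, "4q") == 2

    def test_zero_hits(self):
        assert count_d4z4_units(_scan([]), "4q") == 0


class TestCategorize:
    def anchor(self):
        return _hit("D4F104S1", "4q", "none", 0, 1500, 400)

    def units(self, n, start=1500):
        return [
            _hit("D4Z4", "4q", "none", start + i * 3300, start + (i + 1) * 3300, 500)
            for i in range(n)
        ]

    def plam(self, start):
        return _hit("pLAM_A", "4q", "A", start, start + 500, 200)

    def test_spanning_read_is_complete(self):
        hits = [self.anchor()] + self.units(2) + [self.plam(1500 + 2 * 3300)]
        cat, marker = categorize_read(_scan(hits), "4q", 2)
        assert cat == "complete" and not marker

    def test_units_plus_plam_is_haplotype_only(self):
        hits = self.units(12, start=0) + [self.plam(12 * 3300)]
        cat, marker = categorize_read(_scan(hits, 40000), "4q", 12)
        assert cat == "haplotype_only" and not marker

    def test_anchor_plus_eleven_units_is_marker(self):
        hits = [self.anchor()] + self.units(11)
        cat, marker = categorize_read(_scan(hits, 40000), "4q", 11)
        assert cat == "incomplete" and marker

    def test_marker_needs_ten_units(self):
        hits = [self.anchor()] + self.units(9)
        cat, marker = categorize_read(_scan(hits, 40000), "4q", 9)
        assert cat == "incomplete" and not marker

    def test_order_violation_demoted(self):
        # pLAM upstream of the units: not a well-formed array read
        hits = [self.plam(0)] + self.units(2, start=600) + [
            _hit("D4F104S1", "4q", "none", 7300, 8800, 400)
        ]
        cat, _ = categorize_read(_scan(hits, 10000), "4q", 2)
        assert cat == "uninformative"

    def test_ru_exact_invariant(self):
        with pytest.raises(ValueError):
            ReadTyping(
                read_id="r", chromosome="4q", haplotype="A",
                category="incomplete", ru_observed=3, ru_exact=True,
                usable_nonpathogenetic_marker=False,
            )


@pytest.fixture(scope="module")
def scanner(small_library):
    return FeatureScanner(small_library)


class TestSimulatedTyping:
    """Typing against reads cut from synthetic alleles (small library)."""

    def test_error_free_spanning_read_complete_and_exact(self, small_library, scanner):
        allele = build_allele_sequence(small_library, "4q", "A", 3, flank_lens=(300, 300))
        scan = scanner.scan(allele.array, read_id="r")
        t = type_read(scan)
        assert t.chromosome == "4q"
        assert t.haplotype == "A"
        assert t.category == "complete"
        assert t.ru_observed == 3 and t.ru_exact

    def test_noisy_read_classified_to_true_locus(self, small_library, scanner, rng):
        allele = build_allele_sequence(small_library, "10q", "A", 4, flank_lens=(300, 300))
        read = mutate_subs(allele.array, 0.05, rng)
        t = type_read(scanner.scan(read, read_id="r"))
        assert t.chromosome == "10q"
        assert t.haplotype == "A"
        assert t.ru_observed == 4

    def test_read_ending_before_plam_has_no_haplotype(self, small_library, scanner):
        allele = build_allele_sequence(small_library, "4q", "B", 5, flank_lens=(300, 300))
        # stop inside the 4th unit: anchor + units only
        read = allele.array[: 300 + 300 + 3 * 400 + 200]
        t = type_read(scanner.scan(read, read_id="r"))
        assert t.haplotype == "none"
        assert t.category == "incomplete"
        assert t.ru_observed <= 3

    def test_lower_bound_soundness(self, small_library, scanner, rng):
        # observed count never exceeds the true repeat number
        allele = build_allele_sequence(small_library, "4q", "A", 5, flank_lens=(300, 300))
        L = len(allele.sequence)
        for _ in range(20):
            s = int(rng.integers(0, L - 600))
            e = int(rng.integers(s + 600, min(L, s + 4000) + 1))
            read = mutate_subs(allele.array[s:e], 0.03, rng)
            t = type_read(scanner.scan(read, read_id="r"))
            assert t.ru_observed <= 5
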