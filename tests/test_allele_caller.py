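"""Allele clustering, pathogenicity, mosaicism, concordance."""

import pandas as pd
import pytest

from nanofshd.allele_caller import (
    AlleleCall,
    SampleGenotype,
    call_pathogenicity,
    cluster_alleles,
    concordance_report,
    detect_mosaic,
)
from nanofshd.read_typing import ReadTyping

_counter = [0]


def _typing(category, hap, ru, chrom="4q", has_plam=None):
    _counter[0] += 1
    if has_plam is None:
        has_plam = category in ("complete", "haplotype_only")
    return ReadTyping(
        read_id=f"t{_counter[0]}",
        chromosome=chrom,
        haplotype=hap,
        category=category,
        ru_observed=ru,
        ru_exact=category == "complete",
        usable_nonpathogenetic_marker=(category == "incomplete" and ru >= 10),
        has_anchor=category in ("complete", "incomplete"),
        has_plam=has_plam,
    )


class TestClusterAlleles:
    def test_mosaic_three_allele_pattern(self):
        # three complete reads at 2 (4qA), two long haplotype reads (4qA),
        # two complete reads at 18 (4qB): the mosaic genotype pattern
        typings = (
            [_typing("complete", "A", 2) for _ in range(3)]
            + [_typing("haplotype_only", "A", 31), _typing("haplotype_only", "A", 29)]
            + [_typing("complete", "B", 18) for _ in range(2)]
        )
        calls = cluster_alleles(typings, "S", "4q")
        got = {(c.haplotype, c.ru_count, c.is_exact) for c in calls}
        assert got == {("A", 2, True), ("A", 31, False), ("B", 18, True)}
        geno = SampleGenotype("S", calls)
        assert detect_mosaic(geno)

    def test_single_complete_read_insufficient(self):
        calls = cluster_alleles([_typing("complete", "A", 5)], "S", "4q", min_support=2)
        assert calls == []

    def test_modal_merge_within_tolerance(self):
        typings = [
            _typing("complete", "A", 14),
            _typing("complete", "A", 14),
            _typing("complete", "A", 13),
        ]
        calls = cluster_alleles(typings, "S", "4q", merge_tolerance=1)
        assert len(calls) == 1
        assert calls[0].ru_count == 14 and calls[0].is_exact
        assert calls[0].n_complete == 3

    def test_bound_reads_attach_to_smallest_containing_exact(self):
        typings = (
            [_typing("complete", "A", 4) for _ in range(2)]
            + [_typing("complete", "A", 12) for _ in range(2)]
            + [_typing("haplotype_only", "A", 3)]
        )
        calls = cluster_alleles(typings, "S", "4q")
        small = next(c for c in calls if c.ru_count == 4)
        assert len(small.supporting_reads) == 3

    def test_duplicate_allele_detected_from_distal_depth(self):
        # one cluster (B, 16) with ~2x the expected distal-end support:
        # two same-length alleles merged; multiplicity emits a second call
        typings = [_typing("complete", "B", 16) for _ in range(10)] + [
            _typing("haplotype_only", "B", ru) for ru in ([3] * 26 + [8] * 26)
        ]
        calls = cluster_alleles(
            typings, "S", "4q", expected_end_depth=31.0
        )
        assert len(calls) == 2
        assert {c.is_exact for c in calls} == {True, False}
        assert all(c.haplotype == "B" for c in calls)

    def test_single_allele_not_duplicated(self):
        typings = [_typing("complete", "B", 16) for _ in range(8)] + [
            _typing("haplotype_only", "B", 3) for _ in range(20)
        ]
        calls = cluster_alleles(typings, "S", "4q", expected_end_depth=31.0)
        assert len(calls) == 1

    def test_zero_informative_reads(self):
        typings = [
            ReadTyping("x", "10q", "none", "uninformative", 0, False, False)
        ]
        assert cluster_alleles(typings, "S", "4q") == []


class TestPathogenicity:
    def test_exact_contraction_is_pathogenetic(self):
        a = AlleleCall("S", "4q", "A", 9, is_exact=True, supporting_reads=["r"])
        assert call_pathogenicity(a)

    def test_4qB_never_pathogenetic(self):
        a = AlleleCall("S", "4q", "B", 2, is_exact=True, supporting_reads=["r"])
        assert not call_pathogenicity(a)

    def test_lower_bound_never_pathogenetic(self):
        a = AlleleCall("S", "4q", "A", 12, is_exact=False, supporting_reads=["r"])
        assert not call_pathogenicity(a)
        b = AlleleCall("S", "4q", "A", 8, is_exact=False, supporting_reads=["r"])
        assert not call_pathogenicity(b)


class TestMosaic:
    def _geno(self, n_4q):
        alleles = [
            AlleleCall("S", "4q", "A", 2 + i, is_exact=True, supporting_reads=["r"])
            for i in range(n_4q)
        ]
        return SampleGenotype("S", alleles)

    @pytest.mark.parametrize("n,expected", [(1, False), (2, False), (3, True)])
    def test_mosaic_threshold(self, n, expected):
        assert detect_mosaic(self._geno(n)) is expected


class TestConcordance:
    def _report(self, calls, truth_rows):
        genotypes = {"S": SampleGenotype("S", calls)}
        truth = pd.DataFrame(
            [dict(sample="S", haplotype=h, ru=r) for h, r in truth_rows]
        )
        return concordance_report(genotypes, truth).iloc[0]

    def test_exact_match_concordant(self):
        call = AlleleCall("S", "4q", "A", 2, is_exact=True,
                          pathogenetic=True, supporting_reads=["r"])
        row = self._report([call], [("A", 2)])
        assert row["pathogenetic_concordant"]
        assert row["alleles_concordant"] == 1

    def test_haplotype_mismatch_discordant(self):
        call = AlleleCall("S", "4q", "A", 19, is_exact=False, supporting_reads=["r"])
        row = self._report([call], [("B", 27)])
        assert row["alleles_concordant"] == 0
        assert not row["haplotypes_concordant"]

    def test_lower_bound_within_truth_concordant(self):
        call = AlleleCall("S", "4q", "A", 13, is_exact=False, supporting_reads=["r"])
        row = self._report([call], [("A", 29)])
        assert row["alleles_concordant"] == 1

    def test_bound_exceeding_truth_discordant(self):
        call = AlleleCall("S", "4q", "A", 30, is_exact=False, supporting_reads=["r"])
        row = self._report([call], [("A", 29)])
        assert row["alleles_concordant"] == 0

    def test_sample_missing_from_truth_flagged(self):
        genotypes = {"S2": SampleGenotype("S2", [])}
        truth = pd.DataFrame([dict(sample="S", haplotype="A", ru=2)])
        rep = concordance_report(genotypes, truth)
        assert not rep.iloc[0]["in_truth"]
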