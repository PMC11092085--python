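"""Per-read QC, locus classification, haplotyping, and repeat-unit counting.

A read is typed in four steps:

1. QC: reads with mean base quality < 9 or length < 500 bp are removed.
2. Locus: the best bitscore per feature is summed separately for the 4q35
   and 10q26 variant sets; the read is assigned to the larger sum if it wins
   by at least ``margin_bits``, otherwise it is ambiguous (excluded
   downstream); reads with no feature hit are unclassified.
3. Haplotype: the pLAM variant (A or B) with the higher bitscore at the
   read's locus; no pLAM hit or a tie gives none.
4. Category and repeat count: D4Z4 hits covering >= 60% of the unit each
   count as one repeat unit.  A read spanning D4F104S1 -> units -> pLAM (in
   that order) is *complete* and its count is exact; pLAM + units without the
   proximal anchor is *haplotype_only* (count is a lower bound); anchor +
   units or units alone is *incomplete* (lower bound; usable as a
   non-pathogenetic marker when it shows >= 10 units); anything else is
   uninformative.  Feature-order violations demote the read to uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .local_align import DEFAULT_MIN_UNIT_COVERAGE, AlignmentHit, ReadScan

DEFAULT_MARGIN_BITS = 10.0
DEFAULT_MIN_QUALITY = 9.0
DEFAULT_MIN_LENGTH = 500
#: Lower-bound reads usable as non-pathogenetic markers need >= this many
#: units; note an observed 10 could in principle reflect a pathogenetic
#: 10-unit allele, which is why downstream reports flag rather than act on it.
MARKER_MIN_RU = 10


@dataclass
class ReadTyping:
    read_id: str
    chromosome: str  # 4q | 10q | ambiguous | unclassified
    haplotype: str  # A | B | none
    category: str  # complete | haplotype_only | incomplete | uninformative
    ru_observed: int
    ru_exact: bool
    usable_nonpathogenetic_marker: bool
    has_anchor: bool = False
    has_plam: bool = False
    read_length: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.category != "complete" and self.ru_exact:
            raise ValueError("ru_exact requires a complete read")

    @property
    def informative(self) -> bool:
        return self.category in ("complete", "haplotype_only", "incomplete")


def filter_reads(
    reads: Iterable,
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list:
    """QC filter: keep reads with quality >= min_quality AND length >= min_length.

    The filter removes reads with quality < 9 or length < 500 bp, so reads
    at exactly (Q9, 500 bp) survive.
    """
    return [
        r
        for r in reads
        if r.mean_quality >= min_quality and r.length >= min_length
    ]


def classify_chromosome(scan: ReadScan, margin_bits: float = DEFAULT_MARGIN_BITS) -> str:
    s4 = scan.locus_score("4q")
    s10 = scan.locus_score("10q")
    if s4 == 0.0 and s10 == 0.0:
        return "unclassified"
    if abs(s4 - s10) < margin_bits:
        return "ambiguous"
    return "4q" if s4 > s10 else "10q"


def classify_haplotype(scan: ReadScan, locus: str) -> str:
    if locus not in ("4q", "10q"):
        return "none"
    a = scan.best_bitscore("pLAM_A", locus)
    b = scan.best_bitscore("pLAM_B", locus)
    if a == 0.0 and b == 0.0:
        return "none"
    if a == b:
        return "none"
    return "A" if a > b else "B"


def d4z4_unit_hits(
    scan: ReadScan, locus: str, min_coverage: float = DEFAULT_MIN_UNIT_COVERAGE
) -> list[AlignmentHit]:
    return [
        h
        for h in scan.by_feature("D4Z4", locus)
        if h.feature_coverage >= min_coverage
    ]


def count_d4z4_units(
    scan: ReadScan, locus: str, min_coverage: float = DEFAULT_MIN_UNIT_COVERAGE
) -> int:
    """Repeat units observed on the read: full-coverage D4Z4 hits only."""
    return len(d4z4_unit_hits(scan, locus, min_coverage))


def categorize_read(
    scan: ReadScan,
    locus: str,
    ru_observed: int,
    min_coverage: float = DEFAULT_MIN_UNIT_COVERAGE,
) -> tuple[str, bool]:
    """(category, marker flag) from the feature composition of the read."""
    units = d4z4_unit_hits(scan, locus, min_coverage)
    anchors = scan.by_feature("D4F104S1", locus)
    plams = scan.by_feature("pLAM_A", locus) + scan.by_feature("pLAM_B", locus)
    has_anchor = bool(anchors)
    has_plam = bool(plams)
    has_units = ru_observed > 0

    if has_anchor and has_plam and has_units:
        slack = 100  # alignment jitter at feature junctions
        anchor_end = max(h.read_end for h in anchors)
        first_unit = min(h.read_start for h in units)
        last_unit = max(h.read_end for h in units)
        plam_start = min(h.read_start for h in plams)
        ordered = (anchor_end <= first_unit + slack) and (last_unit <= plam_start + slack)
        if ordered:
            return "complete", False
        return "uninformative", False
    if has_plam and has_units and not has_anchor:
        return "haplotype_only", False
    if has_units:
        return "incomplete", ru_observed >= MARKER_MIN_RU
    return "uninformative", False


def type_read(
    scan: ReadScan,
    margin_bits: float = DEFAULT_MARGIN_BITS,
    min_coverage: float = DEFAULT_MIN_UNIT_COVERAGE,
) -> ReadTyping:
    chrom = classify_chromosome(scan, margin_bits)
    if chrom in ("ambiguous", "unclassified"):
        return ReadTyping(
            read_id=scan.read_id,
            chromosome=chrom,
            haplotype="none",
            category="uninformative",
            ru_observed=0,
            ru_exact=False,
            usable_nonpathogenetic_marker=False,
            read_length=scan.read_length,
            strand=scan.strand,
        )
    hap = classify_haplotype(scan, chrom)
    ru = count_d4z4_units(scan, chrom, min_coverage)
    category, marker = categorize_read(scan, chrom, ru, min_coverage)
    return ReadTyping(
        read_id=scan.read_id,
        chromosome=chrom,
        haplotype=hap,
        category=category,
        ru_observed=ru,
        ru_exact=category == "complete",
        usable_nonpathogenetic_marker=marker,
        has_anchor=bool(scan.by_feature("D4F104S1", chrom)),
        has_plam=bool(
            scan.by_feature("pLAM_A", chrom) + scan.by_feature("pLAM_B", chrom)
        ),
        read_length=scan.read_length,
        strand=scan.strand,
    )


def type_reads(scans: Iterable[ReadScan], **kwargs) -> list[ReadTyping]:
    return [type_read(s, **kwargs) for s in scans]


def typings_to_table(typings: Iterable[ReadTyping]):
    return [
        dict(
            read_id=t.read_id,
            chromosome=t.chromosome,
            haplotype=t.haplotype,
            category=t.category,
            ru_observed=t.ru_observed,
            ru_exact=t.ru_exact,
            usable_nonpathogenetic_marker=t.usable_nonpathogenetic_marker,
        )
        for t in typings
    ]
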