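"""Aggregate read typings into per-sample allele calls.

Complete reads carry exact repeat counts, so exact alleles are formed by
grouping complete reads on (haplotype, observed count), merging counts within
``merge_tolerance`` to the modal value (ties resolved toward the smaller
count, which is conservative toward calling a contraction).  Haplotype-only
and incomplete reads carry lower bounds; each attaches to the compatible
allele with the smallest exact count that can contain it, and leftovers found
a lower-bound allele reported as ">= max observed".

Two same-haplotype alleles of equal (or mutually unresolvable) length produce
a single read cluster.  Such duplicates are detected from read depth: every
allele contributes one distal end, so the number of reads covering pLAM in a
cluster is ~Poisson around the expected per-allele distal-end depth; a
cluster whose distal-end support significantly exceeds one allele's
expectation (one-sided z test) is emitted with the corresponding
multiplicity.  This uses no diploidy prior - one, two, or three-plus alleles
per sample are all representable, so mosaicism stays detectable.

An allele is pathogenetic iff it is 4qA with an exact repeat count <= 10;
lower bounds are never pathogenetic.  A sample is mosaic when more than two
distinct 4q alleles are supported.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .read_typing import ReadTyping

DEFAULT_MIN_SUPPORT = 2
DEFAULT_MERGE_TOLERANCE = 1
PATHOGENIC_MAX_RU = 10
#: one-sided z threshold for declaring a duplicated (multi-copy) cluster
MULTIPLICITY_Z = 3.0


@dataclass
class AlleleCall:
    sample: str
    locus: str
    haplotype: str
    ru_count: int
    is_exact: bool
    pathogenetic: bool = False
    supporting_reads: list[str] = field(default_factory=list)
    n_complete: int = 0
    #: supporting pLAM-covering reads compatible with this cluster only;
    #: the statistic behind duplicate-allele (multiplicity) detection
    n_distal: int = 0

    @property
    def n_support(self) -> int:
        return len(self.supporting_reads)

    @property
    def ru_label(self) -> str:
        return f"{self.ru_count}" if self.is_exact else f">={self.ru_count}"


@dataclass
class SampleGenotype:
    sample: str
    alleles: list[AlleleCall]

    @property
    def mosaic(self) -> bool:
        return len([a for a in self.alleles if a.locus == "4q"]) > 2

    @property
    def pathogenetic(self) -> bool:
        return any(a.pathogenetic for a in self.alleles)


def call_pathogenicity(allele: AlleleCall, max_ru: int = PATHOGENIC_MAX_RU) -> bool:
    """Pathogenetic iff 4qA with an exact count <= max_ru (default 10)."""
    return (
        allele.locus == "4q"
        and allele.haplotype == "A"
        and allele.is_exact
        and allele.ru_count <= max_ru
    )


def detect_mosaic(genotype: SampleGenotype) -> bool:
    return genotype.mosaic


def _merge_exact_counts(
    counts: list[int], merge_tolerance: int
) -> dict[int, list[int]]:
    """Greedy modal merge: {modal count: member counts}, ties to smaller modal."""
    remaining = Counter(counts)
    clusters: dict[int, list[int]] = {}
    while remaining:
        # modal value; ties -> smaller count (conservative toward contraction)
        modal = min(remaining, key=lambda v: (-remaining[v], v))
        members = []
        for v in sorted(remaining):
            if abs(v - modal) <= merge_tolerance:
                members.extend([v] * remaining[v])
        for v in set(members):
            del remaining[v]
        clusters[modal] = members
    return clusters


def cluster_alleles(
    typings: list[ReadTyping],
    sample: str,
    locus: str,
    min_support: int = DEFAULT_MIN_SUPPORT,
    merge_tolerance: int = DEFAULT_MERGE_TOLERANCE,
    expected_end_depth: float | None = None,
    pathogenic_max_ru: int = PATHOGENIC_MAX_RU,
) -> list[AlleleCall]:
    """Cluster one sample's typings at one locus into allele calls.

    ``expected_end_depth`` is the expected number of pLAM-covering reads per
    allele under the sequencing depth model (see
    :class:`nanofshd.simulate.DepthModel`); when provided, clusters whose
    distal-end support significantly exceeds it are emitted with multiplicity.
    """
    informative = [
        t for t in typings if t.chromosome == locus and t.informative
    ]
    if not informative:
        return []

    by_read = {t.read_id: t for t in informative}
    completes = [t for t in informative if t.category == "complete"]
    others = [t for t in informative if t.category != "complete"]

    # --- exact alleles from complete reads --------------------------------
    calls: list[AlleleCall] = []
    leftover_completes: list[ReadTyping] = []
    for hap in ("A", "B"):
        hap_completes = [t for t in completes if t.haplotype == hap]
        if not hap_completes:
            continue
        clusters = _merge_exact_counts(
            [t.ru_observed for t in hap_completes], merge_tolerance
        )
        pool = list(hap_completes)
        for modal, members in clusters.items():
            member_counts = Counter(members)
            support = []
            for t in list(pool):
                if member_counts.get(t.ru_observed, 0) > 0:
                    member_counts[t.ru_observed] -= 1
                    support.append(t)
                    pool.remove(t)
            if len(support) >= min_support:
                calls.append(
                    AlleleCall(
                        sample=sample,
                        locus=locus,
                        haplotype=hap,
                        ru_count=modal,
                        is_exact=True,
                        supporting_reads=[t.read_id for t in support],
                        n_complete=len(support),
                    )
                )
            else:
                leftover_completes.extend(support)
    # complete reads typed with haplotype none (should not happen) and
    # sub-threshold complete clusters are downgraded to bound evidence
    leftover_completes.extend(t for t in completes if t.haplotype not in ("A", "B"))
    others = others + leftover_completes

    # --- attach lower-bound reads ----------------------------------------
    exact_by_hap: dict[str, list[AlleleCall]] = {"A": [], "B": []}
    for c in calls:
        exact_by_hap[c.haplotype].append(c)
    for v in exact_by_hap.values():
        v.sort(key=lambda c: c.ru_count)

    leftover: dict[str, list[ReadTyping]] = {"A": [], "B": []}
    unassigned_nohap: list[ReadTyping] = []
    for t in others:
        hap = t.haplotype
        if hap in ("A", "B"):
            target = next(
                (c for c in exact_by_hap[hap] if c.ru_count + merge_tolerance >= t.ru_observed),
                None,
            )
            if target is not None:
                target.supporting_reads.append(t.read_id)
            else:
                leftover[hap].append(t)
        else:
            unassigned_nohap.append(t)

    # --- lower-bound alleles from leftovers -------------------------------
    for hap in ("A", "B"):
        group = leftover[hap]
        if len(group) >= min_support:
            bound = max(t.ru_observed for t in group)
            calls.append(
                AlleleCall(
                    sample=sample,
                    locus=locus,
                    haplotype=hap,
                    ru_count=bound,
                    is_exact=False,
                    supporting_reads=[t.read_id for t in group],
                )
            )

    # incomplete (haplotype-less) reads: attach when exactly one compatible
    # home exists; otherwise they only inform the marker flag
    bound_calls = [c for c in calls if not c.is_exact]
    for t in unassigned_nohap:
        compatible = [
            c for c in calls
            if (c.is_exact and c.ru_count + merge_tolerance >= t.ru_observed)
        ] + bound_calls
        if len(compatible) == 1:
            compatible[0].supporting_reads.append(t.read_id)

    # --- distal-end support per cluster ----------------------------------
    # Count, per cluster, the pLAM-covering reads that are compatible with
    # that cluster ONLY (a short distal read from a longer same-haplotype
    # allele is compatible with several clusters and must not inflate the
    # small one).  Every allele contributes exactly one distal end, so this
    # statistic is ~constant per allele and doubles when two same-length
    # alleles merge into one cluster.
    def _read_compatible(t: ReadTyping, c: AlleleCall) -> bool:
        if t.haplotype != c.haplotype:
            return False
        if t.category == "complete":
            return c.is_exact and abs(t.ru_observed - c.ru_count) <= merge_tolerance
        if c.is_exact:
            return t.ru_observed <= c.ru_count + merge_tolerance
        return True  # lower-bound allele: length unresolved

    for c in calls:
        n_end = 0
        same_hap = [x for x in calls if x.haplotype == c.haplotype]
        for rid in c.supporting_reads:
            t = by_read.get(rid)
            if t is None or not t.has_plam:
                continue
            if sum(_read_compatible(t, x) for x in same_hap) == 1:
                n_end += 1
        c.n_distal = n_end

    # pLAM-covering reads with no countable unit are uninformative for repeat
    # counting but still mark one distal end with a haplotype; credit them to
    # the cluster when it is the only same-haplotype candidate
    for t in typings:
        if (
            t.chromosome == locus
            and not t.informative
            and t.has_plam
            and t.haplotype in ("A", "B")
        ):
            same_hap = [c for c in calls if c.haplotype == t.haplotype]
            if len(same_hap) == 1:
                same_hap[0].n_distal += 1

    if expected_end_depth is not None and expected_end_depth > 0:
        apply_multiplicity(calls, expected_end_depth)

    for c in calls:
        c.pathogenetic = call_pathogenicity(c, pathogenic_max_ru)
    calls.sort(key=lambda c: (c.haplotype, not c.is_exact, c.ru_count))
    return calls


def apply_multiplicity(calls: list[AlleleCall], lam: float) -> None:
    """Emit duplicate alleles for clusters whose distal-end support
    significantly exceeds the per-allele expectation ``lam`` (one-sided z
    test at ``MULTIPLICITY_Z``)."""
    threshold = lam + MULTIPLICITY_Z * math.sqrt(lam)
    for c in list(calls):
        if c.n_distal > threshold:
            mult = max(2, int(round(c.n_distal / lam)))
            for _ in range(mult - 1):
                calls.append(
                    AlleleCall(
                        sample=c.sample,
                        locus=c.locus,
                        haplotype=c.haplotype,
                        ru_count=c.ru_count,
                        is_exact=False,  # the duplicate's length is unresolved
                        supporting_reads=list(c.supporting_reads),
                        n_distal=c.n_distal,
                    )
                )


def call_genotypes(
    typings_by_sample: dict[str, list[ReadTyping]],
    locus: str = "4q",
    min_support: int = DEFAULT_MIN_SUPPORT,
    merge_tolerance: int = DEFAULT_MERGE_TOLERANCE,
    expected_end_depth: float | None = None,
    min_clusters_for_calibration: int = 8,
) -> dict[str, SampleGenotype]:
    """Cluster every sample, then resolve allele multiplicity cohort-wide.

    The per-allele distal-end depth is self-calibrated as the median
    ``n_distal`` over all clusters in the cohort (single-allele clusters
    dominate); with fewer than ``min_clusters_for_calibration`` clusters the
    provided ``expected_end_depth`` (sequencing-model expectation) is used
    instead.
    """
    out = {}
    for sample, typings in sorted(typings_by_sample.items()):
        alleles = cluster_alleles(
            typings,
            sample,
            locus,
            min_support=min_support,
            merge_tolerance=merge_tolerance,
            expected_end_depth=None,
        )
        out[sample] = SampleGenotype(sample, alleles)

    all_distal = [a.n_distal for g in out.values() for a in g.alleles]
    if len(all_distal) >= min_clusters_for_calibration:
        lam = float(np.median(all_distal))
    else:
        lam = expected_end_depth or 0.0
    if lam > 0:
        for geno in out.values():
            apply_multiplicity(geno.alleles, lam)
            for a in geno.alleles:
                a.pathogenetic = call_pathogenicity(a)
            geno.alleles.sort(
                key=lambda c: (c.haplotype, not c.is_exact, c.ru_count)
            )
    return out


# ---------------------------------------------------------------------------
# Concordance against an orthogonal truth table
# ---------------------------------------------------------------------------

def _allele_concordant(call: AlleleCall, truth_hap: str, truth_ru: int) -> bool:
    if call.haplotype != truth_hap:
        return False
    if call.is_exact:
        return call.ru_count == truth_ru
    return call.ru_count <= truth_ru  # a lower bound must not exceed the truth


def concordance_report(
    genotypes: dict[str, SampleGenotype],
    truth: pd.DataFrame,
    locus: str = "4q",
    pathogenic_max_ru: int = PATHOGENIC_MAX_RU,
) -> pd.DataFrame:
    """Per-sample concordance of calls against a truth genotype table.

    ``truth`` needs columns sample, haplotype, ru (exact counts).  A sample
    is pathogenetic-status concordant when call and truth agree on the
    presence/absence of a 4qA allele with <= 10 repeat units.  Per-allele
    concordance pairs calls with truth alleles (best assignment over
    permutations): exact calls must match the count, bound calls must not
    exceed it.
    """
    rows = []
    truth_by_sample = dict(tuple(truth.groupby("sample")))
    for sample, geno in sorted(genotypes.items()):
        calls = [a for a in geno.alleles if a.locus == locus]
        if sample not in truth_by_sample:
            rows.append(
                dict(sample=sample, in_truth=False, n_calls=len(calls))
            )
            continue
        tr = truth_by_sample[sample]
        t_haps = list(tr["haplotype"])
        t_rus = [int(v) for v in tr["ru"]]
        truth_path = any(
            h == "A" and r <= pathogenic_max_ru for h, r in zip(t_haps, t_rus)
        )
        call_path = any(a.pathogenetic for a in calls)

        # best pairing of calls to distinct truth alleles
        n_conc = 0
        k = min(len(calls), len(t_haps))
        if calls and t_haps:
            best = 0
            idx = range(len(t_haps))
            for perm in itertools.permutations(idx, k):
                score = sum(
                    _allele_concordant(calls[i], t_haps[j], t_rus[j])
                    for i, j in enumerate(perm)
                )
                best = max(best, score)
            n_conc = best
        hap_conc = Counter(a.haplotype for a in calls) == Counter(t_haps)
        rows.append(
            dict(
                sample=sample,
                in_truth=True,
                n_calls=len(calls),
                n_truth=len(t_haps),
                pathogenetic_call=call_path,
                pathogenetic_truth=truth_path,
                pathogenetic_concordant=call_path == truth_path,
                haplotypes_concordant=hap_conc,
                alleles_concordant=n_conc,
            )
        )
    return pd.DataFrame(rows)


def genotypes_to_table(genotypes: dict[str, SampleGenotype]) -> pd.DataFrame:
    rows = []
    for sample, geno in sorted(genotypes.items()):
        for a in geno.alleles:
            rows.append(
                dict(
                    sample=sample,
                    locus=a.locus,
                    haplotype=a.haplotype,
                    ru=a.ru_label,
                    pathogenetic="Y" if a.pathogenetic else "N",
                    n_support=a.n_support,
                    n_complete=a.n_complete,
                    mosaic="Y" if geno.mosaic else "N",
                )
            )
    return pd.DataFrame(rows)
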