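"""Overall and allele-specific CpG methylation of the DUX4 regions.

Methylation input is per-read CpG calls (read id, position, probability of
5-methyl-cytosine), e.g. exported from a modified-base caller.  Positions are
expressed relative to the start of the most distal D4Z4 unit (the methylation
target region), which makes the region definitions - distal unit, *DUX4*
upstream, *DUX4* gene body - identical for alleles of any repeat length.

A region's methylation level is the ratio of methylated calls (probability >=
0.5, inclusive) to total calls in the region, the same ratio definition used
for clone-based bisulfite summaries.  Allele-specific levels restrict the
ratio to reads confidently assigned to one allele; the pooled ("overall")
level over all assigned 4qA reads therefore equals the call-count-weighted
mean of the per-allele levels exactly.

Hypomethylation of a contracted (pathogenetic) 4qA allele can be masked in
the pooled level by a hypermethylated non-pathogenetic 4qA allele; the
allele-specific profiles exist precisely to expose that case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_caller import AlleleCall
from .feature_library import RegionDefinition, distal_regions
from .read_typing import ReadTyping

logger = logging.getLogger(__name__)

DEFAULT_PROB_THRESHOLD = 0.5


@dataclass(frozen=True)
class CpGCall:
    read_id: str
    position: int
    prob_methylated: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_methylated <= 1.0:
            raise ValueError(
                f"prob_methylated must be in [0, 1], got {self.prob_methylated}"
            )


@dataclass
class MethylationProfile:
    scope: str  # "overall" or an allele id
    level_upstream: float | None
    level_gene_body: float | None
    n_calls_upstream: int
    n_calls_gene_body: int

    def as_percent(self) -> dict:
        return dict(
            scope=self.scope,
            upstream_percent=(
                round(100.0 * self.level_upstream, 2)
                if self.level_upstream is not None else None
            ),
            gene_body_percent=(
                round(100.0 * self.level_gene_body, 2)
                if self.level_gene_body is not None else None
            ),
            n_calls_upstream=self.n_calls_upstream,
            n_calls_gene_body=self.n_calls_gene_body,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_cpg_calls(
    path: str | Path, registry: np.ndarray | None = None
) -> pd.DataFrame:
    """Load a CpG-call TSV (read_id, position, prob_methylated).

    Probabilities outside [0, 1] raise; with a CpG position ``registry`` the
    positions are validated against it.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "position", "prob_methylated"}
    if not required.issubset(df.columns):
        raise ValueError(f"CpG-call TSV must have columns {sorted(required)}")
    p = df["prob_methylated"]
    if ((p < 0) | (p > 1)).any():
        bad = df.loc[(p < 0) | (p > 1)].iloc[0]
        raise ValueError(
            f"prob_methylated outside [0, 1] at read {bad['read_id']}: "
            f"{bad['prob_methylated']}"
        )
    if registry is not None:
        known = np.isin(df["position"].to_numpy(), registry)
        if not known.all():
            raise ValueError(
                f"{(~known).sum()} CpG calls at positions absent from the registry"
            )
    return df


def write_cpg_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def binarize(
    prob: float | np.ndarray | CpGCall, threshold: float = DEFAULT_PROB_THRESHOLD
):
    """Methylated iff probability >= threshold (inclusive boundary)."""
    if isinstance(prob, CpGCall):
        prob = prob.prob_methylated
    return np.asarray(prob) >= threshold if isinstance(prob, np.ndarray) else prob >= threshold


# ---------------------------------------------------------------------------
# Region means
# ---------------------------------------------------------------------------

def region_mean(
    calls: pd.DataFrame,
    region: RegionDefinition,
    read_subset: set[str] | None = None,
    threshold: float = DEFAULT_PROB_THRESHOLD,
) -> tuple[float | None, int]:
    """(methylated / total, total) over calls in the region, or (None, 0)."""
    if len(region) <= 0:
        raise ValueError("empty region")
    mask = (calls["position"] >= region.start) & (calls["position"] < region.end)
    if read_subset is not None:
        mask &= calls["read_id"].isin(read_subset)
    sub = calls.loc[mask, "prob_methylated"]
    n = int(len(sub))
    if n == 0:
        return None, 0
    return float((sub >= threshold).mean()), n


def _profile(
    calls: pd.DataFrame,
    regions: dict[str, RegionDefinition],
    reads: set[str] | None,
    scope: str,
    threshold: float,
) -> MethylationProfile:
    up, n_up = region_mean(calls, regions["dux4_upstream"], reads, threshold)
    gb, n_gb = region_mean(calls, regions["dux4_gene_body"], reads, threshold)
    return MethylationProfile(scope, up, gb, n_up, n_gb)


# ---------------------------------------------------------------------------
# Allele-specific analysis
# ---------------------------------------------------------------------------

def assign_reads_to_alleles(
    alleles: list[AlleleCall],
    typings: list[ReadTyping],
    merge_tolerance: int = 1,
) -> dict[str, int]:
    """read_id -> allele index, for reads compatible with exactly one allele.

    Compatibility: a complete read belongs to the exact allele matching its
    count; a lower-bound read can belong to any exact allele whose count can
    contain it and to any lower-bound allele.  Ambiguous reads are dropped -
    methylation purity matters more than depth here.
    """
    by_read = {t.read_id: t for t in typings}
    out: dict[str, int] = {}
    read_ids = {rid for a in alleles for rid in a.supporting_reads}
    for rid in read_ids:
        t = by_read.get(rid)
        if t is None:
            continue
        compat = []
        for i, a in enumerate(alleles):
            if t.haplotype != "none" and t.haplotype != a.haplotype:
                continue
            if t.category == "complete":
                ok = a.is_exact and abs(t.ru_observed - a.ru_count) <= merge_tolerance
            elif a.is_exact:
                ok = t.ru_observed <= a.ru_count + merge_tolerance
            else:
                ok = True
            if ok:
                compat.append(i)
        if len(compat) == 1:
            out[rid] = compat[0]
    return out


def allele_specific_profiles(
    alleles: list[AlleleCall],
    typings: list[ReadTyping],
    calls: pd.DataFrame,
    regions: dict[str, RegionDefinition] | None = None,
    haplotype: str = "A",
    threshold: float = DEFAULT_PROB_THRESHOLD,
) -> tuple[dict[int, MethylationProfile], MethylationProfile]:
    """Per-allele profiles for one haplotype plus the pooled overall profile.

    Returns ({allele index: profile}, overall); alleles without any assigned
    methylation call are omitted with a warning.  The overall profile pools
    the calls of all assigned reads, so it equals the call-count-weighted
    mean of the per-allele levels.
    """
    if regions is None:
        regions = distal_regions()
    targets = [
        (i, a) for i, a in enumerate(alleles) if a.haplotype == haplotype
    ]
    assignment = assign_reads_to_alleles(alleles, typings)
    per_allele: dict[int, MethylationProfile] = {}
    pooled_reads: set[str] = set()
    for i, a in targets:
        reads = {rid for rid, j in assignment.items() if j == i}
        prof = _profile(calls, regions, reads, f"allele{i}:{a.haplotype}{a.ru_label}", threshold)
        if prof.n_calls_upstream == 0 and prof.n_calls_gene_body == 0:
            logger.warning(
                "allele %s%s of %s has no assigned methylation calls; omitted",
                a.haplotype, a.ru_label, a.sample,
            )
            continue
        per_allele[i] = prof
        pooled_reads |= reads
    overall = _profile(calls, regions, pooled_reads, "overall", threshold)
    return per_allele, overall


def profiles_to_table(
    sample: str, per_allele: dict[int, MethylationProfile], overall: MethylationProfile
) -> pd.DataFrame:
    rows = []
    for prof in list(per_allele.values()) + [overall]:
        d = prof.as_percent()
        d["sample"] = sample
        rows.append(d)
    return pd.DataFrame(rows)
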