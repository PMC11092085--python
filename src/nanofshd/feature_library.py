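"""Feature sequences and synthetic allele references for the 4q35/10q26 D4Z4 loci.

The genotyping workflow is read-centric: instead of mapping reads to a whole
reference genome, it aligns a small library of locus-discriminating feature
sequences against each read.  The library holds, for each locus (4q35 and its
10q26 paralog), the proximal single-copy anchor *D4F104S1*, the 3.3-kb D4Z4
repeat unit, and the two haplotype-discriminating *pLAM* variants (4qA carries
the *DUX4* polyadenylation signal; 4qB does not).

Real feature sequences are supplied by the user as FASTA with headers of the
form ``name|locus|haplotype`` (e.g. ``pLAM_A|4q|A``; haplotype ``-`` for
non-pLAM features).  For fully self-contained simulation and testing,
:func:`synth_feature_set` builds a synthetic library in which the 10q paralogs
diverge from their 4q counterparts at a configurable rate (~2% mimics the real
D4Z4/10q26 homology) and CpG dinucleotides are planted at a configurable
density so that methylation analysis has realistic targets.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_NAMES = ("D4F104S1", "D4Z4", "pLAM_A", "pLAM_B")
LOCI = ("4q", "10q")

#: Default feature lengths for the synthetic library (bp).  The D4Z4 unit
#: length is the biological 3.3 kb; anchor lengths only affect simulation
#: realism, not the algorithms.
DEFAULT_UNIT_LEN = 3300
DEFAULT_ANCHOR_LENS = {"D4F104S1": 1500, "pLAM": 500}
DEFAULT_FLANK_LEN = 5000

#: Fraction of the distal D4Z4 unit that lies upstream of the *DUX4* gene
#: body.  The gene body runs from this breakpoint through the end of pLAM
#: (DUX4 exons extend from the distal unit into pLAM); the upstream region is
#: the remainder of the distal unit.  The exact breakpoint only determines
#: which CpGs are attributed to which region.
UPSTREAM_FRACTION = 0.4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN#", b"TGCAN#"):
    _COMP[_a] = _b


class FormatError(ValueError):
    """Malformed FASTA header or record."""


class ValidationError(ValueError):
    """Library content violates an invariant (e.g. duplicate entries)."""


def encode(seq: str | bytes) -> np.ndarray:
    """Nucleotide string -> uint8 array of ASCII codes (upper-cased)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return np.frombuffer(seq.upper(), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


@dataclass(frozen=True)
class FeatureSequence:
    """One feature sequence tagged with its locus and haplotype."""

    name: str
    locus: str
    haplotype: str  # "A" | "B" | "none"
    sequence: str

    def __post_init__(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise ValidationError(f"unknown feature name {self.name!r}")
        if self.locus not in LOCI:
            raise ValidationError(f"unknown locus {self.locus!r}")
        if not self.sequence:
            raise ValidationError(f"{self.name}|{self.locus}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValidationError(
                f"{self.name}|{self.locus}: alphabet not a subset of ACGT"
            )
        if self.name.startswith("pLAM"):
            if self.haplotype not in ("A", "B"):
                raise ValidationError(
                    f"{self.name}|{self.locus}: pLAM must carry haplotype A or B"
                )
        elif self.haplotype != "none":
            raise ValidationError(
                f"{self.name}|{self.locus}: non-pLAM feature with haplotype"
            )

    @property
    def array(self) -> np.ndarray:
        return encode(self.sequence)


@dataclass(frozen=True)
class RegionDefinition:
    """Named interval on an allele sequence (0-based half-open)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"region {self.name}: end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "RegionDefinition":
        return RegionDefinition(self.name, self.start + offset, self.end + offset)


@dataclass
class FeatureLibrary:
    """Collection of feature sequences, keyed by (name, locus)."""

    entries: dict[tuple[str, str], FeatureSequence] = field(default_factory=dict)

    def add(self, feat: FeatureSequence) -> None:
        key = (feat.name, feat.locus)
        if key in self.entries:
            raise ValidationError(f"duplicate feature {feat.name}|{feat.locus}")
        self.entries[key] = feat

    def get(self, name: str, locus: str) -> FeatureSequence:
        try:
            return self.entries[(name, locus)]
        except KeyError:
            raise ValidationError(f"library is missing {name}|{locus}") from None

    def has(self, name: str, locus: str) -> bool:
        return (name, locus) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def plam(self, locus: str, haplotype: str) -> FeatureSequence:
        return self.get(f"pLAM_{haplotype}", locus)


@dataclass
class AnnotatedAllele:
    """A synthetic allele reference: flank + D4F104S1 + D4Z4 x RU + pLAM + flank.

    ``annotations`` lists (feature name, start, end) in allele coordinates,
    ordered and non-overlapping.  ``regions`` holds the methylation target
    intervals: the most distal D4Z4 unit, the *DUX4* upstream region (distal
    unit start to the gene-body breakpoint) and the *DUX4* gene body
    (breakpoint through the end of pLAM).
    """

    allele_id: str
    locus: str
    haplotype: str
    ru_count: int
    sequence: str
    annotations: list[tuple[str, int, int]]
    cpg_positions: np.ndarray
    regions: dict[str, RegionDefinition]

    @property
    def array(self) -> np.ndarray:
        return encode(self.sequence)

    @property
    def distal_unit_start(self) -> int:
        return self.regions["distal_unit"].start

    def to_distal_frame(self, positions: np.ndarray) -> np.ndarray:
        """Allele coordinates -> coordinates relative to the distal unit start."""
        return np.asarray(positions) - self.distal_unit_start


def distal_regions(
    unit_len: int = DEFAULT_UNIT_LEN,
    plam_len: int = DEFAULT_ANCHOR_LENS["pLAM"],
    upstream_fraction: float = UPSTREAM_FRACTION,
) -> dict[str, RegionDefinition]:
    """Region definitions in the distal frame (0 = distal D4Z4 unit start).

    This frame is shared by all alleles regardless of repeat count, which is
    what makes per-allele methylation levels comparable across alleles.
    """
    split = int(round(upstream_fraction * unit_len))
    return {
        "distal_unit": RegionDefinition("distal_unit", 0, unit_len),
        "dux4_upstream": RegionDefinition("dux4_upstream", 0, split),
        "dux4_gene_body": RegionDefinition("dux4_gene_body", split, unit_len + plam_len),
    }


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) != 3:
        raise FormatError(
            f"header {header!r} does not follow the name|locus|haplotype convention"
        )
    name, locus, hap = parts
    if hap in ("-", "", "none"):
        hap = "none"
    return name, locus, hap


def load_features(fasta_path: str | Path | io.TextIOBase) -> FeatureLibrary:
    """Load a feature library from FASTA with ``name|locus|haplotype`` headers."""
    lib = FeatureLibrary()
    for rec in SeqIO.parse(fasta_path, "fasta"):
        name, locus, hap = _parse_header(rec.id)
        lib.add(FeatureSequence(name, locus, hap, str(rec.seq).upper()))
    return lib


def write_features(lib: FeatureLibrary, fasta_path: str | Path) -> None:
    recs = []
    for feat in lib:
        hap = feat.haplotype if feat.haplotype != "none" else "-"
        recs.append(
            SeqRecord(Seq(feat.sequence), id=f"{feat.name}|{feat.locus}|{hap}",
                      description="")
        )
    SeqIO.write(recs, str(fasta_path), "fasta")


def write_regions_bed(
    allele: AnnotatedAllele, bed_path: str | Path, chrom: str | None = None
) -> None:
    """Write the allele's region definitions as BED (0-based half-open)."""
    chrom = chrom or allele.allele_id
    with open(bed_path, "w") as fh:
        for region in allele.regions.values():
            fh.write(f"{chrom}\t{region.start}\t{region.end}\t{region.name}\n")


# ---------------------------------------------------------------------------
# Synthetic library
# ---------------------------------------------------------------------------

def _random_seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute ~rate of positions (binomially sampled) with a different base."""
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    idx = np.searchsorted(_BASES, out[mask])
    out[mask] = _BASES[(idx + 1 + rng.integers(0, 3, mask.sum())) % 4]
    return out


def _plant_cpgs(seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    out = seq.copy()
    out[positions] = ord("C")
    out[positions + 1] = ord("G")
    return out


def synth_feature_set(
    unit_len: int = DEFAULT_UNIT_LEN,
    anchor_lens: dict[str, int] | None = None,
    paralog_divergence: float = 0.02,
    haplotype_divergence: float = 0.10,
    cpg_density: float = 0.02,
    seed: int = 0,
) -> FeatureLibrary:
    """Generate a synthetic feature library.

    The 4q features are random sequence; the 10q paralogs differ from them at
    ~``paralog_divergence`` of positions (binomially sampled), and pLAM_B
    differs from pLAM_A at ~``haplotype_divergence``.  CpG dinucleotides are
    planted at ~``cpg_density`` per bp at positions shared between the 4q and
    10q variants (re-planted after divergence mutation), so most CpG sites are
    common to the paralogs as they are in the real loci.  Deterministic for a
    fixed seed.
    """
    for label, div in (("paralog", paralog_divergence), ("haplotype", haplotype_divergence)):
        if not 0.0 <= div <= 0.2:
            raise ValueError(f"{label}_divergence must be in [0, 0.2], got {div}")
    if not 0.0 <= cpg_density <= 0.2:
        raise ValueError(f"cpg_density must be in [0, 0.2], got {cpg_density}")
    anchor_lens = dict(DEFAULT_ANCHOR_LENS, **(anchor_lens or {}))
    rng = np.random.default_rng(seed)
    lib = FeatureLibrary()

    def cpg_sites(n: int) -> np.ndarray:
        k = int(round(cpg_density * n))
        if k == 0:
            return np.empty(0, dtype=np.int64)
        # sample non-adjacent positions so planted CGs never overlap
        cand = rng.choice(np.arange(0, n - 1, 2), size=min(k, (n - 1) // 2),
                          replace=False)
        return np.sort(cand)

    specs = [
        ("D4F104S1", anchor_lens["D4F104S1"], "none"),
        ("D4Z4", unit_len, "none"),
        ("pLAM_A", anchor_lens["pLAM"], "A"),
    ]
    base_seqs: dict[str, np.ndarray] = {}
    site_map: dict[str, np.ndarray] = {}
    for name, length, hap in specs:
        sites = cpg_sites(length)
        seq4 = _plant_cpgs(_random_seq(length, rng), sites)
        base_seqs[name] = seq4
        site_map[name] = sites
        lib.add(FeatureSequence(name, "4q", hap, decode(seq4)))

    # pLAM_B derives from pLAM_A by haplotype divergence (same CpG scaffold)
    plam_b = _plant_cpgs(_mutate(base_seqs["pLAM_A"], haplotype_divergence, rng),
                         site_map["pLAM_A"])
    base_seqs["pLAM_B"] = plam_b
    site_map["pLAM_B"] = site_map["pLAM_A"]
    lib.add(FeatureSequence("pLAM_B", "4q", "B", decode(plam_b)))

    for name in ("D4F104S1", "D4Z4", "pLAM_A", "pLAM_B"):
        hap = name[-1] if name.startswith("pLAM") else "none"
        seq10 = _plant_cpgs(_mutate(base_seqs[name], paralog_divergence, rng),
                            site_map[name])
        lib.add(FeatureSequence(name, "10q", hap, decode(seq10)))
    return lib


def _flank_seq(length: int, locus: str, haplotype: str, which: str, seed: int) -> np.ndarray:
    """Deterministic flank: proximal flanks shared per locus, distal per haplotype."""
    if which == "prox":
        key = f"{seed}:{locus}:prox"
    else:
        key = f"{seed}:{locus}:{haplotype}:dist"
    rng = np.random.default_rng(zlib.crc32(key.encode()))
    return _random_seq(length, rng)


def build_allele_sequence(
    library: FeatureLibrary,
    locus: str,
    haplotype: str,
    ru_count: int,
    flank_lens: tuple[int, int] = (DEFAULT_FLANK_LEN, DEFAULT_FLANK_LEN),
    allele_id: str | None = None,
    flank_seed: int = 0,
) -> AnnotatedAllele:
    """Assemble an annotated allele: flank + D4F104S1 + RU x D4Z4 + pLAM + flank."""
    if ru_count < 1:
        raise ValueError(f"ru_count must be >= 1, got {ru_count}")
    anchor = library.get("D4F104S1", locus).array
    unit = library.get("D4Z4", locus).array
    plam = library.plam(locus, haplotype).array
    left = _flank_seq(flank_lens[0], locus, haplotype, "prox", flank_seed)
    right = _flank_seq(flank_lens[1], locus, haplotype, "dist", flank_seed)

    parts = [left, anchor] + [unit] * ru_count + [plam, right]
    seq = np.concatenate(parts)

    annotations: list[tuple[str, int, int]] = []
    pos = len(left)
    annotations.append(("D4F104S1", pos, pos + len(anchor)))
    pos += len(anchor)
    for _ in range(ru_count):
        annotations.append(("D4Z4", pos, pos + len(unit)))
        pos += len(unit)
    plam_name = f"pLAM_{haplotype}"
    annotations.append((plam_name, pos, pos + len(plam)))
    pos += len(plam)

    distal_start = annotations[-2][1]  # start of the last D4Z4 unit
    rel = distal_regions(len(unit), len(plam))
    regions = {name: r.shift(distal_start) for name, r in rel.items()}

    arr = seq
    cg = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]

    return AnnotatedAllele(
        allele_id=allele_id or f"{locus}{haplotype}_{ru_count}RU",
        locus=locus,
        haplotype=haplotype,
        ru_count=ru_count,
        sequence=decode(seq),
        annotations=annotations,
        cpg_positions=cg,
        regions=regions,
    )
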