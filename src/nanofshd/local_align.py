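"""Local alignment of feature sequences against reads, with bitscore output.

Reads are classified between the homologous 4q35 and 10q26 loci by comparing
local-alignment bitscores of locus-specific feature sequences, so this module
provides two engines with the same hit contract:

``dp``
    Exact affine-gap Smith-Waterman, row-vectorised with numpy, with
    mask-and-realign to recover multiple non-overlapping hits.  This is the
    reference semantics and is used for small instances and in tests.

``fast``
    Seed-and-align: strided k-mer seeds locate candidate windows on the read
    (one window per tandem-repeat copy, since copies sit on well-separated
    alignment diagonals), and each window is scored with a banded edit-distance
    alignment (edlib).  Raw scores are derived from the edit distance, which
    slightly underestimates the optimal affine score for gap-rich alignments;
    tests verify agreement with the ``dp`` engine on realistic instances.
    This is what the cohort-scale pipeline runs.

Raw scores are converted to bits with the Karlin-Altschul normalisation
``(lambda * S - ln K) / ln 2``.  Bitscores are only ever compared with each
other, so the absolute calibration of lambda and K is immaterial; the classic
ungapped BLASTN constants are used as a fixed normalisation.

A gap of length ``g`` scores ``gap_open + g * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import edlib
import numpy as np

from .feature_library import FeatureLibrary, FeatureSequence, decode, encode, revcomp

LN2 = math.log(2.0)
_MASK_SCORE = -1.0e9  # sentinel score: alignments never cross a masked span


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -2
    gap_extend: int = -1
    lambda_: float = 1.28
    k_: float = 0.46

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if not 0 < self.k_ < 1:
            raise ValueError("K must be in (0, 1)")


DEFAULT_SCHEME = ScoringScheme()

#: Default hit acceptance threshold (bits) for anchors and pLAM.
DEFAULT_MIN_BITSCORE = 50.0
#: A D4Z4 hit counts as one repeat unit only if it covers >= this fraction of
#: the unit, preventing partial edge units from inflating repeat counts.
DEFAULT_MIN_UNIT_COVERAGE = 0.6


def bitscore(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul normalised score in bits: (lambda*S - ln K) / ln 2."""
    return (scheme.lambda_ * raw_score - math.log(scheme.k_)) / LN2


@dataclass
class AlignmentHit:
    feature: str
    read_id: str
    read_start: int
    read_end: int  # half-open
    strand: str
    raw_score: float
    bitscore: float
    identity: float
    feature_coverage: float
    locus: str = ""
    haplotype: str = "none"

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start:
            raise ValueError("read_end must exceed read_start")

    @property
    def span(self) -> int:
        return self.read_end - self.read_start


# ---------------------------------------------------------------------------
# Exact DP engine
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _codes(arr: np.ndarray) -> np.ndarray:
    return _CODE[arr]


def _score_profile(qc: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    """(5, m) score of each possible target code against every query position."""
    prof = np.full((5, len(qc)), float(scheme.mismatch))
    for c in range(4):
        prof[c, qc == c] = scheme.match
    prof[4, :] = _MASK_SCORE
    prof[:, qc == 4] = _MASK_SCORE
    return prof


def sw_affine(
    query: np.ndarray, target: np.ndarray, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[float, int, int, int, int, int, int]:
    """Exact local affine alignment.

    Returns (score, q_start, q_end, t_start, t_end, matches, columns) for the
    best-scoring local alignment (ties broken toward the smallest target end
    position, then smallest query end).  Score 0 means no positive-scoring
    alignment exists.
    """
    qc, tc = _codes(query), _codes(target)
    m, n = len(qc), len(tc)
    if m == 0 or n == 0:
        return 0.0, 0, 0, 0, 0, 0, 0
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    prof = _score_profile(qc, scheme)

    neg = -1.0e18
    H_prev = np.zeros(m + 1)
    E_prev = np.full(m + 1, neg)
    # pointer codes per cell: 0 stop, 1 diag, 2 from E (gap in query), 3 from F
    ptr = np.zeros((n, m), dtype=np.uint8)
    ext_e = np.zeros((n, m), dtype=bool)  # E extended from E above
    ext_f = np.zeros((n, m), dtype=bool)  # F extended from F left
    best, bi, bj = 0.0, 0, 0

    for i in range(n):
        s = prof[tc[i]]
        diag = H_prev[:-1] + s
        open_e = H_prev[1:] + go + ge
        cont_e = E_prev[1:] + ge
        E = np.maximum(open_e, cont_e)
        ext_e[i] = cont_e > open_e

        H_pre = np.maximum(diag, E)
        np.maximum(H_pre, 0.0, out=H_pre)

        # F via prefix-max: F[j] = go + (j+1)*ge + max_{j'<=j}(Hrow[j'] - j'*ge)
        # where Hrow includes the zero boundary column.
        jj = np.arange(m + 1)
        A = np.concatenate(([0.0], H_pre)) - jj * ge
        P = np.maximum.accumulate(A)[:-1]
        F = go + (jj[1:]) * ge + P

        H = np.maximum(H_pre, F)
        if m > 1:
            # F[j] >= F[j-1]+ge always holds; equality means the gap extends
            ext_f[i, 1:] = np.isclose(F[1:], F[:-1] + ge)
        # pointer bookkeeping
        p = np.zeros(m, dtype=np.uint8)
        p[np.isclose(H, E) & (H > 0)] = 2
        p[np.isclose(H, diag) & (H > 0)] = 1
        p[(F > H_pre) & (H > 0)] = 3
        ptr[i] = p

        row_best = H.max()
        if row_best > best:
            best = float(row_best)
            bi, bj = i, int(np.argmax(H))

        H_prev = np.concatenate(([0.0], H))
        E_prev = np.concatenate(([neg], E))

    if best <= 0:
        return 0.0, 0, 0, 0, 0, 0, 0

    # traceback (H/E/F pointers); re-derive E/F runs greedily
    i, j = bi, bj
    matches = cols = 0
    qe, te = bj + 1, bi + 1
    state = "H"
    while i >= 0 and j >= 0:
        if state == "H":
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if qc[j] == tc[i]:
                    matches += 1
                i -= 1
                j -= 1
                if i < 0 or j < 0:
                    break
                continue
            state = "E" if p == 2 else "F"
            continue
        if state == "E":
            cols += 1
            extended = ext_e[i, j]
            i -= 1
            state = "E" if extended else "H"
            if i < 0:
                break
            continue
        cols += 1
        extended = ext_f[i, j]
        j -= 1
        state = "F" if extended else "H"
        if j < 0:
            break
    qs, ts = j + 1, i + 1
    return best, qs, qe, ts, te, matches, cols


def sw_score_only(
    query: np.ndarray, target: np.ndarray, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Best local affine score only (used by property tests on larger pairs)."""
    qc, tc = _codes(query), _codes(target)
    m, n = len(qc), len(tc)
    if m == 0 or n == 0:
        return 0.0
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    prof = _score_profile(qc, scheme)
    neg = -1.0e18
    H_prev = np.zeros(m + 1)
    E_prev = np.full(m + 1, neg)
    jj = np.arange(m + 1)
    best = 0.0
    for i in range(n):
        s = prof[tc[i]]
        E = np.maximum(H_prev[1:] + go + ge, E_prev[1:] + ge)
        H_pre = np.maximum(np.maximum(H_prev[:-1] + s, E), 0.0)
        A = np.concatenate(([0.0], H_pre)) - jj * ge
        F = go + jj[1:] * ge + np.maximum.accumulate(A)[:-1]
        H = np.maximum(H_pre, F)
        b = H.max()
        if b > best:
            best = float(b)
        H_prev = np.concatenate(([0.0], H))
        E_prev = np.concatenate(([neg], E))
    return best


def _align_local_dp(
    feature: np.ndarray,
    read: np.ndarray,
    scheme: ScoringScheme,
    min_bitscore: float,
    max_hits: int = 64,
) -> list[dict]:
    """Mask-and-realign exact SW: returns raw hit dicts on one strand."""
    work = read.copy()
    hits: list[dict] = []
    flen = len(feature)
    for _ in range(max_hits):
        score, qs, qe, ts, te, matches, cols = sw_affine(feature, work, scheme)
        if score <= 0 or bitscore(score, scheme) < min_bitscore:
            break
        hits.append(
            dict(
                read_start=ts,
                read_end=te,
                raw_score=score,
                identity=matches / cols if cols else 0.0,
                feature_coverage=(qe - qs) / flen,
            )
        )
        work[ts:te] = ord("#")
    return hits


# ---------------------------------------------------------------------------
# Fast seeded engine
# ---------------------------------------------------------------------------

def _kmer_codes(arr: np.ndarray, k: int, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes and their start positions (invalid dropped)."""
    v = _CODE[arr].astype(np.int64)
    n = len(v) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    bad = (v >= 4).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    invalid = (cbad[k:] - cbad[:-k]) > 0
    codes = np.zeros(n, dtype=np.int64)
    vv = np.where(v >= 4, 0, v)
    for i in range(k):
        codes = codes * 4 + vv[i : n + i]
    pos = np.arange(0, n, stride)
    codes = codes[pos]
    keep = ~invalid[pos]
    return codes[keep], pos[keep]


@dataclass
class _Entry:
    name: str
    locus: str
    haplotype: str
    arr: np.ndarray
    seq: str


class FeatureScanner:
    """Seeded scanner over a feature library; reusable across reads.

    ``k``/``stride`` control seeding sensitivity; with ~2% paralog divergence
    and ~5% read error, 15-mers at stride 2 give hundreds of seeds per true
    repeat copy, so ``min_seeds`` is a loose noise floor.
    """

    def __init__(
        self,
        library: FeatureLibrary,
        scheme: ScoringScheme = DEFAULT_SCHEME,
        min_bitscore: float = DEFAULT_MIN_BITSCORE,
        k: int = 15,
        stride: int = 2,
        min_seeds: int = 4,
        window_pad: int = 300,
        max_edit_fraction: float = 0.25,
    ) -> None:
        self.scheme = scheme
        self.min_bitscore = min_bitscore
        self.k = k
        self.stride = stride
        self.min_seeds = min_seeds
        self.window_pad = window_pad
        self.max_edit_fraction = max_edit_fraction

        self.entries: list[_Entry] = []
        codes_all, fpos_all, fid_all = [], [], []
        for feat in library:
            arr = feat.array
            codes, pos = _kmer_codes(arr, k, stride=1)
            eid = len(self.entries)
            self.entries.append(_Entry(feat.name, feat.locus, feat.haplotype, arr, feat.sequence))
            codes_all.append(codes)
            fpos_all.append(pos)
            fid_all.append(np.full(len(codes), eid, dtype=np.int64))
        codes_cat = np.concatenate(codes_all)
        order = np.argsort(codes_cat, kind="stable")
        self._codes = codes_cat[order]
        self._fpos = np.concatenate(fpos_all)[order]
        self._fid = np.concatenate(fid_all)[order]

    # -- seeding ----------------------------------------------------------
    def _matches(self, read: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(entry id, feature pos, read pos) of all strided seed matches."""
        rc, rpos = _kmer_codes(read, self.k, self.stride)
        if len(rc) == 0:
            e = np.empty(0, np.int64)
            return e, e, e
        i0 = np.searchsorted(self._codes, rc, side="left")
        i1 = np.searchsorted(self._codes, rc, side="right")
        counts = i1 - i0
        sel = counts > 0
        reps = counts[sel]
        if reps.sum() == 0:
            e = np.empty(0, np.int64)
            return e, e, e
        starts = i0[sel]
        offs = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
        entry_idx = np.repeat(starts, reps) + offs
        rk = np.repeat(rpos[sel], reps)
        return self._fid[entry_idx], self._fpos[entry_idx], rk

    def seed_count(self, read: np.ndarray) -> int:
        fid, _, _ = self._matches(read)
        return len(fid)

    def windows(self, read: np.ndarray) -> dict[int, list[tuple[int, int, int]]]:
        """Candidate (window_start, window_end, n_seeds) per entry id.

        Seed matches are clustered by alignment diagonal; tandem copies of the
        repeat unit fall on diagonals ~unit-length apart and therefore form
        separate clusters, one per visible copy.
        """
        return self._windows_from_matches(self._matches(read), len(read))

    def _windows_from_matches(
        self, matches: tuple[np.ndarray, np.ndarray, np.ndarray], rlen: int
    ) -> dict[int, list[tuple[int, int, int]]]:
        fid, fpos, rpos = matches
        out: dict[int, list[tuple[int, int, int]]] = {}
        for eid in np.unique(fid):
            m = fid == eid
            diag = np.sort(rpos[m] - fpos[m])
            flen = len(self.entries[eid].arr)
            # adjacent tandem copies differ by ~flen in diagonal; indel drift
            # within one copy is only ~error_rate*flen, so flen//2 separates them
            gap = max(100, flen // 2)
            brk = np.nonzero(np.diff(diag) > gap)[0]
            wins = []
            for grp in np.split(diag, brk + 1):
                if len(grp) < self.min_seeds:
                    continue
                d = int(grp[len(grp) // 2])  # grp is sorted: middle element
                ws = max(0, d - self.window_pad)
                we = min(rlen, d + flen + self.window_pad)
                if we - ws >= self.k:
                    wins.append((ws, we, len(grp)))
            if wins:
                out[int(eid)] = wins
        return out

    # -- window alignment --------------------------------------------------
    def _align_window(
        self, eid: int, read_str: str, ws: int, we: int, read_id: str, strand: str
    ) -> AlignmentHit | None:
        ent = self.entries[eid]
        flen = len(ent.arr)
        kmax = max(50, int(self.max_edit_fraction * flen))
        res = edlib.align(ent.seq, read_str[ws:we], mode="HW", task="locations", k=kmax)
        d = res["editDistance"]
        if d < 0 or not res["locations"]:
            return None
        loc = res["locations"][0]
        raw = flen * self.scheme.match - d * (self.scheme.match - self.scheme.mismatch)
        bits = bitscore(raw, self.scheme)
        if raw <= 0 or bits < self.min_bitscore:
            return None
        return AlignmentHit(
            feature=ent.name,
            read_id=read_id,
            read_start=ws + int(loc[0]),
            read_end=ws + int(loc[1]) + 1,
            strand=strand,
            raw_score=float(raw),
            bitscore=bits,
            identity=max(0.0, 1.0 - d / flen),
            feature_coverage=1.0,
            locus=ent.locus,
            haplotype=ent.haplotype,
        )

    def strand_vote(self, read: np.ndarray) -> str:
        """'+' if the read as given matches the library better, else '-'."""
        fwd = self.seed_count(read)
        rev = self.seed_count(revcomp(read))
        return "-" if rev > fwd else "+"

    def scan(
        self,
        read: np.ndarray,
        read_id: str = "",
        normalize_strand: bool = True,
        unit_name: str = "D4Z4",
        enumerate_unit_loci: Sequence[str] | None = None,
    ) -> "ReadScan":
        """Scan one read against the library.

        The best window of every feature entry is always aligned (that is what
        locus classification consumes).  Full tandem-copy enumeration of the
        repeat unit is done for the loci in ``enumerate_unit_loci`` (default:
        the locus whose unit scored best), which is what repeat counting
        consumes; enumerating the losing paralog's copies would not change any
        downstream call.
        """
        strand = "+"
        matches = self._matches(read)
        if normalize_strand:
            rc = revcomp(read)
            rc_matches = self._matches(rc)
            if len(rc_matches[0]) > len(matches[0]):
                strand = "-"
                read = rc
                matches = rc_matches
        read_str = decode(read)
        wins = self._windows_from_matches(matches, len(read))

        hits: list[AlignmentHit] = []
        best_unit: dict[str, float] = {}
        unit_eids: dict[str, int] = {}
        for eid, wlist in wins.items():
            ent = self.entries[eid]
            if ent.name == unit_name:
                unit_eids[ent.locus] = eid
                continue
            ws, we, _ = max(wlist, key=lambda w: w[2])
            hit = self._align_window(eid, read_str, ws, we, read_id, strand)
            if hit:
                hits.append(hit)

        # score the best unit window per locus first, to pick the winner
        unit_best_hit: dict[str, AlignmentHit] = {}
        for locus, eid in unit_eids.items():
            ws, we, _ = max(wins[eid], key=lambda w: w[2])
            hit = self._align_window(eid, read_str, ws, we, read_id, strand)
            if hit:
                unit_best_hit[locus] = hit
                best_unit[locus] = hit.bitscore
        if enumerate_unit_loci is None:
            enumerate_unit_loci = (
                [max(best_unit, key=best_unit.get)] if best_unit else []
            )
        for locus in enumerate_unit_loci:
            eid = unit_eids.get(locus)
            if eid is None:
                continue
            unit_hits = []
            for ws, we, _ in wins[eid]:
                hit = self._align_window(eid, read_str, ws, we, read_id, strand)
                if hit:
                    unit_hits.append(hit)
            hits.extend(_resolve_overlaps(unit_hits))
            unit_best_hit.pop(locus, None)
        hits.extend(unit_best_hit.values())  # losing locus: best hit only
        return ReadScan(read_id=read_id, strand=strand, hits=hits, read_length=len(read))


def _resolve_overlaps(
    hits: list[AlignmentHit], tolerance: int = 0, trim_limit: int = 60
) -> list[AlignmentHit]:
    """Greedy non-overlap enforcement: keep by descending score, trim small
    boundary overlaps (alignment jitter between adjacent tandem copies), drop
    hits overlapping an accepted hit by more than ``trim_limit``."""
    accepted: list[AlignmentHit] = []
    for hit in sorted(hits, key=lambda h: -h.raw_score):
        s, e = hit.read_start, hit.read_end
        ok = True
        for a in accepted:
            ov = min(e, a.read_end) - max(s, a.read_start)
            if ov <= tolerance:
                continue
            if ov > trim_limit:
                ok = False
                break
            if s < a.read_start:
                e = a.read_start + tolerance
            else:
                s = a.read_end - tolerance
            if e - s < 1:
                ok = False
                break
        if not ok:
            continue
        if (s, e) != (hit.read_start, hit.read_end):
            shrink = (hit.read_end - hit.read_start) - (e - s)
            flen_est = hit.span / max(hit.feature_coverage, 1e-9)
            hit = replace(
                hit,
                read_start=s,
                read_end=e,
                feature_coverage=max(0.0, hit.feature_coverage - shrink / flen_est),
            )
        accepted.append(hit)
    return sorted(accepted, key=lambda h: h.read_start)


@dataclass
class ReadScan:
    """Per-read hit table (strand-normalised coordinates)."""

    read_id: str
    strand: str
    hits: list[AlignmentHit]
    read_length: int = 0

    def by_feature(self, name: str, locus: str | None = None) -> list[AlignmentHit]:
        return [
            h
            for h in self.hits
            if h.feature == name and (locus is None or h.locus == locus)
        ]

    def best_bitscore(self, name: str, locus: str) -> float:
        hits = self.by_feature(name, locus)
        return max((h.bitscore for h in hits), default=0.0)

    def locus_score(self, locus: str) -> float:
        """Sum of the best bitscore per feature for one locus variant set.

        The two pLAM haplotype variants cover the same read span, so pLAM
        contributes a single value: the better of the two.
        """
        total = self.best_bitscore("D4F104S1", locus)
        total += self.best_bitscore("D4Z4", locus)
        total += max(
            self.best_bitscore("pLAM_A", locus), self.best_bitscore("pLAM_B", locus)
        )
        return total


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def align_local(
    feature: FeatureSequence | np.ndarray | str,
    read: np.ndarray | str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    both_strands: bool = True,
    engine: str = "dp",
    read_id: str = "",
) -> list[AlignmentHit]:
    """All non-overlapping local hits of ``feature`` on ``read``.

    With ``both_strands`` the reverse complement of the read is also scanned
    and reverse-strand hits are reported in original read coordinates.
    """
    if isinstance(feature, FeatureSequence):
        name, locus, hap = feature.name, feature.locus, feature.haplotype
        farr = feature.array
    else:
        name, locus, hap = "feature", "", "none"
        farr = encode(feature) if isinstance(feature, str) else feature
    rarr = encode(read) if isinstance(read, str) else read
    if len(farr) == 0 or len(rarr) == 0:
        return []

    strands = [("+", rarr)]
    if both_strands:
        strands.append(("-", revcomp(rarr)))

    hits: list[AlignmentHit] = []
    n = len(rarr)
    for strand, arr in strands:
        if engine == "dp":
            raw_hits = _align_local_dp(farr, arr, scheme, min_bitscore)
        elif engine != "fast":
            raise ValueError(f"unknown engine {engine!r}")
        if engine == "fast":
            scanner = _single_feature_scanner(farr, scheme, min_bitscore)
            wins = scanner.windows(arr)
            raw = []
            rs = decode(arr)
            for eid, wlist in wins.items():
                for ws, we, _ in wlist:
                    h = scanner._align_window(eid, rs, ws, we, read_id, strand)
                    if h:
                        raw.append(h)
            found = _resolve_overlaps(raw)
            for h in found:
                h.feature, h.locus, h.haplotype = name, locus, hap
            if strand == "-":
                for h in found:
                    h.read_start, h.read_end = n - h.read_end, n - h.read_start
            hits.extend(found)
            continue
        for rh in raw_hits:
            s, e = rh.pop("read_start"), rh.pop("read_end")
            if strand == "-":
                s, e = n - e, n - s
            hits.append(
                AlignmentHit(
                    feature=name,
                    read_id=read_id,
                    read_start=s,
                    read_end=e,
                    strand=strand,
                    bitscore=bitscore(rh["raw_score"], scheme),
                    locus=locus,
                    haplotype=hap,
                    **rh,
                )
            )
    # keep the better strand's version of duplicated spans
    return _dedupe_strands(hits)


def _single_feature_scanner(
    farr: np.ndarray, scheme: ScoringScheme, min_bitscore: float
) -> FeatureScanner:
    lib = FeatureLibrary()
    lib.add(FeatureSequence("D4Z4", "4q", "none", decode(farr)))
    return FeatureScanner(lib, scheme, min_bitscore)


def _dedupe_strands(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    out: list[AlignmentHit] = []
    for hit in sorted(hits, key=lambda h: -h.raw_score):
        if any(
            min(hit.read_end, a.read_end) - max(hit.read_start, a.read_start)
            > 0.5 * min(hit.span, a.span)
            for a in out
        ):
            continue
        out.append(hit)
    return sorted(out, key=lambda h: h.read_start)


def scan_read(
    read: np.ndarray | str,
    library: FeatureLibrary,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    read_id: str = "",
    scanner: FeatureScanner | None = None,
) -> ReadScan:
    """Scan a read against every library entry (fast engine, strand-normalised)."""
    rarr = encode(read) if isinstance(read, str) else read
    if len(rarr) == 0:
        return ReadScan(read_id=read_id, strand="+", hits=[], read_length=0)
    if scanner is None:
        scanner = FeatureScanner(library, scheme, min_bitscore)
    return scanner.scan(rarr, read_id=read_id)


def hits_to_table(scans: Iterable[ReadScan]):
    """Hit-table rows (one dict per hit) for TSV export via pandas."""
    rows = []
    for scan in scans:
        for h in scan.hits:
            rows.append(
                dict(
                    read_id=scan.read_id,
                    feature=h.feature,
                    locus=h.locus,
                    haplotype=h.haplotype,
                    read_start=h.read_start,
                    read_end=h.read_end,
                    strand=h.strand,
                    raw_score=h.raw_score,
                    bitscore=round(h.bitscore, 2),
                    identity=round(h.identity, 4),
                    feature_coverage=round(h.feature_coverage, 4),
                )
            )
    return rows
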