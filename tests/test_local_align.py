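"""Alignment layer: bitscore normalisation, exact SW vs brute-force oracle,
multi-hit recovery, fast-engine agreement, strand symmetry."""

import numpy as np
import pytest

from nanofshd.feature_library import encode, revcomp
from nanofshd.local_align import (
    DEFAULT_SCHEME,
    ScoringScheme,
    align_local,
    bitscore,
    scan_read,
    sw_affine,
    sw_score_only,
)

from conftest import BASES, mutate_subs, random_seq


def oracle_sw(q, t, scheme=DEFAULT_SCHEME):
    """Plain O(nm) affine local alignment, the independent reference."""
    match, mis = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    m, n = len(q), len(t)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + go + ge, E[i - 1][j] + ge)
            F[i][j] = max(H[i][j - 1] + go + ge, F[i][j - 1] + ge)
            s = match if q[j - 1] == t[i - 1] else mis
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestBitscore:
    def test_zero_raw_score_closed_form(self):
        assert bitscore(0) == pytest.approx(1.1203, abs=1e-4)

    def test_raw_100(self):
        assert bitscore(100) == pytest.approx(185.79, abs=0.01)

    def test_monotonic(self):
        assert bitscore(101) > bitscore(100) > bitscore(0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(match=0), dict(mismatch=1), dict(lambda_=-1.0), dict(k_=1.5)],
    )
    def test_invalid_scheme_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringScheme(**kwargs)


class TestSmithWatermanOracle:
    @pytest.mark.parametrize("trial", range(8))
    def test_random_pairs_match_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        q = random_seq(int(rng.integers(5, 60)), rng)
        t = random_seq(int(rng.integers(5, 120)), rng)
        expected = oracle_sw(q, t)
        assert sw_affine(q, t)[0] == pytest.approx(expected)
        assert sw_score_only(q, t) == pytest.approx(expected)

    @pytest.mark.parametrize("trial", range(4))
    def test_embedded_feature_matches_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        feat = random_seq(200, rng)
        read = np.concatenate(
            [random_seq(400, rng), mutate_subs(feat, 0.05, rng), random_seq(400, rng)]
        )
        expected = oracle_sw(feat, read)
        score, qs, qe, ts, te, matches, cols = sw_affine(feat, read)
        assert score == pytest.approx(expected)
        assert 350 < ts < 450 and abs((te - ts) - 200) < 20


class TestAlignLocal:
    def test_self_alignment(self, rng):
        seq = random_seq(1000, rng)
        hits = align_local(seq, seq, engine="dp")
        assert len(hits) == 1
        h = hits[0]
        assert h.raw_score == 1000
        assert h.identity == 1.0
        assert h.feature_coverage == 1.0

    def test_dissimilar_homopolymers_no_hits(self):
        a = np.full(800, ord("A"), dtype=np.uint8)
        c = np.full(800, ord("C"), dtype=np.uint8)
        assert align_local(a, c, engine="dp") == []

    @pytest.mark.parametrize("engine", ["dp", "fast"])
    def test_tandem_three_units(self, engine, rng):
        unit = random_seq(400, rng)
        read = np.concatenate([random_seq(300, rng)] + [unit] * 3 + [random_seq(200, rng)])
        hits = align_local(unit, read, engine=engine, both_strands=False)
        assert len(hits) == 3
        spans = sorted((h.read_start, h.read_end) for h in hits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # mutually non-overlapping

    @pytest.mark.parametrize("trial", range(4))
    def test_substitution_hit_scores_equal_dp(self, trial):
        # substitution-only instances: the fast engine's edit-distance scoring
        # coincides with the optimal affine score
        rng = np.random.default_rng(300 + trial)
        feat = random_seq(300, rng)
        read = np.concatenate(
            [random_seq(800, rng), mutate_subs(feat, 0.05, rng), random_seq(800, rng)]
        )
        dp = align_local(feat, read, engine="dp", both_strands=False)
        fast = align_local(feat, read, engine="fast", both_strands=False)
        assert len(dp) >= 1 and len(fast) >= 1
        assert max(h.raw_score for h in fast) == pytest.approx(
            max(h.raw_score for h in dp)
        )
        assert dp[0].raw_score == pytest.approx(oracle_sw(feat, read))

    def test_strand_symmetry(self, rng):
        feat = random_seq(300, rng)
        read = np.concatenate([random_seq(200, rng), feat, random_seq(100, rng)])
        fwd = align_local(feat, read, engine="dp")
        rev = align_local(feat, revcomp(read), engine="dp")
        assert [(h.read_start, h.read_end, h.raw_score) for h in fwd] == [
            (len(read) - h.read_end, len(read) - h.read_start, h.raw_score)
            for h in rev
        ]

    def test_empty_inputs_give_no_hits(self, rng):
        seq = random_seq(100, rng)
        assert align_local(np.empty(0, np.uint8), seq) == []
        assert align_local(seq, np.empty(0, np.uint8)) == []


class TestScanRead:
    def test_synthetic_allele_read_hits_all_features(self, small_library):
        from nanofshd.feature_library import build_allele_sequence

        allele = build_allele_sequence(
            small_library, "4q", "A", 3, flank_lens=(300, 300)
        )
        scan = scan_read(allele.array, small_library, read_id="r1")
        assert scan.best_bitscore("D4F104S1", "4q") > 0
        assert scan.best_bitscore("pLAM_A", "4q") > 0
        assert len(scan.by_feature("D4Z4", "4q")) == 3
        # the true locus outscores the paralog
        assert scan.locus_score("4q") > scan.locus_score("10q")

    def test_empty_read(self, small_library):
        scan = scan_read("", small_library)
        assert scan.hits == []

    def test_deterministic(self, small_library, rng):
        from nanofshd.feature_library import build_allele_sequence

        allele = build_allele_sequence(small_library, "4q", "B", 2, flank_lens=(300, 300))
        read = allele.array[100:2000]
        s1 = scan_read(read, small_library, read_id="r")
        s2 = scan_read(read, small_library, read_id="r")
        assert [(h.feature, h.locus, h.read_start, h.read_end, h.raw_score)
                for h in s1.hits] == [
            (h.feature, h.locus, h.read_start, h.read_end, h.raw_score)
            for h in s2.hits
        ]
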