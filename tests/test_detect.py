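"""ROH detection against brute-force oracles and hand-built cases."""

from __future__ import annotations

from decimal import Decimal, getcontext

import numpy as np
import pytest

import rohscan as r
from conftest import make_matrix
from rohscan.io import MISSING


# ---------------------------------------------------------------------------
# independent oracles: plain loops, no shared code with the implementation

def brute_window_fractions(calls, positions, wp):
    n = len(calls)
    w = wp.window_snp
    hom_wins = []
    for s in range(0, n - w + 1):
        win = calls[s:s + w]
        n_het = sum(1 for c in win if c == 1)
        n_mis = sum(1 for c in win if c == MISSING)
        hom_wins.append(n_het <= wp.het_allow and n_mis <= wp.missing_allow)
    frac = np.zeros(n)
    for j in range(n):
        containing = [s for s in range(0, n - w + 1) if s <= j <= s + w - 1]
        if containing:
            frac[j] = sum(hom_wins[s] for s in containing) / len(containing)
    return frac


def brute_call_roh_one(calls, positions, wp, sp):
    """Rule-by-rule segment assembly for one individual on one chromosome;
    returns (start_idx, end_idx) pairs."""
    frac = brute_window_fractions(calls, positions, wp)
    marked = [f >= wp.threshold for f in frac]
    runs = []
    run = []
    for j in range(len(calls)):
        if marked[j]:
            run.append(j)
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)
    pieces = []
    for run in runs:
        piece = [run[0]]
        for a, b in zip(run, run[1:]):
            if positions[b] - positions[a] > sp.max_gap_kb * 1000:
                pieces.append(piece)
                piece = []
            piece.append(b)
        pieces.append(piece)
    out = []
    for piece in pieces:
        while piece and calls[piece[0]] in (1, MISSING):
            piece = piece[1:]
        while piece and calls[piece[-1]] in (1, MISSING):
            piece = piece[:-1]
        if not piece:
            continue
        s, e = piece[0], piece[-1]
        n_snp = e - s + 1
        length = positions[e] - positions[s] + 1
        if n_snp < sp.min_snp:
            continue
        if length < sp.min_length_kb * 1000:
            continue
        if length / 1000 / n_snp > sp.max_density_kb_per_snp:
            continue
        out.append((s, e))
    return out


def random_instance(rng, n_max=500):
    n = int(rng.integers(60, n_max + 1))
    calls = rng.choice([0, 1, 2, MISSING], size=n,
                       p=[0.44, 0.08, 0.44, 0.04]).astype(np.int8)
    # occasionally embed a homozygous stretch so segments actually occur
    if rng.random() < 0.7:
        s = int(rng.integers(0, n - 50))
        e = min(n, s + int(rng.integers(60, 200)))
        calls[s:e] = rng.choice([0, 2], size=e - s)
    gaps = rng.integers(1_000, 60_000, size=n)
    if rng.random() < 0.3:  # occasional Mb-scale gap to exercise splitting
        gaps[rng.integers(0, n)] = int(rng.integers(1_000_000, 3_000_000))
    positions = np.cumsum(gaps)
    wp = r.WindowParams(window_snp=int(rng.integers(5, 51)),
                        het_allow=int(rng.integers(0, 3)),
                        missing_allow=int(rng.integers(0, 3)),
                        threshold=float(rng.uniform(0.02, 0.6)))
    sp = r.SegmentParams(min_snp=int(rng.integers(10, 60)),
                         min_length_kb=float(rng.integers(200, 1500)),
                         max_gap_kb=1000.0,
                         max_density_kb_per_snp=50.0)
    return calls, positions, wp, sp


# ---------------------------------------------------------------------------

class TestComputeMinSnp:
    def test_lower_clamp_at_one(self):
        lp = r.LParams(n_snps=10, n_individuals=1, mean_het=0.999,
                       alpha=0.4)
        assert r.compute_min_snp(lp) == 1

    def test_matches_high_precision_evaluation(self):
        lp = r.LParams(n_snps=164_310, n_individuals=39, mean_het=0.25)
        getcontext().prec = 60
        L = (Decimal("0.05") / (Decimal(164_310) * Decimal(39))).ln() \
            / (Decimal(1) - Decimal("0.25")).ln()
        assert r.compute_min_snp(lp) == int(L)  # floor for positive L

    def test_monotone_in_snp_count(self):
        prev = 0
        for n_snps in (1_000, 10_000, 100_000, 1_000_000):
            val = r.compute_min_snp(r.LParams(
                n_snps=n_snps, n_individuals=39, mean_het=0.3))
            assert val >= prev
            prev = val

    def test_zero_heterozygosity_rejected(self):
        lp = r.LParams(n_snps=100, n_individuals=5, mean_het=0.0)
        with pytest.raises(ValueError):
            r.compute_min_snp(lp)


class TestWindowHitFractions:
    def test_all_homozygous_chromosome_is_all_ones(self):
        calls = np.zeros(60, dtype=np.int8)
        pos = np.arange(1, 61) * 10_000
        frac = r.window_hit_fractions(calls, pos, r.WindowParams())
        assert np.all(frac == 1.0)

    def test_all_heterozygous_is_all_zeros(self):
        calls = np.ones(80, dtype=np.int8)
        pos = np.arange(1, 81) * 10_000
        frac = r.window_hit_fractions(calls, pos, r.WindowParams())
        assert np.all(frac == 0.0)

    def test_chromosome_shorter_than_window_is_all_zero(self):
        calls = np.zeros(49, dtype=np.int8)
        pos = np.arange(1, 50) * 10_000
        frac = r.window_hit_fractions(calls, pos, r.WindowParams())
        assert np.all(frac == 0.0)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            calls = rng.choice([0, 1, 2, MISSING], size=200,
                               p=[0.45, 0.05, 0.45, 0.05]).astype(np.int8)
            pos = np.cumsum(rng.integers(1_000, 50_000, size=200))
            wp = r.WindowParams(window_snp=10,
                                het_allow=int(rng.integers(0, 2)),
                                missing_allow=int(rng.integers(0, 2)))
            got = r.window_hit_fractions(calls, pos, wp)
            want = brute_window_fractions(calls, pos, wp)
            np.testing.assert_allclose(got, want)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r.window_hit_fractions(np.zeros(5), np.zeros(4))


class TestCallRoh:
    def test_ideal_run_single_segment(self):
        calls = np.zeros((1, 300), dtype=np.int8)
        pos = np.arange(1, 301) * 10_000  # ~3 Mb span
        gm = make_matrix(calls, positions=pos)
        segs = r.call_roh(gm, sp=r.SegmentParams(min_snp=50))
        assert len(segs) == 1
        s = segs[0]
        assert (s.start_bp, s.end_bp, s.n_snp) == (10_000, 3_000_000, 300)

    def test_large_gap_splits_run(self):
        calls = np.zeros((1, 300), dtype=np.int8)
        pos = np.arange(1, 301) * 10_000
        pos[150:] += 1_500_000  # 1.5 Mb gap between SNP 150 and 151
        gm = make_matrix(calls, positions=pos)
        segs = r.call_roh(gm, sp=r.SegmentParams(min_snp=50))
        assert len(segs) == 2
        assert segs[0].end_bp == 1_500_000
        assert segs[1].start_bp == 1_510_000 + 1_500_000
        assert all(s.length_bp >= 1_000_000 for s in segs)

    def test_matches_bruteforce_pipeline_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            calls, pos, wp, sp = random_instance(rng)
            gm = make_matrix(calls[None, :], positions=pos)
            got = [(s.start_bp, s.end_bp, s.n_snp)
                   for s in r.call_roh(gm, wp, sp)]
            want = [(int(pos[s]), int(pos[e]), e - s + 1)
                    for s, e in brute_call_roh_one(calls, pos, wp, sp)]
            assert got == want

    def test_every_segment_satisfies_constraints(self, small_sim):
        gm, _ = small_sim
        sp = r.SegmentParams(min_snp=40)
        for s in r.call_roh(gm, sp=sp):
            assert s.n_snp >= sp.min_snp
            assert s.length_bp >= sp.min_length_kb * 1000
            assert s.density_kb_per_snp <= sp.max_density_kb_per_snp
            assert s.start_bp <= s.end_bp

    def test_individual_order_invariance(self, small_sim):
        gm, _ = small_sim
        rev = gm.subset_individuals(np.arange(gm.n_individuals)[::-1])
        key = lambda s: (s.sample_id, s.chrom, s.start_bp)
        a = sorted(r.call_roh(gm, sp=r.SegmentParams(min_snp=40)), key=key)
        b = sorted(r.call_roh(rev, sp=r.SegmentParams(min_snp=40)), key=key)
        assert a == b

    def test_threshold_monotonicity_of_marking(self):
        rng = np.random.default_rng(9)
        calls = rng.choice([0, 1, 2], size=400,
                           p=[0.48, 0.04, 0.48]).astype(np.int8)
        pos = np.cumsum(rng.integers(5_000, 20_000, size=400))
        frac = r.window_hit_fractions(calls, pos, r.WindowParams())
        marked_sets = [set(np.flatnonzero(frac >= t))
                       for t in (0.02, 0.05, 0.2, 0.5, 1.0)]
        for a, b in zip(marked_sets, marked_sets[1:]):
            assert b <= a

    def test_unsorted_positions_rejected(self):
        calls = np.zeros((1, 60), dtype=np.int8)
        pos = np.arange(60, 0, -1) * 1_000
        gm = make_matrix(calls, positions=np.sort(pos))
        gm.positions = pos  # corrupt after validation
        with pytest.raises(ValueError, match="increasing"):
            r.call_roh(gm)

    def test_segment_tsv_round_trip(self, tmp_path, small_sim):
        from rohscan.detect import read_segments_tsv, write_segments_tsv
        gm, _ = small_sim
        segs = r.call_roh(gm, sp=r.SegmentParams(min_snp=40))
        path = tmp_path / "roh.tsv"
        write_segments_tsv(segs, path)
        assert read_segments_tsv(path) == segs
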