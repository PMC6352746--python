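"""Footprint scoring, calling, concordance, merging and prevalence."""

import numpy as np
import pytest

from mitofoot import (
    CircularGenome,
    CoverageTrack,
    FootprintSite,
    PlantedSite,
    ScoringParams,
    SimulationConfig,
    SiteSet,
    best_scores,
    concordant_sites,
    fos_score,
    merge_sites,
    prevalence_filter,
    scan_footprints,
    simulate_track,
)
from mitofoot.footprints import FLANK_FLOOR
from mitofoot.intervals import overlaps

from conftest import base_set, random_intervals


# ------------------------------------------------------- naive oracle

def naive_fos(counts, position, center_len, flank_len, pseudocount=1.0):
    """Explicit-loop re-computation of the occupancy score."""
    L = len(counts)
    c0 = position - center_len // 2
    center = [counts[(c0 + i) % L] for i in range(center_len)]
    left = [counts[(c0 - flank_len + i) % L] for i in range(flank_len)]
    right = [counts[(c0 + center_len + i) % L] for i in range(flank_len)]
    cm = sum(center) / center_len
    lm = sum(left) / flank_len
    rm = sum(right) / flank_len
    num = cm + pseudocount
    return num / max(lm, FLANK_FLOOR) + num / max(rm, FLANK_FLOOR), lm, rm


def naive_best(counts, params):
    """Per-position best score via explicit loops over configurations."""
    L = len(counts)
    best = np.full(L, np.inf)
    scorable = np.zeros(L, bool)
    for p in range(L):
        for c in params.center_lengths:
            if 3 * c > L:
                continue
            score, lm, rm = naive_fos(counts, p, c, c, params.pseudocount)
            if lm >= params.min_flank_mean and rm >= params.min_flank_mean:
                scorable[p] = True
                best[p] = min(best[p], score)
    return best, scorable


# ------------------------------------------------------- fos_score

def test_uniform_coverage_score(uniform_track):
    # mean 9 everywhere, pseudocount 1: (9+1)/9 + (9+1)/9 = 20/9
    for pos in (0, 17, 299):
        assert fos_score(uniform_track, pos, 6, 6) == pytest.approx(20 / 9)


def test_protected_center_score(small_genome):
    counts = np.full(300, 9.0)
    counts[100:110] = 0.0
    track = CoverageTrack(small_genome, counts)
    # center fully inside the protected run, flanks fully outside
    assert fos_score(track, 105, 10, 10) == pytest.approx(2 / 9)


def test_fos_matches_naive_everywhere(small_genome):
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 60, 300).astype(float)
    track = CoverageTrack(small_genome, counts)
    for p in rng.integers(0, 300, 40):
        for c, f in [(6, 6), (10, 4), (41, 41), (7, 13)]:
            expected, _, _ = naive_fos(counts, int(p), c, f)
            assert fos_score(track, int(p), c, f) == pytest.approx(expected)


def test_fos_invalid_windows(uniform_track):
    with pytest.raises(ValueError):
        fos_score(uniform_track, 0, 0, 6)
    with pytest.raises(ValueError):
        fos_score(uniform_track, 0, 150, 150)


def test_scoring_params_window_bounds():
    with pytest.raises(ValueError, match="total window"):
        ScoringParams(center_lengths=(5,))
    with pytest.raises(ValueError, match="total window"):
        ScoringParams(center_lengths=(42,))
    assert ScoringParams().center_lengths == tuple(range(6, 42))


# ------------------------------------------------------- scan

def test_best_scores_match_naive_oracle(small_genome):
    rng = np.random.default_rng(8)
    params = ScoringParams(center_lengths=(6, 10, 20, 41))
    counts = rng.integers(0, 40, 300).astype(float)
    track = CoverageTrack(small_genome, counts)
    best, scorable = best_scores(track, params)
    nbest, nscorable = naive_best(counts, params)
    np.testing.assert_array_equal(scorable, nscorable)
    np.testing.assert_allclose(best[scorable], nbest[nscorable], rtol=1e-12)


def test_uniform_track_calls_nothing(uniform_track):
    assert len(scan_footprints(uniform_track)) == 0


def test_all_zero_track_warns_empty(small_genome):
    track = CoverageTrack(small_genome, np.zeros(300))
    with pytest.warns(UserWarning, match="all-zero"):
        assert len(scan_footprints(track)) == 0


def test_planted_protection_recovered():
    cfg = SimulationConfig(planted_sites=[PlantedSite(5000, 20, 0.9)],
                           n_replicates=1, seed=21)
    tracks, _ = simulate_track(cfg)
    called = scan_footprints(tracks[0])
    hits = [s for s in called if overlaps(s.interval, (5000, 5020), 16299)]
    assert len(hits) == 1
    s = hits[0]
    assert s.start <= 5010 <= s.end  # planted center inside the call


def test_scan_rotation_equivariance():
    cfg = SimulationConfig(planted_sites=[PlantedSite(4000, 30, 0.95)],
                           n_replicates=1, seed=22)
    tracks, _ = simulate_track(cfg)
    track = tracks[0]
    called = scan_footprints(track)
    for k in (1, 137, 16000):
        rot_called = scan_footprints(track.rotated(k))
        assert rot_called.intervals() == called.rotated(k).intervals()


# ------------------------------------------------------- concordance

def test_concordance_union_rule(small_genome):
    A = SiteSet(small_genome, [FootprintSite(10, 30, 0.4)])
    B = SiteSet(small_genome, [FootprintSite(25, 50, 0.6)])
    got = concordant_sites(A, B)
    assert got.intervals() == [(10, 50)]
    assert got.sites[0].score == 0.4  # min of the pair


def test_concordance_half_open_adjacency_is_not_overlap(small_genome):
    A = SiteSet(small_genome, [FootprintSite(10, 30, 0.4)])
    B = SiteSet(small_genome, [FootprintSite(30, 50, 0.6)])
    assert len(concordant_sites(A, B)) == 0


def test_concordance_intersection_flag(small_genome):
    A = SiteSet(small_genome, [FootprintSite(10, 30, 0.4)])
    B = SiteSet(small_genome, [FootprintSite(25, 50, 0.6)])
    got = concordant_sites(A, B, coordinates="intersection")
    assert got.intervals() == [(25, 30)]


def test_concordance_symmetric_and_matches_bruteforce(small_genome):
    rng = np.random.default_rng(9)
    L = 300
    for _ in range(30):
        a_ivls = random_intervals(rng, int(rng.integers(1, 8)), L, max_len=30)
        b_ivls = random_intervals(rng, int(rng.integers(1, 8)), L, max_len=30)
        A = SiteSet(small_genome, _sites(a_ivls, L))
        B = SiteSet(small_genome, _sites(b_ivls, L))
        ab = concordant_sites(A, B)
        ba = concordant_sites(B, A)
        assert ab.intervals() == ba.intervals()
        # brute force: union of bases of every overlapping pair
        expected = set()
        for x in A.intervals():
            for y in B.intervals():
                if base_set(x, L) & base_set(y, L):
                    expected |= base_set(x, L) | base_set(y, L)
        got = set()
        for ivl in ab.intervals():
            got |= base_set(ivl, L)
        assert got == expected


def _sites(ivls, L):
    """Non-overlapping subset of random intervals as FootprintSites."""
    kept = []
    for ivl in ivls:
        if all(not overlaps(ivl, k.interval, L) for k in kept):
            kept.append(FootprintSite(ivl[0], ivl[1], 0.5))
    return kept


def test_genome_mismatch_rejected(small_genome):
    other = CircularGenome("other", 300)
    A = SiteSet(small_genome, [FootprintSite(0, 10, 0.1)])
    B = SiteSet(other, [FootprintSite(0, 10, 0.1)])
    with pytest.raises(ValueError):
        concordant_sites(A, B)


# ------------------------------------------------------- merge / prevalence

def test_merge_examples_and_idempotence(small_genome):
    S = SiteSet(small_genome, _sites([(1, 10), (30, 40)], 300))
    T = SiteSet(small_genome, _sites([(5, 20)], 300))
    merged = merge_sites(S, T)
    assert merged.intervals() == [(1, 20), (30, 40)]
    assert merge_sites(merged).intervals() == merged.intervals()


def test_merge_preserves_covered_bases(small_genome):
    rng = np.random.default_rng(10)
    L = 300
    for _ in range(30):
        sets = [SiteSet(small_genome, _sites(random_intervals(
            rng, int(rng.integers(1, 6)), L, max_len=40), L)) for _ in range(3)]
        merged = merge_sites(*sets)
        inputs = set().union(*[base_set(i, L) for ss in sets for i in ss.intervals()]) \
            if any(len(ss) for ss in sets) else set()
        got = set().union(*[base_set(i, L) for i in merged.intervals()]) \
            if len(merged) else set()
        assert got == inputs


def test_prevalence_filter_thresholds(small_genome):
    mk = lambda ivls: SiteSet(small_genome, _sites(ivls, 300))
    # one site present in 4 of 5 samples, another in all 5
    samples = [mk([(10, 30), (100, 120)]) for _ in range(4)] + [mk([(100, 120)])]
    assert prevalence_filter(samples, 0.9).intervals() == [(100, 120)]
    assert prevalence_filter(samples, 0.1).intervals() == [(10, 30), (100, 120)]
    assert prevalence_filter(samples, 0.8).intervals() == [(10, 30), (100, 120)]
    # strict mode: 0.8 is not > 0.8
    assert prevalence_filter(samples, 0.8, strict=True).intervals() == [(100, 120)]


def test_prevalence_matches_bruteforce(small_genome):
    rng = np.random.default_rng(11)
    L = 300
    for _ in range(20):
        samples = [SiteSet(small_genome, _sites(random_intervals(
            rng, int(rng.integers(1, 6)), L, max_len=30), L)) for _ in range(5)]
        merged = merge_sites(*samples)
        for frac in (0.2, 0.5, 0.9):
            got = prevalence_filter(samples, frac).intervals()
            expected = []
            for ivl in merged.intervals():
                support = sum(
                    1 for ss in samples
                    if any(base_set(ivl, L) & base_set(x, L) for x in ss.intervals())
                )
                if support / 5 >= frac:
                    expected.append(ivl)
            assert got == expected
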