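"""G-quadruplex scanning, proximity status, and enrichment statistics."""

import numpy as np
import pytest
from scipy import stats

from mitofoot import (
    CircularGenome,
    Feature,
    FeatureAnnotation,
    FootprintSite,
    GQPMotifParams,
    ProximityParams,
    SiteSet,
    chi_square_enrichment,
    colocalize,
    dilated_site_fraction,
    n_colocalized,
    rotation_permutation_test,
    scan_gqp,
    status_counts,
)

from conftest import base_set


# ------------------------------------------------------- GQP oracle

def _run_at(seq, i):
    """Length of the maximal G-run starting exactly at i (0 if none starts here)."""
    if seq[i] != "G" or (i > 0 and seq[i - 1] == "G"):
        return 0
    j = i
    while j < len(seq) and seq[j] == "G":
        j += 1
    return j - i


def _next_long_run(seq, pos, min_run):
    """Start of the first maximal run of >= min_run guanines at or after pos."""
    for j in range(pos, len(seq)):
        if _run_at(seq, j) >= min_run:
            return j
    return None


def oracle_gqp_spans(seq, params):
    """Per-position brute-force motif matcher on a linear sequence.

    From each qualifying run start, greedily chain the successive long
    G-runs whenever the distance between one run's end and the next long
    run's start is within the loop bounds (loop content is unrestricted,
    short G-runs included); report leftmost-maximal non-overlapping spans.
    """
    n = len(seq)
    spans = []
    i = 0
    while i < n:
        first = _run_at(seq, i)
        if first < params.min_run:
            i += 1
            continue
        runs, end = 1, i + first
        while True:
            nxt = _next_long_run(seq, end, params.min_run)
            if nxt is None or not (params.loop_min <= nxt - end <= params.loop_max):
                break
            runs += 1
            end = nxt + _run_at(seq, nxt)
        if runs >= params.n_runs:
            spans.append((i, end))
            i = end
        else:
            i += 1
    return spans


def test_canonical_quadruplex_found():
    core = "GGGAGGGTGGGTGGG"
    seq = "A" * 30 + core + "A" * 55
    genome = CircularGenome("mt", len(seq), seq)
    ann = scan_gqp(genome)
    assert len(ann) == 1
    f = ann.features[0]
    assert (f.start, f.end) == (30, 30 + len(core))
    assert f.strand == "+"


def test_no_runs_no_motifs():
    seq = ("ACT" * 40)
    genome = CircularGenome("mt", len(seq), seq)
    assert len(scan_gqp(genome)) == 0


def test_c_runs_give_minus_strand():
    core = "CCCACCCTCCCTCCC"
    seq = "A" * 20 + core + "A" * 45
    genome = CircularGenome("mt", len(seq), seq)
    ann = scan_gqp(genome)
    assert len(ann) == 1
    assert ann.features[0].strand == "-"
    assert (ann.features[0].start, ann.features[0].end) == (20, 20 + len(core))


def test_wraps_across_origin():
    core = "GGGTGGGTGGGTGGG"
    # place the motif so it straddles the origin
    L = 120
    tail = core[:7]
    head = core[7:]
    seq = head + "A" * (L - len(core)) + tail
    genome = CircularGenome("mt", L, seq)
    ann = scan_gqp(genome)
    assert len(ann) == 1
    f = ann.features[0]
    assert f.start == L - 7 and f.end == len(head)


def test_matches_bruteforce_oracle_on_random_sequences():
    params = GQPMotifParams()
    rng = np.random.default_rng(0)
    for trial in range(20):
        # G-rich composition so motifs actually occur
        seq = "".join(rng.choice(list("ACGT"), size=3000,
                                 p=[0.2, 0.15, 0.45, 0.2]))
        genome = CircularGenome("mt", 3000, seq)
        got = sorted((f.start, f.end) for f in scan_gqp(genome) if f.strand == "+")
        doubled = seq * 2
        spans = [(s, e) for s, e in oracle_gqp_spans(doubled, params) if s < 3000]
        expected = sorted((s % 3000, ((e - 1) % 3000) + 1) for s, e in spans
                          if e - s < 3000)
        assert got == expected, trial


def test_reverse_complement_swaps_strands():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.2, 0.2, 0.4, 0.2]))
    genome = CircularGenome("mt", 2000, seq)
    fwd = scan_gqp(genome)
    rc = scan_gqp(genome.reverse_complement())
    L = genome.length

    def key(feats, strand):
        return sorted((f.start, f.end) for f in feats if f.strand == strand)

    # position i maps to L-1-i under reverse complement
    mapped = sorted(((L - f.end) % L, (L - f.start - 1) % L + 1)
                    for f in rc if f.strand == "-")
    assert key(fwd, "+") == mapped


# ------------------------------------------------------- proximity

def _sites(genome, ivls):
    return SiteSet(genome, [FootprintSite(s, e, 0.5) for s, e in ivls])


def test_status_examples():
    genome = CircularGenome("mt", 1000)
    feats = FeatureAnnotation(genome, [Feature("f1", "regulatory", 100, 120)])
    assert colocalize(_sites(genome, [(110, 130)]), feats)["status"][0] == "overlap"
    assert colocalize(_sites(genome, [(140, 160)]), feats)["status"][0] == "proximal"
    assert colocalize(_sites(genome, [(200, 220)]), feats)["status"][0] == "none"
    # the 40-base bound is exclusive: gap of exactly 40 is not proximal
    assert colocalize(_sites(genome, [(160, 180)]), feats)["status"][0] == "none"
    assert colocalize(_sites(genome, [(159, 180)]), feats)["status"][0] == "proximal"


def test_status_matches_bruteforce_distance():
    from conftest import random_intervals

    rng = np.random.default_rng(2)
    L = 500
    genome = CircularGenome("mt", L)
    for _ in range(10):
        site_ivls, kept = random_intervals(rng, 6, L, 30), []
        for ivl in site_ivls:
            if all(not (base_set(ivl, L) & base_set(k, L)) for k in kept):
                kept.append(ivl)
        sites = _sites(genome, kept)
        feats = FeatureAnnotation(genome, [
            Feature(f"f{i}", "other", s, e if e != 0 else L)
            for i, (s, e) in enumerate(random_intervals(rng, 8, L, 25))])
        table = colocalize(sites, feats, ProximityParams(40))
        site_bases = set().union(*[base_set(i, L) for i in sites.intervals()])
        for _, row in table.iterrows():
            fb = base_set((row["start"], row["end"]), L)
            if fb & site_bases:
                expected = "overlap"
            else:
                gap = min(min((q - p - 1) % L, (p - q - 1) % L)
                          for p in fb for q in site_bases)
                expected = "proximal" if gap < 40 else "none"
            assert row["status"] == expected


def test_rotation_invariance_of_status():
    genome = CircularGenome("mt", 1000)
    sites = _sites(genome, [(100, 130), (800, 850)])
    feats = FeatureAnnotation(genome, [Feature("a", "tRNA", 140, 170),
                                       Feature("b", "tRNA", 400, 430)])
    base = colocalize(sites, feats)["status"].tolist()
    for k in (13, 500, 999):
        rot = colocalize(sites.rotated(k), feats.rotated(k))
        assert rot["status"].tolist() == base


# ------------------------------------------------------- chi-square

def test_chi_square_worked_example():
    # 81 features, 25 co-localized, null fraction 0.20:
    # chi2 = (25-16.2)^2/16.2 + (56-64.8)^2/64.8 ~= 5.975, p ~= 0.0145
    res = chi_square_enrichment(81, 25, 0.20)
    assert res.chi_square == pytest.approx(5.9753, abs=1e-3)
    assert res.p_value == pytest.approx(0.01452, abs=1e-4)
    assert res.df == 1
    assert res.expected_colocalized == pytest.approx(16.2)


def test_chi_square_matches_scipy_on_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(20, 500))
        p0 = float(rng.uniform(0.05, 0.9))
        k = int(rng.integers(0, n + 1))
        if min(n * p0, n * (1 - p0)) < 1:
            continue
        res = chi_square_enrichment(n, k, p0)
        ref = stats.chisquare([k, n - k], [n * p0, n * (1 - p0)])
        assert res.chi_square == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_chi_square_exact_expectation_gives_p_one():
    res = chi_square_enrichment(100, 20, 0.2)
    assert res.chi_square == 0.0
    assert res.p_value == 1.0


def test_chi_square_degenerate_rejected():
    with pytest.raises(ValueError):
        chi_square_enrichment(10, 5, 0.0)
    with pytest.raises(ValueError):
        chi_square_enrichment(10, 5, 1.0)


def test_dilated_fraction():
    genome = CircularGenome("mt", 1000)
    sites = _sites(genome, [(100, 120)])
    # 20 site bases + 39 on each side
    assert dilated_site_fraction(sites, ProximityParams(40)) == pytest.approx(98 / 1000)


# ------------------------------------------------------- permutation

def test_permutation_features_equal_sites_min_p():
    genome = CircularGenome("mt", 16299)
    sites = _sites(genome, [(100, 140), (9000, 9050), (15000, 15020)])
    feats = FeatureAnnotation(genome, [
        Feature(f"f{i}", "other", s, e) for i, (s, e) in enumerate(sites.intervals())])
    p, obs = rotation_permutation_test(sites, feats, n_perm=199, seed=0)
    assert obs == 3
    assert p <= 0.02  # near-minimal up to rotation ties


def test_permutation_deterministic_under_seed():
    genome = CircularGenome("mt", 2000)
    sites = _sites(genome, [(100, 140), (900, 950)])
    feats = FeatureAnnotation(genome, [Feature("a", "other", 300, 330),
                                       Feature("b", "other", 1200, 1260)])
    p1, _ = rotation_permutation_test(sites, feats, n_perm=199, seed=42)
    p2, _ = rotation_permutation_test(sites, feats, n_perm=199, seed=42)
    assert p1 == p2
    with pytest.raises(ValueError):
        rotation_permutation_test(sites, feats, n_perm=50)


def test_permutation_count_statistic_matches_colocalize():
    genome = CircularGenome("mt", 2000)
    sites = _sites(genome, [(100, 140), (900, 950)])
    feats = FeatureAnnotation(genome, [Feature("a", "other", 150, 170),
                                       Feature("b", "other", 1200, 1260),
                                       Feature("c", "other", 120, 135)])
    _, obs = rotation_permutation_test(sites, feats, n_perm=100, seed=1)
    assert obs == n_colocalized(colocalize(sites, feats))
    counts = status_counts(colocalize(sites, feats))
    assert counts["overlap"] == 1 and counts["proximal"] == 1 and counts["none"] == 1
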