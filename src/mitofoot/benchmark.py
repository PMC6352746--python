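"""Validation experiments run against the synthetic generator's ground truth.

Each routine simulates data under known conditions, runs the corresponding
pipeline stage, and measures recovery or calibration.  They power both the
test suite and the reproducibility script.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bias_numt import compare_numt_groups, kmer_bias_screen, numt_read_fraction
from .colocalization import ProximityParams, rotation_permutation_test
from .dynamics import build_occupancy, classify_dynamics
from .footprints import ScoringParams, SiteSet, FootprintSite, concordant_sites, scan_footprints
from .genome import CircularGenome
from .intervals import interval_length, overlaps
from .reads import ReadSet
from .simulate import (
    PlantedSite,
    SimulationConfig,
    random_catalog,
    random_genome,
    random_planted_sites,
    seven_stage_config,
    simulate_reads,
    simulate_stage_series,
    simulate_track,
)


def _boundary_error(called: tuple[int, int], truth: tuple[int, int], L: int) -> float:
    """Mean absolute offset of the two boundaries, modular."""
    ds = min((called[0] - truth[0]) % L, (truth[0] - called[0]) % L)
    de = min((called[1] - truth[1]) % L, (truth[1] - called[1]) % L)
    return (ds + de) / 2


def footprint_recovery(n_sims: int = 200, seed: int = 0, genome_length: int = 16299,
                       params: ScoringParams | None = None) -> dict:
    """Planted-footprint recovery of the scanner on single tracks.

    Each simulation plants 2-5 protections (width 15-60, protection
    0.8-1.0) on deep overdispersed coverage (background mean 30-80) and
    scans one replicate.  Sensitivity counts planted sites overlapped by a
    call; boundary error averages the absolute start/end offsets of the
    best-overlapping call.  A matched null track (no planted sites) per
    simulation measures false calls against the calling quantile's
    expectation (at most ``call_quantile`` of positions can fall below the
    empirical threshold, so called bases per null track are bounded by it).
    """
    params = params or ScoringParams()
    rng = np.random.default_rng(seed)
    found = total = 0
    errors = []
    null_sites = []
    null_bases = []
    for i in range(n_sims):
        n_sites = int(rng.integers(2, 6))
        bg = float(rng.uniform(30, 80))
        sites = random_planted_sites(rng, n_sites, genome_length, width_range=(15, 60),
                                     protection_range=(0.8, 1.0))
        cfg = SimulationConfig(genome_length=genome_length, background_mean=bg,
                               planted_sites=sites, n_replicates=1,
                               seed=int(rng.integers(2 ** 31)))
        tracks, truth = simulate_track(cfg)
        called = scan_footprints(tracks[0], params)
        for p in truth:
            total += 1
            t_ivl = (p.start % genome_length, (p.start + p.width) % genome_length)
            hits = [s for s in called if overlaps(s.interval, t_ivl, genome_length)]
            if hits:
                found += 1
                errors.append(min(_boundary_error(s.interval, t_ivl, genome_length)
                                  for s in hits))
        null_cfg = SimulationConfig(genome_length=genome_length, background_mean=bg,
                                    n_replicates=1, seed=int(rng.integers(2 ** 31)))
        null_tracks, _ = simulate_track(null_cfg)
        null_called = scan_footprints(null_tracks[0], params)
        null_sites.append(len(null_called))
        null_bases.append(sum(s.length(genome_length) for s in null_called))
    return {
        "n_sims": n_sims,
        "n_planted": total,
        "sensitivity": found / total,
        "mean_boundary_error": float(np.mean(errors)) if errors else np.nan,
        "null_mean_sites": float(np.mean(null_sites)),
        "null_mean_called_bases": float(np.mean(null_bases)),
        "null_expected_called_bases": params.call_quantile * genome_length,
    }


def end_to_end_series(seed: int = 0, params: ScoringParams | None = None) -> dict:
    """Scripted 7-stage series through scan → concordance → occupancy → classify.

    Measures whether the ground-truth occupancy matrix and trajectory
    classes are reproduced exactly.
    """
    params = params or ScoringParams()
    cfg = seven_stage_config(seed=seed)
    sim = simulate_stage_series(cfg)
    L = cfg.genome_length
    per_stage = []
    for st in sim["stages"]:
        reps = [scan_footprints(t, params) for t in sim["tracks"][st]]
        per_stage.append(concordant_sites(*reps))
    occ = build_occupancy(per_stage, sim["stages"])
    script = sim["truth_presence"]
    n_truth = script.shape[0]
    matched = 0
    rows_equal = 0
    classes_equal = 0
    for i, ref in enumerate(occ.reference_sites):
        js = [j for j, p in enumerate(sim["planted_sites"])
              if overlaps(ref.interval, (p.start % L, (p.start + p.width) % L), L)]
        if len(js) == 1:
            matched += 1
            if (occ.presence[i] == script[js[0]]).all():
                rows_equal += 1
            if classify_dynamics(occ.presence[i]) == classify_dynamics(script[js[0]]):
                classes_equal += 1
    return {
        "n_truth_sites": int(n_truth),
        "n_reference_sites": len(occ.reference_sites),
        "n_matched": matched,
        "occupancy_rows_exact": rows_equal,
        "classes_exact": classes_equal,
        "matrix_exact": bool(len(occ.reference_sites) == n_truth == rows_equal),
        "class_accuracy": classes_equal / n_truth,
    }


def _random_siteset(rng: np.random.Generator, genome: CircularGenome, n: int,
                    width_range=(10, 60)) -> SiteSet:
    sites = random_planted_sites(rng, n, genome.length, width_range=width_range,
                                 min_separation=60)
    return SiteSet(genome, [FootprintSite(s.start % genome.length,
                                          (s.start + s.width) % genome.length, 0.5)
                            for s in sites])


def permutation_type_i(n_sims: int = 600, n_perm: int = 199, seed: int = 0,
                       genome_length: int = 16299, n_features: int = 200,
                       n_sites: int = 25, alpha: float = 0.05) -> float:
    """Rejection rate of the rotation permutation test under independence.

    The experiment uses enough features that the co-localization count
    statistic has a wide support; with very few features its heavy ties
    make the permutation p-value strongly conservative and the measured
    level uninformative.
    """
    from .genome import Feature, FeatureAnnotation

    rng = np.random.default_rng(seed)
    genome = CircularGenome("chrM", genome_length)
    rejections = 0
    for i in range(n_sims):
        sites = _random_siteset(rng, genome, n_sites)
        feats = []
        for j in range(n_features):
            s = int(rng.integers(0, genome_length))
            w = int(rng.integers(10, 40))
            feats.append(Feature(f"f{j}", "other", s, (s + w - 1) % genome_length + 1
                                 if (s + w) % genome_length else genome_length))
        ann = FeatureAnnotation(genome, feats)
        p, _ = rotation_permutation_test(sites, ann, ProximityParams(), n_perm=n_perm,
                                         seed=int(rng.integers(2 ** 31)))
        if p <= alpha:
            rejections += 1
    return rejections / n_sims


def mannwhitney_type_i(n_sims: int = 1000, seed: int = 0, n_per_group: int = 30,
                       coverage: int = 5000, rate: float = 0.01,
                       alpha: float = 0.05) -> float:
    """Type-I error of the site/non-site NUMT comparison under equal rates.

    Per-position NUMT fractions in both groups are drawn from the same
    binomial contamination model; the comparison should reject at ~alpha.
    """
    genome = CircularGenome("chrM", 4000)
    rng = np.random.default_rng(seed)
    rejections = 0
    in_site_pos = np.arange(0, n_per_group * 50, 50)  # inside the single site below
    out_pos = np.arange(2500, 2500 + n_per_group * 40, 40)
    sites = SiteSet(genome, [FootprintSite(0, 2000, 0.2)])
    from .bias_numt import NUMTReport

    for _ in range(n_sims):
        rows = []
        for pos in np.concatenate([in_site_pos, out_pos]):
            n_inf = int(rng.poisson(coverage))
            k = int(rng.binomial(n_inf, rate))
            rows.append((int(pos), n_inf, k, k / n_inf if n_inf else np.nan))
        report = NUMTReport(pd.DataFrame(
            rows, columns=["position", "n_informative", "n_numt", "fraction"]))
        res = compare_numt_groups(report, sites)
        if res.p_value is not None and res.p_value <= alpha:
            rejections += 1
    return rejections / n_sims


def numt_recovery(rates: Sequence[float] = (0.0, 0.002, 0.01), n_runs: int = 100,
                  seed: int = 0, genome_length: int = 2000, coverage: float = 5000.0,
                  read_length: int = 50, n_variants: int = 20) -> pd.DataFrame:
    """Recovery of simulated NUMT contamination rates at deep coverage.

    For each rate, ``n_runs`` read sets are simulated and the pooled
    estimate is checked against the two-sided 95% binomial confidence
    interval around the true rate (given the realized number of
    informative reads).
    """
    rng = np.random.default_rng(seed)
    genome = random_genome(genome_length, seed=seed)
    catalog = random_catalog(genome, n_variants, seed=seed + 1,
                             min_separation=read_length)
    n_reads = int(genome_length * coverage / read_length)
    rows = []
    for rate in rates:
        est, covered = [], 0
        for _ in range(n_runs):
            cfg = SimulationConfig(genome_length=genome_length, numt_rate=rate,
                                   read_length=read_length,
                                   seed=int(rng.integers(2 ** 31)))
            reads = simulate_reads(cfg, genome, catalog=catalog, n_reads=n_reads)
            report = numt_read_fraction(reads, catalog)
            pooled = report.pooled_fraction
            n_inf = int(report.per_position["n_informative"].sum())
            lo, hi = stats.binom.interval(0.95, n_inf, rate) if rate > 0 else (0, 0)
            est.append(pooled)
            k = int(report.per_position["n_numt"].sum())
            if lo <= k <= hi:
                covered += 1
        rows.append((rate, float(np.mean(est)), covered / n_runs))
    return pd.DataFrame(rows, columns=["true_rate", "mean_estimate", "ci_coverage"])


def kmer_bias_calibration(n_null: int = 20, n_cuts: int = 10000, seed: int = 0,
                          genome_length: int = 16299, k: int = 6) -> dict:
    """Null behaviour and planted-bias detection of the k-mer screen.

    Null: uniform random cuts on a random genome should leave at most 5%
    of k-mers flagged (BH-adjusted p < 0.05) in nearly every replicate.
    Planted: cuts biased 5-fold toward one 6-mer must flag that k-mer on
    top.
    """
    rng = np.random.default_rng(seed)
    genome = random_genome(genome_length, seed=seed + 17)
    n_kmers = 4 ** k
    quiet_runs = 0
    flag_fractions = []
    for _ in range(n_null):
        cuts = rng.integers(0, genome_length, size=n_cuts)
        rep = kmer_bias_screen(cuts, genome, k=k)
        frac = rep.n_flagged / n_kmers
        flag_fractions.append(frac)
        if frac <= 0.05:
            quiet_runs += 1
    # planted 5x bias toward one kmer present in the genome
    target = "AATTCC"
    doubled = genome.sequence + genome.sequence[:k]
    hits = [i for i in range(genome_length)
            if doubled[(i - k // 2) % genome_length:(i - k // 2) % genome_length + k] == target]
    if not hits:
        raise RuntimeError("target k-mer absent from the random genome")
    w = np.ones(genome_length)
    w[hits] = 5.0
    cuts = rng.choice(genome_length, size=n_cuts, p=w / w.sum())
    biased = kmer_bias_screen(cuts, genome, k=k)
    top = biased.table.sort_values("enrichment", ascending=False).iloc[0]
    target_row = biased.table.set_index("kmer").loc[target]
    return {
        "null_runs": n_null,
        "null_quiet_runs": quiet_runs,
        "null_mean_flag_fraction": float(np.mean(flag_fractions)),
        "planted_biased_flag": biased.biased,
        "planted_top_kmer": top["kmer"],
        "planted_target_enrichment": float(target_row["enrichment"]),
        "planted_target_p_adj": float(target_row["p_adj"]),
        "planted_detected": bool(biased.biased and target_row["p_adj"] < 0.05
                                 and target_row["enrichment"] > 2),
    }
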