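"""Co-localization of footprint sites with annotated features and
G-quadruplex-prone motifs, with chi-square and rotation-permutation
significance.

A feature *overlaps* a site set if it shares at least one base with some
site; it is *proximal* if disjoint but within a circular gap smaller than
``max_gap`` (default 40 bases, exclusive); otherwise *none*.  Enrichment of
(overlap + proximal) features is tested against a per-feature binomial
null whose expected fraction defaults to the fraction of genome bases
lying within ``max_gap`` of any site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CircularGenome, Feature, FeatureAnnotation
from .footprints import SiteSet
from .intervals import circular_gap, coverage_mask, dilate, interval_length, overlaps


@dataclass(frozen=True)
class ProximityParams:
    """``max_gap`` is an exclusive bound: gap < max_gap counts as proximal."""

    max_gap: int = 40

    def __post_init__(self):
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class GQPMotifParams:
    """Quadparser-style motif: ``n_runs`` runs of >= ``min_run`` guanines
    separated by loops of ``loop_min``..``loop_max`` bases, on both strands."""

    min_run: int = 3
    loop_min: int = 1
    loop_max: int = 7
    n_runs: int = 4

    def __post_init__(self):
        if self.min_run < 2 or self.n_runs < 2:
            raise ValueError("min_run and n_runs must each be >= 2")
        if not (0 < self.loop_min <= self.loop_max):
            raise ValueError("need 0 < loop_min <= loop_max")


@dataclass
class EnrichmentResult:
    n_features: int
    n_colocalized: int
    expected_colocalized: float
    chi_square: float
    df: int
    p_value: float
    permutation_p: Optional[float] = None
    n_permutations: Optional[int] = None


# ---------------------------------------------------------------- GQP scan

def _g_runs(seq: str, min_run: int, base: str) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` of length >= min_run, as (start, end) half-open."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _chain_motifs(seq: str, params: GQPMotifParams, base: str) -> list[tuple[int, int]]:
    """Leftmost-maximal non-overlapping motif spans on a linear sequence.

    Greedy chaining over maximal base-runs: from each unconsumed run, chain
    successive runs whenever the inter-run gap is within the loop bounds,
    as far as possible; emit if at least ``n_runs`` runs chained.
    """
    runs = _g_runs(seq, params.min_run, base)
    matches = []
    consumed_until = -1
    i = 0
    while i < len(runs):
        if runs[i][0] <= consumed_until:
            i += 1
            continue
        chain_end = runs[i][1]
        count = 1
        j = i
        while j + 1 < len(runs):
            gap = runs[j + 1][0] - runs[j][1]
            if params.loop_min <= gap <= params.loop_max:
                j += 1
                count += 1
                chain_end = runs[j][1]
            else:
                break
        if count >= params.n_runs:
            matches.append((runs[i][0], chain_end))
            consumed_until = chain_end - 1
            i = j + 1
        else:
            i += 1
    return matches


def scan_gqp(genome: CircularGenome, params: GQPMotifParams | None = None) -> FeatureAnnotation:
    """Scan both strands of the circular genome for G-quadruplex-prone motifs.

    The forward strand is scanned for guanine-run chains, the reverse
    strand via cytosine-run chains on the forward sequence (equivalent to
    guanine runs on the reverse complement); scanning is modular across the
    origin, and overlapping same-strand matches collapse to the
    leftmost-maximal one.
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required")
    params = params or GQPMotifParams()
    L = genome.length
    doubled = genome.sequence.upper() * 2
    features = []
    for strand, base in (("+", "G"), ("-", "C")):
        spans = [(s, e) for s, e in _chain_motifs(doubled, params, base) if s < L]
        # drop second-copy duplicates of matches already seen in the first copy
        uniq = []
        seen = set()
        for s, e in spans:
            key = (s % L, (e - s))
            if key not in seen:
                seen.add(key)
                uniq.append((s, e))
        for s, e in uniq:
            if e - s >= L:
                continue
            features.append(Feature(f"gqp_{strand}_{s % L}", "gqp", s % L, ((e - 1) % L) + 1,
                                    strand))
    return FeatureAnnotation(genome, features)


# ---------------------------------------------------------------- proximity

def colocalize(sites: SiteSet, features: FeatureAnnotation,
               params: ProximityParams | None = None) -> pd.DataFrame:
    """Per-feature co-localization status against a site set.

    Status is ``overlap`` (>=1 shared base), ``proximal`` (disjoint but
    circular gap < ``max_gap``) or ``none``.
    """
    if sites.genome.length != features.genome.length:
        raise ValueError("genome mismatch between sites and features")
    params = params or ProximityParams()
    L = sites.genome.length
    rows = []
    for f in features:
        status = "none"
        best_gap = None
        for s in sites:
            if overlaps(f.interval, s.interval, L):
                status, best_gap = "overlap", 0
                break
            g = circular_gap(f.interval, s.interval, L)
            if best_gap is None or g < best_gap:
                best_gap = g
        if status != "overlap" and best_gap is not None and best_gap < params.max_gap:
            status = "proximal"
        rows.append((f.feature_id, f.feature_class, f.start, f.end, status, best_gap))
    return pd.DataFrame(rows, columns=["feature_id", "feature_class", "start", "end",
                                       "status", "gap"])


def status_counts(table: pd.DataFrame) -> dict[str, int]:
    return {k: int((table["status"] == k).sum()) for k in ("overlap", "proximal", "none")}


def n_colocalized(table: pd.DataFrame, overlap_only: bool = False) -> int:
    ok = {"overlap"} if overlap_only else {"overlap", "proximal"}
    return int(table["status"].isin(ok).sum())


def dilated_site_fraction(sites: SiteSet, params: ProximityParams | None = None) -> float:
    """Fraction of genome bases within ``max_gap`` of any site (the default
    per-feature null for enrichment)."""
    params = params or ProximityParams()
    L = sites.genome.length
    pad = max(params.max_gap - 1, 0)  # gap < max_gap is 'close'
    dilated = [dilate(s.interval, pad, L) for s in sites]
    return float(coverage_mask(dilated, L).mean()) if dilated else 0.0


# ---------------------------------------------------------------- statistics

def chi_square_enrichment(n_features: int, n_colocalized: int,
                          expected_fraction: float) -> EnrichmentResult:
    """1-df goodness-of-fit chi-square of (colocalized, not) vs the null split."""
    if not (0 < expected_fraction < 1):
        raise ValueError("expected_fraction must be strictly between 0 and 1")
    if not (0 <= n_colocalized <= n_features):
        raise ValueError("n_colocalized must be between 0 and n_features")
    expected = np.array([n_features * expected_fraction,
                         n_features * (1 - expected_fraction)])
    if expected.min() < 1:
        raise ValueError("expected count below 1; the chi-square approximation is invalid")
    if expected.min() < 5:
        warnings.warn("expected count below 5; chi-square approximation is rough")
    observed = np.array([n_colocalized, n_features - n_colocalized], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(n_features, n_colocalized, float(expected[0]), chi2, 1, p)


def rotation_permutation_test(sites: SiteSet, features: FeatureAnnotation,
                              params: ProximityParams | None = None,
                              n_perm: int = 999, seed: int = 0,
                              overlap_only: bool = False) -> tuple[float, int]:
    """Permutation p-value for co-localization, by random circular rotation.

    The null rotates the whole feature set by a uniform random offset
    (sites stay fixed, preserving the coverage structure the calls came
    from); the statistic is the number of co-localized features, and
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    params = params or ProximityParams()
    rng = np.random.default_rng(seed)
    obs = n_colocalized(colocalize(sites, features, params), overlap_only)
    L = features.genome.length
    # vectorized: per feature, colocalized iff min circular distance to any
    # site is < max_gap (0 distance = overlap)
    exceed = 0
    fstarts = np.array([f.start for f in features])
    flens = np.array([interval_length(f.interval, L) for f in features])
    sstarts = np.array([s.start for s in sites])
    slens = np.array([interval_length(s.interval, L) for s in sites])
    for _ in range(n_perm):
        k = int(rng.integers(0, L))
        stat = _count_close((fstarts + k) % L, flens, sstarts, slens, L, params.max_gap,
                            overlap_only)
        if stat >= obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1), obs


def _count_close(fstarts, flens, sstarts, slens, L, max_gap, overlap_only) -> int:
    if len(sstarts) == 0 or len(fstarts) == 0:
        return 0
    d1 = (sstarts[None, :] - (fstarts + flens)[:, None]) % L  # gap feature -> site
    d2 = (fstarts[:, None] - (sstarts + slens)[None, :]) % L  # gap site -> feature
    olap = (((sstarts[None, :] - fstarts[:, None]) % L) < flens[:, None]) | \
           (((fstarts[:, None] - sstarts[None, :]) % L) < slens[None, :])
    if overlap_only:
        close = olap
    else:
        gap = np.where(olap, 0, np.minimum(d1, d2))
        close = gap < max_gap
    return int(close.any(axis=1).sum())
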