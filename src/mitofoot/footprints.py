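"""Footprint detection on circular coverage tracks.

A footprint is a localized depression in accessibility coverage, read as
protein protection.  Every position is scored with a footprint occupancy
score (FOS) over a family of sliding windows: a central window of ``c``
bases flanked left and right by windows of equal size, with the total
window span constrained to the configured bounds.  The FOS at a position is

    FOS = (C + pc) / max(Lm, eps)  +  (C + pc) / max(Rm, eps)

where ``C`` is the mean coverage of the central window, ``Lm``/``Rm`` the
mean coverage of the flanks, ``pc`` a pseudocount and ``eps`` a floor
guarding empty flanks.  Low scores mean deep protection relative to both
flanks.  A position's best score is the minimum over all scanned window
configurations; contiguous runs of positions whose best score falls below
an empirical per-track quantile threshold are emitted as candidate sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .genome import CircularGenome, CoverageTrack
from .intervals import (
    hull,
    interval_length,
    merge_intervals,
    normalize,
    overlaps,
    rotate_interval,
)

FLANK_FLOOR = 0.25  # eps guarding division by an empty flank


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the sliding-window footprint scan.

    ``center_lengths`` lists the central-window widths scanned; with equal
    flanks the total span is three times the center, so the default range
    6..41 keeps every span within the 18–124 base bounds.
    ``call_quantile`` sets the empirical calling threshold: the quantile of
    the per-position best-score distribution below which positions are
    treated as protected.
    """

    min_total_window: int = 18
    max_total_window: int = 124
    center_lengths: tuple[int, ...] = tuple(range(6, 42))
    min_flank_mean: float = 5.0
    call_quantile: float = 0.01
    pseudocount: float = 1.0

    def __post_init__(self):
        if not self.center_lengths:
            raise ValueError("center_lengths must be nonempty")
        if not (0 < self.call_quantile < 1):
            raise ValueError("call_quantile must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        for c in self.center_lengths:
            if not (self.min_total_window <= 3 * c <= self.max_total_window):
                raise ValueError(
                    f"center length {c} gives total window {3 * c} outside "
                    f"[{self.min_total_window}, {self.max_total_window}]"
                )


@dataclass(frozen=True)
class FootprintSite:
    """A called footprint: half-open interval on the circle with its best score."""

    start: int
    end: int
    score: float
    stage_id: str = ""
    sample_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        object.__setattr__(self, "score", float(self.score))

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def length(self, L: int) -> int:
        return interval_length((self.start, self.end), L)


@dataclass
class SiteSet:
    """Sorted, pairwise non-overlapping footprint sites on one genome."""

    genome: CircularGenome
    sites: list[FootprintSite] = field(default_factory=list)
    stage_id: str = ""
    call_threshold: Optional[float] = None

    def __post_init__(self):
        self.sites = sorted(self.sites, key=lambda s: (s.start, s.end))
        L = self.genome.length
        for a, b in zip(self.sites, self.sites[1:]):
            if overlaps(a.interval, b.interval, L):
                raise ValueError(f"overlapping sites {a.interval} / {b.interval}")
        if len(self.sites) > 1 and overlaps(self.sites[-1].interval, self.sites[0].interval, L):
            raise ValueError("origin-wrapping site overlaps first site")

    def __iter__(self) -> Iterator[FootprintSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def intervals(self) -> list[tuple[int, int]]:
        return [s.interval for s in self.sites]

    def rotated(self, k: int) -> "SiteSet":
        L = self.genome.length
        rot = [replace(s, **dict(zip(("start", "end"), rotate_interval(s.interval, k, L))))
               for s in self.sites]
        return SiteSet(self.genome, rot, self.stage_id, self.call_threshold)


def _window_means(counts: np.ndarray, position: int, start_offset: int, width: int) -> float:
    L = len(counts)
    idx = (position + start_offset + np.arange(width)) % L
    return float(counts[idx].mean())


def fos_score(track: CoverageTrack, position: int, center_len: int, flank_len: int,
              pseudocount: float = 1.0) -> float:
    """Footprint occupancy score at one position for one window configuration.

    The central window of ``center_len`` bases is centered on ``position``;
    flanks of ``flank_len`` bases sit immediately left and right of it, all
    modular on the circle.  Lower scores indicate deeper protection.
    """
    if center_len < 1 or flank_len < 1:
        raise ValueError("window lengths must be >= 1")
    if center_len + 2 * flank_len > track.genome.length:
        raise ValueError("total window exceeds genome length")
    c0 = -(center_len // 2)  # center window start, relative to position
    cm = _window_means(track.counts, position, c0, center_len)
    lm = _window_means(track.counts, position, c0 - flank_len, flank_len)
    rm = _window_means(track.counts, position, c0 + center_len, flank_len)
    num = cm + pseudocount
    return num / max(lm, FLANK_FLOOR) + num / max(rm, FLANK_FLOOR)


def _rolling_sums(counts: np.ndarray, w: int) -> np.ndarray:
    """s[i] = sum of counts[i .. i+w-1] with modular wrap."""
    L = len(counts)
    ext = np.concatenate([counts, counts[: w - 1]]) if w > 1 else counts
    cs = np.concatenate([[0.0], np.cumsum(ext)])
    return cs[w: w + L] - cs[:L]


def best_scores(track: CoverageTrack, params: ScoringParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-position minimum FOS over all window configurations.

    Returns ``(best, scorable)``: ``best[p]`` is the minimum score over
    configurations whose flanks both clear ``min_flank_mean`` (inf where no
    configuration qualifies), and ``scorable[p]`` marks positions with at
    least one qualifying configuration.
    """
    counts = track.counts
    L = len(counts)
    best = np.full(L, np.inf)
    scorable = np.zeros(L, dtype=bool)
    for c in params.center_lengths:
        f = c  # equal flanks
        if c + 2 * f > L:
            continue
        sc = _rolling_sums(counts, c)
        sf = _rolling_sums(counts, f) if f != c else sc
        shift = c // 2
        center = np.roll(sc, shift) / c
        left = np.roll(sf, shift + f) / f
        right = np.roll(sf, shift - c) / f
        ok = (left >= params.min_flank_mean) & (right >= params.min_flank_mean)
        num = center + params.pseudocount
        score = num / np.maximum(left, FLANK_FLOOR) + num / np.maximum(right, FLANK_FLOOR)
        best = np.where(ok, np.minimum(best, score), best)
        scorable |= ok
    return best, scorable


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array, as half-open intervals."""
    L = len(mask)
    if mask.all():
        return [(0, L)]
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(L)
    runs = [(s, e) for s, e in zip(starts, ends)]
    # join a run ending at L with one starting at 0 across the origin
    if len(runs) > 1 and runs[-1][1] == L and runs[0][0] == 0:
        s, _ = runs.pop()
        _, e = runs.pop(0)
        runs.append((s, e))
    return runs


def scan_footprints(track: CoverageTrack, params: ScoringParams | None = None) -> SiteSet:
    """Call footprint sites on one coverage track.

    The calling threshold is the ``call_quantile`` quantile of the track's
    own per-position best-score distribution (over scorable positions); by
    circular symmetry this equals the threshold a rotation null would give.
    Unscorable positions (a flank mean below ``min_flank_mean`` in every
    configuration) break candidate runs and never seed a site.
    """
    params = params or ScoringParams()
    if not track.counts.any():
        warnings.warn("all-zero coverage track: no sites can be called")
        return SiteSet(track.genome, [], stage_id=track.stage_id)
    best, scorable = best_scores(track, params)
    if not scorable.any():
        warnings.warn("no scorable positions (coverage below min_flank_mean everywhere)")
        return SiteSet(track.genome, [], stage_id=track.stage_id)
    threshold = float(np.quantile(best[scorable], params.call_quantile))
    candidate = scorable & (best < threshold)
    sites = []
    for s, e in _circular_runs(candidate):
        n = interval_length((s, e), track.genome.length)
        idx = (s + np.arange(n)) % track.genome.length
        sites.append(FootprintSite(s, e, float(best[idx].min()),
                                   stage_id=track.stage_id, sample_id=track.sample_id))
    return SiteSet(track.genome, sites, stage_id=track.stage_id, call_threshold=threshold)


def concordant_sites(rep_a: SiteSet, rep_b: SiteSet, coordinates: str = "union") -> SiteSet:
    """Sites reproduced across a replicate pair.

    A site is retained iff it overlaps (>=1 base, modular) a site of the
    other replicate.  Retained coordinates are the union hull of each
    overlapping pair (``coordinates="intersection"`` keeps the shared bases
    instead); hulls that themselves overlap are merged.
    """
    if rep_a.genome.length != rep_b.genome.length or rep_a.genome.name != rep_b.genome.name:
        raise ValueError("replicate site sets are on different genomes")
    if coordinates not in ("union", "intersection"):
        raise ValueError("coordinates must be 'union' or 'intersection'")
    L = rep_a.genome.length
    pieces: list[tuple[tuple[int, int], float]] = []
    for a in rep_a:
        for b in rep_b:
            if overlaps(a.interval, b.interval, L):
                if coordinates == "union":
                    ivl = hull(a.interval, b.interval, L)
                else:
                    ivl = _intersection(a.interval, b.interval, L)
                pieces.append((ivl, min(a.score, b.score)))
    return _merge_scored(pieces, rep_a.genome, stage_id=rep_a.stage_id or rep_b.stage_id)


def _intersection(a: tuple[int, int], b: tuple[int, int], L: int) -> tuple[int, int]:
    # shared bases of two overlapping intervals; for doubly-wrapping overlap
    # keep the longer shared arc.
    la, lb = interval_length(a, L), interval_length(b, L)
    sa, sb = a[0] % L, b[0] % L
    arcs = []
    d = (sb - sa) % L
    if d < la:
        arcs.append((sb, min(la - d, lb)))
    d = (sa - sb) % L
    if d < lb:
        arcs.append((sa, min(lb - d, la)))
    s, n = max(arcs, key=lambda t: t[1])
    return normalize((s, (s + n) % L), L)


def _merge_scored(pieces: list[tuple[tuple[int, int], float]], genome: CircularGenome,
                  stage_id: str = "") -> SiteSet:
    """Merge scored intervals by >=1-base overlap; merged score = min of members."""
    L = genome.length
    merged = merge_intervals([ivl for ivl, _ in pieces], L)
    sites = []
    for ivl in merged:
        score = min((sc for piece, sc in pieces if overlaps(piece, ivl, L)), default=np.nan)
        sites.append(FootprintSite(ivl[0], ivl[1], score, stage_id=stage_id))
    return SiteSet(genome, sites, stage_id=stage_id)


def merge_sites(*sets: SiteSet) -> SiteSet:
    """Merge one or more site sets: transitive closure of >=1-base overlap.

    The output is pairwise non-overlapping; each merged site's score is the
    minimum over its contributors.  Idempotent.
    """
    if not sets:
        raise ValueError("merge_sites needs at least one SiteSet")
    genome = sets[0].genome
    for s in sets[1:]:
        if s.genome.length != genome.length or s.genome.name != genome.name:
            raise ValueError("site sets are on different genomes")
    pieces = [(site.interval, site.score) for ss in sets for site in ss]
    stages = sorted({ss.stage_id for ss in sets if ss.stage_id})
    return _merge_scored(pieces, genome, stage_id=",".join(stages))


def prevalence_filter(sets: Sequence[SiteSet], min_fraction: float,
                      strict: bool = False) -> SiteSet:
    """Merged reference sites supported by enough samples.

    A merged site is kept iff the fraction of samples contributing at least
    one overlapping site is >= ``min_fraction`` (strictly > with
    ``strict=True``, for "shared by more than X%" usage).
    """
    if not sets:
        raise ValueError("prevalence_filter needs at least one sample")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    reference = merge_sites(*sets)
    L = reference.genome.length
    kept = []
    n = len(sets)
    for site in reference:
        support = sum(
            1 for ss in sets if any(overlaps(site.interval, s.interval, L) for s in ss)
        )
        frac = support / n
        if (frac > min_fraction) if strict else (frac >= min_fraction):
            kept.append(site)
    return SiteSet(reference.genome, kept, stage_id=reference.stage_id)
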