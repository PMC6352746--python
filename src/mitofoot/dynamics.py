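"""Occupancy dynamics across an ordered developmental series.

Per-stage footprint sites are merged into reference sites; each reference
site gets a binary presence vector over the ordered stages, and the vector
is classified into one of four trajectory patterns:

* ``core`` — present at every stage;
* ``emergent_persistent`` — absent early, then present through the final
  stage once it appears;
* ``alternating`` — present, absent, then present again (any internal gap);
* ``transient`` — a single block of presence that ends before the final
  stage.

These four patterns partition all nonzero binary vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import FeatureAnnotation
from .footprints import SiteSet, merge_sites
from .intervals import coverage_mask, interval_length, overlaps

DYNAMICS_CLASSES = ("core", "emergent_persistent", "alternating", "transient")


@dataclass
class OccupancyMatrix:
    """Merged reference sites × ordered stages, with binary presence."""

    reference_sites: SiteSet
    stages: list[str]
    presence: np.ndarray  # (n_sites, n_stages) of 0/1

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.reference_sites), len(self.stages)):
            raise ValueError("presence shape does not match sites × stages")
        if len(self.reference_sites) and not self.presence.any(axis=1).all():
            raise ValueError("every reference site must be present in at least one stage")

    def to_dataframe(self) -> pd.DataFrame:
        idx = [f"{s.start}-{s.end}" for s in self.reference_sites]
        return pd.DataFrame(self.presence, index=idx, columns=self.stages)

    def classes(self) -> list[str]:
        return [classify_dynamics(row) for row in self.presence]


def build_occupancy(per_stage_sites: Sequence[SiteSet], stages: Sequence[str] | None = None
                    ) -> OccupancyMatrix:
    """Reference sites = merge over all stages; presence by modular overlap.

    Stage order is positional: the i-th site set belongs to the i-th stage
    label regardless of the labels' values.
    """
    if len(per_stage_sites) < 2:
        raise ValueError("need at least two stages")
    genome = per_stage_sites[0].genome
    for ss in per_stage_sites[1:]:
        if ss.genome.length != genome.length or ss.genome.name != genome.name:
            raise ValueError("stage site sets are on different genomes")
    if stages is None:
        stages = [ss.stage_id or f"stage{i + 1}" for i, ss in enumerate(per_stage_sites)]
    if len(stages) != len(per_stage_sites):
        raise ValueError("stage labels do not match the number of site sets")
    reference = merge_sites(*per_stage_sites)
    L = genome.length
    presence = np.zeros((len(reference), len(per_stage_sites)), dtype=np.int8)
    for i, ref in enumerate(reference):
        for t, ss in enumerate(per_stage_sites):
            if any(overlaps(ref.interval, s.interval, L) for s in ss):
                presence[i, t] = 1
    return OccupancyMatrix(reference, list(stages), presence)


def classify_dynamics(presence_vector: Sequence[int]) -> str:
    """Classify one site's presence vector into the four trajectory patterns."""
    v = np.asarray(presence_vector, dtype=int)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("presence vector must be 1-D with >= 2 stages")
    if not set(np.unique(v)) <= {0, 1}:
        raise ValueError("presence vector must be binary")
    if not v.any():
        raise ValueError("a site cannot be absent from every stage")
    ones = np.flatnonzero(v)
    first, last = ones[0], ones[-1]
    contiguous = len(ones) == last - first + 1
    if not contiguous:
        return "alternating"
    if last == len(v) - 1:
        return "core" if first == 0 else "emergent_persistent"
    return "transient"


def class_counts(matrix: OccupancyMatrix) -> pd.Series:
    """Number of reference sites per trajectory class (all classes listed)."""
    counts = pd.Series(0, index=list(DYNAMICS_CLASSES), dtype=int)
    for cls in matrix.classes():
        counts[cls] += 1
    return counts


def gain_loss(matrix: OccupancyMatrix) -> pd.DataFrame:
    """Per-stage counts of sites gained and lost relative to the previous stage.

    The first stage's gains are its present sites; its losses are 0.
    """
    p = matrix.presence
    if p.shape[1] < 2:
        raise ValueError("need at least two stages")
    gained = [int(p[:, 0].sum())]
    lost = [0]
    for t in range(1, p.shape[1]):
        gained.append(int(((p[:, t - 1] == 0) & (p[:, t] == 1)).sum()))
        lost.append(int(((p[:, t - 1] == 1) & (p[:, t] == 0)).sum()))
    return pd.DataFrame({"stage": matrix.stages, "gained": gained, "lost": lost})


def region_distribution(sites: SiteSet, annotation: FeatureAnnotation) -> pd.DataFrame:
    """Site counts and occupied-base fractions per feature class.

    A site counts toward a class iff it overlaps at least one feature of
    that class (a site spanning a boundary counts in both classes).  The
    base fraction is occupied bases within the class's footprint over the
    class's total bases.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    L = annotation.genome.length
    site_mask = coverage_mask(sites.intervals(), L)
    rows = []
    for cls in sorted({f.feature_class for f in annotation}):
        feats = [f for f in annotation if f.feature_class == cls]
        n_sites = sum(
            1 for s in sites if any(overlaps(s.interval, f.interval, L) for f in feats)
        )
        cls_mask = coverage_mask([f.interval for f in feats], L)
        total = int(cls_mask.sum())
        occupied = int((cls_mask & site_mask).sum())
        rows.append((cls, len(feats), n_sites, total, occupied,
                     occupied / total if total else np.nan))
    return pd.DataFrame(rows, columns=["feature_class", "n_features", "n_sites",
                                       "class_bases", "occupied_bases", "occupied_fraction"])


def embryo_adult_overlap(embryo_sites: SiteSet, adult_sites: SiteSet,
                         matrix: OccupancyMatrix) -> tuple[pd.DataFrame, dict]:
    """For each adult site: does it overlap an embryonic site, and if so the
    earliest stage at which any overlapping embryonic reference site was
    present.

    Returns a per-adult-site table and a summary with overlap counts and,
    per stage, the fraction of overlapping adult sites first seen at that
    stage (plus the cumulative fraction first seen at or before it).
    """
    if adult_sites.genome.length != embryo_sites.genome.length:
        raise ValueError("genome mismatch")
    L = embryo_sites.genome.length
    rows = []
    for a in adult_sites:
        overlapping_rows = [
            i for i, ref in enumerate(matrix.reference_sites)
            if overlaps(a.interval, ref.interval, L)
        ]
        direct = any(overlaps(a.interval, e.interval, L) for e in embryo_sites)
        earliest = None
        if overlapping_rows:
            earliest = int(min(np.flatnonzero(matrix.presence[i]).min()
                               for i in overlapping_rows))
        rows.append((a.start, a.end, direct, matrix.stages[earliest] if earliest is not None
                     else None))
    table = pd.DataFrame(rows, columns=["start", "end", "overlaps_embryo", "earliest_stage"])
    n_overlap = int(table["overlaps_embryo"].sum())
    by_stage = {}
    cum = 0
    for stage in matrix.stages:
        n = int((table["earliest_stage"] == stage).sum())
        cum += n
        by_stage[stage] = {
            "first_seen": n,
            "fraction_first_seen": n / n_overlap if n_overlap else np.nan,
            "cumulative_fraction": cum / n_overlap if n_overlap else np.nan,
        }
    summary = {"n_adult_sites": len(adult_sites), "n_overlapping": n_overlap,
               "fraction_overlapping": n_overlap / len(adult_sites) if len(adult_sites)
               else np.nan, "by_stage": by_stage}
    return table, summary
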