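"""Core containers: circular genome, per-base coverage, feature annotation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

VALID_BASES = set("ACGTN")
FEATURE_CLASSES = ("regulatory", "tRNA", "rRNA", "protein_coding", "d_loop", "gqp", "other")


@dataclass(frozen=True)
class CircularGenome:
    """A circular reference sequence of known length (e.g. a mitochondrial genome)."""

    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("genome length must be >= 1")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
            extra = set(self.sequence.upper()) - VALID_BASES
            if extra:
                raise ValueError(f"invalid bases in sequence: {sorted(extra)}")

    def base(self, position: int) -> str:
        """Base at a (modular) position."""
        if self.sequence is None:
            raise ValueError("genome has no sequence")
        return self.sequence[position % self.length]

    def subsequence(self, start: int, length: int) -> str:
        """``length`` bases starting at ``start``, wrapping across the origin."""
        if self.sequence is None:
            raise ValueError("genome has no sequence")
        L = self.length
        start %= L
        if start + length <= L:
            return self.sequence[start:start + length]
        s = self.sequence + self.sequence
        if length > L:
            raise ValueError("subsequence longer than genome")
        return s[start:start + length]

    def rotated(self, k: int) -> "CircularGenome":
        """The same circle read from an origin shifted by ``k`` bases."""
        if self.sequence is None:
            return self
        k %= self.length
        return CircularGenome(self.name, self.length,
                              self.sequence[-k:] + self.sequence[:-k] if k else self.sequence)

    def reverse_complement(self) -> "CircularGenome":
        if self.sequence is None:
            raise ValueError("genome has no sequence")
        comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
        return CircularGenome(self.name, self.length, self.sequence.translate(comp)[::-1])


@dataclass
class CoverageTrack:
    """Per-base non-negative counts on a circular genome.

    Indexing is modular: position ``p`` and ``p + length`` are the same base.
    """

    genome: CircularGenome
    counts: np.ndarray
    sample_id: str = ""
    stage_id: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) != self.genome.length:
            raise ValueError("counts length must equal genome length")
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")

    def __getitem__(self, position: int) -> float:
        return float(self.counts[position % self.genome.length])

    def rotated(self, k: int) -> "CoverageTrack":
        """Track with every base shifted by ``k`` around the circle."""
        return replace(self, counts=np.roll(self.counts, k % self.genome.length))

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class Feature:
    feature_id: str
    feature_class: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class FeatureAnnotation:
    """Named, typed intervals on the circle (genes, tRNAs, D-loop, motifs, ...)."""

    genome: CircularGenome
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        L = self.genome.length
        seen = set()
        for f in self.features:
            if not (0 <= f.start < L):
                raise ValueError(f"feature {f.feature_id}: start {f.start} out of range")
            if not (0 < f.end <= L):
                raise ValueError(f"feature {f.feature_id}: end {f.end} out of range")
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_class(self, feature_class: str) -> "FeatureAnnotation":
        return FeatureAnnotation(
            self.genome, [f for f in self.features if f.feature_class == feature_class]
        )

    def rotated(self, k: int) -> "FeatureAnnotation":
        from .intervals import rotate_interval

        L = self.genome.length
        rot = []
        for f in self.features:
            s, e = rotate_interval((f.start, f.end), k, L)
            rot.append(Feature(f.feature_id, f.feature_class, s, e, f.strand))
        return FeatureAnnotation(self.genome, rot)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.feature_id, f.feature_class, f.start, f.end, f.strand) for f in self.features],
            columns=["feature_id", "feature_class", "start", "end", "strand"],
        )
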