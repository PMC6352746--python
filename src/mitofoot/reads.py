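"""In-memory read collections on a circular genome, with SAM interchange.

Reads are stored positionally (start, fixed length, strand) against the
reference; base calls equal the reference except at recorded substitutions.
This keeps million-read simulations cheap while still exposing per-base
calls for variant counting.  Reads may wrap across the origin in memory;
SAM export requires non-wrapping reads (a linear alignment cannot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .genome import CircularGenome


@dataclass
class ReadSet:
    """Ungapped fixed-length reads aligned to a circular genome.

    ``sub_keys`` / ``sub_bases`` encode substituted base calls as sorted
    flat keys ``read_index * read_length + offset`` with the called base.
    """

    genome: CircularGenome
    starts: np.ndarray
    read_length: int
    is_reverse: np.ndarray | None = None
    sub_keys: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sub_bases: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U1"))

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64) % self.genome.length
        if self.is_reverse is None:
            self.is_reverse = np.zeros(len(self.starts), dtype=bool)
        if self.read_length > self.genome.length:
            raise ValueError("read length exceeds genome length")
        order = np.argsort(self.sub_keys, kind="stable")
        self.sub_keys = np.asarray(self.sub_keys, dtype=np.int64)[order]
        self.sub_bases = np.asarray(self.sub_bases, dtype="U1")[order]

    def __len__(self) -> int:
        return len(self.starts)

    def covering(self, position: int) -> np.ndarray:
        """Indices of reads whose alignment covers ``position`` (modular)."""
        offs = (position - self.starts) % self.genome.length
        return np.flatnonzero(offs < self.read_length)

    def base_calls(self, position: int) -> tuple[np.ndarray, np.ndarray]:
        """(read indices covering ``position``, their called base at it)."""
        idx = self.covering(position)
        if self.genome.sequence is None:
            raise ValueError("genome has no sequence")
        ref_base = self.genome.base(position)
        bases = np.full(len(idx), ref_base, dtype="U1")
        if len(self.sub_keys):
            offs = (position - self.starts[idx]) % self.genome.length
            keys = idx * self.read_length + offs
            pos_in_subs = np.searchsorted(self.sub_keys, keys)
            hit = (pos_in_subs < len(self.sub_keys)) & (
                self.sub_keys[np.minimum(pos_in_subs, len(self.sub_keys) - 1)] == keys
            )
            bases[hit] = self.sub_bases[pos_in_subs[hit]]
        return idx, bases

    def sequence_of(self, i: int) -> str:
        """Reference-orientation base calls of read ``i``."""
        seq = list(self.genome.subsequence(int(self.starts[i]), self.read_length))
        lo = np.searchsorted(self.sub_keys, i * self.read_length)
        hi = np.searchsorted(self.sub_keys, (i + 1) * self.read_length)
        for key, base in zip(self.sub_keys[lo:hi], self.sub_bases[lo:hi]):
            seq[int(key) - i * self.read_length] = str(base)
        return "".join(seq)

    def cut_positions(self, tn5_offset: bool = False) -> np.ndarray:
        """5' alignment-start positions (one per read), optionally Tn5-shifted.

        Forward reads cut at the alignment start (+4 with the Tn5 offset);
        reverse reads at the last aligned base (-5 with the offset).
        """
        L = self.genome.length
        fwd = (self.starts + (4 if tn5_offset else 0)) % L
        rev = (self.starts + self.read_length - 1 - (5 if tn5_offset else 0)) % L
        return np.where(self.is_reverse, rev, fwd)

    def to_sam(self, path: str) -> None:
        """Write as a coordinate-sorted SAM file (reads must not wrap the origin)."""
        if np.any(self.starts + self.read_length > self.genome.length):
            raise ValueError("origin-wrapping reads cannot be written to SAM")
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.genome.name, "LN": self.genome.length}],
        }
        order = np.argsort(self.starts, kind="stable")
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            for rank, i in enumerate(order):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read{int(i)}"
                a.reference_id = 0
                a.reference_start = int(self.starts[i])
                a.flag = 16 if self.is_reverse[i] else 0
                a.mapping_quality = 60
                a.cigarstring = f"{self.read_length}M"
                a.query_sequence = self.sequence_of(int(i))
                a.query_qualities = pysam.qualitystring_to_array("I" * self.read_length)
                out.write(a)

    @classmethod
    def from_sam(cls, path: str, genome: CircularGenome) -> "ReadSet":
        """Load ungapped fixed-length reads back from SAM (inverse of :meth:`to_sam`)."""
        starts, rev, sub_keys, sub_bases = [], [], [], []
        read_length = None
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for a in sam:
                if a.is_unmapped:
                    continue
                if a.reference_name != genome.name:
                    raise ValueError(
                        f"alignment reference {a.reference_name!r} != genome {genome.name!r}"
                    )
                if read_length is None:
                    read_length = a.query_length
                elif a.query_length != read_length:
                    raise ValueError("mixed read lengths are not supported")
                i = len(starts)
                starts.append(a.reference_start)
                rev.append(a.is_reverse)
                if genome.sequence is not None:
                    ref = genome.subsequence(a.reference_start, read_length)
                    for off, (r, q) in enumerate(zip(ref, a.query_sequence)):
                        if q != r:
                            sub_keys.append(i * read_length + off)
                            sub_bases.append(q)
        return cls(genome, np.array(starts, dtype=np.int64), read_length or 0,
                   np.array(rev, dtype=bool),
                   np.array(sub_keys, dtype=np.int64), np.array(sub_bases, dtype="U1"))
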