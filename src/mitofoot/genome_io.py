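"""Readers and writers for the standard formats the pipeline touches.

Coordinates are 0-based half-open internally (BED-native); GFF input is
converted from 1-based closed.  All per-base arithmetic is modular on the
circular genome.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome, CoverageTrack, Feature, FeatureAnnotation
from .footprints import SiteSet, FootprintSite


# ---------------------------------------------------------------- FASTA

def load_genome(path: str) -> CircularGenome:
    """Read a single-record FASTA as a circular genome.

    More than one record signals a non-mitochondrial reference and is
    rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA record found")
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} records; a mitochondrial reference must be a single contig"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{path}: empty record")
    return CircularGenome(rec.id, len(seq), seq)


def write_genome(genome: CircularGenome, path: str) -> None:
    if genome.sequence is None:
        raise ValueError("genome has no sequence to write")
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.name, description="")], path, "fasta")


# ---------------------------------------------------------------- alignments

def coverage_from_alignments(path: str, genome: CircularGenome, mode: str = "cut_sites",
                             tn5_offset: bool = False, deduplicate: bool = False,
                             sample_id: str = "", stage_id: str = "",
                             replicate_id: str = "") -> CoverageTrack:
    """Per-base coverage from a coordinate-sorted SAM/BAM.

    ``mode="full_read"`` counts every base covered by the alignment;
    ``mode="cut_sites"`` counts one event per read at its 5' end (forward
    reads at the alignment start, reverse reads at the last aligned base),
    optionally shifted by the +4/-5 Tn5 convention.  Alignments extending
    past the reference end wrap onto the origin.  Duplicate alignments
    (same start/end/strand) are kept unless ``deduplicate`` is set — deep
    mtDNA coverage makes genuine duplicates common.
    """
    if mode not in ("full_read", "cut_sites"):
        raise ValueError(f"unknown mode {mode!r}")
    L = genome.length
    counts = np.zeros(L, dtype=float)
    seen: set[tuple[int, int, bool]] = set()
    last_start = -1
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            if a.reference_name != genome.name:
                raise ValueError(
                    f"alignment reference {a.reference_name!r} does not match "
                    f"genome {genome.name!r}"
                )
            if a.reference_start < last_start:
                raise ValueError("alignment file is not coordinate-sorted")
            last_start = a.reference_start
            start, end = a.reference_start, a.reference_end
            if deduplicate:
                key = (start, end, a.is_reverse)
                if key in seen:
                    continue
                seen.add(key)
            if mode == "full_read":
                idx = np.arange(start, end) % L
                np.add.at(counts, idx, 1.0)
            else:
                if a.is_reverse:
                    cut = (end - 1 - (5 if tn5_offset else 0)) % L
                else:
                    cut = (start + (4 if tn5_offset else 0)) % L
                counts[cut] += 1.0
    return CoverageTrack(genome, counts, sample_id=sample_id, stage_id=stage_id,
                         replicate_id=replicate_id)


# ---------------------------------------------------------------- bedGraph

def load_coverage(path: str, genome: CircularGenome, sample_id: str = "",
                  stage_id: str = "", replicate_id: str = "") -> CoverageTrack:
    """Dense per-base track from a bedGraph; unspecified bases are 0."""
    counts = np.zeros(genome.length, dtype=float)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: malformed bedGraph line")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom != genome.name:
                raise ValueError(f"{path}:{ln}: chromosome {chrom!r} != genome {genome.name!r}")
            if not (0 <= start < end <= genome.length):
                raise ValueError(f"{path}:{ln}: interval [{start},{end}) out of bounds")
            if value < 0:
                raise ValueError(f"{path}:{ln}: negative coverage value")
            counts[start:end] = value
    return CoverageTrack(genome, counts, sample_id=sample_id, stage_id=stage_id,
                         replicate_id=replicate_id)


def write_coverage(track: CoverageTrack, path: str) -> None:
    """Run-length encode a dense track to bedGraph (zero runs included)."""
    c = track.counts
    change = np.flatnonzero(np.diff(c)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(c)]])
    with open(path, "w") as out:
        for s, e in zip(starts, ends):
            v = c[s]
            out.write(f"{track.genome.name}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------- features

_DEFAULT_CLASS_MAP = {
    "tRNA": "tRNA", "trna": "tRNA",
    "rRNA": "rRNA", "rrna": "rRNA",
    "gene": "protein_coding", "CDS": "protein_coding", "mRNA": "protein_coding",
    "D_loop": "d_loop", "D-loop": "d_loop", "d_loop": "d_loop",
    "regulatory": "regulatory", "regulatory_region": "regulatory",
    "promoter": "regulatory", "origin_of_replication": "regulatory",
    # canonical mtDNA regulatory element names
    "HSP": "regulatory", "LSP": "regulatory", "CSB": "regulatory",
    "Ori": "regulatory", "TAS": "regulatory",
    "gqp": "gqp",
}


def _classify(key: str, class_map: Optional[Mapping[str, str]]) -> str:
    table = dict(_DEFAULT_CLASS_MAP)
    if class_map:
        table.update(class_map)
    if key in table:
        return table[key]
    for prefix, cls in table.items():
        if key.startswith(prefix):
            return cls
    return "other"


def load_features(path: str, genome: CircularGenome,
                  class_map: Optional[Mapping[str, str]] = None) -> FeatureAnnotation:
    """Read features from BED (0-based half-open) or GFF3 (1-based closed).

    For BED the name column keys the class map; for GFF the type column.
    A wrap-around feature split into two BED blocks sharing a name — one
    ending at the genome end and one starting at the origin — is rejoined
    into a single wrapped feature.
    """
    ext = os.path.splitext(path)[1].lower()
    raw: list[tuple[str, str, int, int, str]] = []  # (id, class, start, end, strand)
    if ext in (".gff", ".gff3", ".gtf"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 8:
                    raise ValueError(f"{path}:{ln}: malformed GFF line")
                ftype, start, end = fields[2], int(fields[3]) - 1, int(fields[4])
                strand = fields[6] if fields[6] in "+-" else "."
                fid = f"{ftype}_{ln}"
                if len(fields) >= 9:
                    for part in fields[8].split(";"):
                        if part.startswith(("ID=", "Name=")):
                            fid = part.split("=", 1)[1]
                            break
                raw.append((fid, _classify(ftype, class_map), start, end, strand))
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{ln}: BED needs at least 4 columns")
                start, end, name = int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
                raw.append((name, _classify(name, class_map), start, end, strand))
    for fid, _, start, end, _ in raw:
        if not (0 <= start < end <= genome.length):
            raise ValueError(f"feature {fid!r}: [{start},{end}) out of range for genome")
    # rejoin wrap-around features split into two blocks
    by_name: dict[str, list[int]] = {}
    for i, rec in enumerate(raw):
        by_name.setdefault(rec[0], []).append(i)
    features, consumed = [], set()
    counters: dict[str, int] = {}
    for fid, idxs in by_name.items():
        if len(idxs) == 2:
            a, b = raw[idxs[0]], raw[idxs[1]]
            blocks = sorted([a, b], key=lambda r: r[2])
            if blocks[0][2] == 0 and blocks[1][3] == genome.length:
                features.append(Feature(fid, a[1], blocks[1][2], blocks[0][3], a[4]))
                consumed.update(idxs)
    for i, (fid, cls, start, end, strand) in enumerate(raw):
        if i in consumed:
            continue
        if len(by_name[fid]) > 1:
            counters[fid] = counters.get(fid, 0) + 1
            fid = f"{fid}.{counters[fid]}"
        features.append(Feature(fid, cls, start, end, strand))
    return FeatureAnnotation(genome, features)


def write_features_bed(annotation: FeatureAnnotation, path: str) -> None:
    """BED6; wrap-around features are written as two blocks sharing a name."""
    L = annotation.genome.length
    with open(path, "w") as out:
        for f in annotation:
            name = annotation.genome.name
            if f.end > f.start:
                out.write(f"{name}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n")
            else:
                out.write(f"{name}\t{f.start}\t{L}\t{f.feature_id}\t0\t{f.strand}\n")
                out.write(f"{name}\t0\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n")


# ---------------------------------------------------------------- sites

def write_sites_bed(sites: SiteSet, path: str) -> None:
    """BED6 with score = 1000*(1 - FOS/threshold) clipped to [0, 1000]."""
    L = sites.genome.length
    thr = sites.call_threshold
    with open(path, "w") as out:
        for s in sites:
            if thr and np.isfinite(s.score):
                score = int(np.clip(1000 * (1 - s.score / thr), 0, 1000))
            else:
                score = 0
            end = s.end if s.end > s.start else s.end + L  # linearized for BED readers
            if end <= L:
                out.write(f"{sites.genome.name}\t{s.start}\t{end}\t"
                          f"site_{s.start}_{s.end}\t{score}\t.\n")
            else:
                out.write(f"{sites.genome.name}\t{s.start}\t{L}\t"
                          f"site_{s.start}_{s.end}\t{score}\t.\n")
                out.write(f"{sites.genome.name}\t0\t{end - L}\t"
                          f"site_{s.start}_{s.end}\t{score}\t.\n")


def write_sites_tsv(sites: SiteSet, path: str) -> None:
    with open(path, "w") as out:
        out.write("start\tend\tscore\tstage_id\tsample_id\n")
        for s in sites:
            out.write(f"{s.start}\t{s.end}\t{s.score:.6g}\t{s.stage_id}\t{s.sample_id}\n")


def read_sites_tsv(path: str, genome: CircularGenome) -> SiteSet:
    sites = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            start, end, score, stage_id, sample_id = (line.rstrip("\n").split("\t") + [""] * 5)[:5]
            sites.append(FootprintSite(int(start), int(end), float(score), stage_id, sample_id))
    return SiteSet(genome, sites)
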