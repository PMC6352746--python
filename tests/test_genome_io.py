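"""Format round-trips, coverage building, and circular correctness of IO."""

import numpy as np
import pytest

from mitofoot import CircularGenome, CoverageTrack, ReadSet
from mitofoot.genome_io import (
    coverage_from_alignments,
    load_coverage,
    load_features,
    load_genome,
    write_coverage,
    write_features_bed,
    write_genome,
    write_sites_bed,
    write_sites_tsv,
    read_sites_tsv,
)
from mitofoot.footprints import FootprintSite, SiteSet


# ---------------------------------------------------------------- FASTA

def test_fasta_roundtrip_and_single_record(tmp_path, seq_genome):
    path = tmp_path / "mt.fa"
    write_genome(seq_genome, str(path))
    loaded = load_genome(str(path))
    assert loaded.length == seq_genome.length
    assert loaded.sequence == seq_genome.sequence
    assert loaded.name == seq_genome.name


def test_fasta_multi_record_rejected(tmp_path):
    path = tmp_path / "two.fa"
    path.write_text(">a\nACGT\n>b\nACGT\n")
    with pytest.raises(ValueError, match="2 records"):
        load_genome(str(path))
    with pytest.raises(FileNotFoundError):
        load_genome(str(tmp_path / "missing.fa"))


# ---------------------------------------------------------------- bedGraph

def test_bedgraph_dense_roundtrip(tmp_path, small_genome):
    rng = np.random.default_rng(0)
    track = CoverageTrack(small_genome, rng.integers(0, 50, 300).astype(float))
    path = tmp_path / "cov.bedGraph"
    write_coverage(track, str(path))
    back = load_coverage(str(path), small_genome)
    np.testing.assert_array_equal(back.counts, track.counts)


def test_bedgraph_basics(tmp_path, small_genome):
    path = tmp_path / "c.bedGraph"
    path.write_text("mt\t0\t5\t3\n")
    t = load_coverage(str(path), small_genome)
    assert list(t.counts[:6]) == [3, 3, 3, 3, 3, 0]
    (tmp_path / "empty.bedGraph").write_text("")
    t0 = load_coverage(str(tmp_path / "empty.bedGraph"), small_genome)
    assert not t0.counts.any()
    (tmp_path / "bad.bedGraph").write_text("mt\t290\t310\t1\n")
    with pytest.raises(ValueError, match="out of bounds"):
        load_coverage(str(tmp_path / "bad.bedGraph"), small_genome)
    (tmp_path / "neg.bedGraph").write_text("mt\t0\t5\t-1\n")
    with pytest.raises(ValueError, match="negative"):
        load_coverage(str(tmp_path / "neg.bedGraph"), small_genome)


# ---------------------------------------------------------------- alignments

def _readset(genome, starts, read_length=20, reverse=None):
    starts = np.array(starts)
    rev = np.zeros(len(starts), bool) if reverse is None else np.array(reverse)
    return ReadSet(genome, starts, read_length, rev)


def test_coverage_full_read_and_cut_sites(tmp_path, seq_genome):
    reads = _readset(seq_genome, [10], read_length=20)
    sam = tmp_path / "one.sam"
    reads.to_sam(str(sam))
    full = coverage_from_alignments(str(sam), seq_genome, mode="full_read")
    assert full.counts[10:30].sum() == 20
    assert full.total == 20
    cuts = coverage_from_alignments(str(sam), seq_genome, mode="cut_sites")
    assert cuts.counts[10] == 1 and cuts.total == 1
    shifted = coverage_from_alignments(str(sam), seq_genome, mode="cut_sites",
                                       tn5_offset=True)
    assert shifted.counts[14] == 1


def test_reverse_read_cut_site(tmp_path, seq_genome):
    reads = _readset(seq_genome, [10], read_length=20, reverse=[True])
    sam = tmp_path / "rev.sam"
    reads.to_sam(str(sam))
    cuts = coverage_from_alignments(str(sam), seq_genome, mode="cut_sites")
    assert cuts.counts[29] == 1  # last aligned base
    shifted = coverage_from_alignments(str(sam), seq_genome, mode="cut_sites",
                                       tn5_offset=True)
    assert shifted.counts[24] == 1


def test_coverage_mass_conservation(tmp_path, seq_genome):
    rng = np.random.default_rng(1)
    n = 500
    starts = rng.integers(0, seq_genome.length - 25, n)
    reads = _readset(seq_genome, starts, read_length=25)
    sam = tmp_path / "many.sam"
    reads.to_sam(str(sam))
    full = coverage_from_alignments(str(sam), seq_genome, mode="full_read")
    assert full.total == n * 25
    cuts = coverage_from_alignments(str(sam), seq_genome, mode="cut_sites")
    assert cuts.total == n


def test_reference_name_mismatch(tmp_path, seq_genome):
    reads = _readset(seq_genome, [0], read_length=20)
    sam = tmp_path / "m.sam"
    reads.to_sam(str(sam))
    other = CircularGenome("nuclear", seq_genome.length)
    with pytest.raises(ValueError, match="does not match"):
        coverage_from_alignments(str(sam), other)


def test_unsorted_rejected(tmp_path, seq_genome):
    sam = tmp_path / "unsorted.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:mt\tLN:400\n"
        "r1\t0\tmt\t101\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
        "r2\t0\tmt\t51\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
    )
    with pytest.raises(ValueError, match="not coordinate-sorted"):
        coverage_from_alignments(str(sam), seq_genome)


def test_origin_spanning_alignment_wraps(tmp_path, seq_genome):
    # read aligned at position 395 of a 400-base circle, 10M: wraps onto 0..4
    sam = tmp_path / "wrap.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:mt\tLN:405\n"
        "r1\t0\tmt\t396\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
    )
    full = coverage_from_alignments(str(sam), seq_genome, mode="full_read")
    assert full.counts[395:400].sum() == 5
    assert full.counts[0:5].sum() == 5
    # equivalent rotated read on the rotated genome gives the rotated track
    rot_sam = tmp_path / "rot.sam"
    rot_sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:mt\tLN:405\n"
        "r1\t0\tmt\t96\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
    )
    rot = coverage_from_alignments(str(rot_sam), seq_genome, mode="full_read")
    np.testing.assert_array_equal(np.roll(full.counts, 100), rot.counts)


def test_deduplication_flag(tmp_path, seq_genome):
    reads = _readset(seq_genome, [10, 10, 10], read_length=20)
    sam = tmp_path / "dup.sam"
    reads.to_sam(str(sam))
    keep = coverage_from_alignments(str(sam), seq_genome, mode="cut_sites")
    assert keep.counts[10] == 3
    dedup = coverage_from_alignments(str(sam), seq_genome, mode="cut_sites",
                                     deduplicate=True)
    assert dedup.counts[10] == 1


# ---------------------------------------------------------------- features

def test_bed_and_gff_conventions(tmp_path, seq_genome):
    bed = tmp_path / "f.bed"
    bed.write_text("mt\t0\t10\ttRNA-Phe\t0\t+\n")
    ann = load_features(str(bed), seq_genome)
    f = ann.features[0]
    assert (f.start, f.end) == (0, 10)
    assert f.feature_class == "tRNA"
    gff = tmp_path / "f.gff3"
    gff.write_text("mt\tsrc\ttRNA\t1\t10\t.\t+\t.\tID=tRNA-Phe\n")
    ann2 = load_features(str(gff), seq_genome)
    assert (ann2.features[0].start, ann2.features[0].end) == (0, 10)
    assert ann2.features[0].feature_class == "tRNA"


def test_wraparound_bed_two_blocks_rejoined(tmp_path, seq_genome):
    bed = tmp_path / "wrap.bed"
    bed.write_text("mt\t390\t400\tD_loop\t0\t+\nmt\t0\t15\tD_loop\t0\t+\n")
    ann = load_features(str(bed), seq_genome)
    assert len(ann) == 1
    f = ann.features[0]
    assert (f.start, f.end) == (390, 15)  # wrapped representation
    # round-trip back through BED re-splits into the same two blocks
    out = tmp_path / "out.bed"
    write_features_bed(ann, str(out))
    again = load_features(str(out), seq_genome)
    assert (again.features[0].start, again.features[0].end) == (390, 15)


def test_feature_out_of_range(tmp_path, seq_genome):
    bed = tmp_path / "bad.bed"
    bed.write_text("mt\t0\t500\tgene1\n")
    with pytest.raises(ValueError, match="out of range"):
        load_features(str(bed), seq_genome)


# ---------------------------------------------------------------- sites

def test_sites_tsv_roundtrip_and_bed(tmp_path, seq_genome):
    sites = SiteSet(seq_genome, [FootprintSite(10, 40, 0.3, "2C", "s1"),
                                 FootprintSite(390, 5, 0.7, "2C", "s1")],
                    stage_id="2C", call_threshold=1.0)
    tsv = tmp_path / "s.tsv"
    write_sites_tsv(sites, str(tsv))
    back = read_sites_tsv(str(tsv), seq_genome)
    assert [(s.start, s.end, s.score) for s in back] == \
           [(s.start, s.end, s.score) for s in sites]
    bed = tmp_path / "s.bed"
    write_sites_bed(sites, str(bed))
    lines = bed.read_text().strip().split("\n")
    assert len(lines) == 3  # wrapped site written as two blocks
    score = int(lines[0].split("\t")[4])
    assert score == 700  # 1000 * (1 - 0.3/1.0)
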