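#!/usr/bin/env python
"""Simulate the full synthetic study: a mouse-sized circular mitochondrial
genome, a scripted 7-stage developmental series of replicate coverage
pairs, a feature annotation, a NUMT diagnostic-variant catalog, and read
sets with contamination and an optional cut-site bias.

Bulky per-base tracks and read files go to scratch/ (inputs for the later
steps); ground-truth tables go to results/.
"""

import os
import sys

import numpy as np

import mitofoot as mf
from mitofoot.genome_io import write_coverage, write_features_bed, write_genome
from mitofoot.simulate import MOUSE_STAGES, seven_stage_config

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch", "simulated")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(SCRATCH, exist_ok=True)
os.makedirs(RESULTS, exist_ok=True)

cfg = seven_stage_config(seed=SEED)
genome = mf.random_genome(cfg.genome_length, seed=SEED)
# plant quadruplex-prone motifs: random mtDNA-like composition is too
# guanine-poor to contain any by chance
rng = np.random.default_rng(SEED + 10)
g4_positions = sorted(rng.choice(cfg.genome_length, size=12, replace=False))
genome = mf.embed_sequence(genome, "GGGTTGGGTTGGGTTGGG", g4_positions)
write_genome(genome, os.path.join(SCRATCH, "chrM.fa"))

sim = mf.simulate_stage_series(cfg, genome=genome)
for stage in sim["stages"]:
    for track in sim["tracks"][stage]:
        name = f"{stage}.{track.replicate_id}.bedGraph"
        write_coverage(track, os.path.join(SCRATCH, name))

ann = mf.example_annotation(genome)
write_features_bed(ann, os.path.join(SCRATCH, "features.bed"))

# diagnostic variants: one inside each planted site plus spaced background
in_site = [int((s.start + s.width // 2) % cfg.genome_length)
           for s in sim["planted_sites"]]
background = []
while len(background) < 20:
    p = int(rng.integers(0, cfg.genome_length))
    if all(min((p - q) % cfg.genome_length, (q - p) % cfg.genome_length) >= 60
           for q in in_site + background):
        background.append(p)
catalog = mf.catalog_at_positions(genome, in_site + background, seed=SEED + 1)
catalog.to_tsv(os.path.join(SCRATCH, "numt_catalog.tsv"))

reads_cfg = mf.SimulationConfig(genome_length=cfg.genome_length, numt_rate=0.002,
                                read_length=50, seed=SEED + 2)
reads = mf.simulate_reads(reads_cfg, genome, catalog=catalog, n_reads=150_000)
reads.to_sam(os.path.join(SCRATCH, "reads.sam"))

biased_cfg = mf.SimulationConfig(genome_length=cfg.genome_length, read_length=50,
                                 bias_kmer=("AATTCC", 5.0), seed=SEED + 3)
biased = mf.simulate_reads(biased_cfg, genome, n_reads=60_000)
np.savetxt(os.path.join(SCRATCH, "biased_cuts.txt"),
           biased.cut_positions(), fmt="%d")

# ground truth for later comparison
with open(os.path.join(RESULTS, "planted_truth.tsv"), "w") as fh:
    fh.write("site\tstart\twidth\tprotection\t" + "\t".join(MOUSE_STAGES) + "\n")
    for i, s in enumerate(sim["planted_sites"]):
        flags = "\t".join(map(str, sim["truth_presence"][i]))
        fh.write(f"site{i + 1}\t{s.start}\t{s.width}\t{s.protection:.3f}\t{flags}\n")

n_tracks = sum(len(v) for v in sim["tracks"].values())
print(f"wrote genome ({genome.length} bp), {n_tracks} coverage tracks over "
      f"{len(sim['stages'])} stages, {len(ann)} features, "
      f"{len(catalog)} catalog variants, {len(reads)} reads "
      f"(NUMT rate 0.002) and {len(biased)} biased cut sites to {SCRATCH}")
print(f"planted truth: {len(sim['planted_sites'])} sites -> results/planted_truth.tsv")
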