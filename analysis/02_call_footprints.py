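#!/usr/bin/env python
"""Call footprint sites per stage from the simulated coverage tracks.

Each stage's replicate pair is scanned independently with the sliding-
window occupancy score; only replicate-concordant sites are kept, matching
the duplicate-restriction step of the pipeline.  Writes per-stage site
tables and a summary count table.
"""

import os

import mitofoot as mf
from mitofoot.genome_io import load_coverage, load_genome, write_sites_bed, write_sites_tsv
from mitofoot.simulate import MOUSE_STAGES

HERE = os.path.dirname(__file__)
SCRATCH = os.path.join(HERE, "..", "scratch", "simulated")
RESULTS = os.path.join(HERE, "..", "results")
os.makedirs(RESULTS, exist_ok=True)

genome = load_genome(os.path.join(SCRATCH, "chrM.fa"))
params = mf.ScoringParams()  # 18-124 bp windows, 1% calling quantile

counts = []
for stage in MOUSE_STAGES:
    reps = [load_coverage(os.path.join(SCRATCH, f"{stage}.rep{r}.bedGraph"), genome,
                          stage_id=stage, replicate_id=f"rep{r}")
            for r in (1, 2)]
    scans = [mf.scan_footprints(t, params) for t in reps]
    conc = mf.concordant_sites(*scans)
    write_sites_tsv(conc, os.path.join(RESULTS, f"sites_{stage}.tsv"))
    write_sites_bed(conc, os.path.join(SCRATCH, f"sites_{stage}.bed"))
    counts.append((stage, len(scans[0]), len(scans[1]), len(conc)))

with open(os.path.join(RESULTS, "footprint_counts.tsv"), "w") as fh:
    fh.write("stage\trep1_sites\trep2_sites\tconcordant_sites\n")
    for row in counts:
        fh.write("\t".join(map(str, row)) + "\n")

print("stage  rep1  rep2  concordant")
for stage, r1, r2, c in counts:
    print(f"{stage:8s} {r1:4d} {r2:4d} {c:6d}")
print("concordance removes nearly all single-replicate noise calls; "
      "tables in results/sites_<stage>.tsv")
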