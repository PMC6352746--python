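# mitofoot

Footprint detection and occupancy dynamics on circular mitochondrial
genomes from chromatin-accessibility coverage.

Mitochondrial DNA is coated by proteins — the packaging factor TFAM and a
growing list of imported regulators — and where a protein sits, ATAC-seq
or DNase-seq coverage dips. `mitofoot` turns deep per-base coverage over
the circular mitochondrial genome into called **footprint sites**, follows
their **gain, loss and persistence across an ordered developmental
series**, and asks whether they **co-localize** with regulatory elements,
tRNA genes and G-quadruplex-prone sequence, while screening for the two
classic artifacts of this analysis: transposase sequence bias and reads
that really come from nuclear mitochondrial inserts (NUMTs).

It is written for researchers analysing mtDNA protein–DNA organization
from bulk accessibility data, and for anyone who needs careful interval
algebra on a circular genome.

## The score at the core

Every position *p* is scored over sliding windows of total span 18–124
bases: a central window of width *c* with equal flanks,

    FOS(p, c) = (C + 1) / max(L, 0.25) + (C + 1) / max(R, 0.25)

where *C*, *L*, *R* are the central, left- and right-flank coverage means.
Low scores mean the center is depleted relative to *both* flanks — a
footprint, not a slope. The per-position best score is the minimum over
all window widths; positions below an empirical per-track quantile
threshold (default 1%) form candidate sites, only replicate-concordant
sites are kept, and sites overlapping by at least one base are merged
across stages. Merged sites × stages yields a binary occupancy matrix,
and each site's trajectory is classified as `core`,
`emergent_persistent`, `alternating` or `transient`.

All coordinates are 0-based half-open and all arithmetic is modular on
the circle; origin-wrapping sites, reads, features and motifs are
first-class citizens. See `docs/methods.md` for the full model.

## Worked example

The `analysis/` scripts run the whole pipeline on synthetic data with
planted ground truth: ten footprints (36 bp wide, ≥95% protection) follow
a scripted presence matrix across seven developmental stages on a
16,299-base circular genome at ~80× overdispersed coverage, two
replicates per stage.

```bash
python analysis/01_simulate_inputs.py        # genome, tracks, reads, truth
python analysis/02_call_footprints.py        # scan + replicate concordance
python analysis/03_occupancy_dynamics.py     # occupancy matrix + classes
python analysis/04_structure_colocalization.py
python analysis/05_bias_and_numt.py
```

Step 02 prints the per-stage calls — single-replicate scans admit ~1% of
positions by construction, replicate concordance strips them back to the
planted sites:

```
stage  rep1  rep2  concordant
early2C     7    6      6
2C          6    7      6
4C          6    6      6
8C          7    7      6
ICM         9   12      5
E6          6    6      6
E7.2        6    6      6
```

(the script planted 6, 6, 6, 6, 5, 6 and 6 sites per stage). Step 03
recovers the scripted trajectory classes exactly:

```
trajectory classes:
  core                   1  (10%)
  emergent_persistent    3  (30%)
  alternating            4  (40%)
  transient              2  (20%)
recovered class multiset matches the generator's script: True
```

and step 05 recovers the planted 0.2% NUMT contamination and finds no
site/non-site difference, while flagging the read set generated with a
5-fold cut-site preference:

```
unbiased reads: 0/4096 6-mers flagged -> biased = False
biased reads:   AATTCC enrichment 3.31, p_adj 1.66e-11 -> biased = True
pooled NUMT read fraction: 0.2274% (planted 0.2%)
site positions mean 0.2964%, non-site 0.1986%; rank-test p = 0.859
```

Library use is one import away:

```python
import mitofoot as mf

genome = mf.random_genome(16299, seed=0)
cfg = mf.SimulationConfig(planted_sites=[mf.PlantedSite(5000, 30, 0.95)], seed=0)
(rep1, rep2), truth = mf.simulate_track(cfg, genome=genome)
sites = mf.concordant_sites(mf.scan_footprints(rep1), mf.scan_footprints(rep2))
print(sites.intervals())   # [(5000, 5034)] — the planted [5000, 5030) site
```

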