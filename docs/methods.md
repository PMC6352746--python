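# Methods

`mitofoot` detects protein-occupancy footprints in chromatin-accessibility
coverage over a circular mitochondrial genome, follows their dynamics
across an ordered developmental series, and tests their association with
annotated elements, G-quadruplex-prone sequence, and nuclear-insert (NUMT)
read contamination. Because mtDNA is circular, every interval, window and
distance computation in the package is modular; intervals are 0-based
half-open `(start, end)` with `end < start` denoting an origin-wrapping
interval.

## Footprint occupancy score

Accessibility protection appears as a local depression in per-base
coverage. Each position *p* is scored over a family of symmetric sliding
windows: a central window of *c* bases centered on *p*, flanked
immediately left and right by windows of the same width, so the total span
is 3*c*. With central mean *C* and flank means *L*, *R*:

    FOS(p, c) = (C + pc) / max(L, eps) + (C + pc) / max(R, eps)

with pseudocount `pc = 1` and flank floor `eps = 0.25`. The score is low
when the center is depleted relative to **both** flanks, which
distinguishes a footprint from a coverage slope or a deletion edge; it is
monotone in protection depth, which is all the downstream logic requires.

The scanned central widths are `c = 6 … 41`, keeping every total span
within 18–124 bases — the scale of single-protein to small-complex
footprints. A position's **best score** is the minimum of FOS(p, c) over
all scanned widths whose flanks both clear a minimum mean coverage
(`min_flank_mean = 5`); positions without any qualifying configuration are
unscorable, never seed a site, and break candidate runs, so coverage
deserts cannot produce calls.

### Calling threshold

The threshold is empirical and per-track: the `call_quantile` (default
0.01) quantile of the track's own per-position best-score distribution.
Conceptually this is a circular-rotation null — rotating the track
preserves its marginal coverage structure — but a rotation permutes
positions without changing the multiset of best scores, so the
rotation-null quantile equals the direct quantile exactly. The
implementation therefore computes the quantile directly and is fully
deterministic.

Maximal circular runs of sub-threshold scorable positions become candidate
sites (extent = the run, score = the run minimum). The quantile makes the
threshold adaptive: on a track with genuine footprints occupying more than
the quantile mass, it lands inside the planted score range and false calls
essentially vanish; on a null track it admits `call_quantile` of positions
by construction, which is the expected false-call budget quoted in the
validation output.

## Replicate concordance, merging, prevalence

Only sites reproduced across a replicate pair are kept: a site survives if
it overlaps (at least one shared base, modular) a site of the other
replicate, and the retained coordinates are the union hull of the
overlapping pair (an `intersection` mode is available). Half-open
adjacency is *not* overlap. Merging across stages or samples is the
transitive closure of one-base overlap, implemented with a circular sweep
and verified against a quadratic union-find oracle; it is idempotent and
supply-order invariant. Prevalence filtering keeps merged reference sites
supported by at least (or, in strict mode, more than) a given fraction of
samples.

## Occupancy dynamics

Per-stage concordant sites are merged into reference sites; presence of a
reference site at a stage is overlap-based, not coordinate-identical,
which is exactly why one-base-overlap merging is used. Each nonzero
presence vector falls into exactly one of four trajectory classes:

| class | pattern |
|---|---|
| `core` | present at every stage |
| `emergent_persistent` | leading absence, then present through the final stage |
| `alternating` | any internal gap between two presences |
| `transient` | one presence block ending before the final stage |

Boundary cases the verbal definitions leave open are resolved as:
persistence requires a suffix of ones (a site present only at the last
stage is `emergent_persistent` with a suffix of length 1), and `transient`
must end before the final stage. The partition is checked exhaustively for
all nonzero binary vectors of lengths 2–8. Gain/loss per stage is column
differencing of the presence matrix; embryo-to-adult persistence reports,
for each adult site, whether it overlaps an embryonic reference site and
the earliest stage at which an overlapping reference site was present.

## Sequence screens

**k-mer digestion bias.** Cut-site counting uses the 5′ alignment start
(forward reads) or last aligned base (reverse reads), with an optional
+4/−5 transposase offset. The k-mer at a cut is centered (`cut − k/2 …`),
the common convention for transposase bias. Observed k-mer counts at cuts
are compared against expected counts from circular genome-wide k-mer
frequencies by an exact two-sided binomial test per k-mer
(minimum-likelihood method, evaluated on the truncated support where the
pmf is non-negligible; verified against the standard exact test), with
Benjamini–Hochberg correction over all 4^k k-mers. The screen reports
"biased" only when a k-mer is both significant (adjusted p < 0.05) and
more than two-fold enriched or depleted.

**G-quadruplex-prone motifs.** The scanner chains maximal guanine runs of
length ≥ `min_run` (default 3) whenever the distance from one run's end to
the next long run's start lies within the loop bounds (1–7 bases; loop
content is unrestricted, short G-runs included), and emits
leftmost-maximal non-overlapping chains of ≥ `n_runs` (default 4) runs —
the classic G₃₊(N₁₋₇G₃₊)₃ quadruplex motif. The reverse strand is scanned
via cytosine runs on the forward sequence; scanning is modular across the
origin. Chaining maximal runs (rather than letting a regex backtracker
split one long G-run into run + loop + run) makes the definition
direction-symmetric and unambiguous; a per-position brute-force matcher
serves as the independent oracle in the tests. Default parameters are
deliberately exposed: stricter or looser quadruplex definitions change
motif counts substantially, so no particular genome-wide count is claimed.

**NUMT contamination.** Given a catalog of diagnostic positions where the
organellar and nuclear-insert alleles differ, the per-position NUMT read
fraction is (reads calling the insert allele) / (reads calling either
allele); positions with no informative read are undefined, not zero.
Site vs non-site positions are compared with a two-sided Mann–Whitney
test on unweighted per-position fractions — fractions are bounded and
skewed, so a rank test is preferred to a t-test.

## Co-localization statistics

A feature *overlaps* a site set if it shares a base with any site, and is
*proximal* if disjoint but with circular gap strictly less than `max_gap`
(default 40 bases). Enrichment of (overlap + proximal) features uses a
1-df goodness-of-fit chi-square whose null fraction defaults to the
fraction of genome bases within `max_gap` of any site (sites dilated by
`max_gap − 1` on each side, matching the exclusive bound); the null is
stated explicitly so the result is interpretable, and the expected count
must be ≥ 1 (warning below 5). A rotation permutation test accompanies
it: the feature set is rotated by a uniform random offset (sites stay
fixed, preserving the coverage structure the calls came from), the
statistic is the co-localized feature count, and
p = (1 + #{perm ≥ obs}) / (n_perm + 1).

## Synthetic data

The generator emulates the structure the analysis assumes, with planted
ground truth:

* **Counts**: gamma–Poisson (negative-binomial) per-base counts,
  `dispersion = 10` by default, under a smooth positional multiplier
  (low-frequency sinusoid mixture, amplitude ~0.3, mean 1) — flat Poisson
  coverage would make footprint calling unrealistically easy.
* **Footprints**: multiplicative depressions `(1 − protection)` of width
  10–60 bases; default protections 0.8–1.0 at background means 30–80,
  deep-coverage conditions typical of mtDNA accessibility data.
* **Replicates**: share the multiplier and planted sites, draw counts
  independently, with a lognormal per-replicate depth factor (sd 0.05).
* **Stage series**: a scripted presence matrix per planted site; the
  canonical 7-stage script exercises all four trajectory classes with
  near-equal sites per stage (5–6), so the adaptive quantile threshold
  behaves comparably at every stage.
* **Reads**: fixed-length reads sampled under the coverage model; a
  `numt_rate` fraction derive from a nuclear copy and call the insert
  allele at every catalog position they span; an optional k-mer bias
  multiplies cut-site weights at matching positions.

What the generator does **not** model: fragment-size distributions,
sequencing error beyond the catalog alleles, mappability, and real mtDNA
sequence composition beyond base frequencies. Passing the recovery tests
therefore shows the algorithms are correct under the stated statistical
model, not that any particular biological dataset would yield particular
site counts.

## Validation experiment sizes

The validation suite uses: 200 simulated tracks on full-length
(16,299-base) genomes for planted-footprint recovery (sensitivity ≥ 0.9
with mean boundary error ≤ 5 bases under the conditions above); the
scripted 7-stage series recovered exactly end to end; brute-force oracle
equivalence on 50 random tracks (lengths 130–500) at every position and
window configuration and 1,000 random circular interval sets; 600 null
simulations for the permutation test's type-I error and 1,000 for the
rank test (both expected in [0.03, 0.07] at α = 0.05); 20 null k-mer
screens of 10,000 cuts plus one planted 5× bias; and 100 read-set
simulations per contamination rate {0, 0.002, 0.01} at 5,000× coverage on
a 2,000-base genome with read-length-separated catalog positions (so the
pooled count is exactly binomial and the 95% interval calibrated). The
permutation calibration uses 200 features × 25 sites per simulation: with
few features the count statistic's heavy ties make the permutation
p-value strongly conservative and the measured level uninformative.

## Known limitations

* The calling threshold is relative to each track's own score
  distribution; absolute site counts are therefore not comparable between
  datasets processed with different quantiles.
* Window geometry is symmetric (flanks = center); asymmetric footprints
  at steep coverage slopes may be called with shifted boundaries.
* Merged or concordance-union sites can exceed the maximum scan window
  when nearby footprints fuse.
* The chi-square null treats features as independent points; strongly
  clustered features inflate its significance, which is why the rotation
  permutation test is reported alongside.
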