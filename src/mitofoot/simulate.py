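"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the statistical structure of deep chromatin-
accessibility coverage on a circular mitochondrial genome:

* overdispersed (gamma–Poisson) per-base counts with a smooth low-frequency
  positional multiplier, so the background is non-uniform as real mtDNA
  coverage is;
* footprints as localized protection — multiplicative coverage depressions
  10–60 bases wide;
* replicate pairs sharing the positional structure and planted sites but
  drawing counts independently (plus a per-replicate depth factor);
* an ordered stage series with scripted presence/absence per planted site;
* reads carrying NUMT diagnostic alleles at a set contamination rate, and
  an optional cut-site k-mer insertion bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from .bias_numt import NUMTCatalog
from .genome import CircularGenome, CoverageTrack, Feature, FeatureAnnotation
from .reads import ReadSet

import pandas as pd

# mouse-mtDNA-like base composition (heavy strand is strikingly G-poor)
BASE_PROBS = {"A": 0.345, "C": 0.255, "G": 0.125, "T": 0.275}


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth protected interval: coverage inside is multiplied by
    (1 - protection)."""

    start: int
    width: int
    protection: float

    def __post_init__(self):
        if not (0 <= self.protection <= 1):
            raise ValueError("protection must be in [0, 1]")
        if self.width < 1:
            raise ValueError("width must be positive")

    @property
    def end(self) -> int:
        return self.start + self.width  # caller normalizes modularly


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic mitochondrial accessibility data.

    Defaults mirror the scales of the system being emulated: a mouse-sized
    mitochondrial genome (16,299 bases), deep background coverage, and
    footprints 10–60 bases wide at high protection.
    """

    genome_length: int = 16299
    background_mean: float = 50.0
    dispersion: float = 10.0  # negative-binomial size; larger = closer to Poisson
    planted_sites: list[PlantedSite] = field(default_factory=list)
    n_replicates: int = 2
    replicate_noise_sd: float = 0.05  # lognormal sd of per-replicate depth factor
    stage_names: Optional[list[str]] = None
    stage_script: Optional[np.ndarray] = None  # (n_sites, n_stages) 0/1
    numt_rate: float = 0.0
    bias_kmer: Optional[tuple[str, float]] = None  # (kmer, enrichment)
    read_length: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.stage_script is not None:
            self.stage_script = np.asarray(self.stage_script, dtype=np.int8)
            if self.stage_script.ndim != 2 or \
                    self.stage_script.shape[0] != len(self.planted_sites):
                raise ValueError("stage_script must be (n_planted_sites, n_stages)")
            if self.stage_names is not None and \
                    len(self.stage_names) != self.stage_script.shape[1]:
                raise ValueError("stage_names length must match stage_script columns")
        if not (0 <= self.numt_rate <= 1):
            raise ValueError("numt_rate must be a fraction")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["planted_sites"] = [PlantedSite(**p) for p in raw.get("planted_sites", [])]
        if raw.get("stage_script") is not None:
            raw["stage_script"] = np.array(raw["stage_script"])
        if raw.get("bias_kmer") is not None:
            raw["bias_kmer"] = tuple(raw["bias_kmer"])
        return cls(**raw)


MOUSE_STAGES = ["early2C", "2C", "4C", "8C", "ICM", "E6", "E7.2"]
HUMAN_STAGES = ["2C", "8C", "ICM"]

# Scripted 7-stage presence matrix exercising all four trajectory classes.
# Column sums are kept nearly equal (5-6 sites per stage) so that the
# adaptive per-track calling threshold behaves comparably at every stage.
SEVEN_STAGE_SCRIPT = np.array([
    [1, 1, 1, 1, 1, 1, 1],  # core
    [0, 1, 1, 1, 1, 1, 1],  # emergent_persistent
    [0, 0, 1, 1, 1, 1, 1],  # emergent_persistent
    [0, 0, 0, 0, 0, 1, 1],  # emergent_persistent
    [1, 0, 1, 0, 1, 0, 1],  # alternating
    [0, 1, 0, 1, 0, 1, 1],  # alternating
    [1, 0, 0, 1, 0, 1, 0],  # alternating
    [1, 1, 0, 1, 1, 0, 0],  # alternating
    [1, 1, 1, 0, 0, 0, 0],  # transient
    [1, 1, 1, 0, 0, 0, 0],  # transient
], dtype=np.int8)


def seven_stage_config(seed: int = 0, background_mean: float = 80.0,
                       protection: tuple[float, float] = (0.95, 1.0),
                       width: int = 36) -> "SimulationConfig":
    """Canonical scripted developmental series over a mouse-sized genome.

    Ten planted sites of equal width follow :data:`SEVEN_STAGE_SCRIPT`
    across the seven stages, at high protection and deep coverage.
    """
    rng = np.random.default_rng(seed)
    sites = random_planted_sites(rng, SEVEN_STAGE_SCRIPT.shape[0], 16299,
                                 width_range=(width, width),
                                 protection_range=protection)
    return SimulationConfig(background_mean=background_mean, planted_sites=sites,
                            stage_script=SEVEN_STAGE_SCRIPT.copy(),
                            stage_names=list(MOUSE_STAGES), seed=seed)


def random_genome(length: int = 16299, seed: int = 0, name: str = "chrM") -> CircularGenome:
    """A random circular genome with mouse-mtDNA-like base composition."""
    rng = np.random.default_rng(seed)
    bases = np.array(list(BASE_PROBS))
    seq = "".join(rng.choice(bases, size=length, p=list(BASE_PROBS.values())))
    return CircularGenome(name, length, seq)


def positional_multiplier(length: int, seed: int, amplitude: float = 0.3,
                          n_waves: int = 3) -> np.ndarray:
    """Smooth low-frequency multiplicative coverage profile with mean ~1."""
    rng = np.random.default_rng(seed)
    x = np.arange(length) / length
    s = np.zeros(length)
    for _ in range(n_waves):
        freq = rng.integers(1, 6)
        phase = rng.uniform(0, 2 * np.pi)
        s += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * x + phase)
    m = np.exp(amplitude * s / n_waves)
    return m / m.mean()


def _protection_profile(config: SimulationConfig, active: Sequence[bool] | None = None
                        ) -> np.ndarray:
    L = config.genome_length
    prof = np.ones(L)
    for i, site in enumerate(config.planted_sites):
        if active is not None and not active[i]:
            continue
        idx = (site.start + np.arange(site.width)) % L
        prof[idx] *= (1 - site.protection)
    return prof


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draws with the given per-base mean and size ``dispersion``."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 0) / dispersion)
    return rng.poisson(lam).astype(float)


def simulate_track(config: SimulationConfig, genome: CircularGenome | None = None,
                   active: Sequence[bool] | None = None, stage_id: str = "",
                   seed: Optional[int] = None
                   ) -> tuple[list[CoverageTrack], list[PlantedSite]]:
    """Replicate coverage tracks with planted footprints.

    Replicates share the positional multiplier and the planted sites but
    draw counts independently; each replicate additionally gets a lognormal
    depth factor of sd ``replicate_noise_sd``.  Returns the tracks and the
    ground-truth list of active planted sites.
    """
    L = config.genome_length
    if genome is None:
        genome = CircularGenome("chrM", L)
    if genome.length != L:
        raise ValueError("genome length does not match config")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mult = positional_multiplier(L, seed=seed)
    prot = _protection_profile(config, active)
    tracks = []
    for r in range(config.n_replicates):
        depth = np.exp(rng.normal(0.0, config.replicate_noise_sd))
        mean = config.background_mean * depth * mult * prot
        counts = _nb_counts(rng, mean, config.dispersion)
        tracks.append(CoverageTrack(genome, counts, sample_id=f"sim_rep{r + 1}",
                                    stage_id=stage_id, replicate_id=f"rep{r + 1}"))
    truth = [s for i, s in enumerate(config.planted_sites)
             if active is None or active[i]]
    return tracks, truth


def simulate_stage_series(config: SimulationConfig, genome: CircularGenome | None = None
                          ) -> dict:
    """Replicate pairs per stage following the scripted presence matrix.

    Returns a dict with ``stages``, ``tracks`` (stage -> replicate list),
    ``truth_presence`` (the script), and ``planted_sites``.
    """
    if config.stage_script is None:
        raise ValueError("config.stage_script is required for a stage series")
    script = config.stage_script
    n_stages = script.shape[1]
    stages = config.stage_names or [f"stage{i + 1}" for i in range(n_stages)]
    tracks = {}
    for t, stage in enumerate(stages):
        reps, _ = simulate_track(config, genome=genome, active=script[:, t].astype(bool),
                                 stage_id=stage, seed=config.seed + 1000 * (t + 1))
        tracks[stage] = reps
    return {"stages": stages, "tracks": tracks, "truth_presence": script.copy(),
            "planted_sites": list(config.planted_sites)}


def embed_sequence(genome: CircularGenome, insert: str, positions: Sequence[int]
                   ) -> CircularGenome:
    """Overwrite the genome sequence with ``insert`` at each position
    (modular), e.g. to plant quadruplex-prone motifs at known places."""
    if genome.sequence is None:
        raise ValueError("genome has no sequence")
    seq = list(genome.sequence)
    for p in positions:
        for i, base in enumerate(insert):
            seq[(p + i) % genome.length] = base
    return CircularGenome(genome.name, genome.length, "".join(seq))


def catalog_at_positions(genome: CircularGenome, positions: Sequence[int],
                         seed: int = 0) -> NUMTCatalog:
    """Diagnostic-variant catalog at the given positions, with NUMT alleles
    drawn at random among the non-reference bases."""
    rng = np.random.default_rng(seed)
    rows = []
    for pos in sorted(int(p) % genome.length for p in positions):
        mt = genome.base(pos)
        alts = [b for b in "ACGT" if b != mt]
        rows.append((pos, mt, alts[int(rng.integers(len(alts)))], "synthetic"))
    return NUMTCatalog(pd.DataFrame(rows, columns=["position", "mt_allele",
                                                   "numt_allele", "source_id"]))


def random_catalog(genome: CircularGenome, n_variants: int, seed: int = 0,
                   min_separation: int = 1) -> NUMTCatalog:
    """Random diagnostic-variant catalog consistent with the genome sequence.

    ``min_separation`` spaces the positions on the circle (e.g. one read
    length apart, so no read is informative at two positions at once).
    """
    rng = np.random.default_rng(seed)
    if min_separation > 1:
        if n_variants * min_separation > genome.length:
            raise ValueError("cannot space that many variants")
        chosen: list[int] = []
        while len(chosen) < n_variants:
            p = int(rng.integers(0, genome.length))
            if all(min((p - q) % genome.length, (q - p) % genome.length) >= min_separation
                   for q in chosen):
                chosen.append(p)
        positions = np.sort(np.array(chosen))
    else:
        positions = np.sort(rng.choice(genome.length, size=n_variants, replace=False))
    rows = []
    for pos in positions:
        mt = genome.base(int(pos))
        alts = [b for b in "ACGT" if b != mt]
        rows.append((int(pos), mt, alts[int(rng.integers(len(alts)))], "synthetic"))
    return NUMTCatalog(pd.DataFrame(rows, columns=["position", "mt_allele", "numt_allele",
                                                   "source_id"]))


def simulate_reads(config: SimulationConfig, genome: CircularGenome,
                   catalog: Optional[NUMTCatalog] = None, n_reads: Optional[int] = None,
                   seed: Optional[int] = None, allow_wrap: bool = False) -> ReadSet:
    """Reads sampled under the coverage model, with NUMT alleles and optional
    cut-site k-mer bias.

    Read 5' starts follow the positional multiplier × protection profile;
    when ``bias_kmer`` is configured the start weight is multiplied by the
    enrichment wherever the centered k-mer matches.  A ``numt_rate``
    fraction of reads derive from a nuclear copy and call the NUMT allele
    at every catalog position they span.
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required to simulate reads")
    L = config.genome_length
    if genome.length != L:
        raise ValueError("genome length does not match config")
    if config.read_length > L:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if n_reads is None:
        n_reads = int(round(config.background_mean * L / config.read_length))
    w = positional_multiplier(L, seed=config.seed) * _protection_profile(config)
    if config.bias_kmer is not None:
        kmer, enrichment = config.bias_kmer
        k = len(kmer)
        doubled = genome.sequence.upper() + genome.sequence.upper()[:k]
        half = k // 2
        hit = np.array([doubled[(p - half) % L:(p - half) % L + k] == kmer.upper()
                        for p in range(L)])
        w = w * np.where(hit, enrichment, 1.0)
    if not allow_wrap:
        w = w.copy()
        w[L - config.read_length + 1:] = 0.0  # keep alignments linear for SAM export
    starts = rng.choice(L, size=n_reads, p=w / w.sum())
    is_rev = rng.random(n_reads) < 0.5
    sub_keys, sub_bases = [], []
    if catalog is not None and config.numt_rate > 0:
        is_numt = rng.random(n_reads) < config.numt_rate
        numt_idx = np.flatnonzero(is_numt)
        cat = catalog.table
        for _, rec in cat.iterrows():
            pos = int(rec["position"])
            offs = (pos - starts[numt_idx]) % L
            cover = offs < config.read_length
            for ridx, off in zip(numt_idx[cover], offs[cover]):
                sub_keys.append(int(ridx) * config.read_length + int(off))
                sub_bases.append(rec["numt_allele"])
    return ReadSet(genome, starts, config.read_length, is_rev,
                   np.array(sub_keys, dtype=np.int64), np.array(sub_bases, dtype="U1"))


def random_planted_sites(rng: np.random.Generator, n_sites: int, genome_length: int,
                         width_range: tuple[int, int] = (10, 60),
                         protection_range: tuple[float, float] = (0.8, 1.0),
                         min_separation: int = 200) -> list[PlantedSite]:
    """Non-overlapping planted sites with random widths and protections."""
    sites: list[PlantedSite] = []
    attempts = 0
    while len(sites) < n_sites and attempts < 10000:
        attempts += 1
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        start = int(rng.integers(0, genome_length))
        if all(min((start - s.start) % genome_length,
                   (s.start - start) % genome_length) > width + s.width + min_separation
               for s in sites):
            prot = float(rng.uniform(*protection_range))
            sites.append(PlantedSite(start, width, prot))
    if len(sites) < n_sites:
        raise RuntimeError("could not place the requested number of sites")
    return sites


def example_annotation(genome: CircularGenome) -> FeatureAnnotation:
    """A synthetic mitochondrial-genome-like feature map (not a real map).

    Lays out a D-loop with regulatory elements at the origin, two rRNAs,
    22 tRNAs and 13 protein-coding genes at plausible relative scales, for
    exercising region statistics and co-localization end to end.
    """
    L = genome.length
    scale = L / 16299
    feats = [
        Feature("D_loop", "d_loop", int(L - 880 * scale) % L, int(20 * scale) or 1),
        Feature("HSP", "regulatory", int(L - 250 * scale), int(L - 220 * scale)),
        Feature("LSP", "regulatory", int(L - 700 * scale), int(L - 670 * scale)),
        Feature("CSB1", "regulatory", int(L - 600 * scale), int(L - 570 * scale)),
        Feature("CSB2", "regulatory", int(L - 540 * scale), int(L - 515 * scale)),
        Feature("CSB3", "regulatory", int(L - 500 * scale), int(L - 480 * scale)),
        Feature("OriL", "regulatory", int(5160 * scale), int(5190 * scale)),
        Feature("rRNA_12S", "rRNA", int(70 * scale), int(1020 * scale)),
        Feature("rRNA_16S", "rRNA", int(1090 * scale), int(2670 * scale)),
    ]
    rng = np.random.default_rng(7)
    pos = int(2700 * scale)
    gene_ends = []
    for g in range(13):
        width = int(rng.integers(680, 1800) * scale * 0.72)
        feats.append(Feature(f"gene_{g + 1}", "protein_coding", pos % L,
                             (pos + width - 1) % L + 1))
        pos += width + int(90 * scale)
        gene_ends.append(pos)
        if pos >= L - int(1000 * scale):
            break
    trna_slots = np.linspace(int(30 * scale), L - int(950 * scale), 22).astype(int)
    for i, s in enumerate(trna_slots):
        s = int(s) + int(rng.integers(0, 25))
        feats.append(Feature(f"tRNA_{i + 1}", "tRNA", s % L, (s + 69) % L + 1
                             if (s + 69) % L + 1 != s % L else (s + 70) % L))
    return FeatureAnnotation(genome, feats)
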