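"""Enzyme sequence-bias screening and NUMT read-contamination quantification.

Transposase insertion is screened for k-mer digestion bias by comparing the
k-mer composition at observed cut sites against the genome-wide circular
k-mer frequencies (exact binomial test per k-mer, Benjamini–Hochberg
corrected).  NUMT contamination — reads deriving from nuclear copies of
mitochondrial sequence — is quantified from diagnostic variant positions
where the organellar and nuclear alleles differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import CircularGenome
from .footprints import SiteSet
from .intervals import coverage_mask
from .reads import ReadSet

BASES = "ACGT"


# ---------------------------------------------------------------- k-mer bias

@dataclass
class KmerBiasReport:
    k: int
    n_cuts: int
    table: pd.DataFrame  # kmer, observed, expected, enrichment, p_value, p_adj

    @property
    def biased(self) -> bool:
        """Any k-mer significantly depleted/enriched beyond 2-fold."""
        t = self.table
        return bool(((t["p_adj"] < 0.05)
                     & ((t["enrichment"] < 0.5) | (t["enrichment"] > 2.0))).any())

    @property
    def n_flagged(self) -> int:
        return int((self.table["p_adj"] < 0.05).sum())


def _binom_two_sided(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method).

    Equivalent to ``scipy.stats.binomtest(k, n, p).pvalue`` but evaluated
    on the truncated support where the pmf is non-negligible, which keeps
    screens over thousands of k-mers fast.
    """
    if p <= 0:
        return 1.0 if k == 0 else 0.0
    if p >= 1:
        return 1.0 if k == n else 0.0
    mean, sd = n * p, np.sqrt(n * p * (1 - p))
    lo = max(0, int(mean - 40 * sd - 10))
    hi = min(n, int(mean + 40 * sd + 10) + max(k - int(mean), 0))
    hi = max(hi, k)
    support = np.arange(lo, hi + 1)
    pmf = stats.binom.pmf(support, n, p)
    pk = stats.binom.pmf(k, n, p)
    return float(min(1.0, pmf[pmf <= pk * (1 + 1e-10)].sum()))


def kmer_bias_screen(cut_positions: Sequence[int], genome: CircularGenome,
                     k: int = 6) -> KmerBiasReport:
    """Compare k-mer composition at cut sites against the genome background.

    The k-mer is centered on the cut: bases ``cut - k//2 .. cut + k - k//2 - 1``
    read modularly.  Expected counts are (number of cuts) × (circular
    genome-wide frequency of the k-mer).  Order of the cut positions is
    irrelevant.
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required for k-mer screening")
    if not (1 <= k <= genome.length):
        raise ValueError("k must be between 1 and the genome length")
    L = genome.length
    doubled = genome.sequence.upper() + genome.sequence.upper()[: k]
    half = k // 2

    genome_counts: dict[str, int] = {}
    for i in range(L):
        kmer = doubled[i:i + k]
        genome_counts[kmer] = genome_counts.get(kmer, 0) + 1

    cuts = np.asarray(cut_positions, dtype=np.int64) % L
    n = len(cuts)
    observed: dict[str, int] = {}
    for c in cuts:
        i = (int(c) - half) % L
        kmer = doubled[i:i + k]
        observed[kmer] = observed.get(kmer, 0) + 1

    rows = []
    for kmer_tuple in itertools.product(BASES, repeat=k):
        kmer = "".join(kmer_tuple)
        obs = observed.get(kmer, 0)
        freq = genome_counts.get(kmer, 0) / L
        exp = n * freq
        enr = obs / exp if exp > 0 else (np.inf if obs else 1.0)
        pval = _binom_two_sided(obs, n, freq) if n else 1.0
        rows.append((kmer, obs, exp, enr, pval))
    table = pd.DataFrame(rows, columns=["kmer", "observed", "expected", "enrichment", "p_value"])
    if len(table):
        table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    assert int(table["observed"].sum()) == n - sum(
        v for key, v in observed.items() if set(key) - set(BASES)
    )
    return KmerBiasReport(k=k, n_cuts=n, table=table)


# ---------------------------------------------------------------- NUMT

@dataclass
class NUMTCatalog:
    """Diagnostic variants distinguishing organellar from nuclear-copy reads."""

    table: pd.DataFrame  # position, mt_allele, numt_allele, source_id

    def __post_init__(self):
        required = {"position", "mt_allele", "numt_allele"}
        if not required <= set(self.table.columns):
            raise ValueError(f"catalog needs columns {sorted(required)}")
        if "source_id" not in self.table.columns:
            self.table = self.table.assign(source_id="")
        if (self.table["mt_allele"] == self.table["numt_allele"]).any():
            raise ValueError("mt_allele must differ from numt_allele at every position")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path: str) -> "NUMTCatalog":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def validate_against(self, genome: CircularGenome) -> None:
        if (self.table["position"] >= genome.length).any() or (self.table["position"] < 0).any():
            raise ValueError("catalog position outside genome")
        if genome.sequence is not None:
            for _, row in self.table.iterrows():
                if genome.base(int(row["position"])) != row["mt_allele"]:
                    raise ValueError(
                        f"catalog mt_allele at {row['position']} does not match reference"
                    )


@dataclass
class NUMTReport:
    """Per-position NUMT read fractions, with an optional site/non-site comparison."""

    per_position: pd.DataFrame  # position, n_informative, n_numt, fraction (NaN if undefined)
    site_mean: Optional[float] = None
    site_sd: Optional[float] = None
    nonsite_mean: Optional[float] = None
    nonsite_sd: Optional[float] = None
    statistic: Optional[float] = None
    p_value: Optional[float] = None

    @property
    def pooled_fraction(self) -> float:
        """Total NUMT reads over total informative reads across positions."""
        inf = self.per_position["n_informative"].sum()
        return float(self.per_position["n_numt"].sum() / inf) if inf else np.nan


def numt_read_fraction(reads: ReadSet, catalog: NUMTCatalog) -> NUMTReport:
    """Fraction of NUMT-allele reads at each diagnostic position.

    At each catalog position the fraction is (reads calling the NUMT
    allele) / (reads calling either allele); positions with no informative
    read are undefined (NaN), not zero.
    """
    rows = []
    for _, rec in catalog.table.iterrows():
        pos = int(rec["position"])
        _, bases = reads.base_calls(pos)
        n_mt = int((bases == rec["mt_allele"]).sum())
        n_numt = int((bases == rec["numt_allele"]).sum())
        informative = n_mt + n_numt
        rows.append((pos, informative, n_numt,
                     n_numt / informative if informative else np.nan))
    return NUMTReport(pd.DataFrame(rows, columns=["position", "n_informative", "n_numt",
                                                  "fraction"]))


def compare_numt_groups(report: NUMTReport, sites: SiteSet) -> NUMTReport:
    """Compare NUMT fractions inside vs outside footprint sites.

    Positions are split by membership in any called site; group means and
    SDs are unweighted over defined per-position fractions, and the groups
    are compared with a two-sided Mann–Whitney rank test.  If either group
    has no defined fraction the comparison is undefined but the available
    means are still reported.
    """
    L = sites.genome.length
    mask = coverage_mask(sites.intervals(), L)
    df = report.per_position
    defined = df[np.isfinite(df["fraction"])]
    in_site = defined[mask[defined["position"].to_numpy() % L]]
    out_site = defined[~mask[defined["position"].to_numpy() % L]]

    def _stats(frame):
        if len(frame) == 0:
            return None, None
        return float(frame["fraction"].mean()), float(frame["fraction"].std(ddof=1)) \
            if len(frame) > 1 else 0.0

    site_mean, site_sd = _stats(in_site)
    nonsite_mean, nonsite_sd = _stats(out_site)
    statistic = p_value = None
    if len(in_site) and len(out_site):
        res = stats.mannwhitneyu(in_site["fraction"], out_site["fraction"],
                                 alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return NUMTReport(df, site_mean, site_sd, nonsite_mean, nonsite_sd, statistic, p_value)
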