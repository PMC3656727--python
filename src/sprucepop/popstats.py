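"""Site-frequency-spectrum summary statistics and Hudson-style F_ST.

Implements the per-locus quantities reported in multilocus diversity
surveys of haploid sequence samples: segregating sites S, singleton count,
haplotype number/diversity, Watterson's theta, mean pairwise nucleotide
diversity pi, and Tajima's D with a beta-distribution significance
approximation.  All per-site rates divide by the number of analyzed sites
(indel and multiallelic columns never count), so theta and pi are
per-base-pair estimates of 4*Ne*mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import LocusAlignment, PopulationMap, SiteTable, classify_sites

__all__ = [
    "DiversitySummary",
    "FstResult",
    "harmonic_number",
    "tajima_constants",
    "watterson_theta",
    "nucleotide_diversity",
    "pairwise_differences_total",
    "haplotype_stats",
    "tajimas_d",
    "tajimas_d_bounds",
    "summarize_locus",
    "summarize_population",
    "global_fst",
]


class InsufficientSampleError(ValueError):
    """Statistic requested for fewer than two sequences."""


@dataclass
class DiversitySummary:
    """One row of a per-locus (optionally per-population) diversity table."""

    locus_id: str
    population_id: str | None
    n: int
    L: int
    S: int
    singletons: int
    H: int | None
    Hd: float | None
    theta_w: float
    pi: float
    tajimas_d: float | None
    d_significant: bool | None
    d_pvalue_approx: float | None
    computed: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FstResult:
    locus_id: str
    fst: float | None
    n_populations: int
    within_diversity: float
    between_diversity: float


def harmonic_number(m: int, power: int = 1) -> float:
    """sum_{i=1}^{m} 1/i**power (a1 uses m = n-1, a2 likewise)."""
    return float(sum(1.0 / i**power for i in range(1, m + 1)))


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 normalizing constants for a sample of n sequences."""
    if n < 2:
        raise InsufficientSampleError("need n >= 2 sequences")
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's per-site estimator S / (a1 * L)."""
    if n < 2:
        raise InsufficientSampleError("need n >= 2 sequences")
    if L < 1:
        raise ValueError("L must be >= 1")
    if S == 0:
        return 0.0
    return S / (harmonic_number(n - 1) * L)


def _per_site_counts(aln: LocusAlignment, positions: np.ndarray) -> list[np.ndarray]:
    """Allele counts at each position, over called (non-N, non-gap) rows."""
    out = []
    for pos in positions:
        col = aln.matrix[:, pos - 1]
        called = col[(col != "N") & (col != "-")]
        _, counts = np.unique(called, return_counts=True)
        out.append(counts.astype(float))
    return out


def pairwise_differences_total(aln: LocusAlignment, sites: SiteTable) -> float:
    """Mean number of pairwise differences per sequence pair (k-hat).

    Under ``complete_deletion`` every analyzed site is fully called and the
    per-site pair count is C(n,2); under ``pairwise_available`` each site
    contributes with its own called sample size.
    """
    if aln.n < 2:
        raise InsufficientSampleError("need n >= 2 sequences")
    # Each site contributes the probability that a random called pair of
    # sequences differs there; summed over sites this is the mean pairwise
    # difference count.
    total = 0.0
    for counts in _per_site_counts(aln, sites.snp_positions()):
        nc = counts.sum()
        if nc < 2:
            continue
        pairs = nc * (nc - 1) / 2.0
        same = float(sum(c * (c - 1) / 2.0 for c in counts))
        total += (pairs - same) / pairs
    return total


def nucleotide_diversity(aln: LocusAlignment, sites: SiteTable) -> float:
    """Per-site mean pairwise diversity pi over the analyzed sites."""
    L = sites.n_analyzed_sites
    if L == 0:
        return 0.0
    return pairwise_differences_total(aln, sites) / L


def haplotype_stats(aln: LocusAlignment, sites: SiteTable) -> tuple[int, float]:
    """Haplotype count H and diversity Hd over the analyzed sites.

    Sequences still containing missing data at analyzed sites (possible only
    under ``pairwise_available``) are excluded: haplotype identity is
    undefined with missing characters.
    """
    positions = sites.analyzed_positions
    if aln.n < 2:
        raise InsufficientSampleError("need n >= 2 sequences")
    if len(positions) == 0:
        return 1, 0.0
    sub = aln.matrix[:, positions - 1]
    keep = ~((sub == "N") | (sub == "-")).any(axis=1)
    sub = sub[keep]
    n = sub.shape[0]
    if n < 2:
        return (1 if n else 0), 0.0
    haplotypes = ["".join(row) for row in sub]
    _, counts = np.unique(haplotypes, return_counts=True)
    freqs = counts / n
    hd = (n / (n - 1.0)) * (1.0 - float(np.sum(freqs**2)))
    return int(len(counts)), hd


def tajimas_d_bounds(n: int) -> tuple[float, float]:
    """Attainable (min, max) of D for a sample of n, in the large-S limit.

    The minimum corresponds to every segregating site being a singleton, the
    maximum to every site at frequency n/2.
    """
    c = tajima_constants(n)
    dmin = (2.0 / n - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / c["a1"]) / math.sqrt(c["e2"])
    return dmin, dmax


def tajimas_d(
    S: int, n: int, pi_total: float, alpha: float = 0.05
) -> tuple[float | None, bool | None, float | None]:
    """Tajima's D with beta-approximation significance.

    Parameters
    ----------
    S : segregating sites
    n : haploid sample size
    pi_total : mean pairwise differences per sequence pair (k-hat, not per site)

    Returns ``(D, significant, two_sided_p)``; all ``None`` when S = 0
    (the statistic is undefined, not zero).  The null distribution of D is
    approximated by a beta distribution rescaled to the attainable range of
    D with mean 0 and variance 1, the approximation introduced with the
    statistic and used by standard software.
    """
    if n < 2:
        raise InsufficientSampleError("need n >= 2 sequences")
    if S == 0:
        return None, None, None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return None, None, None
    d = (pi_total - S / c["a1"]) / math.sqrt(var)
    dmin, dmax = tajimas_d_bounds(n)
    span = dmax - dmin
    m = -dmin / span  # mean of the rescaled variate
    v = 1.0 / span**2  # its variance
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        return d, None, None
    a, b = m * common, (1.0 - m) * common
    x = min(max((d - dmin) / span, 0.0), 1.0)
    cdf = float(stats.beta.cdf(x, a, b))
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    p = max(p, np.finfo(float).tiny)
    return d, p < alpha, p


def summarize_locus(
    aln: LocusAlignment,
    sites: SiteTable | None = None,
    population_id: str | None = None,
) -> DiversitySummary:
    """Assemble the full diversity summary row for one alignment."""
    if sites is None:
        sites = classify_sites(aln)
    if aln.n < 2:
        return DiversitySummary(
            locus_id=aln.locus_id,
            population_id=population_id,
            n=aln.n,
            L=0,
            S=0,
            singletons=0,
            H=None,
            Hd=None,
            theta_w=float("nan"),
            pi=float("nan"),
            tajimas_d=None,
            d_significant=None,
            d_pvalue_approx=None,
            computed=False,
        )
    L = sites.n_analyzed_sites
    S = sites.n_segregating
    pi_total = pairwise_differences_total(aln, sites)
    d, sig, p = tajimas_d(S, aln.n, pi_total)
    H, Hd = haplotype_stats(aln, sites)
    return DiversitySummary(
        locus_id=aln.locus_id,
        population_id=population_id,
        n=aln.n,
        L=L,
        S=S,
        singletons=sites.n_singletons,
        H=H,
        Hd=Hd,
        theta_w=watterson_theta(S, aln.n, max(L, 1)),
        pi=pi_total / L if L else 0.0,
        tajimas_d=d,
        d_significant=sig,
        d_pvalue_approx=p,
    )


def summarize_population(
    aln: LocusAlignment,
    popmap: PopulationMap,
    population_id: str,
    missing_policy: Literal["complete_deletion", "pairwise_available"] = "complete_deletion",
) -> DiversitySummary:
    """Diversity summary for one population's sequences at one locus.

    Sites are re-classified within the population subsample (a site
    segregating overall may be monomorphic here, and complete deletion
    applies to the subsample's missingness only).
    """
    members = popmap.individuals_in(population_id)
    sub = aln.subset(members)
    if sub.n < 2:
        out = DiversitySummary(
            locus_id=aln.locus_id,
            population_id=population_id,
            n=sub.n,
            L=0,
            S=0,
            singletons=0,
            H=None,
            Hd=None,
            theta_w=float("nan"),
            pi=float("nan"),
            tajimas_d=None,
            d_significant=None,
            d_pvalue_approx=None,
            computed=False,
        )
        return out
    sites = classify_sites(sub, missing_policy)
    return summarize_locus(sub, sites, population_id=population_id)


def summary_table(summaries: Iterable[DiversitySummary]) -> pd.DataFrame:
    """Long-format table of summary rows, per-site rates at full precision."""
    return pd.DataFrame([s.as_dict() for s in summaries])


def _site_frequency_blocks(
    block: np.ndarray,
) -> list[dict[str, float]]:
    """Per-site allele frequency dictionaries for one population block."""
    out = []
    for j in range(block.shape[1]):
        col = block[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        n = counts.sum()
        out.append({a: c / n for a, c in zip(alleles.tolist(), counts.tolist())})
    return out


def global_fst(
    aln: LocusAlignment, popmap: PopulationMap, min_n: int = 2
) -> FstResult:
    """Hudson-style global F_ST = 1 - Hw/Hb for one locus.

    Per analyzed site, a population's within diversity is the unbiased
    heterozygosity (1 - sum(p_a^2)) * n/(n-1) (equal to its mean pairwise
    difference rate) and the between diversity of a population pair is
    1 - sum(p_a * q_a) (the probability that one sequence from each
    population differs at the site, unbiased because the two samples are
    independent).  Hw averages within-diversity over populations, Hb
    averages between-diversity over unordered population pairs, both summed
    over complete-deletion analyzed sites of the pooled alignment.

    Populations fixed for different alleles yield exactly 1; samples split
    from one panmictic pool are centered on 0.  Feeding two literal copies
    of one sample yields exactly -1/(n-1) - the samples are then not
    independent, and the small negative value is the estimator's signature
    on that degenerate input rather than a bias on real data.
    """
    sites = classify_sites(aln, "complete_deletion")
    positions = sites.analyzed_positions
    freqs: dict[str, list[dict[str, float]]] = {}
    for pop in popmap.population_ids:
        members = [i for i in popmap.individuals_in(pop) if i in aln.individual_ids]
        if len(members) >= min_n:
            freqs[pop] = _site_frequency_blocks(
                aln.subset(members).matrix[:, positions - 1]
            )
    pops = sorted(freqs)
    if len(pops) < 2:
        raise InsufficientSampleError("need >= 2 populations with n >= 2")
    sizes = {
        p: len([i for i in popmap.individuals_in(p) if i in aln.individual_ids])
        for p in pops
    }
    hw_pop = []
    for p in pops:
        n = sizes[p]
        het = sum(1.0 - sum(v * v for v in site.values()) for site in freqs[p])
        hw_pop.append(float(het * n / (n - 1)))
    hw = float(np.mean(hw_pop))
    between = []
    for i, p in enumerate(pops):
        for q in pops[i + 1 :]:
            hb_pq = 0.0
            for sp, sq in zip(freqs[p], freqs[q]):
                shared = set(sp) & set(sq)
                hb_pq += 1.0 - sum(sp[a] * sq[a] for a in shared)
            between.append(hb_pq)
    hb = float(np.mean(between))
    L = max(len(positions), 1)
    if hb == 0.0:
        return FstResult(aln.locus_id, None, len(pops), hw / L, hb / L)
    return FstResult(aln.locus_id, 1.0 - hw / hb, len(pops), hw / L, hb / L)
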