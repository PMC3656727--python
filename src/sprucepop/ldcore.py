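"""Pairwise linkage disequilibrium between parsimony-informative sites.

Haploid (megagametophyte) sequences mean phase is observed directly, so LD
between two biallelic sites is a 2x2 haplotype count table over the
individuals called at both sites.  Statistics are r^2 (squared allele-
frequency correlation), D' (coupling disequilibrium normalized by its
attainable maximum) and a two-sided Fisher exact p-value, with Bonferroni
multiple-testing control over all retained pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .seqio import LocusAlignment, SiteTable, encode_biallelic, site_alleles

logger = logging.getLogger(__name__)

__all__ = [
    "LDPair",
    "LDPairSet",
    "ld_pair",
    "ld_exact_test",
    "build_ld_pairs",
    "prune_linked_snps",
]

#: Minimum complete (called-at-both-sites) haplotypes for a pair to be kept.
MIN_COMPLETE_HAPLOTYPES = 4


@dataclass
class LDPair:
    locus_id: str
    pos_i: int
    pos_j: int
    hap_counts: tuple[int, int, int, int]  # (n11, n12, n21, n22)
    r2: float
    dprime: float
    p_value: float
    significant: bool = False
    n_missing_i: int = 0
    n_missing_j: int = 0

    @property
    def distance_bp(self) -> int:
        return abs(self.pos_j - self.pos_i)


@dataclass
class LDPairSet:
    pairs: list[LDPair]
    correction_scope: Literal["per_locus", "global"] = "global"
    alpha: float = 0.05
    n_dropped: int = 0
    drop_log: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_significant(self) -> int:
        return sum(p.significant for p in self.pairs)

    @property
    def mean_r2(self) -> float:
        if not self.pairs:
            return float("nan")
        return float(np.mean([p.r2 for p in self.pairs]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus_id": p.locus_id,
                    "pos_i": p.pos_i,
                    "pos_j": p.pos_j,
                    "distance_bp": p.distance_bp,
                    "r2": p.r2,
                    "dprime": p.dprime,
                    "p_value": p.p_value,
                    "significant": p.significant,
                }
                for p in self.pairs
            ]
        )

    def locus_summary(self) -> pd.DataFrame:
        """Per-locus summary: informative pair bookkeeping and mean r^2."""
        rows = []
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame(
                columns=["locus_id", "n_pairs", "n_significant", "pct_significant", "mean_r2"]
            )
        for locus, grp in df.groupby("locus_id", sort=True):
            rows.append(
                {
                    "locus_id": locus,
                    "n_pairs": len(grp),
                    "n_significant": int(grp["significant"].sum()),
                    "pct_significant": 100.0 * grp["significant"].mean(),
                    "mean_r2": grp["r2"].mean(),
                }
            )
        return pd.DataFrame(rows)


def ld_pair(hap_counts: Sequence[int]) -> tuple[float, float]:
    """r^2 and D' from a 2x2 haplotype count table (n11, n12, n21, n22).

    Rows index the allele at the first site, columns at the second.  All
    four marginal allele counts must be positive.
    """
    n11, n12, n21, n22 = (float(v) for v in hap_counts)
    n = n11 + n12 + n21 + n22
    pa = (n11 + n12) / n  # allele 1 at first site
    pb = (n11 + n21) / n  # allele 1 at second site
    if min(pa, 1 - pa, pb, 1 - pb) <= 0:
        raise ValueError("monomorphic margin: LD undefined")
    d = n11 / n - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    return r2, dprime


def ld_exact_test(hap_counts: Sequence[int]) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by hypergeometric summation.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed table's.  Comparisons are done
    on exact integer numerators so there is no tie tolerance.  A table with
    any zero margin is degenerate: p = 1 by convention.
    """
    a, b, c, d = (int(v) for v in hap_counts)
    if min(a, b, c, d) < 0:
        raise ValueError("negative count")
    r1, r2_, c1 = a + b, c + d, a + c
    n = r1 + r2_
    if r1 == 0 or r2_ == 0 or c1 == 0 or c1 == n:
        return 1.0
    # P(k in first cell) = C(r1,k) C(r2,c1-k) / C(n,c1); compare numerators.
    lo, hi = max(0, c1 - r2_), min(r1, c1)
    obs = math.comb(r1, a) * math.comb(r2_, c1 - a)
    num = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(r1, k) * math.comb(r2_, c1 - k)) <= obs
    )
    return num / math.comb(n, c1)


def _pair_table(
    enc_i: np.ndarray, enc_j: np.ndarray
) -> tuple[tuple[int, int, int, int], int] | None:
    """2x2 haplotype counts over individuals called at both sites.

    Alleles are re-coded within the jointly-called subset; returns ``None``
    (with the reason logged by the caller) when a margin is monomorphic
    there or fewer than MIN_COMPLETE_HAPLOTYPES haplotypes remain.
    """
    called = (enc_i >= 0) & (enc_j >= 0)
    x, y = enc_i[called], enc_j[called]
    n = int(called.sum())
    if n < MIN_COMPLETE_HAPLOTYPES:
        return None
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return None
    n11 = int(np.sum((x == 0) & (y == 0)))
    n12 = int(np.sum((x == 0) & (y == 1)))
    n21 = int(np.sum((x == 1) & (y == 0)))
    n22 = int(np.sum((x == 1) & (y == 1)))
    return (n11, n12, n21, n22), n


def build_ld_pairs(
    alignments: Iterable[LocusAlignment],
    site_tables: Iterable[SiteTable],
    correction_scope: Literal["per_locus", "global"] = "global",
    alpha: float = 0.05,
    informative_only: bool = True,
) -> LDPairSet:
    """All within-locus pairs of parsimony-informative biallelic sites.

    Individuals enter a pair's table only when called at both sites
    (pairwise deletion).  Bonferroni significance uses 0.05 divided by the
    number of retained pairs in the correction scope (default: all loci
    jointly, the convention behind a single survey-wide significant-pair
    percentage).
    """
    pairs: list[LDPair] = []
    dropped: list[str] = []
    for aln, sites in zip(alignments, site_tables):
        positions = sites.snp_positions(informative_only=informative_only)
        if len(positions) < 2:
            continue
        encoded = {
            pos: encode_biallelic(site_alleles(aln, pos)) for pos in positions
        }
        miss = {pos: int(np.sum(encoded[pos] < 0)) for pos in positions}
        for i, pi in enumerate(positions):
            for pj in positions[i + 1 :]:
                tab = _pair_table(encoded[pi], encoded[pj])
                if tab is None:
                    dropped.append(
                        f"{aln.locus_id}:{pi}-{pj}: degenerate after joint-missing removal"
                    )
                    continue
                counts, _ = tab
                r2, dprime = ld_pair(counts)
                p = ld_exact_test(counts)
                pairs.append(
                    LDPair(
                        locus_id=aln.locus_id,
                        pos_i=int(pi),
                        pos_j=int(pj),
                        hap_counts=counts,
                        r2=r2,
                        dprime=dprime,
                        p_value=p,
                        n_missing_i=miss[pi],
                        n_missing_j=miss[pj],
                    )
                )
    if dropped:
        logger.info("dropped %d degenerate site pairs", len(dropped))
    result = LDPairSet(
        pairs=pairs,
        correction_scope=correction_scope,
        alpha=alpha,
        n_dropped=len(dropped),
        drop_log=dropped,
    )
    _apply_bonferroni(result)
    return result


def _apply_bonferroni(pair_set: LDPairSet) -> None:
    if pair_set.correction_scope == "global":
        m = pair_set.n_pairs
        for p in pair_set.pairs:
            p.significant = m > 0 and p.p_value < pair_set.alpha / m
    else:
        counts: dict[str, int] = {}
        for p in pair_set.pairs:
            counts[p.locus_id] = counts.get(p.locus_id, 0) + 1
        for p in pair_set.pairs:
            p.significant = p.p_value < pair_set.alpha / counts[p.locus_id]


def prune_linked_snps(
    pair_set: LDPairSet, threshold_r2: float = 0.2
) -> tuple[set[tuple[str, int]], list[tuple[str, int]]]:
    """Remove SNPs until no pair is both significant and above the r^2 threshold.

    Greedy and deterministic: offending pairs are visited in (locus, pos_i,
    pos_j) order; from each pair still intact, the member with the higher
    missingness is removed (ties broken toward the higher position).
    Returns (retained SNP set, removal log); SNPs are keyed (locus_id,
    position).
    """
    all_snps = {
        key
        for p in pair_set.pairs
        for key in ((p.locus_id, p.pos_i), (p.locus_id, p.pos_j))
    }
    removed: list[tuple[str, int]] = []
    removed_set: set[tuple[str, int]] = set()
    offending = sorted(
        (p for p in pair_set.pairs if p.significant and p.r2 > threshold_r2),
        key=lambda p: (p.locus_id, p.pos_i, p.pos_j),
    )
    for p in offending:
        ki, kj = (p.locus_id, p.pos_i), (p.locus_id, p.pos_j)
        if ki in removed_set or kj in removed_set:
            continue
        if p.n_missing_i > p.n_missing_j:
            victim = ki
        elif p.n_missing_j > p.n_missing_i:
            victim = kj
        else:
            victim = max(ki, kj, key=lambda k: k[1])
        removed.append(victim)
        removed_set.add(victim)
    return all_snps - removed_set, removed
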