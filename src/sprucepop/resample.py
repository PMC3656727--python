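"""Subsampling experiment: sensitivity of Tajima's D to sample size.

Within a densely sampled population, k individuals (default 8, the size
of the survey's sparsely sampled populations) are drawn without
replacement B times (default 100); sites are re-filtered within each draw
(complete deletion inside the subsample, so a site segregating in the
full population may be monomorphic in a draw) and Tajima's D and pi are
recomputed.  pi is expected to be robust to subsampling while D loses the
rare variants that push it negative under population expansion, so
subsample means drift upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .popstats import DiversitySummary, summarize_locus, summarize_population
from .seqio import LocusAlignment, PopulationMap, classify_sites

__all__ = ["ResampleSummary", "resample_statistics", "latitude_trend_table"]


@dataclass
class ResampleSummary:
    population_id: str
    locus_id: str
    k: int
    B: int
    seed: int
    d_values: list[float] = field(default_factory=list)  # finite replicates only
    pi_values: list[float] = field(default_factory=list)
    n_undefined_d: int = 0  # replicates with S = 0 (D undefined, excluded)

    @property
    def mean_d(self) -> float:
        return float(np.mean(self.d_values)) if self.d_values else float("nan")

    @property
    def min_d(self) -> float:
        return float(np.min(self.d_values)) if self.d_values else float("nan")

    @property
    def max_d(self) -> float:
        return float(np.max(self.d_values)) if self.d_values else float("nan")

    @property
    def mean_pi(self) -> float:
        return float(np.mean(self.pi_values)) if self.pi_values else float("nan")

    @property
    def min_pi(self) -> float:
        return float(np.min(self.pi_values)) if self.pi_values else float("nan")

    @property
    def max_pi(self) -> float:
        return float(np.max(self.pi_values)) if self.pi_values else float("nan")

    def as_row(self) -> dict:
        return {
            "population_id": self.population_id,
            "locus_id": self.locus_id,
            "k": self.k,
            "B": self.B,
            "mean_pi": self.mean_pi,
            "min_pi": self.min_pi,
            "max_pi": self.max_pi,
            "mean_d": self.mean_d,
            "min_d": self.min_d,
            "max_d": self.max_d,
            "n_undefined_d": self.n_undefined_d,
            "seed": self.seed,
        }


def _replicate_stats(sub: LocusAlignment) -> tuple[float | None, float]:
    sites = classify_sites(sub, "complete_deletion")
    summary = summarize_locus(sub, sites)
    return summary.tajimas_d, summary.pi


def resample_statistics(
    aln: LocusAlignment,
    popmap: PopulationMap,
    population_id: str,
    k: int = 8,
    B: int = 100,
    seed: int = 0,
    draws: list[list[str]] | None = None,
) -> ResampleSummary:
    """B random subsamples of k individuals; D and pi per subsample.

    Draws are without replacement among the population's individuals
    present at this locus.  Pass precomputed ``draws`` to share the same
    individuals across loci (joint resampling); otherwise draws are
    seed-deterministic and independent per call.  Replicates with no
    segregating site have undefined D and are counted, not imputed.
    """
    members = [
        ind
        for ind in popmap.individuals_in(population_id)
        if ind in aln.individual_ids
    ]
    if draws is None:
        if len(members) < k:
            raise ValueError(
                f"population {population_id} has {len(members)} sequenced "
                f"individuals at {aln.locus_id}, need >= {k}"
            )
        rng = np.random.default_rng(seed)
        draws = [
            list(rng.choice(members, size=k, replace=False)) for _ in range(B)
        ]
    if k < 4:
        import warnings

        warnings.warn("Tajima's D is unstable below k = 4", stacklevel=2)
    summary = ResampleSummary(
        population_id=population_id, locus_id=aln.locus_id, k=k, B=len(draws), seed=seed
    )
    for draw in draws:
        sub = aln.subset([ind for ind in draw if ind in aln.individual_ids])
        if sub.n < 2:
            summary.n_undefined_d += 1
            continue
        d, pi = _replicate_stats(sub)
        summary.pi_values.append(pi)
        if d is None:
            summary.n_undefined_d += 1
        else:
            summary.d_values.append(d)
    return summary


def joint_draws(
    popmap: PopulationMap,
    population_id: str,
    k: int,
    B: int,
    seed: int,
) -> list[list[str]]:
    """Shared subsample draws for joint (same-trees-across-loci) resampling."""
    members = popmap.individuals_in(population_id)
    if len(members) < k:
        raise ValueError(f"population {population_id} smaller than k = {k}")
    rng = np.random.default_rng(seed)
    return [list(rng.choice(members, size=k, replace=False)) for _ in range(B)]


def latitude_trend_table(
    alignments: Iterable[LocusAlignment],
    popmap: PopulationMap,
    resample_summaries: Iterable[ResampleSummary] = (),
) -> pd.DataFrame:
    """Per-population mean Tajima's D across loci, against latitude.

    One row per population: latitude, the mean D of the full-sample
    per-population estimates over loci where D is defined, and - when
    resampling summaries are supplied - the mean of resampled-replicate
    means across loci.
    """
    alignments = list(alignments)
    rows = []
    resampled: dict[str, list[float]] = {}
    for rs in resample_summaries:
        if np.isfinite(rs.mean_d):
            resampled.setdefault(rs.population_id, []).append(rs.mean_d)
    for pop in popmap.population_ids:
        d_values = []
        for aln in alignments:
            summary: DiversitySummary = summarize_population(aln, popmap, pop)
            if summary.computed and summary.tajimas_d is not None:
                d_values.append(summary.tajimas_d)
        lat = (
            float(popmap.populations.loc[pop, "latitude"])
            if "latitude" in popmap.populations.columns
            else float("nan")
        )
        rows.append(
            {
                "population_id": pop,
                "latitude": lat,
                "n_loci": len(d_values),
                "mean_tajimas_d": float(np.mean(d_values)) if d_values else float("nan"),
                "resampled_mean_d": float(np.mean(resampled[pop]))
                if pop in resampled
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
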