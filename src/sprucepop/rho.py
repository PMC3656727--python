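"""Composite-likelihood estimation of the population recombination rate.

The estimator follows the pairwise composite-likelihood strategy of
two-locus likelihood methods: for every pair of biallelic SNPs the 2x2
haplotype configuration is looked up in a precomputed table of two-locus
sampling likelihoods L(config | rho_pair), the per-pair scaled
recombination rate rho_pair is the candidate per-kb rate times the pair
distance, and the per-locus estimate maximizes the sum of per-pair log
likelihoods over a fixed candidate grid.

The lookup table itself is generated by Monte Carlo: two-locus coalescent
genealogies are simulated at each grid value of rho, and haplotype
configurations are drawn from branch-length exposure at each locus - the
small-theta limit of conditioning on each locus carrying exactly one
mutation (the table's nominal theta, fixed at 0.001 per site by default,
matches the regime where this limit is accurate).  Tables are reproducible
under a fixed seed, can be written to and re-read from a documented text
dialect, and can be swapped for externally produced likelihood files in
the same dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import LocusAlignment, SiteTable, encode_biallelic, site_alleles

logger = logging.getLogger(__name__)

__all__ = [
    "LookupTable",
    "RhoEstimate",
    "build_lookup",
    "write_lookup",
    "read_ldhat_lookup",
    "estimate_rho",
    "rho_over_theta",
    "canonical_config",
]

#: Haplotype-configuration exposure samples drawn per simulated genealogy.
_SAMPLES_PER_TREE = 20
#: Flatness criterion: profile maximum within this many log-units of the
#: grid boundary farthest from the maximizer.
_FLAT_LOGLIK_MARGIN = 2.0


class LookupError_(ValueError):
    """Problem building or reading a two-locus lookup table."""


def log_grid(n_points: int = 15, rho_max: float = 100.0) -> np.ndarray:
    """Zero plus a log-spaced grid up to rho_max.

    LD carries most recombination information at small two-locus rho, so a
    grid dense near zero resolves the likelihood better than a linear one
    at equal cost.
    """
    return np.concatenate(
        [[0.0], np.geomspace(0.5, rho_max, n_points - 1)]
    )


def canonical_config(counts: Sequence[int]) -> tuple[int, int, int, int]:
    """Canonical form of a 2x2 haplotype count table.

    Two-locus sampling likelihoods are invariant under relabeling the
    alleles at either site and under swapping the two sites; the canonical
    form is the lexicographic minimum over those eight images.
    """
    a, b, c, d = (int(v) for v in counts)
    images = []
    for t in ((a, b, c, d), (a, c, b, d)):  # site swap = transpose
        x, y, z, w = t
        images.extend(
            [
                (x, y, z, w),
                (z, w, x, y),  # relabel site-A alleles
                (y, x, w, z),  # relabel site-B alleles
                (w, z, y, x),  # both
            ]
        )
    return min(images)


@lru_cache(maxsize=8)
def _config_universe_size(n: int) -> int:
    """Number of canonical configurations with both sites segregating."""
    seen = set()
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                d = n - a - b - c
                if 0 < a + b < n and 0 < a + c < n:
                    seen.add(canonical_config((a, b, c, d)))
    return len(seen)


@dataclass
class LookupTable:
    """Two-locus composite-likelihood lookup table.

    ``log_likelihoods`` maps a canonical configuration to an array of log
    likelihoods along ``rho_grid`` (two-locus scaled recombination values).
    Configurations never observed in the Monte Carlo share a floor value
    from the +1-pseudocount smoothing.
    """

    n: int
    theta_per_site: float
    rho_grid: np.ndarray
    log_likelihoods: dict[tuple[int, int, int, int], np.ndarray]
    floor: np.ndarray = field(default=None)  # log-lik of unseen configs
    seed: int | None = None

    def loglik(self, config: Sequence[int], rho_pair: float) -> float:
        """Log likelihood of a configuration at a two-locus rho value.

        Linear interpolation between grid points; rho values beyond the
        grid are clamped to the boundary.
        """
        key = canonical_config(config)
        row = self.log_likelihoods.get(key)
        if row is None:
            row = self.floor
        x = float(np.clip(rho_pair, self.rho_grid[0], self.rho_grid[-1]))
        return float(np.interp(x, self.rho_grid, row))


@dataclass
class RhoEstimate:
    locus_id: str
    rho_per_kb: float | None
    rho_locus: float | None
    rho_per_site: float | None
    profile: list[tuple[float, float]] = field(default_factory=list)
    flat_likelihood_flag: bool = False
    n_pairs: int = 0
    computed: bool = True


# --- two-locus coalescent simulation -----------------------------------------

def _simulate_two_locus_exposure(
    rng: np.random.Generator, n: int, rho_pair: float
) -> tuple[dict[frozenset, float], dict[frozenset, float]]:
    """Branch-exposure (descendant-set -> time-length mass) at two loci.

    Standard neutral coalescent for n haploid samples with recombination
    rate rho_pair between the two loci (time in 2N-generation units).
    """
    full = frozenset(range(n))
    # lineage = [anc_left or None, anc_right or None]
    lineages: list[list[frozenset | None]] = [
        [frozenset([i]), frozenset([i])] for i in range(n)
    ]
    expo_l: dict[frozenset, float] = {}
    expo_r: dict[frozenset, float] = {}
    while lineages:
        k = len(lineages)
        if k == 1:
            break
        coal = k * (k - 1) / 2.0
        n_both = sum(1 for lin in lineages if lin[0] is not None and lin[1] is not None)
        rec = 0.5 * rho_pair * n_both
        total = coal + rec
        dt = rng.exponential() / total
        for lin in lineages:
            if lin[0] is not None:
                expo_l[lin[0]] = expo_l.get(lin[0], 0.0) + dt
            if lin[1] is not None:
                expo_r[lin[1]] = expo_r.get(lin[1], 0.0) + dt
        if rng.uniform() < coal / total:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            merged: list[frozenset | None] = []
            for side in (0, 1):
                if a[side] is None:
                    merged.append(b[side])
                elif b[side] is None:
                    merged.append(a[side])
                else:
                    u = a[side] | b[side]
                    merged.append(None if u == full else u)
            for idx in sorted((int(i), int(j)), reverse=True):
                lineages.pop(idx)
            if merged[0] is not None or merged[1] is not None:
                lineages.append(merged)
        else:
            both = [lin for lin in lineages if lin[0] is not None and lin[1] is not None]
            lin = both[int(rng.integers(len(both)))]
            right = lin[1]
            lin[1] = None
            lineages.append([None, right])
    return expo_l, expo_r


def _sample_configs(
    rng: np.random.Generator,
    expo_l: dict[frozenset, float],
    expo_r: dict[frozenset, float],
    n: int,
    m: int,
) -> tuple[list[tuple[int, int, int, int]], float]:
    """Draw m configurations proportional to branch exposure at each locus.

    Returns the configs and the tree's importance weight W_left * W_right
    (the small-theta probability that both loci segregate is proportional
    to the product of total exposures).
    """
    sets_l, w_l = list(expo_l.keys()), np.array(list(expo_l.values()))
    sets_r, w_r = list(expo_r.keys()), np.array(list(expo_r.values()))
    wl, wr = float(w_l.sum()), float(w_r.sum())
    out = []
    il = rng.choice(len(sets_l), size=m, p=w_l / wl)
    ir = rng.choice(len(sets_r), size=m, p=w_r / wr)
    for i, j in zip(il, ir):
        a_set, b_set = sets_l[int(i)], sets_r[int(j)]
        n11 = len(a_set & b_set)
        n12 = len(a_set) - n11
        n21 = len(b_set) - n11
        n22 = n - n11 - n12 - n21
        out.append(canonical_config((n11, n12, n21, n22)))
    return out, wl * wr


def build_lookup(
    n: int,
    theta_per_site: float = 0.001,
    rho_grid: Sequence[float] | None = None,
    n_sims_per_cell: int = 1000,
    seed: int = 0,
) -> LookupTable:
    """Monte-Carlo two-locus likelihood table for a sample of n haplotypes.

    For each grid value of the two-locus rho, ``n_sims_per_cell``
    genealogies are simulated and configuration frequencies tabulated from
    branch-exposure draws, importance-weighted by the probability that both
    loci segregate.  +1 pseudocount smoothing over the full configuration
    universe keeps composite log likelihoods finite.
    """
    if n > 100:
        raise LookupError_("lookup tables supported up to n = 100")
    if rho_grid is None:
        rho_grid = np.linspace(0.0, 100.0, 101)
    rho_grid = np.asarray(sorted(rho_grid), dtype=float)
    if len(rho_grid) > 101:
        raise LookupError_("grid length limited to 101 points")
    if rho_grid[0] != 0.0:
        raise LookupError_("rho grid must start at 0")
    rng = np.random.default_rng(seed)
    universe = _config_universe_size(n)
    counts: dict[tuple[int, int, int, int], np.ndarray] = {}
    totals = np.zeros(len(rho_grid))
    for gi, rho in enumerate(rho_grid):
        weighted: dict[tuple[int, int, int, int], float] = {}
        wsum = 0.0
        for _ in range(n_sims_per_cell):
            expo_l, expo_r = _simulate_two_locus_exposure(rng, n, float(rho))
            configs, w = _sample_configs(rng, expo_l, expo_r, n, _SAMPLES_PER_TREE)
            if not configs:
                continue
            share = w / len(configs)
            for cfg in configs:
                weighted[cfg] = weighted.get(cfg, 0.0) + share
            wsum += w
        if wsum == 0.0:
            raise LookupError_(f"no accepted simulations in cell rho={rho}")
        # rescale weighted counts to n_sims_per_cell "effective" draws
        scale = n_sims_per_cell / wsum
        for cfg, wv in weighted.items():
            if cfg not in counts:
                counts[cfg] = np.zeros(len(rho_grid))
            counts[cfg][gi] = wv * scale
        totals[gi] = n_sims_per_cell
    denom = totals + universe  # +1 pseudocount for every possible config
    log_likelihoods = {
        cfg: np.log((row + 1.0) / denom) for cfg, row in counts.items()
    }
    floor = np.log(1.0 / denom)
    return LookupTable(
        n=n,
        theta_per_site=theta_per_site,
        rho_grid=rho_grid,
        log_likelihoods=log_likelihoods,
        floor=floor,
        seed=seed,
    )


# --- lookup file dialect ------------------------------------------------------
#
# Line 1: "<n> <theta_per_site> <n_grid>"
# Line 2: the grid rho values, whitespace-separated
# Line 3: "floor" followed by the unseen-configuration log likelihoods
# Then one line per configuration: "n11 n12 n21 n22 <loglik per grid point>"

def write_lookup(table: LookupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{table.n} {table.theta_per_site} {len(table.rho_grid)}\n")
        fh.write(" ".join(f"{v:.6g}" for v in table.rho_grid) + "\n")
        fh.write("floor " + " ".join(f"{v:.10g}" for v in table.floor) + "\n")
        for cfg in sorted(table.log_likelihoods):
            row = table.log_likelihoods[cfg]
            fh.write(
                " ".join(map(str, cfg)) + " " + " ".join(f"{v:.10g}" for v in row) + "\n"
            )


def read_ldhat_lookup(
    path: str | Path,
    expected_theta: float | None = None,
    expected_n: int | None = None,
) -> LookupTable:
    """Read a lookup table in the package's likelihood-file dialect.

    A header theta different from ``expected_theta`` produces a warning and
    the header value wins; a header n different from ``expected_n`` is a
    hard error (likelihoods are not interpolated across sample sizes).
    Truncated files raise with the line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        n_s, theta_s, k_s = lines[0].split()
        n, theta, k = int(n_s), float(theta_s), int(k_s)
    except (IndexError, ValueError) as exc:
        raise LookupError_(f"{path}:1: malformed header") from exc
    if expected_n is not None and n != expected_n:
        raise LookupError_(
            f"{path}: table n = {n} does not match dataset n = {expected_n}"
        )
    if expected_theta is not None and not math.isclose(theta, expected_theta):
        logger.warning(
            "%s: header theta %g differs from configured %g; header wins",
            path.name,
            theta,
            expected_theta,
        )
    try:
        grid = np.array([float(v) for v in lines[1].split()])
        if len(grid) != k:
            raise ValueError
    except (IndexError, ValueError) as exc:
        raise LookupError_(f"{path}:2: expected {k} grid values") from exc
    floor = None
    logliks: dict[tuple[int, int, int, int], np.ndarray] = {}
    for lineno, line in enumerate(lines[2:], start=3):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "floor":
            vals = parts[1:]
            if len(vals) != k:
                raise LookupError_(f"{path}:{lineno}: truncated floor row")
            floor = np.array([float(v) for v in vals])
            continue
        if len(parts) != 4 + k:
            raise LookupError_(f"{path}:{lineno}: truncated configuration row")
        cfg = tuple(int(v) for v in parts[:4])
        logliks[cfg] = np.array([float(v) for v in parts[4:]])
    if floor is None:
        raise LookupError_(f"{path}: missing floor row")
    return LookupTable(
        n=n, theta_per_site=theta, rho_grid=grid, log_likelihoods=logliks, floor=floor
    )


# --- composite-likelihood estimation ------------------------------------------

def _project_config(
    counts: tuple[int, int, int, int], n_target: int
) -> tuple[int, int, int, int]:
    """Project a configuration to a different total by expectation scaling.

    The expected composition of a hypergeometric subsample of size
    ``n_target`` is proportional to the observed counts; fractional
    expectations are resolved by largest remainder so the projected counts
    sum exactly to ``n_target``.
    """
    n = sum(counts)
    if n == n_target:
        return counts
    raw = [c * n_target / n for c in counts]
    base = [int(math.floor(v)) for v in raw]
    short = n_target - sum(base)
    order = sorted(range(4), key=lambda i: (raw[i] - base[i], counts[i]), reverse=True)
    for i in order[:short]:
        base[i] += 1
    return tuple(base)  # type: ignore[return-value]


def pair_configs(
    aln: LocusAlignment, sites: SiteTable, min_complete: int = 4
) -> list[tuple[int, tuple[int, int, int, int]]]:
    """(distance_bp, haplotype configuration) for usable biallelic SNP pairs.

    An individual enters a pair only when called at both sites; pairs
    monomorphic at either margin after joint-missing removal, or with fewer
    than ``min_complete`` complete haplotypes, are dropped.
    """
    positions = sites.snp_positions()
    encoded = {pos: encode_biallelic(site_alleles(aln, pos)) for pos in positions}
    out = []
    for i, pi in enumerate(positions):
        for pj in positions[i + 1 :]:
            x, y = encoded[pi], encoded[pj]
            called = (x >= 0) & (y >= 0)
            if int(called.sum()) < min_complete:
                continue
            xs, ys = x[called], y[called]
            if len(np.unique(xs)) < 2 or len(np.unique(ys)) < 2:
                continue
            cfg = (
                int(np.sum((xs == 0) & (ys == 0))),
                int(np.sum((xs == 0) & (ys == 1))),
                int(np.sum((xs == 1) & (ys == 0))),
                int(np.sum((xs == 1) & (ys == 1))),
            )
            out.append((int(abs(pj - pi)), cfg))
    return out


def estimate_rho(
    aln: LocusAlignment,
    sites: SiteTable,
    table: LookupTable,
    candidate_grid_per_kb: Sequence[float] | None = None,
) -> RhoEstimate:
    """Composite-likelihood rho estimate for one locus.

    The composite log likelihood at candidate rate rho_kb sums, over SNP
    pairs, the table log likelihood of the pair's configuration at
    rho_pair = rho_kb * distance_kb.  Configurations whose complete-
    haplotype count differs from the table's n are projected to n by
    expectation scaling.  The estimate is the grid maximizer;
    ``rho_locus`` scales it by the alignment length.
    """
    if candidate_grid_per_kb is None:
        candidate_grid_per_kb = np.linspace(0.0, 100.0, 101)
    cands = np.asarray(candidate_grid_per_kb, dtype=float)
    pairs = pair_configs(aln, sites)
    if len(pairs) < 1 or len(sites.snp_positions()) < 2:
        return RhoEstimate(
            locus_id=aln.locus_id,
            rho_per_kb=None,
            rho_locus=None,
            rho_per_site=None,
            computed=False,
        )
    projected = [
        (d, _project_config(cfg, table.n) if sum(cfg) != table.n else cfg)
        for d, cfg in pairs
    ]
    profile = np.zeros(len(cands))
    for ci, cand in enumerate(cands):
        total = 0.0
        for d, cfg in projected:
            total += table.loglik(cfg, cand * d / 1000.0)
        profile[ci] = total
    best = int(np.argmax(profile))
    far_edge = 0 if best > len(cands) // 2 else len(cands) - 1
    flat = (profile[best] - profile[far_edge]) < _FLAT_LOGLIK_MARGIN
    rho_kb = float(cands[best])
    return RhoEstimate(
        locus_id=aln.locus_id,
        rho_per_kb=rho_kb,
        rho_locus=rho_kb * aln.length / 1000.0,
        rho_per_site=rho_kb / 1000.0,
        profile=list(zip(cands.tolist(), profile.tolist())),
        flat_likelihood_flag=bool(flat),
        n_pairs=len(pairs),
    )


def rho_over_theta(estimate: RhoEstimate, theta_w: float) -> float | None:
    """Ratio of the per-site recombination and mutation rate estimates."""
    if estimate.rho_per_site is None:
        return None
    if theta_w <= 0:
        return None
    return estimate.rho_per_site / theta_w
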