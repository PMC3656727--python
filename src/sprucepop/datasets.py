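"""Published summary tables of the Scandinavian Norway spruce survey.

The package re-implements the analysis pipeline of a multilocus
amplicon-resequencing survey of *Picea abies*: 11 candidate-gene loci
sequenced in haploid megagametophytes from 10 populations along a
latitudinal gradient (58-67 degrees N), seven populations of 8 trees and
three densely sampled populations (SE-61, SE-64, FI-67) of 24 trees.  The
survey's printed per-locus summary numbers are embedded here as plain
data: they parameterize the synthetic-data generator (amplicon lengths,
sequenced fractions, sample sizes) and serve as inputs to bookkeeping and
report-arithmetic checks.

Diversity columns follow the survey's display convention: theta_w and pi
are per-site rates times 10^3.
"""

from __future__ import annotations

import io

import pandas as pd

from .seqio import PopulationMap

__all__ = [
    "population_table",
    "population_map",
    "locus_summary_table",
    "ld_summary_table",
]

# Sampled populations: id, name, decimal latitude/longitude, trees sampled.
_POPULATIONS_TSV = """\
population_id	name	latitude	longitude	n_sampled
SE-58	Saleby	58.36	13.12	8
SE-60	SorAmsberg	60.45	15.42	8
SE-61	Fulufjallet	61.57	12.78	24
SE-62	Strangsund	62.63	15.12	8
SE-64	Hoglunda	64.08	18.74	24
SE-66	Jock-Erkinvinsa	66.58	22.70	8
FI-61	Punkaharju	61.72	29.39	8
FI-62	Vilpuula	62.02	24.63	8
FI-66	St2	66.24	26.53	8
FI-67	Sodankyla	67.41	26.62	24
"""

# Pooled per-locus diversity summary (all 10 populations merged).
# n: individuals successfully sequenced; bp_sequenced: restricted-dataset
# alignment length; S/singletons: segregating and singleton site counts;
# H/Hd: haplotype count and diversity; theta_w_e3 / pi_e3: per-site rates
# x 10^3; d_significant: deviation from the standard neutral model at 5%.
_LOCUS_SUMMARY_TSV = """\
locus_id	n	amplicon_bp	bp_sequenced	S	singletons	H	Hd	theta_w_e3	pi_e3	tajimas_d	d_significant
PaAP2L3	74	4681	457	5	1	7	0.58	2.2	1.8	-0.42	False
PaCDF1	107	1585	1028	23	4	22	0.92	4.3	2.9	-0.94	False
PaCOL1	81	2970	2449	64	26	39	0.97	5.3	3.3	-1.22	False
PaMFT1	96	4328	1597	62	34	54	0.95	7.6	3.3	-1.81	True
PaFTL1	109	2742	748	14	4	14	0.82	3.6	3.3	-0.18	False
PaCCA1	88	4126	742	24	5	21	0.90	6.4	4.1	-1.10	False
PaPRR7	93	7271	1796	31	21	23	0.88	3.4	1.6	-1.65	False
PaPRR1	114	1859	986	25	8	20	0.89	4.8	4.8	0.02	False
PaWS02746	97	4411	470	34	13	40	0.96	14.1	12.0	-0.43	False
PaWS02749	100	3189	605	53	20	23	0.82	16.9	10.5	-1.21	False
PaZIP	113	4107	803	21	6	15	0.74	4.9	3.6	-0.78	False
"""

# Pooled per-locus LD and recombination summary: parsimony-informative
# site counts, pairwise-comparison bookkeeping, percent significant after
# Bonferroni, mean r^2, distance (bp) at which the fitted expected-r^2
# curve falls below 0.2 (0 = below at origin), and the composite-likelihood
# recombination estimates (rho per locus, per site, and over theta_w).
_LD_SUMMARY_TSV = """\
locus_id	informative	n_pairs	pct_significant	mean_r2	lt02_bp	rho	rho_per_site	rho_over_theta
PaAP2L3	4	6	16.7	NaN	NaN	2.04	0.0004	1.98
PaCDF1	19	171	6.4	0.041	0	5.10	0.003	1.16
PaCOL1	38	703	6.3	0.079	74	18.4	0.006	1.42
PaMFT1	28	378	15.0	0.056	12	25.5	0.006	2.11
PaFTL1	10	45	28.9	0.13	5	19.4	0.007	7.29
PaCCA1	18	153	8.5	0.069	7	11.2	0.003	2.36
PaPRR7	10	45	20.0	0.097	88	8.16	0.001	1.34
PaPRR1	17	136	30.9	0.17	96	3.06	0.002	0.65
PaWS02746	19	171	21.6	0.14	118	21.4	0.005	3.24
PaWS02749	31	465	11.8	0.12	59	11.2	0.004	1.10
PaZIP	15	105	26.7	0.20	353	0	0	0
"""


def population_table() -> pd.DataFrame:
    """The 10 surveyed populations with coordinates and sample sizes."""
    return pd.read_csv(io.StringIO(_POPULATIONS_TSV), sep="\t")


def population_map(individual_ids: dict[str, list[str]] | None = None) -> PopulationMap:
    """PopulationMap over the surveyed populations.

    By default individuals are named ``<population>_t<NN>`` following the
    per-population sample sizes; pass explicit id lists per population to
    override (e.g. to match a real alignment's record names).
    """
    pops = population_table().set_index("population_id")
    if individual_ids is None:
        individual_ids = {
            pop: [f"{pop}_t{k:02d}" for k in range(1, int(row.n_sampled) + 1)]
            for pop, row in pops.iterrows()
        }
    assignments = {
        ind: pop for pop, inds in individual_ids.items() for ind in inds
    }
    return PopulationMap(assignments=assignments, populations=pops)


def locus_summary_table() -> pd.DataFrame:
    """Pooled per-locus diversity summary of the survey (display scaling)."""
    return pd.read_csv(io.StringIO(_LOCUS_SUMMARY_TSV), sep="\t")


def ld_summary_table() -> pd.DataFrame:
    """Pooled per-locus LD / recombination summary of the survey."""
    return pd.read_csv(io.StringIO(_LD_SUMMARY_TSV), sep="\t")
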