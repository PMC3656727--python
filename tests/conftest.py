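import numpy as np
import pandas as pd
import pytest

from sprucepop.seqio import LocusAlignment, PopulationMap


def make_alignment(seqs, locus_id="testlocus", ids=None, **kwargs):
    """Build a LocusAlignment from a list of equal-length strings."""
    if ids is None:
        ids = [f"ind{i+1:02d}" for i in range(len(seqs))]
    matrix = np.array([list(s.upper()) for s in seqs], dtype="<U1")
    return LocusAlignment(
        locus_id=locus_id, individual_ids=ids, matrix=matrix, **kwargs
    )


def make_popmap(assignments, latitudes=None):
    """Build a PopulationMap from {individual: population}."""
    pops = sorted(set(assignments.values()))
    counts = {p: sum(1 for v in assignments.values() if v == p) for p in pops}
    df = pd.DataFrame(
        {
            "name": pops,
            "n_sampled": [counts[p] for p in pops],
            "latitude": [
                (latitudes or {}).get(p, float("nan")) for p in pops
            ],
            "longitude": float("nan"),
        },
        index=pd.Index(pops, name="population_id"),
    )
    return PopulationMap(assignments=dict(assignments), populations=df)


@pytest.fixture
def tiny_alignment():
    # 6 haploid sequences, 10 columns: SNPs at 3 (singleton), 5 (informative),
    # indel column at 8, multiallelic at 10
    return make_alignment(
        [
            "ACGTACGTAA",
            "ACGTACGTAA",
            "ACTTACGTAC",
            "ACGTTCGTAC",
            "ACGTTCG-AG",
            "ACGTTCGTAG",
        ]
    )


@pytest.fixture
def two_pop_map():
    return make_popmap(
        {
            "ind01": "north",
            "ind02": "north",
            "ind03": "north",
            "ind04": "south",
            "ind05": "south",
            "ind06": "south",
        },
        latitudes={"north": 67.0, "south": 58.0},
    )
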