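"""Reading haploid locus alignments, site classification and format writers.

The data model mirrors amplicon-resequencing surveys of conifer
megagametophytes: each locus is a multi-FASTA of haploid sequences, one
record per individual, with unsequenced internal stretches written as ``N``
(a consequence of sequencing only the two ends of each amplified fragment).
Alignment gaps (``-``) mark indels; indel columns are excluded wholesale
from every downstream statistic.  Ambiguity codes other than ``N`` are
conservatively treated as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")
#: IUPAC ambiguity codes (other than N) that are demoted to missing data.
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

MissingPolicy = Literal["complete_deletion", "pairwise_available"]


class AlignmentShapeError(ValueError):
    """Sequences in one locus alignment do not all have the same length."""


class EmptyInputError(ValueError):
    """An input file contained no usable records."""


class MetadataError(KeyError):
    """An individual is missing from the population map."""


@dataclass
class LocusAlignment:
    """Haploid multiple sequence alignment for one locus.

    Rows are individuals (megagametophytes, so phase is known); the
    character matrix is over ``{A, C, G, T, N, -}``.
    """

    locus_id: str
    individual_ids: list[str]
    matrix: np.ndarray  # 2-D array of single characters, dtype '<U1'
    amplicon_length_bp: int | None = None
    sequenced_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentShapeError("alignment matrix must be 2-D")
        if len(self.individual_ids) != self.matrix.shape[0]:
            raise AlignmentShapeError("one row per individual required")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError(f"duplicate individual ids in locus {self.locus_id}")
        for start, end in self.sequenced_segments:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"sequenced segment ({start}, {end}) outside [1, {self.length}]"
                )
        if self.amplicon_length_bp is None:
            self.amplicon_length_bp = self.length

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def sequences(self) -> list[tuple[str, str]]:
        return [
            (ind, "".join(row)) for ind, row in zip(self.individual_ids, self.matrix)
        ]

    def subset(self, individuals: Sequence[str]) -> "LocusAlignment":
        """Restrict to the given individuals (order follows `individuals`)."""
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        rows = [index[ind] for ind in individuals if ind in index]
        return LocusAlignment(
            locus_id=self.locus_id,
            individual_ids=[self.individual_ids[i] for i in rows],
            matrix=self.matrix[rows].copy(),
            amplicon_length_bp=self.amplicon_length_bp,
            sequenced_segments=list(self.sequenced_segments),
        )


@dataclass
class PopulationMap:
    """Individual-to-population assignment plus population metadata."""

    assignments: dict[str, str]
    populations: pd.DataFrame  # index population_id; name, latitude, longitude, n_sampled

    def population_of(self, individual_id: str) -> str:
        try:
            return self.assignments[individual_id]
        except KeyError as exc:
            raise MetadataError(
                f"individual {individual_id!r} missing from population map"
            ) from exc

    def individuals_in(self, population_id: str) -> list[str]:
        return [i for i, p in self.assignments.items() if p == population_id]

    @property
    def population_ids(self) -> list[str]:
        return list(self.populations.index)


@dataclass
class SiteTable:
    """Per-column classification of a locus alignment.

    ``table`` has one row per alignment column with columns::

        position (1-based), klass, n_called, is_singleton,
        is_parsimony_informative, has_missing, alleles (dict char->count)

    ``klass`` partitions columns into {monomorphic, biallelic_snp,
    multiallelic, indel_column}; multiallelic and indel columns are excluded
    from all analyses, matching the filtering applied to the survey data.
    """

    locus_id: str
    table: pd.DataFrame
    missing_policy: MissingPolicy = "complete_deletion"

    def _analyzed_mask(self) -> pd.Series:
        ok = self.table["klass"].isin(["monomorphic", "biallelic_snp"])
        if self.missing_policy == "complete_deletion":
            ok &= ~self.table["has_missing"]
        else:  # pairwise_available still needs >= 2 called sequences
            ok &= self.table["n_called"] >= 2
        return ok

    @property
    def analyzed_positions(self) -> np.ndarray:
        """Positions entering diversity statistics under the active policy."""
        return self.table.loc[self._analyzed_mask(), "position"].to_numpy()

    @property
    def n_analyzed_sites(self) -> int:
        return int(self._analyzed_mask().sum())

    def snp_positions(self, informative_only: bool = False) -> np.ndarray:
        mask = self._analyzed_mask() & (self.table["klass"] == "biallelic_snp")
        if informative_only:
            mask &= self.table["is_parsimony_informative"]
        return self.table.loc[mask, "position"].to_numpy()

    @property
    def n_segregating(self) -> int:
        return int(len(self.snp_positions()))

    @property
    def n_singletons(self) -> int:
        mask = self._analyzed_mask() & self.table["is_singleton"]
        return int(mask.sum())

    def with_policy(self, policy: MissingPolicy) -> "SiteTable":
        return SiteTable(self.locus_id, self.table, policy)


def read_locus_alignment(path: str | Path, locus_id: str | None = None) -> LocusAlignment:
    """Read one locus alignment from a multi-FASTA file.

    Characters are uppercased; IUPAC ambiguity codes other than ``N`` are
    mapped to ``N`` with a logged warning.  All records must have equal
    length.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"{path}: unequal sequence lengths {sorted(lengths)}"
        )
    ids = [r.id for r in records]
    raw = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    bad = ~np.isin(raw, list(VALID_CHARS))
    if bad.any():
        offending = sorted(set(raw[bad]))
        unknown = [c for c in offending if c not in AMBIGUITY_CODES]
        if unknown:
            raise ValueError(f"{path}: invalid alignment characters {unknown}")
        logger.warning(
            "%s: %d ambiguity-code bases (%s) treated as missing (N)",
            path.name,
            int(bad.sum()),
            ",".join(offending),
        )
        raw[bad] = "N"
    return LocusAlignment(
        locus_id=locus_id or path.stem, individual_ids=ids, matrix=raw
    )


def write_locus_alignment(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=ind, description="")
        for ind, seq in aln.sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a population map TSV: individual_id, population_id[, latitude, longitude]."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "population_id": str})
    if df.empty:
        raise EmptyInputError(f"empty population map {path}")
    assignments = dict(zip(df["individual_id"], df["population_id"]))
    agg: dict[str, object] = {"n_sampled": ("individual_id", "size")}
    for col in ("latitude", "longitude"):
        if col in df.columns:
            agg[col] = (col, "first")
    pops = df.groupby("population_id").agg(**agg)
    pops["name"] = pops.index
    return PopulationMap(assignments=assignments, populations=pops)


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    rows = []
    for ind, pop in popmap.assignments.items():
        rec = {"individual_id": ind, "population_id": pop}
        for col in ("latitude", "longitude"):
            if col in popmap.populations.columns:
                rec[col] = popmap.populations.loc[pop, col]
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_sites(
    aln: LocusAlignment, missing_policy: MissingPolicy = "complete_deletion"
) -> SiteTable:
    """Classify every alignment column.

    A column containing any ``-`` is an indel column and excluded outright;
    among the remainder the observed non-``N`` characters decide the class.
    Multiallelic (>2 alleles) columns are flagged and excluded.  Singleton
    and parsimony-informative flags partition the biallelic SNPs.
    """
    if aln.n == 0:
        raise EmptyInputError("empty alignment")
    mat = aln.matrix
    rows = []
    for j in range(aln.length):
        col = mat[:, j]
        has_gap = bool((col == "-").any())
        called = col[(col != "N") & (col != "-")]
        alleles, counts = np.unique(called, return_counts=True)
        n_called = int(called.size)
        n_alleles = len(alleles)
        if has_gap:
            klass = "indel_column"
        elif n_alleles <= 1:
            klass = "monomorphic"
        elif n_alleles == 2:
            klass = "biallelic_snp"
        else:
            klass = "multiallelic"
        minor = int(counts.min()) if n_alleles == 2 else 0
        rows.append(
            {
                "position": j + 1,
                "klass": klass,
                "n_called": n_called,
                "is_singleton": klass == "biallelic_snp" and minor == 1,
                "is_parsimony_informative": klass == "biallelic_snp" and minor >= 2,
                "has_missing": bool((col == "N").any()),
                "alleles": dict(zip(alleles.tolist(), counts.astype(int).tolist())),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "position",
            "klass",
            "n_called",
            "is_singleton",
            "is_parsimony_informative",
            "has_missing",
            "alleles",
        ],
    )
    return SiteTable(locus_id=aln.locus_id, table=table, missing_policy=missing_policy)


def site_alleles(aln: LocusAlignment, position: int) -> np.ndarray:
    """Column of the alignment at a 1-based position."""
    return aln.matrix[:, position - 1]


def encode_biallelic(column: np.ndarray) -> np.ndarray:
    """Encode a biallelic column as 0 (major) / 1 (minor) / -1 (missing or gap).

    Ties at frequency n/2 are broken alphabetically (earlier character =
    allele 0) so the coding is deterministic.
    """
    called = column[(column != "N") & (column != "-")]
    alleles, counts = np.unique(called, return_counts=True)
    if len(alleles) != 2:
        raise ValueError("column is not biallelic among called sequences")
    order = np.lexsort((alleles, -counts))  # by descending count, then character
    major, minor = alleles[order[0]], alleles[order[1]]
    out = np.full(column.shape, -1, dtype=np.int8)
    out[column == major] = 0
    out[column == minor] = 1
    return out


def write_structure_input(
    alignments: Iterable[LocusAlignment],
    site_tables: Iterable[SiteTable],
    popmap: PopulationMap,
    path: str | Path,
) -> pd.DataFrame:
    """Write a STRUCTURE-format flat file over the biallelic SNPs of all loci.

    One row per (haploid) individual: label, numeric population column, then
    one integer-coded allele per SNP (1/2; missing ``-9``).  Returns the
    emitted matrix as a DataFrame for round-trip checking.
    """
    alignments = list(alignments)
    site_tables = list(site_tables)
    all_inds: list[str] = []
    for aln in alignments:
        for ind in aln.individual_ids:
            popmap.population_of(ind)  # raises MetadataError if absent
            if ind not in all_inds:
                all_inds.append(ind)
    pop_codes = {p: i + 1 for i, p in enumerate(popmap.population_ids)}
    columns: dict[str, np.ndarray] = {}
    for aln, sites in zip(alignments, site_tables):
        idx = {ind: i for i, ind in enumerate(aln.individual_ids)}
        for pos in sites.snp_positions():
            coded = encode_biallelic(site_alleles(aln, pos))
            col = np.full(len(all_inds), -9, dtype=int)
            for k, ind in enumerate(all_inds):
                if ind in idx:
                    v = coded[idx[ind]]
                    col[k] = -9 if v < 0 else int(v) + 1
            columns[f"{aln.locus_id}_{pos}"] = col
    df = pd.DataFrame(columns, index=all_inds)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for ind in all_inds:
            pop = pop_codes[popmap.population_of(ind)]
            vals = "\t".join(str(v) for v in df.loc[ind])
            fh.write(f"{ind}\t{pop}\t{vals}\n")
    return df


def read_structure_input(path: str | Path) -> pd.DataFrame:
    """Re-parse a file written by :func:`write_structure_input`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows[parts[0]] = [int(v) for v in parts[2:]]
    return pd.DataFrame.from_dict(rows, orient="index", columns=header)


def write_ldhat_inputs(
    sites: SiteTable, aln: LocusAlignment, path_prefix: str | Path
) -> tuple[Path, Path]:
    """Write LDhat-dialect ``.sites`` / ``.locs`` files for one locus.

    Haplotypes are 0/1-coded over the biallelic SNPs (missing ``?``); the
    locs file lists SNP positions in kilobases.
    """
    prefix = Path(path_prefix)
    positions = sites.snp_positions()
    if len(positions) == 0:
        logger.warning("%s: no biallelic SNPs, LDhat output empty", aln.locus_id)
    coded = np.full((aln.n, len(positions)), "?", dtype="<U1")
    for k, pos in enumerate(positions):
        enc = encode_biallelic(site_alleles(aln, pos))
        coded[enc == 0, k] = "0"
        coded[enc == 1, k] = "1"
    sites_path = prefix.with_suffix(".sites")
    locs_path = prefix.with_suffix(".locs")
    with open(sites_path, "w") as fh:
        fh.write(f"{aln.n} {len(positions)} 1\n")
        for ind, row in zip(aln.individual_ids, coded):
            fh.write(f">{ind}\n{''.join(row)}\n")
    with open(locs_path, "w") as fh:
        span_kb = aln.length / 1000.0
        fh.write(f"{len(positions)} {span_kb:.3f} L\n")
        fh.write("\n".join(f"{pos / 1000.0:.3f}" for pos in positions) + "\n")
    return sites_path, locs_path


def write_site_table(sites: SiteTable, path: str | Path) -> None:
    out = sites.table.copy()
    out["alleles"] = out["alleles"].map(
        lambda d: ",".join(f"{a}:{c}" for a, c in sorted(d.items()))
    )
    out.insert(0, "locus_id", sites.locus_id)
    out.to_csv(path, sep="\t", index=False)
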