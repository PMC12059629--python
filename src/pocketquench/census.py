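"""Gene-complement census and alignment conservation statistics.

Operates on precomputed per-sequence clade score tables (e.g. from an HMM
search, one row per sequence x clade) and on multiple alignments: assigns
each sequence its best-scoring clade, tallies per-genome complements of the
carotenoid-protein families (HCP1..HCP9, OCP1/OCP2/OCP3), computes
per-column amino-acid frequencies and information content for logo
rendering, and global pairwise sequence identities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLADE_LABELS = tuple(f"HCP{i}" for i in range(1, 10)) + ("OCP1", "OCP2", "OCP3")
HCP_CLADES = frozenset(c for c in CLADE_LABELS if c.startswith("HCP"))
OCP_CLADES = frozenset(c for c in CLADE_LABELS if c.startswith("OCP"))

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_IC = math.log2(20)


class CensusError(ValueError):
    pass


@dataclass(frozen=True)
class CladeAssignment:
    sequence_id: str
    genome_id: str
    clade: str
    score: float
    margin: float  # bits to the runner-up; >= 0


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV score table (sequence_id, genome_id, clade, bit_score).

    Also accepts the space-delimited tabular output of a standard homology
    search ('#'-prefixed comment lines; query name in column 3, target in
    column 1, bit score in column 6, genome id taken as the target's prefix
    before the last '_').
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") or not first.lower().startswith("sequence_id"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.split()
                target, query, score = f[0], f[2], float(f[5])
                genome = target.rsplit("_", 1)[0]
                rows.append((target, genome, query, score))
        return pd.DataFrame(rows, columns=["sequence_id", "genome_id", "clade", "bit_score"])
    return pd.read_csv(path, sep="\t")


def assign_clades(
    score_table: pd.DataFrame, score_floor: float | None = None
) -> list[CladeAssignment]:
    """Best-scoring clade per sequence; ties break lexicographically (warned).

    Sequences whose best score falls below ``score_floor`` are unassigned
    (dropped).
    """
    required = {"sequence_id", "genome_id", "clade", "bit_score"}
    if score_table is None or len(score_table) == 0:
        raise CensusError("empty score table")
    if not required <= set(score_table.columns):
        raise CensusError(f"score table needs columns {sorted(required)}")
    out: list[CladeAssignment] = []
    for (seq_id, genome), grp in score_table.groupby(["sequence_id", "genome_id"], sort=True):
        grp = grp.sort_values(["bit_score", "clade"], ascending=[False, True])
        best = grp.iloc[0]
        scores = grp["bit_score"].to_numpy()
        if len(grp) > 1 and scores[1] == scores[0]:
            logger.warning(
                "sequence %s: tie at %.2f bits; assigned lexicographically first clade %s",
                seq_id, scores[0], best["clade"],
            )
        margin = float(scores[0] - scores[1]) if len(grp) > 1 else 0.0
        if score_floor is not None and scores[0] < score_floor:
            continue
        out.append(
            CladeAssignment(
                sequence_id=str(seq_id),
                genome_id=str(genome),
                clade=str(best["clade"]),
                score=float(scores[0]),
                margin=margin,
            )
        )
    return out


@dataclass
class CensusTable:
    """Per-genome clade complements with derived presence booleans."""

    complements: dict[str, frozenset[str]]

    @classmethod
    def from_assignments(cls, assignments: Iterable[CladeAssignment]) -> "CensusTable":
        comp: dict[str, set[str]] = {}
        for a in assignments:
            comp.setdefault(a.genome_id, set()).add(a.clade)
        return cls({g: frozenset(s) for g, s in comp.items()})

    @classmethod
    def from_complements(cls, complements: dict[str, Iterable[str]]) -> "CensusTable":
        return cls({g: frozenset(c) for g, c in complements.items()})

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, Iterable[str]]]) -> "CensusTable":
        comp: dict[str, frozenset[str]] = {}
        for genome, clades in rows:
            if genome in comp:
                raise CensusError(f"duplicate genome row {genome!r}")
            comp[genome] = frozenset(clades)
        return cls(comp)

    def has(self, genome: str, clades: frozenset[str]) -> bool:
        return bool(self.complements[genome] & clades)


def tally(census: CensusTable) -> dict:
    """Complement tallies: OCP/HCP prevalence and the HCP4/HCP5 partition.

    Percentages are of the parent group: top-level counts are percent of all
    genomes; ``with_ocp`` within each HCP4/HCP5 group is percent of that
    group.  The four-way partition (HCP4-only / HCP5-only / both / neither)
    is exhaustive and mutually exclusive.
    """
    if not census.complements:
        raise CensusError("empty census")
    n = len(census.complements)
    genomes = list(census.complements)

    def pct(k: int, parent: int) -> float:
        return round(100.0 * k / parent, 1) if parent else 0.0

    any_ocp = [g for g in genomes if census.has(g, OCP_CLADES)]
    any_hcp = [g for g in genomes if census.has(g, HCP_CLADES)]
    h4 = {g for g in genomes if "HCP4" in census.complements[g]}
    h5 = {g for g in genomes if "HCP5" in census.complements[g]}
    groups = {
        "hcp4_not_hcp5": sorted(h4 - h5),
        "hcp5_not_hcp4": sorted(h5 - h4),
        "both_hcp4_hcp5": sorted(h4 & h5),
        "neither_hcp4_nor_hcp5": sorted(set(genomes) - h4 - h5),
    }
    result: dict = {
        "n_genomes": n,
        "any_ocp": {"count": len(any_ocp), "pct_of_genomes": pct(len(any_ocp), n)},
        "any_hcp": {"count": len(any_hcp), "pct_of_genomes": pct(len(any_hcp), n)},
    }
    for name, members in groups.items():
        with_ocp = sum(1 for g in members if census.has(g, OCP_CLADES))
        result[name] = {
            "count": len(members),
            "pct_of_genomes": pct(len(members), n),
            "with_ocp": {"count": with_ocp, "pct_of_group": pct(with_ocp, len(members))},
        }
    # containing-group views (parent = genomes containing the gene)
    for gene, members in (("hcp4", h4), ("hcp5", h5)):
        with_ocp = sum(1 for g in members if census.has(g, OCP_CLADES))
        other = sum(
            1 for g in members if census.complements[g] & (HCP_CLADES - {gene.upper()})
        )
        result[f"{gene}_containing"] = {
            "count": len(members),
            "with_ocp": {"count": with_ocp, "pct_of_group": pct(with_ocp, len(members))},
            "with_other_hcp": {"count": other, "pct_of_group": pct(other, len(members))},
        }
    return result


@dataclass
class ConservationMatrix:
    """Per-column residue frequencies, gap fractions, and IC in bits."""

    frequencies: pd.DataFrame  # columns = AMINO_ACIDS, one row per column
    gap_fraction: np.ndarray
    information_content: np.ndarray
    annotations: dict[int, set[str]] = field(default_factory=dict)


def _column_ic(freqs: np.ndarray) -> float:
    nz = freqs[freqs > 0]
    entropy = -(nz * np.log2(nz)).sum() if nz.size else MAX_IC
    return MAX_IC - entropy


def conservation(
    alignment: Sequence[tuple[str, str]],
    annotations: dict[int, Iterable[str]] | None = None,
    reference_id: str | None = None,
) -> ConservationMatrix:
    """Column frequencies and information content of a protein alignment.

    ``alignment`` is a list of (id, aligned sequence) pairs of equal length
    (gaps '-'); frequencies use a gap-excluded denominator and IC(col) =
    log2(20) - H(col) in bits.  ``annotations`` maps *reference-sequence
    residue numbers* (1-based, ungapped positions of ``reference_id``; the
    first sequence by default) to flag sets such as {'P'} or {'R'}; they are
    projected onto alignment columns through the reference's coordinate map.
    """
    if not alignment:
        raise CensusError("empty alignment")
    length = len(alignment[0][1])
    if any(len(seq) != length for _, seq in alignment):
        raise CensusError("aligned sequences must have equal length")
    counts = np.zeros((length, 20))
    gaps = np.zeros(length)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for _, seq in alignment:
        for col, ch in enumerate(seq.upper()):
            if ch in aa_index:
                counts[col, aa_index[ch]] += 1
            else:
                gaps[col] += 1
    totals = counts.sum(axis=1)
    freqs = np.divide(
        counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0
    )
    ic = np.array([_column_ic(f) for f in freqs])
    mapped: dict[int, set[str]] = {}
    if annotations:
        ref_id = reference_id if reference_id is not None else alignment[0][0]
        ref_seq = dict(alignment).get(ref_id)
        if ref_seq is None:
            raise CensusError(f"reference sequence {ref_id!r} not in alignment")
        residue_to_col: dict[int, int] = {}
        resnum = 0
        for col, ch in enumerate(ref_seq):
            if ch != "-":
                resnum += 1
                residue_to_col[resnum] = col
        for pos, flags in annotations.items():
            if pos not in residue_to_col:
                raise CensusError(f"annotation position {pos} outside the reference sequence")
            mapped.setdefault(residue_to_col[pos], set()).update(flags)
    return ConservationMatrix(
        frequencies=pd.DataFrame(freqs, columns=list(AMINO_ACIDS)),
        gap_fraction=gaps / len(alignment),
        information_content=ic,
        annotations=mapped,
    )


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
    region: tuple[int, int] | None = None,
) -> float:
    """Percent identity from a global alignment of two protein sequences.

    Global (Needleman-Wunsch) alignment with the named substitution matrix
    and affine gaps; identity = identical positions / columns where neither
    sequence is gapped, x100, one decimal.  ``region`` optionally restricts
    ``seq_a`` to a 1-based inclusive residue range (e.g. an N-terminal
    domain) before aligning.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not seq_a or not seq_b:
        raise CensusError("empty sequence")
    if region is not None:
        lo, hi = region
        seq_a = seq_a[lo - 1 : hi]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    pairs = [(x, y) for x, y in zip(a_row, b_row) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    ident = sum(1 for x, y in pairs if x == y)
    return round(100.0 * ident / len(pairs), 1)


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
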