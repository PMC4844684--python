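"""Codon degeneracy classes, per-class nucleotide tallies and observed skews.

Coding positions are classified by how many of the four nucleotides at
that position preserve the encoded amino acid under the bacterial genetic
code (translation table 11): nondegenerate (NS), twofold (2s), threefold
(3s, the isoleucine third position, tallied as "other" and excluded from
estimation) and fourfold (4s). Tallies are pooled per replication strand,
with interoperonic regions tallied in leading-strand orientation only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from . import _seq
from .genome_io import (LAGGING, LEADING, AnnotatedGenome, InteroperonicRegion,
                        assign_replication_strand)

log = logging.getLogger(__name__)

NS, TWOFOLD, THREEFOLD, FOURFOLD = "ns", "2s", "3s", "4s"
INTEROPERONIC = "io"
CODING_CLASSES = (NS, TWOFOLD, THREEFOLD, FOURFOLD)
SKEW_CLASSES = (INTEROPERONIC, NS, TWOFOLD, FOURFOLD)


class CodonTable:
    """Bacterial code with per-position degeneracy classes.

    The degeneracy of position p of a sense codon is the number of
    nucleotides at p (including the current one) that yield a sense codon
    encoding the same amino acid.
    """

    def __init__(self, table_id: int = 11):
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons = frozenset(bio.stop_codons)
        self.forward = dict(bio.forward_table)  # codon -> one-letter AA
        if len(self.forward) != 64 - len(self.stop_codons):
            raise AssertionError("incomplete codon table")
        self.is_stop = np.zeros(64, dtype=bool)
        for c in self.stop_codons:
            self.is_stop[_seq.codon_index(_seq.encode(c))] = True
        # degeneracy count per codon x position (0 for stop codons)
        self.degeneracy = np.zeros((64, 3), dtype=np.int8)
        for idx, codon in enumerate(_seq.ALL_CODONS):
            aa = self.forward.get(codon)
            if aa is None:
                continue
            for pos in range(3):
                n = sum(
                    1
                    for b in _seq.BASES
                    if self.forward.get(codon[:pos] + b + codon[pos + 1:]) == aa
                )
                self.degeneracy[idx, pos] = n

    def classify_codon(self, codon: str) -> tuple[str, str, str]:
        """Degeneracy class of each position of a sense codon."""
        if any(b not in _seq.BASES for b in codon.upper()) or len(codon) != 3:
            raise ValueError(f"ambiguous or malformed codon {codon!r}")
        codon = codon.upper()
        if codon in self.stop_codons:
            raise ValueError(f"stop codon {codon}")
        idx = int(_seq.codon_index(_seq.encode(codon)))
        names = {1: NS, 2: TWOFOLD, 3: THREEFOLD, 4: FOURFOLD}
        return tuple(names[int(d)] for d in self.degeneracy[idx])

    def amino_acid(self, codon: str) -> str:
        return self.forward[codon.upper()]

    def degeneracy_table(self) -> pd.DataFrame:
        """Codon/AA/degeneracy-string table ('114' = NS, NS, 4s)."""
        rows = []
        for codon in sorted(self.forward):
            idx = int(_seq.codon_index(_seq.encode(codon)))
            rows.append(
                {
                    "codon": codon,
                    "aa": self.forward[codon],
                    "degeneracy": "".join(str(int(d)) for d in self.degeneracy[idx]),
                }
            )
        return pd.DataFrame(rows)

    def contribution_matrix(self, cls: str) -> np.ndarray:
        """(64, 4) matrix: count of positions of class ``cls`` holding each base.

        ``hist @ M`` turns a codon histogram into A/C/G/T counts at sites
        of that class.
        """
        target = {NS: 1, TWOFOLD: 2, THREEFOLD: 3, FOURFOLD: 4}[cls]
        M = np.zeros((64, 4), dtype=np.int64)
        for idx in range(64):
            if self.is_stop[idx]:
                continue
            if self.degeneracy[idx, 0] == 0:  # not a sense codon (stops only)
                continue
            for pos in range(3):
                if self.degeneracy[idx, pos] == target:
                    base = (idx // (4 ** (2 - pos))) % 4
                    M[idx, base] += 1
        return M


_DEFAULT_TABLE: CodonTable | None = None


def default_table() -> CodonTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = CodonTable(11)
    return _DEFAULT_TABLE


def classify_codon(codon: str) -> tuple[str, str, str]:
    return default_table().classify_codon(codon)


# ---------------------------------------------------------------------------
# counts

#: count-array base order
COUNT_BASES = "ACGT"


@dataclass
class SiteCounts:
    """A/C/G/T tallies per (site class, replication strand).

    Keys are ``(cls, strand)`` for coding classes and
    ``('io', 'leading')`` for interoperonic regions (leading orientation
    only); values are length-4 int arrays in A, C, G, T order.
    """

    genome_id: str
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def get(self, cls: str, strand: str = LEADING) -> np.ndarray:
        return self.counts.get((cls, strand), np.zeros(4, dtype=np.int64))

    def add(self, cls: str, strand: str, acgt: np.ndarray) -> None:
        key = (cls, strand)
        if key not in self.counts:
            self.counts[key] = np.zeros(4, dtype=np.int64)
        self.counts[key] += np.asarray(acgt, dtype=np.int64)


def _gene_codon_histogram(codes: np.ndarray, table: CodonTable, gene_id: str) -> np.ndarray | None:
    """Codon histogram of a sense-strand gene, START and trailing STOP dropped.

    Returns None (and logs) for genes with non-triplet length, ambiguity
    codes or internal stop codons.
    """
    if codes.shape[0] % 3 != 0 or codes.shape[0] < 9:
        log.warning("gene %s skipped: length %d not a usable triplet", gene_id, codes.shape[0])
        return None
    if np.any(codes < 0):
        log.warning("gene %s skipped: ambiguity codes", gene_id)
        return None
    cod = _seq.codon_index(codes.reshape(-1, 3))
    cod = cod[1:]  # drop annotated START regardless of identity
    if table.is_stop[cod[-1]]:
        cod = cod[:-1]
    if np.any(table.is_stop[cod]):
        log.warning("gene %s skipped: internal stop codon", gene_id)
        return None
    return np.bincount(cod, minlength=64)


def gene_sense_codes(genome: AnnotatedGenome, feat) -> np.ndarray:
    codes = genome.sequence[feat.start:feat.end]
    if feat.strand == "-":
        codes = _seq.revcomp_codes(codes)
    return codes


def count_sites(
    genome: AnnotatedGenome,
    regions: list[InteroperonicRegion] | None = None,
    table: CodonTable | None = None,
) -> SiteCounts:
    """Tally nucleotides per site class and replication strand.

    Coding tallies pool all genes of each replication strand on their
    sense strand; interoperonic tallies pool the oriented region
    sequences verbatim.
    """
    table = table or default_table()
    sc = SiteCounts(genome.genome_id)
    hists = {LEADING: np.zeros(64, dtype=np.int64), LAGGING: np.zeros(64, dtype=np.int64)}
    for feat in genome.features:
        if feat.kind != "gene":
            continue
        hist = _gene_codon_histogram(gene_sense_codes(genome, feat), table, feat.id)
        if hist is None:
            continue
        hists[assign_replication_strand(feat, genome.length)] += hist
    for strand, hist in hists.items():
        for cls in CODING_CLASSES:
            sc.add(cls, strand, hist @ table.contribution_matrix(cls))
    if regions:
        for reg in regions:
            ok = reg.oriented_codes[reg.oriented_codes >= 0]
            sc.add(INTEROPERONIC, LEADING, np.bincount(ok, minlength=4))
    return sc


def counts_from_histogram(hist: np.ndarray, table: CodonTable | None = None) -> dict[str, np.ndarray]:
    """Per-class ACGT counts from a 64-codon histogram (no strand split)."""
    table = table or default_table()
    return {cls: hist @ table.contribution_matrix(cls) for cls in CODING_CLASSES}


# ---------------------------------------------------------------------------
# skews

@dataclass(frozen=True)
class Skew:
    value: float
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0


@dataclass
class SkewSet:
    """AT and GC skews per (site class, strand), with denominators.

    Undefined skews (zero denominator) are flagged via
    :attr:`Skew.defined`, never silently reported as 0.
    """

    genome_id: str
    skews: dict[tuple[str, str, str], Skew] = field(default_factory=dict)

    def get(self, pair: str, cls: str, strand: str = LEADING) -> Skew:
        return self.skews[(pair, cls, strand)]


def skew_from_counts(acgt: np.ndarray, pair: str) -> Skew:
    a, c, g, t = (int(x) for x in acgt)
    if pair == "AT":
        denom = a + t
        return Skew((a - t) / denom if denom else float("nan"), denom)
    if pair == "GC":
        denom = g + c
        return Skew((g - c) / denom if denom else float("nan"), denom)
    raise ValueError(f"unknown pair {pair!r}")


def observed_skews(counts: SiteCounts) -> SkewSet:
    """gamma_AT=(A-T)/(A+T) and gamma_GC=(G-C)/(G+C) per class and strand."""
    ss = SkewSet(counts.genome_id)
    for (cls, strand), acgt in counts.counts.items():
        for pair in ("AT", "GC"):
            ss.skews[(pair, cls, strand)] = skew_from_counts(acgt, pair)
    return ss


# ---------------------------------------------------------------------------
# complementary-symmetric-context filter

def _symmetric_tally(codes: np.ndarray, classes: np.ndarray) -> dict[str, np.ndarray]:
    """ACGT counts per class, restricted to sites whose left neighbour is the
    complement of the right neighbour (CxG, GxC, TxA, AxT). Terminal sites
    (missing a neighbour) are excluded."""
    out: dict[str, np.ndarray] = {}
    if codes.shape[0] < 3:
        return out
    mid = codes[1:-1]
    keep = (codes[:-2] == 3 - codes[2:]) & (mid >= 0) & (codes[:-2] >= 0)
    for cls in np.unique(classes[1:-1][keep]):
        if cls == "":
            continue
        sel = mid[keep & np.asarray(classes[1:-1] == cls)]
        out[str(cls)] = np.bincount(sel, minlength=4)
    return out


_CLASS_NAMES = np.array(["", NS, TWOFOLD, THREEFOLD, FOURFOLD])


def filter_symmetric_context(
    genome: AnnotatedGenome,
    regions: list[InteroperonicRegion] | None = None,
    table: CodonTable | None = None,
) -> SiteCounts:
    """Site tallies restricted to complementary-symmetric flanking contexts.

    Neighbours are resolved on the sense strand within each gene (after
    dropping START/STOP) and within each oriented interoperonic region.
    """
    table = table or default_table()
    sc = SiteCounts(genome.genome_id)
    for feat in genome.features:
        if feat.kind != "gene":
            continue
        codes = gene_sense_codes(genome, feat)
        if codes.shape[0] % 3 != 0 or codes.shape[0] < 9 or np.any(codes < 0):
            continue
        cod = _seq.codon_index(codes.reshape(-1, 3))
        inner = cod[1:]
        trailing_stop = bool(table.is_stop[inner[-1]])
        if trailing_stop:
            inner = inner[:-1]
        if np.any(table.is_stop[inner]):
            continue
        n0 = 1
        n1 = len(cod) - (1 if trailing_stop else 0)
        codes = codes[3 * n0:3 * n1]
        classes = _CLASS_NAMES[table.degeneracy[cod[n0:n1]].reshape(-1)]
        strand = assign_replication_strand(feat, genome.length)
        for cls, acgt in _symmetric_tally(codes, classes).items():
            sc.add(cls, strand, acgt)
    for reg in regions or []:
        classes = np.full(reg.oriented_codes.shape[0], INTEROPERONIC, dtype=object)
        for cls, acgt in _symmetric_tally(reg.oriented_codes, classes).items():
            sc.add(cls, LEADING, acgt)
    return sc


# ---------------------------------------------------------------------------
# TSV interchange in the published counts dialect

_CLS_CODE = {NS: "1", TWOFOLD: "2", FOURFOLD: "4"}
_STRAND_CODE = {LEADING: "le", LAGGING: "la"}


def counts_to_row(sc: SiteCounts) -> dict:
    """Flatten counts to the published column convention.

    ``A1le`` = A at NS sites on the leading strand (1/2/4 = NS/2s/4s,
    le/la = leading/lagging); interoperonic counts are ``Aio`` etc.
    """
    row: dict = {"genome_id": sc.genome_id}
    for cls, code in _CLS_CODE.items():
        for strand, scode in _STRAND_CODE.items():
            acgt = sc.get(cls, strand)
            for b, n in zip(COUNT_BASES, acgt):
                row[f"{b}{code}{scode}"] = int(n)
    for b, n in zip(COUNT_BASES, sc.get(INTEROPERONIC, LEADING)):
        row[f"{b}io"] = int(n)
    return row


def counts_from_row(row: dict) -> SiteCounts:
    sc = SiteCounts(str(row["genome_id"]))
    for cls, code in _CLS_CODE.items():
        for strand, scode in _STRAND_CODE.items():
            sc.add(cls, strand, [int(row[f"{b}{code}{scode}"]) for b in COUNT_BASES])
    sc.add(INTEROPERONIC, LEADING, [int(row[f"{b}io"]) for b in COUNT_BASES])
    return sc


def write_counts(table: list[SiteCounts], path) -> pd.DataFrame:
    df = pd.DataFrame([counts_to_row(sc) for sc in table])
    df.to_csv(path, sep="\t", index=False)
    return df


def read_counts(path) -> list[SiteCounts]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [counts_from_row(r._asdict()) for r in df.itertuples(index=False)]
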