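"""Genome, annotation and replication-origin I/O plus coordinate conventions.

A prokaryotic chromosome is handled as a circle. All internal coordinates
are 0-based half-open on the plus strand. After :func:`rotate_to_origin`
the replication origin sits at position 0 and the terminus is assumed
antipodal, so the first half ``[0, L/2)`` of the plus strand is replicated
as leading strand and the second half ``[L/2, L)`` as lagging strand (and
vice versa for the minus strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import _seq

log = logging.getLogger(__name__)

LEADING = "leading"
LAGGING = "lagging"


@dataclass(frozen=True)
class OrientedInterval:
    """A stranded feature in 0-based half-open plus-strand coordinates.

    A feature wrapping the circular origin is stored as its two fragments
    sharing an ``id``.
    """

    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str    # 'gene', 'operon', 'tRNA', 'rRNA'
    id: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.id}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class AnnotatedGenome:
    """Circular chromosome sequence with origin and oriented features."""

    genome_id: str
    sequence: np.ndarray          # int8 base codes, plus strand
    ori: int
    features: list[OrientedInterval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return int(self.sequence.shape[0])

    def validate(self) -> None:
        L = self.length
        if not (0 <= self.ori < L):
            raise ValueError(f"ori {self.ori} outside [0, {L})")
        for f in self.features:
            if not (0 <= f.start < f.end <= L):
                raise ValueError(f"feature {f.id} outside [0, {L}): [{f.start}, {f.end})")

    def sequence_str(self) -> str:
        return _seq.decode(self.sequence)


@dataclass(frozen=True)
class InteroperonicRegion:
    """A trimmed non-transcribed gap, expressed in leading-strand orientation.

    ``start``/``end`` are plus-strand coordinates of this fragment; the
    fragment of a gap in the second genome half carries the
    reverse-complemented sequence. Fragments split at the ori/ter boundary
    share a ``region_id``.
    """

    start: int
    end: int
    oriented_codes: np.ndarray
    region_id: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_sequence(self) -> str:
        return _seq.decode(self.oriented_codes)


# ---------------------------------------------------------------------------
# readers

def read_fasta_largest(path) -> tuple[str, np.ndarray]:
    """Read a (multi-)FASTA and return (record id, codes) of the largest record.

    Multi-chromosome genomes contribute only their largest replicon.
    """
    best = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if best is None or len(rec.seq) > len(best.seq):
            best = rec
    if best is None:
        raise ValueError(f"no FASTA records in {path}")
    codes = _seq.encode(str(best.seq))
    return best.id, codes


_GFF_KINDS = {"gene": "gene", "CDS": "gene", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_gff_features(path, kinds=None) -> list[OrientedInterval]:
    """Read gene/tRNA/rRNA intervals from a GFF3 file.

    GFF3 is 1-based inclusive; intervals are converted to 0-based
    half-open. Only feature types in ``kinds`` (default: gene/CDS/tRNA/rRNA)
    are kept; CDS is treated as a gene.
    """
    kinds = kinds or _GFF_KINDS
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
            _seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in kinds:
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            fid = _attr_id(attrs) or f"{ftype}_{lineno}"
            feats.append(OrientedInterval(s - 1, e, strand, kinds[ftype], fid))
    return feats


def _attr_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        if part.startswith("ID="):
            return part[3:]
    return None


def read_operons(path, genome_id: str | None = None) -> list[OrientedInterval]:
    """Read a DOOR-style operon TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome_id", "operon_id", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"operon TSV missing columns {sorted(required - set(df.columns))}")
    if genome_id is not None:
        df = df[df["genome_id"] == genome_id]
    return [
        OrientedInterval(int(r.start) - 1, int(r.end), str(r.strand), "operon", str(r.operon_id))
        for r in df.itertuples()
    ]


def read_origin(path, genome_id: str) -> int:
    """Read the replication-origin position from a DoriC-style TSV.

    1-based ``ori_start``; when a genome has several entries the first is
    used.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    hits = df[df["genome_id"] == genome_id]
    if hits.empty:
        raise KeyError(f"genome {genome_id} not in origin table {path}")
    return int(hits.iloc[0]["ori_start"]) - 1


def load_genome(fasta, gff, operons, ori_tsv, genome_id: str | None = None) -> AnnotatedGenome:
    """Assemble an :class:`AnnotatedGenome` from the four standard inputs."""
    rec_id, codes = read_fasta_largest(fasta)
    gid = genome_id or rec_id
    feats = read_gff_features(gff) + read_operons(operons, gid)
    ori = read_origin(ori_tsv, gid)
    g = AnnotatedGenome(gid, codes, ori, feats)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# coordinate operations

def rotate_to_origin(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Rotate the circular chromosome so the replication origin is position 0.

    Features are shifted modulo L; a feature that comes to wrap the new
    end is split into two fragments sharing its id.
    """
    genome.validate()
    L = genome.length
    ori = genome.ori
    if ori == 0:
        return genome
    seq = np.concatenate([genome.sequence[ori:], genome.sequence[:ori]])
    feats: list[OrientedInterval] = []
    for f in genome.features:
        s = (f.start - ori) % L
        e = s + f.length
        if e <= L:
            feats.append(replace(f, start=s, end=e))
        else:  # wraps the rotated end
            feats.append(replace(f, start=s, end=L))
            feats.append(replace(f, start=0, end=e - L))
    return AnnotatedGenome(genome.genome_id, seq, 0, feats)


def assign_replication_strand(interval: OrientedInterval, L: int) -> str:
    """Classify a feature as leading or lagging, on a rotated genome (ori=0).

    A plus-strand feature in the first half (midpoint < L/2), or a
    minus-strand feature in the second half, is transcribed in the same
    direction as the replication fork and is leading; otherwise lagging.
    Features straddling the half boundary are assigned by midpoint.
    """
    if interval.length <= 0:
        raise ValueError("empty interval")
    first_half = interval.midpoint() < L / 2
    if interval.strand == "+":
        return LEADING if first_half else LAGGING
    return LAGGING if first_half else LEADING


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(ivals)
    out: list[list[int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def extract_interoperonic(
    genome: AnnotatedGenome, min_len: int = 100, trim5: int = 60
) -> list[InteroperonicRegion]:
    """Extract non-transcribed gaps in leading-strand orientation.

    The complement of all features on the circle is computed; from each
    gap, ``trim5`` bases abutting any feature's 5' end are removed; merged
    gaps shorter than ``min_len`` after trimming are discarded. Gaps are
    then split at the ori (0) and terminus (L/2) boundaries, and fragments
    in the second genome half are reverse-complemented so every returned
    sequence reads in leading-strand orientation.
    """
    if genome.ori != 0:
        raise ValueError("genome must be rotated so that ori = 0")
    L = genome.length
    feats = genome.features
    if not feats:
        raise ValueError("no features annotated; cannot define interoperonic regions")

    merged = _merge_intervals([(f.start, f.end) for f in feats])
    total_cov = sum(e - s for s, e in merged)
    if total_cov >= L:
        raise ValueError("features tile the whole chromosome; no gaps")

    # complement on the circle; a gap spanning the rotated end is merged
    gaps: list[tuple[int, int]] = []  # (start, end) with end possibly > L for wrap
    prev_end = merged[0][1]
    for s, e in merged[1:]:
        if s > prev_end:
            gaps.append((prev_end, s))
        prev_end = max(prev_end, e)
    # wrap gap between the last feature end and the first feature start
    first_start = merged[0][0]
    if prev_end < L or first_start > 0:
        gaps.append((prev_end, L + first_start))  # may be empty if contiguous
        if gaps[-1][0] >= gaps[-1][1]:
            gaps.pop()

    # 5' ends of features: position just upstream of which trim5 bases of gap
    # are removed. Plus-strand 5' end = start; minus-strand 5' end = end.
    trims: list[tuple[int, int]] = []
    for f in feats:
        if f.strand == "+":
            trims.append(((f.start - trim5) % L, trim5))
        else:
            trims.append((f.end % L, trim5))

    regions: list[InteroperonicRegion] = []
    half = L / 2
    for gi, (gs, ge) in enumerate(gaps):
        # apply trims that overlap this (possibly wrapped) gap
        lo, hi = gs, ge
        for tstart, tlen in trims:
            for off in (0, L):  # wrapped gap coordinates extend past L
                ts, te = tstart + off, tstart + tlen + off
                if ts <= lo < te:
                    lo = min(te, hi)
                if ts < hi <= te:
                    hi = max(ts, lo)
        if hi - lo < min_len:
            continue
        rid = f"{genome.genome_id}.io{gi}"
        # split at ori/ter boundaries (multiples of L/2) for orientation
        bounds = sorted({lo, hi} | {b for b in (half, float(L), 1.5 * L) if lo < b < hi})
        for j in range(len(bounds) - 1):
            s, e = int(bounds[j]), int(bounds[j + 1])
            codes = np.concatenate([genome.sequence, genome.sequence])[s:e]
            in_second_half = (s % L) >= half
            if in_second_half:
                codes = _seq.revcomp_codes(codes)
            regions.append(InteroperonicRegion(s % L, ((e - 1) % L) + 1, codes, rid))
    return regions
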