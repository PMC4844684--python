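"""Simulations: no-selection null skews, the codon-table cost trade-off,
and the synthetic annotated-genome generator used for parameter recovery.

Random codon ensembles are drawn from the product distribution over the
three positions conditioned on not being a stop codon — the stationary
distribution of stop-codon rejection sampling — so codon counts can be
drawn exactly as one multinomial per genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _seq
from .costs import CostTable, aa_cost_vector, default_costs, nt_cost_vector
from .genome_io import LAGGING, LEADING, AnnotatedGenome, OrientedInterval
from .model import equilibrium_prob
from .sites import (FOURFOLD, NS, CodonTable, counts_from_histogram,
                    default_table, skew_from_counts)

BASE_COUNT_MATRIX = np.zeros((64, 4), dtype=np.int64)
for _i in range(64):
    for _p in (16, 4, 1):
        BASE_COUNT_MATRIX[_i, (_i // _p) % 4] += 1


def base_probs(gc: float, at_skew: float = 0.0, gc_skew: float = 0.0) -> np.ndarray:
    """i.i.d. base frequencies (A, C, G, T) for given GC content and skews."""
    p = np.array(
        [
            (1 - gc) * (1 + at_skew) / 2,
            gc * (1 - gc_skew) / 2,
            gc * (1 + gc_skew) / 2,
            (1 - gc) * (1 - at_skew) / 2,
        ]
    )
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError(f"degenerate base frequencies for gc={gc}, skews=({at_skew}, {gc_skew})")
    return p


def conditional_codon_probs(p: np.ndarray, table: CodonTable | None = None) -> np.ndarray:
    """Product codon distribution conditioned on not being a stop codon."""
    table = table or default_table()
    probs = np.einsum("i,j,k->ijk", p, p, p).reshape(64).copy()
    probs[table.is_stop] = 0.0
    total = probs.sum()
    if total <= 0:
        raise ValueError("no valid (non-stop) codon has positive probability")
    return probs / total


def sample_codon_histogram(rng: np.random.Generator, n_codons: int, probs: np.ndarray) -> np.ndarray:
    return rng.multinomial(n_codons, probs)


# ---------------------------------------------------------------------------
# null study: skews without mutation or selection

def enumerate_null_skews(gc: float, table: CodonTable | None = None) -> dict[str, float]:
    """Exact infinite-codon NS/4s skews of the null ensemble at given GC.

    Brute-force expectation over the 61 sense codons weighted by the
    conditional product distribution; any nonzero value stems from the
    composition of the excluded stop codons.
    """
    table = table or default_table()
    probs = conditional_codon_probs(base_probs(gc), table)
    by_class = counts_from_histogram(probs, table)
    out = {}
    for cls in (NS, FOURFOLD):
        a, c, g, t = by_class[cls]
        out[f"at_{cls}"] = (a - t) / (a + t)
        out[f"gc_{cls}"] = (g - c) / (g + c)
    return out


def simulate_null_genomes(
    n_genomes: int = 1200,
    gc_range: tuple[float, float] = (0.20, 0.80),
    n_codons: int = 1_000_000,
    seed: int = 1,
    table: CodonTable | None = None,
) -> pd.DataFrame:
    """Per-genome NS/4s skews of random no-selection genomes.

    Each genome draws ``n_codons`` non-stop codons i.i.d. with equal A/T
    and equal G/C frequencies at a GC content taken from a grid equally
    spaced over ``gc_range``. Returns one row per genome (columns gc,
    at_ns, gc_ns, at_4s, gc_4s); cross-genome medians summarise the
    ensemble.
    """
    table = table or default_table()
    rng = np.random.default_rng(seed)
    gcs = np.linspace(gc_range[0], gc_range[1], n_genomes)
    rows = []
    for gc in gcs:
        hist = sample_codon_histogram(rng, n_codons, conditional_codon_probs(base_probs(gc), table))
        by_class = counts_from_histogram(hist, table)
        row = {"gc": gc}
        for cls, name in ((NS, "ns"), (FOURFOLD, "4s")):
            row[f"at_{name}"] = skew_from_counts(by_class[cls], "AT").value
            row[f"gc_{name}"] = skew_from_counts(by_class[cls], "GC").value
        rows.append(row)
    return pd.DataFrame(rows)


def null_medians(df: pd.DataFrame) -> dict[str, float]:
    return {k: float(df[k].median()) for k in ("at_ns", "gc_ns", "at_4s", "gc_4s")}


# ---------------------------------------------------------------------------
# codon-table energy trade-off

def simulate_tradeoff_grid(
    gc_values=None,
    skew_values=None,
    n_codons: int = 1_000_000,
    costs: CostTable | None = None,
    mode: str = "both",
    seed: int = 1,
    table: CodonTable | None = None,
) -> pd.DataFrame:
    """Mean amino-acid and nucleotide costs of random coding sequences.

    For every (GC content, skew) combination, ``n_codons`` valid codons
    are drawn with the given GC content and with AT and GC skews set
    according to ``mode``: 'both' applies the skew to both pairs,
    'AT-only' leaves GC skew at 0, 'GC-only' leaves AT skew at 0.
    """
    if mode not in ("both", "AT-only", "GC-only"):
        raise ValueError(f"unknown mode {mode!r}")
    costs = costs or default_costs()
    table = table or default_table()
    gc_values = np.round(np.arange(0.1, 0.91, 0.1), 10) if gc_values is None else np.asarray(gc_values)
    skew_values = np.round(np.arange(-0.8, 0.81, 0.2), 10) if skew_values is None else np.asarray(skew_values)
    rng = np.random.default_rng(seed)
    aa_vec = np.nan_to_num(aa_cost_vector(costs, table))
    nt_vec = nt_cost_vector(costs)
    rows = []
    for gc in gc_values:
        for skew in skew_values:
            at_skew = 0.0 if mode == "GC-only" else float(skew)
            gc_skew = 0.0 if mode == "AT-only" else float(skew)
            probs = conditional_codon_probs(base_probs(float(gc), at_skew, gc_skew), table)
            hist = sample_codon_histogram(rng, n_codons, probs)
            base_counts = hist @ BASE_COUNT_MATRIX
            a, c, g, t = (float(x) for x in base_counts)
            rows.append(
                {
                    "gc": float(gc),
                    "skew": float(skew),
                    "at_skew": at_skew,
                    "gc_skew": gc_skew,
                    "n_codons": n_codons,
                    "obs_at_skew": (a - t) / (a + t),
                    "obs_gc_skew": (g - c) / (g + c),
                    "mean_aa_cost": float(hist @ aa_vec / n_codons),
                    "mean_nt_cost": float(base_counts @ nt_vec / base_counts.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic annotated genomes with known evolutionary parameters

@dataclass
class SyntheticTruth:
    """Ground truth and structural layout of a synthetic genome.

    ``mu_io``, ``s_rna`` and ``s_aa`` are per-pair ('AT', 'GC'); ``tau``
    amplifies the mutational bias in transcribed regions and ``f`` is the
    neutrally-evolving fraction of NS sites. Structure: ``n_operons``
    single-gene operons, alternating strands, split evenly between the
    two replichores; each gene is ``units_per_gene`` five-codon blocks
    plus START/STOP; gaps of ``gap_len`` bp separate operons.
    """

    mu_io: dict = field(default_factory=lambda: {"AT": 0.05, "GC": 0.05})
    tau: float = 1.5
    s_rna: dict = field(default_factory=lambda: {"AT": -0.3, "GC": -0.3})
    s_aa: dict = field(default_factory=lambda: {"AT": 0.8, "GC": 0.8})
    f: float = 0.35
    n_operons: int = 112
    units_per_gene: int = 450
    gap_len: int = 2000
    seed: int = 1

    def validate(self) -> None:
        for pair in ("AT", "GC"):
            if abs(self.mu_io[pair]) >= 1:
                raise ValueError("|mu_io| must be < 1")
        if not (0 < self.f <= 0.4):
            # f <= 2/5 keeps the equilibrium-drawn fraction of free GC-NS
            # sites (2.5 f) a valid probability in the codon engine
            raise ValueError("generator supports 0 < f <= 0.4")
        if self.n_operons % 4 or self.n_operons < 4:
            raise ValueError("n_operons must be a positive multiple of 4")
        if self.units_per_gene < 1 or self.gap_len < 1:
            raise ValueError("inconsistent structural parameters")

    @property
    def gene_len(self) -> int:
        return 3 * (6 * self.units_per_gene + 2)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


_START = _seq.encode("ATG")
_STOP = _seq.encode("TAA")


def _bern(rng, p, n, one, zero):
    return np.where(rng.random(n) < p, one, zero).astype(np.int8)


def _gene_codes(truth: SyntheticTruth, branch: str, rng: np.random.Generator) -> np.ndarray:
    """Sense-strand codes of one gene drawn from the equilibrium model.

    Six-codon units [A/T]CN, [A/T]CN, [G/C]CN, G[G/C]N, G[G/C]N, G[G/C]N
    (Thr/Ser, Ala/Pro, Gly/Ala families) keep every position
    deterministically NS or 4s under the bacterial code, with no
    reachable stop codon (CGN is avoided: its first position is twofold
    through the arginine AGR synonyms). The three fixed C's are balanced
    by three fixed G's; fixed sites count toward the zero-skew share of
    NS sites, so the pooled NS skew is exactly f times the model skew in
    expectation. Per unit: 2 free AT-NS sites, 4 free + 6 fixed GC-NS
    sites, 6 fourfold sites.
    """
    m = truth.units_per_gene
    mu_t = {p: truth.tau * truth.mu_io[p] for p in ("AT", "GC")}
    p_ns = {
        p: equilibrium_prob(mu_t[p], truth.s_rna[p] + truth.s_aa[p], branch)
        for p in ("AT", "GC")
    }
    p_4s = {p: equilibrium_prob(mu_t[p], truth.s_rna[p], branch) for p in ("AT", "GC")}
    # marginal first-base probabilities of the equilibrium/neutral mixture;
    # free GC-NS sites are 4 of 10, hence the 10/4 * f equilibrium share
    pA_ns = truth.f * p_ns["AT"] + (1 - truth.f) * 0.5
    q_gc = 2.5 * truth.f
    pG_ns = q_gc * p_ns["GC"] + (1 - q_gc) * 0.5

    def draw_4s(n):
        is_at = rng.random(n) < 0.5
        at = _bern(rng, p_4s["AT"], n, _seq.A, _seq.T)
        gc = _bern(rng, p_4s["GC"], n, _seq.G, _seq.C)
        return np.where(is_at, at, gc)

    unit = np.empty((m, 6, 3), dtype=np.int8)
    unit[:, 0, 0] = _bern(rng, pA_ns, m, _seq.A, _seq.T)
    unit[:, 1, 0] = _bern(rng, pA_ns, m, _seq.A, _seq.T)
    unit[:, 2, 0] = _bern(rng, pG_ns, m, _seq.G, _seq.C)
    unit[:, 0:3, 1] = _seq.C
    unit[:, 3:6, 0] = _seq.G
    for ci in (3, 4, 5):
        unit[:, ci, 1] = _bern(rng, pG_ns, m, _seq.G, _seq.C)
    unit[:, :, 2] = draw_4s(6 * m).reshape(m, 6)
    return np.concatenate([_START, unit.reshape(-1), _STOP])


def _gap_codes(truth: SyntheticTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    """Interoperonic codes in leading-strand orientation (S = 0)."""
    is_at = rng.random(n) < 0.5
    at = _bern(rng, (1 + truth.mu_io["AT"]) / 2, n, _seq.A, _seq.T)
    gc = _bern(rng, (1 + truth.mu_io["GC"]) / 2, n, _seq.G, _seq.C)
    return np.where(is_at, at, gc).astype(np.int8)


def generate_synthetic_genome(
    truth: SyntheticTruth | None = None,
    genome_id: str = "syn",
    seed: int | None = None,
) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Build an annotated circular genome drawn from the equilibrium model.

    ori = 0; each replichore holds alternating plus/minus single-gene
    operons separated by interoperonic gaps whose AT/GC sites are drawn
    at mutation equilibrium in leading orientation; 4s sites follow the
    amplified-bias equilibrium with S_RNA, NS sites the S_RNA + S_AA
    equilibrium on a fraction f of positions.
    """
    truth = truth or SyntheticTruth()
    truth.validate()
    if seed is not None:
        truth.seed = seed
    rng = np.random.default_rng(truth.seed)
    per_half = truth.n_operons // 2
    chunks: list[np.ndarray] = []
    features: list[OrientedInterval] = []
    pos = 0
    for half in range(2):
        for k in range(per_half):
            gap = _gap_codes(truth, truth.gap_len, rng)
            if half == 1:  # leading orientation is the minus strand here
                gap = _seq.revcomp_codes(gap)
            chunks.append(gap)
            pos += truth.gap_len
            strand = "+-"[k % 2]
            branch = (
                LEADING
                if (strand == "+") == (half == 0)
                else LAGGING
            )
            sense = _gene_codes(truth, branch, rng)
            plus = sense if strand == "+" else _seq.revcomp_codes(sense)
            gid = f"{genome_id}.g{half}_{k}"
            features.append(OrientedInterval(pos, pos + truth.gene_len, strand, "gene", gid))
            features.append(OrientedInterval(pos, pos + truth.gene_len, strand, "operon", f"op_{gid}"))
            chunks.append(plus)
            pos += truth.gene_len
    genome = AnnotatedGenome(genome_id, np.concatenate(chunks), 0, features)
    genome.validate()
    return genome, truth


def write_synthetic_genome(genome: AnnotatedGenome, truth: SyntheticTruth, outdir) -> dict:
    """Write FASTA/GFF3/operon TSV/ori TSV/truth JSON in the input dialects."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gid = genome.genome_id
    paths = {k: outdir / f"{gid}.{ext}" for k, ext in
             [("fasta", "fna"), ("gff", "gff"), ("operons", "operons.tsv"),
              ("ori", "ori.tsv"), ("truth", "truth.json")]}
    seq = genome.sequence_str()
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{gid}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.features:
            if f.kind == "operon":
                continue
            fh.write(
                f"{gid}\tntskew\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\tID={f.id}\n"
            )
    ops = [f for f in genome.features if f.kind == "operon"]
    pd.DataFrame(
        {
            "genome_id": gid,
            "operon_id": [f.id for f in ops],
            "start": [f.start + 1 for f in ops],
            "end": [f.end for f in ops],
            "strand": [f.strand for f in ops],
        }
    ).to_csv(paths["operons"], sep="\t", index=False)
    pd.DataFrame({"genome_id": [gid], "ori_start": [genome.ori + 1]}).to_csv(
        paths["ori"], sep="\t", index=False
    )
    paths["truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in paths.items()}
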