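"""Synthesis-cost tables and sequence-level cost accounting.

Costs are counted in high-energy phosphate bonds (ATP equivalents)
consumed in de novo synthesis. Amino-acid costs are the published E. coli
values (Akashi & Gojobori). The packaged nucleotide table is a synthetic
stand-in constructed to satisfy the reported cost orderings
(G > A > T/U, G > C > T/U, G + C > A + U); only these orderings, never
the absolute values, drive any conclusion in this package. DNA 'T' is
priced as RNA 'U' in transcript-cost contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import _seq
from .sites import CodonTable, default_table

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CostTable:
    nucleotide_cost: dict[str, float]   # keys A, C, G, U
    aa_cost: dict[str, float]           # 20 one-letter amino acids
    cost_source: str = "default"

    def __post_init__(self):
        missing = set("ACGU") - set(self.nucleotide_cost)
        if missing:
            raise ValueError(f"missing nucleotide costs: {sorted(missing)}")
        missing = set(AA_LETTERS) - set(self.aa_cost)
        if missing:
            raise ValueError(f"missing amino-acid costs: {sorted(missing)}")
        for name, cost in {**self.nucleotide_cost, **self.aa_cost}.items():
            if not cost > 0:
                raise ValueError(f"non-positive cost for {name}: {cost}")

    def nt_cost(self, base: str) -> float:
        return self.nucleotide_cost["U" if base in "TU" else base]

    def check_orderings(self) -> None:
        """Assert the reported cost orderings A>U, G>C, G+C>A+U (and G>A, C>U)."""
        c = self.nucleotide_cost
        if not (c["A"] > c["U"] and c["G"] > c["C"] and c["G"] + c["C"] > c["A"] + c["U"]):
            raise ValueError("nucleotide cost orderings violated")


def _read_cost_tsv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    if not {"name", "cost"}.issubset(df.columns):
        raise ValueError("cost TSV needs columns: name, cost[, source]")
    return df


def load_costs(nt_path=None, aa_path=None, source: str | None = None) -> CostTable:
    """Load a cost table; defaults to the packaged fixtures.

    TSVs carry columns (name, cost, source); when ``source`` is given,
    rows are filtered to that variant.
    """
    data = resources.files("ntskew.data")
    nt_df = _read_cost_tsv(nt_path if nt_path is not None else (data / "nt_costs_synthetic.tsv").open())
    aa_df = _read_cost_tsv(aa_path if aa_path is not None else (data / "aa_costs.tsv").open())
    if source is not None:
        nt_df = nt_df[nt_df.get("source", source) == source] if "source" in nt_df else nt_df
        aa_df = aa_df[aa_df["source"] == source]
    nt = {str(r.name): float(r.cost) for r in nt_df.itertuples(index=False)}
    nt = {("U" if k in "TU" else k): v for k, v in nt.items()}
    aa = {str(r.name): float(r.cost) for r in aa_df.itertuples(index=False)}
    label = source or "default"
    return CostTable(nt, aa, label)


_DEFAULT: CostTable | None = None


def default_costs() -> CostTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_costs()
        _DEFAULT.check_orderings()
    return _DEFAULT


# ---------------------------------------------------------------------------
# vectorised accounting over codon histograms

def aa_cost_vector(costs: CostTable, table: CodonTable | None = None) -> np.ndarray:
    """(64,) cost of the encoded amino acid per codon (NaN for stops)."""
    table = table or default_table()
    out = np.full(64, np.nan)
    for idx, codon in enumerate(_seq.ALL_CODONS):
        aa = table.forward.get(codon)
        if aa is not None:
            out[idx] = costs.aa_cost[aa]
    return out


def nt_cost_vector(costs: CostTable) -> np.ndarray:
    """(4,) cost per base in A, C, G, T(=U) order."""
    return np.array([costs.nt_cost(b) for b in _seq.BASES])


def mean_aa_cost(codon_counts: np.ndarray, costs: CostTable | None = None) -> float:
    """Count-weighted mean cost of the encoded amino acids.

    ``codon_counts`` is a 64-histogram over sense codons (stop entries
    must be zero). Zero total is flagged as NaN.
    """
    costs = costs or default_costs()
    hist = np.asarray(codon_counts, dtype=float)
    vec = aa_cost_vector(costs)
    stops = np.isnan(vec)
    if np.any(hist[stops] != 0):
        raise ValueError("stop codons in codon counts")
    total = hist[~stops].sum()
    if total == 0:
        return float("nan")
    return float(np.nansum(hist * np.where(stops, 0.0, vec)) / total)


def mean_nt_cost(nt_counts: np.ndarray, costs: CostTable | None = None) -> float:
    """Count-weighted mean nucleotide cost (RNA alphabet; T priced as U)."""
    costs = costs or default_costs()
    counts = np.asarray(nt_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return float("nan")
    return float(counts @ nt_cost_vector(costs) / total)
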