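"""Expression proxies and codon-usage bias: tAI, Nc and preferred codons.

tAI scores a gene by the genomic availability of tRNAs for its codons
(geometric mean of relative codon adaptiveness values, with wobble-pairing
penalties); genes are ranked into expression quintiles per replication
strand. Nc is Wright's effective number of codons, from 20 (one codon per
family) to 61 (uniform usage). Preferred codons are detected per family
from the negative association between within-family codon usage and Nc
across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _seq
from .costs import CostTable, aa_cost_vector, default_costs
from .genome_io import LAGGING, LEADING
from .sites import (FOURFOLD, NS, CodonTable, counts_from_histogram,
                    default_table, skew_from_counts)

log = logging.getLogger(__name__)

#: wobble-pairing penalties s (0 = as good as Watson-Crick, 1 = no pairing):
#: anticodon G reading codon U, inosine reading C, inosine reading A,
#: anticodon U reading codon G, lysidine-modified CAU reading AUA.
DEFAULT_WOBBLE = {"GU": 0.41, "IC": 0.28, "IA": 0.9999, "UG": 0.68, "LYS": 0.89}


@dataclass
class TRNAPool:
    """Genomic tRNA gene copy numbers keyed by anticodon (5'->3', DNA)."""

    copies: dict[str, float]
    wobble: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WOBBLE))
    prokaryote: bool = True

    def __post_init__(self):
        if not self.copies or all(v == 0 for v in self.copies.values()):
            raise ValueError("empty tRNA pool")
        if any(v < 0 for v in self.copies.values()):
            raise ValueError("negative tRNA copy number")
        self.copies = {k.upper().replace("U", "T"): float(v) for k, v in self.copies.items()}

    def n(self, anticodon: str) -> float:
        return self.copies.get(anticodon, 0.0)


def read_trna_pool(path) -> TRNAPool:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"anticodon", "copies"}.issubset(df.columns):
        raise ValueError("tRNA TSV needs columns: anticodon, copies")
    return TRNAPool(dict(zip(df["anticodon"].astype(str), df["copies"].astype(float))))


def absolute_adaptiveness(pool: TRNAPool, table: CodonTable | None = None) -> dict[str, float]:
    """W per sense codon: copies of perfect plus penalised wobble anticodons."""
    table = table or default_table()
    s = pool.wobble
    W: dict[str, float] = {}
    for codon in table.forward:
        wc = _seq.revcomp(codon)                       # Watson-Crick anticodon
        head = codon[:2]
        third = codon[2]
        if third == "T":   # also read by anticodon with G at the wobble position
            w = pool.n(wc) + (1 - s["GU"]) * pool.n(_seq.revcomp(head + "C"))
        elif third == "C":  # inosine (genomically A) reads C
            w = pool.n(wc) + (1 - s["IC"]) * pool.n(_seq.revcomp(head + "T"))
        elif third == "A":  # inosine reads A, weakly
            w = pool.n(wc) + (1 - s["IA"]) * pool.n(_seq.revcomp(head + "T"))
        else:               # third == 'G': anticodon U reads G
            w = pool.n(wc) + (1 - s["UG"]) * pool.n(_seq.revcomp(head + "A"))
        W[codon] = w
    if pool.prokaryote:
        # ATA is read by the lysidine-modified CAT tRNA in bacteria
        W["ATA"] = (1 - s["LYS"]) * pool.n("CAT")
    return W


def relative_adaptiveness(pool: TRNAPool, table: CodonTable | None = None) -> dict[str, float]:
    """w = W / max(W); zero entries replaced by the geometric mean of non-zeros."""
    W = absolute_adaptiveness(pool, table)
    wmax = max(W.values())
    if wmax <= 0:
        raise ValueError("tRNA pool recognises no codon")
    w = {c: v / wmax for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = float(np.exp(np.mean(np.log(nonzero))))
    return {c: (v if v > 0 else gm) for c, v in w.items()}


def tai(codon_hist: np.ndarray, pool: TRNAPool, table: CodonTable | None = None) -> float:
    """Gene tAI: geometric mean of w over the gene's (sense) codons."""
    table = table or default_table()
    w = relative_adaptiveness(pool, table)
    hist = np.asarray(codon_hist, dtype=float)
    logw = np.zeros(64)
    use = np.zeros(64, dtype=bool)
    for codon, v in w.items():
        idx = int(_seq.codon_index(_seq.encode(codon)))
        logw[idx] = np.log(v)
        use[idx] = True
    n = hist[use].sum()
    if n <= 0:
        raise ValueError("gene has no sense codons")
    return float(np.exp(hist[use] @ logw[use] / n))


# ---------------------------------------------------------------------------
# effective number of codons (Wright)

def _families(table: CodonTable) -> dict[str, list[int]]:
    fams: dict[str, list[int]] = {}
    for codon, aa in table.forward.items():
        fams.setdefault(aa, []).append(int(_seq.codon_index(_seq.encode(codon))))
    return fams


def effective_number_of_codons(codon_hist: np.ndarray, table: CodonTable | None = None) -> float:
    """Wright's Nc from a gene's codon histogram.

    Per family, homozygosity F = (n * sum p_i^2 - 1) / (n - 1); Nc =
    2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 over the degeneracy-class means, with
    the threefold class falling back to the mean of the two- and fourfold
    means when unused. Clamped to [20, 61]; NaN when no class is
    estimable.
    """
    table = table or default_table()
    hist = np.asarray(codon_hist, dtype=float)
    by_size: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in _families(table).items():
        size = len(codons)
        if size == 1:
            continue
        counts = hist[codons]
        n = counts.sum()
        if n <= 1:
            continue
        p = counts / n
        F = (n * np.sum(p**2) - 1) / (n - 1)
        by_size[size].append(F)
    means = {k: (np.mean(v) if v else np.nan) for k, v in by_size.items()}
    if np.isnan(means[3]) and not (np.isnan(means[2]) and np.isnan(means[4])):
        means[3] = np.nanmean([means[2], means[4]])
    weights = {2: 9, 3: 1, 4: 5, 6: 3}
    nc = 2.0  # Met and Trp, the single-codon families of the bacterial code
    for size, k in weights.items():
        F = means[size]
        if np.isnan(F) or F <= 0:
            if size in (2, 4):
                return float("nan")
            continue  # family class absent from this gene
        nc += k / F
    return float(np.clip(nc, 20.0, 61.0))


# ---------------------------------------------------------------------------
# expression quintiles

@dataclass
class ExpressionBins:
    """Per-strand quintile summary: pooled skews, GC and mean AA cost."""

    table: pd.DataFrame  # gene_id, strand, tai, quintile
    summary: pd.DataFrame  # strand, quintile, skews, gc, mean_aa_cost


def bin_by_expression(
    genes: list[dict],
    k: int = 5,
    pool: TRNAPool | None = None,
    costs: CostTable | None = None,
    table: CodonTable | None = None,
) -> ExpressionBins:
    """Rank genes by tAI per strand and summarise k equal-sized bins.

    ``genes`` holds dicts with keys gene_id, strand (leading/lagging) and
    hist (64-codon histogram); tAI may be precomputed under key 'tai',
    otherwise ``pool`` is required. Q1 holds the lowest-tAI genes; ties
    are broken by stable input order.
    """
    table = table or default_table()
    costs = costs or default_costs()
    aa_vec = np.nan_to_num(aa_cost_vector(costs, table))
    rows = []
    for i, g in enumerate(genes):
        score = g["tai"] if "tai" in g else tai(g["hist"], pool, table)
        rows.append({"gene_id": g["gene_id"], "strand": g["strand"], "tai": score, "_i": i})
    df = pd.DataFrame(rows)
    out_rows, summaries = [], []
    for strand, sub in df.groupby("strand", sort=False):
        if len(sub) < k:
            raise ValueError(f"fewer than {k} genes on the {strand} strand")
        sub = sub.sort_values(["tai", "_i"], kind="stable").reset_index(drop=True)
        # equal-sized bins (+/-1)
        edges = np.linspace(0, len(sub), k + 1).round().astype(int)
        for q in range(k):
            members = sub.iloc[edges[q]:edges[q + 1]]
            hist = np.zeros(64)
            for _, r in members.iterrows():
                hist += np.asarray(genes[int(r["_i"])]["hist"], dtype=float)
            by_class = counts_from_histogram(hist, table)
            base_counts = hist @ _basecounts()
            gc_frac = (base_counts[1] + base_counts[2]) / base_counts.sum()
            summaries.append(
                {
                    "strand": strand, "quintile": f"Q{q + 1}",
                    "n_genes": len(members),
                    "at_4s": skew_from_counts(by_class[FOURFOLD], "AT").value,
                    "gc_4s": skew_from_counts(by_class[FOURFOLD], "GC").value,
                    "at_ns": skew_from_counts(by_class[NS], "AT").value,
                    "gc_ns": skew_from_counts(by_class[NS], "GC").value,
                    "gc_content": float(gc_frac),
                    "mean_aa_cost": float(hist @ aa_vec / hist.sum()),
                }
            )
            for _, r in members.iterrows():
                out_rows.append(
                    {"gene_id": r["gene_id"], "strand": strand, "tai": r["tai"],
                     "quintile": f"Q{q + 1}"}
                )
    return ExpressionBins(pd.DataFrame(out_rows), pd.DataFrame(summaries))


_BC = None


def _basecounts():
    global _BC
    if _BC is None:
        _BC = np.zeros((64, 4))
        for i in range(64):
            for p in (16, 4, 1):
                _BC[i, (i // p) % 4] += 1
    return _BC


# ---------------------------------------------------------------------------
# preferred codons

@dataclass
class CUBResult:
    nc: pd.Series                 # per gene
    preferred: dict[str, str | None]   # family (amino acid) -> codon or None
    correlations: pd.DataFrame    # codon, family, rho, p


def preferred_codons(
    gene_hists: list[np.ndarray],
    table: CodonTable | None = None,
    fourfold_only: bool = True,
    alpha: float = 0.05,
) -> CUBResult:
    """Identify preferred codons from usage-vs-Nc correlations.

    For each codon, Spearman's correlation between its within-family
    usage across genes and the genes' Nc values; the preferred codon of a
    family is the one with the strongest negative correlation significant
    at p < alpha / n (n = family size). Restricted to fourfold families
    by default.
    """
    table = table or default_table()
    hists = [np.asarray(h, dtype=float) for h in gene_hists]
    if len(hists) < 30:
        log.warning("preferred_codons: only %d genes; >=30 recommended", len(hists))
    nc = pd.Series([effective_number_of_codons(h, table) for h in hists], name="nc")
    usable = nc.notna().to_numpy()
    fams = _families(table)
    if fourfold_only:
        fams = {aa: idxs for aa, idxs in fams.items() if len(idxs) == 4}
    rows = []
    preferred: dict[str, str | None] = {}
    nc_arr = nc.to_numpy()[usable]
    if nc_arr.size < 3 or np.all(nc_arr == nc_arr[0]):
        log.warning("preferred_codons: Nc constant or too few genes; no correlations")
        return CUBResult(nc, {aa: None for aa in fams}, pd.DataFrame())
    H = np.stack([h for h, u in zip(hists, usable) if u])
    for aa, idxs in fams.items():
        fam_tot = H[:, idxs].sum(axis=1)
        ok = fam_tot > 0
        best: tuple[float, str] | None = None
        for idx in idxs:
            codon = _seq.codon_str(idx)
            if ok.sum() < 3:
                continue
            freq = H[ok, idx] / fam_tot[ok]
            if np.all(freq == freq[0]):
                continue
            rho, p = stats.spearmanr(freq, nc_arr[ok])
            rows.append({"codon": codon, "family": aa, "rho": rho, "p": p})
            if rho < 0 and p < alpha / len(idxs):
                if best is None or rho < best[0]:
                    best = (rho, codon)
        preferred[aa] = best[1] if best else None
    return CUBResult(nc, preferred, pd.DataFrame(rows))


def ending_preference_tables(preferred_sets: list[dict[str, str | None]]):
    """2x2 Fisher tests of T- vs A-ending and C- vs G-ending preference.

    Pools preferred/non-preferred codon endings over genomes (one
    preferred-codon map per genome) and returns
    {'TA': (odds_ratio, p, table), 'CG': ...}.
    """
    counts = {b: {"pref": 0, "non": 0} for b in "TACG"}
    fwd = default_table().forward
    for pref in preferred_sets:
        for aa, codon in pref.items():
            if codon is None:
                continue
            for c in (c for c, a in fwd.items() if a == aa):
                counts[c[2]]["pref" if c == codon else "non"] += 1
    out = {}
    for key, (b1, b2) in {"TA": ("T", "A"), "CG": ("C", "G")}.items():
        tab = np.array(
            [[counts[b1]["pref"], counts[b2]["pref"]],
             [counts[b1]["non"], counts[b2]["non"]]]
        )
        odds, p = stats.fisher_exact(tab)
        out[key] = (float(odds), float(p), tab)
    return out
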