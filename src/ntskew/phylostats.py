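"""Cross-genome statistics controlling for phylogenetic relatedness.

Felsenstein's phylogenetically independent contrasts decorrelate
trait values of related genomes under a Brownian-motion model on an
ultrametric tree; correlations and regressions are then computed through
the origin on the contrasts (contrasts have arbitrary sign and no
location). Also: the exact binomial sign test used for the S<0 / S>0
fractions, and the lifestyle general linear model with backward
elimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ContrastSet:
    contrasts: np.ndarray      # n_leaves - 1 standardized contrasts
    node_labels: list[str]     # deterministic postorder node identifiers


def load_ultrametric_tree(path_or_str, schema: str = "newick") -> dendropy.Tree:
    if "\n" in str(path_or_str) or str(path_or_str).strip().startswith("("):
        tree = dendropy.Tree.get(data=str(path_or_str), schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(path_or_str), schema=schema)
    return tree


def check_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> None:
    depths = []
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    for leaf in tree.leaf_node_iter():
        depths.append(leaf.root_distance)
    if max(depths) - min(depths) > tol * max(max(depths), 1.0):
        raise ValueError("tree is not ultrametric within tolerance")


def _resolved_children(node) -> list:
    return list(node.child_nodes())


def independent_contrasts(tree: dendropy.Tree, values: dict[str, float]) -> ContrastSet:
    """Felsenstein's contrasts for one trait.

    Post-order traversal: each internal node contributes the contrast
    (x1 - x2) / sqrt(b1 + b2) of its two daughters, takes the
    branch-length-weighted mean as its ancestral value, and augments its
    parent branch by b1*b2/(b1+b2). Polytomies are resolved to zero-
    length caterpillars in deterministic child order (a covariance-
    preserving resolution). Leaves without a value are pruned (logged).
    """
    tree = tree.clone(depth=1)
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = taxa - set(values)
    if missing:
        log.info("pruning %d leaves without trait values", len(missing))
        tree.retain_taxa_with_labels(sorted(taxa & set(values)))
    contrasts: list[float] = []
    labels: list[str] = []

    def reduce_pair(n1, n2, parent_label):
        x1, b1 = n1
        x2, b2 = n2
        if b1 + b2 <= 0:
            raise ValueError(f"zero-length branch pair at node {parent_label}")
        contrasts.append((x1 - x2) / np.sqrt(b1 + b2))
        labels.append(parent_label)
        xa = (x1 / b1 + x2 / b2) / (1 / b1 + 1 / b2) if b1 > 0 and b2 > 0 else (
            x1 if b1 == 0 else x2)
        return xa, b1 * b2 / (b1 + b2)

    def visit(node, idx="r") -> tuple[float, float]:
        """Returns (ancestral value, augmented branch length above node)."""
        blen = node.edge.length or 0.0
        children = _resolved_children(node)
        if not children:
            return values[node.taxon.label], blen
        states = [visit(ch, f"{idx}.{i}") for i, ch in enumerate(children)]
        # caterpillar reduction handles binary nodes and polytomies alike
        cur = states[0]
        for j, nxt in enumerate(states[1:], 1):
            cur = reduce_pair(cur, nxt, f"{idx}#{j}")
        return cur[0], blen + cur[1]

    root = tree.seed_node
    if len(_resolved_children(root)) == 0:
        raise ValueError("tree has a single node; no contrasts")
    visit(root)
    return ContrastSet(np.array(contrasts), labels)


def tree_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian covariance: shared root-to-tip path length per taxon pair."""
    pdm = tree.phylogenetic_distance_matrix()
    tree.calc_node_root_distances()
    depth = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = taxa[j]
            shared = 0.5 * (depth[a] + depth[b] - pdm.patristic_distance(tx[a], tx[b]))
            C[i, j] = C[j, i] = shared
    return C


def correlation_on_contrasts(cx: ContrastSet | np.ndarray, cy: ContrastSet | np.ndarray):
    """Pearson correlation through the origin of two contrast sets.

    r = sum(xy) / sqrt(sum(x^2) sum(y^2)); two-sided p from the t
    distribution with n-1 degrees of freedom. Zero-variance input is
    flagged as NaN.
    """
    x = cx.contrasts if isinstance(cx, ContrastSet) else np.asarray(cx, dtype=float)
    y = cy.contrasts if isinstance(cy, ContrastSet) else np.asarray(cy, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("need two matching contrast vectors of length >= 3")
    sx, sy = np.sum(x**2), np.sum(y**2)
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.sum(x * y) / np.sqrt(sx * sy))
    n = x.shape[0]
    if abs(r) >= 1:
        return r, 0.0
    t = r * np.sqrt((n - 1) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return r, float(p)


def sign_binomial_test(values) -> tuple[float, float]:
    """Fraction of negative values and the exact two-sided binomial p (null 1/2)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    k = int(np.sum(v < 0))
    res = stats.binomtest(k, v.size, 0.5, alternative="two-sided")
    return k / v.size, float(res.pvalue)


# ---------------------------------------------------------------------------
# lifestyle general linear model on contrasts

_TERMS = ("INTRA", "GC", "L", "INTRA:GC", "INTRA:L", "GC:L", "INTRA:GC:L")


def _term_columns(tip_data: pd.DataFrame) -> dict[str, pd.Series]:
    cols = {
        "INTRA": tip_data["INTRA"].astype(float),
        "GC": tip_data["GC"].astype(float),
        "L": tip_data["L"].astype(float),
    }
    for t in _TERMS[3:]:
        parts = t.split(":")
        prod = cols[parts[0]].copy()
        for p in parts[1:]:
            prod = prod * cols[p]
        cols[t] = prod
    return cols


def _removable(terms: list[str]) -> list[str]:
    """Terms whose removal respects marginality (no remaining higher-order
    term contains them)."""
    out = []
    for t in terms:
        factors = set(t.split(":"))
        if any(t != o and factors < set(o.split(":")) for o in terms):
            continue
        out.append(t)
    return out


@dataclass
class LifestyleModel:
    terms: list[str]
    params: pd.Series
    pvalues: pd.Series
    aic_trace: list[tuple[str, float]]
    model: object


def lifestyle_model(
    tree: dendropy.Tree,
    response: dict[str, float],
    tip_data: pd.DataFrame,
    alpha: float = 0.05,
) -> LifestyleModel:
    """S ~ INTRA x GC x L on independent contrasts, backward-eliminated.

    ``tip_data`` is indexed by genome_id with columns INTRA (0/1 or
    bool), GC and L. Interaction terms are formed as products of tip
    values before contrasting; OLS is fitted through the origin on the
    contrasts. The highest-p removable term (respecting marginality) is
    dropped until every remaining term is significant; the AIC of each
    reduced model is recorded alongside.
    """
    taxa = sorted(set(response) & set(tip_data.index.astype(str)))
    if len(taxa) < 4:
        raise ValueError("need >= 4 genomes with complete data")
    tip = tip_data.loc[taxa]
    y = independent_contrasts(tree, {t: response[t] for t in taxa}).contrasts
    cols = _term_columns(tip)
    X = pd.DataFrame(
        {t: independent_contrasts(tree, dict(zip(taxa, cols[t]))).contrasts for t in _TERMS}
    )
    terms = list(_TERMS)
    trace: list[tuple[str, float]] = []
    fit = sm.OLS(y, X[terms]).fit()
    trace.append(("full", float(fit.aic)))
    while terms:
        cand = [t for t in _removable(terms) if fit.pvalues[t] >= alpha]
        if not cand:
            break
        worst = max(cand, key=lambda t: fit.pvalues[t])
        reduced = [t for t in terms if t != worst]
        if not reduced:
            terms, fit = [], None
            trace.append((f"-{worst}", float("nan")))
            break
        new_fit = sm.OLS(y, X[reduced]).fit()
        terms, fit = reduced, new_fit
        trace.append((f"-{worst}", float(new_fit.aic)))
    if fit is not None and np.linalg.matrix_rank(X[terms].to_numpy()) < len(terms):
        raise ValueError("collinear design after elimination")
    params = fit.params if fit is not None else pd.Series(dtype=float)
    pvals = fit.pvalues if fit is not None else pd.Series(dtype=float)
    return LifestyleModel(terms, params, pvals, trace, fit)
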