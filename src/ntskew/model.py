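"""Mutation-selection-drift equilibrium model for nucleotide skews.

Each AT (or GC) basepair site is treated as a two-state system fixed for
one of its two orientations. With strand-specific mutation rates u, v
between the two states and scaled selection S = 2*N_e*s on the
first-listed (more expensive) nucleotide (A over T; G over C), the
stationary skew on the leading strand is

    gamma_lead = (kappa * e^S - 1) / (kappa * e^S + 1),

with kappa = (1 + mu) / (1 - mu) the mutation-rate ratio and
mu = (v - u)/(v + u) the relative mutational skew; on the lagging strand
u and v swap roles, giving gamma_lag = (e^S / kappa - 1)/(e^S / kappa + 1).
At S = 0 the skew reduces to +mu (leading) and -mu (lagging). The pair
(mu, S) is exactly recoverable from the two strand skews; only S = 2*N_e*s
is identifiable, never N_e and s separately.

Cross-genome quantities: the transcription amplification factor tau
(regression through the origin of transcribed-site mutational bias on the
interoperonic bias) and the free-site fraction f (fraction of NS sites
evolving effectively neutrally, so the pooled NS skew is f times the
model skew).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genome_io import LAGGING, LEADING
from .sites import FOURFOLD, INTEROPERONIC, NS, SkewSet

log = logging.getLogger(__name__)

PAIRS = ("AT", "GC")


def _check_mu(mu):
    mu = np.asarray(mu, dtype=float)
    if np.any(np.abs(mu) >= 1):
        raise ValueError("|mu| must be < 1")
    return mu


def kappa_from_mu(mu):
    """Mutation-rate ratio kappa = (1+mu)/(1-mu); bijective with mu."""
    mu = _check_mu(mu)
    return (1 + mu) / (1 - mu)


def mu_from_kappa(kappa):
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be > 0")
    return (kappa - 1) / (kappa + 1)


def forward_skew(mu, S, strand: str):
    """Equilibrium skew for mutational bias mu and scaled selection S."""
    kappa = kappa_from_mu(mu)
    S = np.asarray(S, dtype=float)
    if strand == LEADING:
        x = kappa * np.exp(S)
    elif strand == LAGGING:
        x = np.exp(S) / kappa
    else:
        raise ValueError(f"unknown strand {strand!r}")
    return (x - 1) / (x + 1)


def equilibrium_prob(mu, S, strand: str):
    """Probability that a site is fixed for the first-listed (expensive) base."""
    return (1 + forward_skew(mu, S, strand)) / 2


def _logit(gamma):
    gamma = np.asarray(gamma, dtype=float)
    if np.any(np.abs(gamma) >= 1):
        raise ValueError("boundary skew |gamma| >= 1: estimation not possible")
    return np.log((1 + gamma) / (1 - gamma))


def invert_S(gamma_lead, gamma_lag):
    """Scaled selection from the two strand skews (exact joint inverse)."""
    return 0.5 * (_logit(gamma_lead) + _logit(gamma_lag))


def invert_mu(gamma_lead, gamma_lag):
    """Mutational bias from the two strand skews (exact joint inverse)."""
    log_kappa = 0.5 * (_logit(gamma_lead) - _logit(gamma_lag))
    return mu_from_kappa(np.exp(log_kappa))


def S_from_single_strand(gamma, mu, strand: str):
    """Scaled selection from one strand's skew, given the mutational bias."""
    log_kappa = np.log(kappa_from_mu(mu))
    if strand == LEADING:
        return _logit(gamma) - log_kappa
    if strand == LAGGING:
        return _logit(gamma) + log_kappa
    raise ValueError(f"unknown strand {strand!r}")


# ---------------------------------------------------------------------------
# cross-genome estimators

@dataclass(frozen=True)
class FitResult:
    value: float
    ci_low: float
    ci_high: float
    n: int


def regression_through_origin(x, y, conf: float = 0.95) -> FitResult:
    """Least-squares slope through the origin with a normal-theory CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all-zero predictor: slope undefined")
    slope = float(np.sum(x * y) / sxx)
    n = x.shape[0]
    resid = y - slope * x
    if n < 2:
        return FitResult(slope, float("nan"), float("nan"), n)
    se = np.sqrt(float(np.sum(resid**2)) / (n - 1) / sxx)
    tcrit = stats.t.ppf(0.5 + conf / 2, df=n - 1)
    return FitResult(slope, slope - tcrit * se, slope + tcrit * se, n)


def estimate_tau(mu_io, mu_4s, conf: float = 0.95) -> FitResult:
    """Species-independent amplification factor tau.

    Slope of the transcribed-site mutational bias mu_4s on the
    interoperonic bias mu_io, regression through the origin; requires
    paired finite estimates for >= 3 genomes for a CI.
    """
    mu_io = np.asarray(mu_io, dtype=float)
    mu_4s = np.asarray(mu_4s, dtype=float)
    ok = np.isfinite(mu_io) & np.isfinite(mu_4s)
    if ok.sum() < mu_io.shape[0]:
        log.info("estimate_tau: dropping %d genomes with undefined bias", int((~ok).sum()))
    return regression_through_origin(mu_io[ok], mu_4s[ok], conf)


def _f_objective(f, gl, gg, target):
    with np.errstate(invalid="ignore", divide="ignore"):
        xl, xg = gl / f, gg / f
        usable = (np.abs(xl) < 1) & (np.abs(xg) < 1)
    if not np.any(usable):
        return np.inf
    m = invert_mu(xl[usable], xg[usable])
    return float(np.sum((m - target[usable]) ** 2))


def estimate_f(
    gamma_ns_lead,
    gamma_ns_lag,
    mu_io,
    tau: float,
    bounds: tuple[float, float] = (0.01, 1.0),
    n_boot: int = 1000,
    seed: int = 1,
    conf: float = 0.95,
) -> FitResult:
    """Free-site fraction f maximising mu^NS vs tau*mu^io agreement.

    Minimises, over f, the sum of squared differences between the
    mutational bias recovered from the f-upscaled NS skews and tau*mu_io;
    genomes whose upscaled skew leaves the model domain at a candidate f
    are excluded from that candidate's objective. CI by bootstrap over
    genomes.
    """
    gl = np.asarray(gamma_ns_lead, dtype=float)
    gg = np.asarray(gamma_ns_lag, dtype=float)
    target = tau * np.asarray(mu_io, dtype=float)
    ok = np.isfinite(gl) & np.isfinite(gg) & np.isfinite(target)
    if not np.any(ok):
        raise ValueError("no usable genomes for the f fit")
    gl, gg, target = gl[ok], gg[ok], target[ok]

    def fit_once(gl, gg, target):
        res = optimize.minimize_scalar(
            _f_objective, bounds=bounds, args=(gl, gg, target),
            method="bounded", options={"xatol": 1e-6},
        )
        if not res.success or not np.isfinite(res.fun):
            raise RuntimeError("f optimisation did not converge")
        return float(res.x)

    f_hat = fit_once(gl, gg, target)
    if n_boot <= 0:
        return FitResult(f_hat, float("nan"), float("nan"), gl.shape[0])
    rng = np.random.default_rng(seed)
    n = gl.shape[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = fit_once(gl[idx], gg[idx], target[idx])
    lo, hi = np.quantile(boot, [(1 - conf) / 2, 0.5 + conf / 2])
    return FitResult(f_hat, float(lo), float(hi), n)


# ---------------------------------------------------------------------------
# per-genome decomposition

@dataclass
class EvolParams:
    """Per-genome estimates, per pair: mutational biases and S components.

    ``s_rna``/``s_aa``/``s_total`` map (pair, strand) -> estimate, with
    strand in {leading, lagging, mean}; the mean is the arithmetic mean of
    the two strand estimates. NaN marks a flagged (non-estimable) value.
    """

    genome_id: str
    mu_io: dict = field(default_factory=dict)      # pair -> float
    mu_4s: dict = field(default_factory=dict)      # pair -> float (joint inverse)
    mu_ns: dict = field(default_factory=dict)      # pair -> float (f-upscaled joint inverse)
    s_rna: dict = field(default_factory=dict)      # (pair, strand) -> float
    s_aa: dict = field(default_factory=dict)
    s_total: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for pair in PAIRS:
            for qty, d in (("mu_io", self.mu_io), ("mu_4s", self.mu_4s), ("mu_ns", self.mu_ns)):
                if pair in d:
                    rows.append(
                        {"genome_id": self.genome_id, "pair": pair, "quantity": qty,
                         "strand": "", "value": d[pair], "flag": "" if np.isfinite(d[pair]) else "undefined"}
                    )
            for qty, d in (("S_RNA", self.s_rna), ("S_AA", self.s_aa), ("S_total", self.s_total)):
                for strand in (LEADING, LAGGING, "mean"):
                    if (pair, strand) in d:
                        v = d[(pair, strand)]
                        rows.append(
                            {"genome_id": self.genome_id, "pair": pair, "quantity": qty,
                             "strand": strand, "value": v, "flag": "" if np.isfinite(v) else "undefined"}
                        )
        return rows


def _safe(skew) -> float:
    """Skew value, NaN-flagged at the boundary or when undefined."""
    if not skew.defined or abs(skew.value) >= 1:
        return float("nan")
    return skew.value


def mu_io_from_skews(skews: SkewSet) -> dict[str, float]:
    """Interoperonic skew in leading orientation = mutational bias (S=0)."""
    return {pair: _safe(skews.get(pair, INTEROPERONIC, LEADING)) for pair in PAIRS}


def mu_4s_from_skews(skews: SkewSet) -> dict[str, float]:
    out = {}
    for pair in PAIRS:
        gl = _safe(skews.get(pair, FOURFOLD, LEADING))
        gg = _safe(skews.get(pair, FOURFOLD, LAGGING))
        out[pair] = float(invert_mu(gl, gg)) if np.isfinite(gl) and np.isfinite(gg) else float("nan")
    return out


def decompose_selection(
    skews: SkewSet,
    tau: dict[str, float],
    f: dict[str, float],
    mu_io: dict[str, float] | None = None,
    per_genome_mu: bool = False,
) -> EvolParams:
    """Split selection into transcription (RNA) and translation (AA) parts.

    S_RNA per strand comes from the 4s skew with amplified bias tau*mu_io
    (or, in ``per_genome_mu`` mode, the genome's own mu' recovered jointly
    from its two 4s skews); S_total per strand from the f-upscaled NS
    skew; S_AA = S_total - S_RNA. Flagged skews propagate as NaN.
    """
    p = EvolParams(skews.genome_id)
    p.mu_io = mu_io if mu_io is not None else mu_io_from_skews(skews)
    p.mu_4s = mu_4s_from_skews(skews)
    for pair in PAIRS:
        if per_genome_mu:
            mu_t = p.mu_4s[pair]
        else:
            mu_t = tau[pair] * p.mu_io[pair]
        g4 = {s: _safe(skews.get(pair, FOURFOLD, s)) for s in (LEADING, LAGGING)}
        gns = {s: _safe(skews.get(pair, NS, s)) for s in (LEADING, LAGGING)}
        gns_up = {}
        for s, v in gns.items():
            up = v / f[pair]
            gns_up[s] = up if np.isfinite(up) and abs(up) < 1 else float("nan")
        if all(np.isfinite(v) for v in gns_up.values()):
            p.mu_ns[pair] = float(invert_mu(gns_up[LEADING], gns_up[LAGGING]))
        else:
            p.mu_ns[pair] = float("nan")
        for strand in (LEADING, LAGGING):
            s_rna = _single(g4[strand], mu_t, strand)
            s_tot = _single(gns_up[strand], mu_t, strand)
            p.s_rna[(pair, strand)] = s_rna
            p.s_total[(pair, strand)] = s_tot
            p.s_aa[(pair, strand)] = s_tot - s_rna
        for d in (p.s_rna, p.s_total, p.s_aa):
            d[(pair, "mean")] = 0.5 * (d[(pair, LEADING)] + d[(pair, LAGGING)])
    return p


def _single(gamma: float, mu: float, strand: str) -> float:
    if not (np.isfinite(gamma) and np.isfinite(mu)) or abs(mu) >= 1:
        return float("nan")
    return float(S_from_single_strand(gamma, mu, strand))


@dataclass
class GlobalFit:
    """Cross-genome tau and f per pair, with confidence intervals."""

    tau: dict[str, FitResult]
    f: dict[str, FitResult]

    def to_dict(self) -> dict:
        return {
            key: {
                pair: {"value": r.value, "ci_low": r.ci_low, "ci_high": r.ci_high, "n": r.n}
                for pair, r in d.items()
            }
            for key, d in (("tau", self.tau), ("f", self.f))
        }


def fit_global(
    skew_sets: list[SkewSet],
    n_boot: int = 1000,
    seed: int = 1,
) -> tuple[GlobalFit, list[EvolParams]]:
    """Full cross-genome fit: tau, then f, then per-genome decomposition.

    Genomes with undefined or boundary skews are excluded from the global
    fits (and logged) but still receive flagged per-genome estimates.
    """
    per = {"mu_io": {}, "mu_4s": {}, "ns_l": {}, "ns_g": {}}
    for ss in skew_sets:
        mio, m4 = mu_io_from_skews(ss), mu_4s_from_skews(ss)
        for pair in PAIRS:
            per["mu_io"].setdefault(pair, []).append(mio[pair])
            per["mu_4s"].setdefault(pair, []).append(m4[pair])
            per["ns_l"].setdefault(pair, []).append(_safe(ss.get(pair, NS, LEADING)))
            per["ns_g"].setdefault(pair, []).append(_safe(ss.get(pair, NS, LAGGING)))
    tau, f = {}, {}
    for pair in PAIRS:
        tau[pair] = estimate_tau(per["mu_io"][pair], per["mu_4s"][pair])
        f[pair] = estimate_f(
            per["ns_l"][pair], per["ns_g"][pair], per["mu_io"][pair],
            tau[pair].value, n_boot=n_boot, seed=seed,
        )
    gfit = GlobalFit(tau, f)
    tau_v = {p: tau[p].value for p in PAIRS}
    f_v = {p: f[p].value for p in PAIRS}
    params = [decompose_selection(ss, tau_v, f_v) for ss in skew_sets]
    return gfit, params


def params_to_frame(params: list[EvolParams]) -> pd.DataFrame:
    """Tidy TSV-ready frame (genome_id, pair, quantity, strand, value, flag)."""
    return pd.DataFrame([row for p in params for row in p.to_rows()])
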