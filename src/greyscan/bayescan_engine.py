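"""Bayesian F_ST-outlier test for one population pair.

The model is the hierarchical F-model for biallelic loci: subpopulation
allele frequencies are Beta-distributed around an ancestral frequency
``p_i`` with dispersion set by the pair- and locus-specific differentiation

    logit(F_ST^{ij}) = alpha_i + beta_j,

where ``alpha_i`` is a locus effect (non-zero under locus-specific
selection) and ``beta_j`` a population effect shared across loci.
Integrating the subpopulation frequency out of the binomial sampling layer
gives a beta-binomial marginal likelihood per locus and population with
concentration ``theta_ij = (1 - F_ST^{ij}) / F_ST^{ij} = exp(-(alpha_i +
beta_j))``.

A reversible-jump MCMC moves between models with ``alpha_i`` included
(indicator ``delta_i = 1``) and excluded; the posterior inclusion
probability ``gamma_i`` measures support for selection at locus *i*, its
complement is the posterior error probability (PEP), and q-values are
running means of sorted PEPs.

Proposal widths are adapted during pilot runs targeting acceptance rates
in [0.25, 0.45] and then frozen, preserving detailed balance for the
reported sample.  Each locus consumes its own deterministic random stream
(keyed by the master seed and the marker name) and loci are processed in a
canonical marker-name order internally, so results are exactly invariant
to the input locus order.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import betaln, gammaln

from .genotype_io import AlleleCountTable

logger = logging.getLogger(__name__)

_LOGIT_CLAMP = 25.0


@dataclass
class MCMCConfig:
    """Chain settings; defaults mirror the reference tool's documented defaults."""

    n_pilot: int = 20
    pilot_length: int = 5000
    burn_in: int = 50_000
    n_samples: int = 5000
    thinning: int = 10
    prior_odds: float = 10.0  # P(delta=0) / P(delta=1)
    alpha_prior_sd: float = 1.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pilot_length", "n_samples", "thinning"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_pilot < 0 or self.burn_in < 0:
            raise ValueError("n_pilot and burn_in must be non-negative")
        if self.prior_odds <= 0:
            raise ValueError("prior_odds must be > 0")
        if self.alpha_prior_sd <= 0 or self.beta_prior_sd <= 0:
            raise ValueError("prior standard deviations must be > 0")


@dataclass
class LocusPosterior:
    snp_id: str
    gamma: float
    pep: float
    q_value: float
    alpha_mean: float
    fst_mean: float

    def __post_init__(self) -> None:
        for name in ("gamma", "pep", "q_value"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def fst_from_effects(alpha: float, beta: float) -> float:
    """F_ST implied by the logit decomposition: logistic(alpha + beta)."""
    return 1.0 / (1.0 + math.exp(-(alpha + beta)))


def beta_binomial_loglik(a: int, n: int, p: float, theta: float) -> float:
    """Marginal log-likelihood of ``a`` A-alleles out of ``n`` under the F-model.

    The subpopulation frequency is Beta(theta*p, theta*(1-p)); integrating it
    out of Binomial(n, .) gives

        log C(n, a) + log B(a + theta*p, n - a + theta*(1-p))
                    - log B(theta*p, theta*(1-p)).
    """
    if not (0 <= a <= n):
        raise ValueError(f"require 0 <= a <= n, got a={a}, n={n}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"require 0 < p < 1, got {p}")
    if theta <= 0.0:
        raise ValueError(f"require theta > 0, got {theta}")
    if n == 0:
        return 0.0
    tp, tq = theta * p, theta * (1.0 - p)
    log_choose = gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
    return float(log_choose + betaln(a + tp, n - a + tq) - betaln(tp, tq))


# ---------------------------------------------------------------------------
# numba MCMC kernel
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _cell_ll(a: float, n: float, p: float, x: float) -> float:
    """Beta-binomial log-likelihood (no binomial coefficient) at logit-F_ST x."""
    if n == 0.0:
        return 0.0
    if x > _LOGIT_CLAMP:
        x = _LOGIT_CLAMP
    elif x < -_LOGIT_CLAMP:
        x = -_LOGIT_CLAMP
    theta = math.exp(-x)
    tp = theta * p
    tq = theta - tp
    return (
        math.lgamma(theta)
        - math.lgamma(tp)
        - math.lgamma(tq)
        + math.lgamma(a + tp)
        + math.lgamma(n - a + tq)
        - math.lgamma(n + theta)
    )


@njit(cache=True)
def _run_block(
    a,
    n,
    p,
    alpha,
    delta,
    beta,
    ll,
    scratch,
    wp,
    wa,
    wb,
    rjm,
    rjs,
    sa,
    bm,
    bs,
    lpr,
    zp,
    up,
    za,
    ua,
    zr,
    ur,
    zb,
    ub,
    accp,
    atta,
    acca,
    attr,
    accr,
    accb,
    asum,
    asumsq,
    acnt,
    accum_every,
    sdelta,
    salpha,
    sfst,
    sbeta,
):
    B, L = zp.shape
    n_pops = beta.shape[0]
    for t in range(B):
        for l in range(L):
            al = alpha[l]
            # --- ancestral frequency: random walk on the logit scale ------
            x = math.log(p[l] / (1.0 - p[l]))
            xn = x + wp[l] * zp[t, l]
            if xn > _LOGIT_CLAMP:
                xn = _LOGIT_CLAMP
            elif xn < -_LOGIT_CLAMP:
                xn = -_LOGIT_CLAMP
            pn = 1.0 / (1.0 + math.exp(-xn))
            l0 = _cell_ll(a[l, 0], n[l, 0], pn, al + beta[0])
            l1 = _cell_ll(a[l, 1], n[l, 1], pn, al + beta[1])
            # uniform prior on p => density |dp/dx| = p(1-p) on the logit scale
            d = (
                l0
                + l1
                - ll[l, 0]
                - ll[l, 1]
                + math.log(pn * (1.0 - pn))
                - math.log(p[l] * (1.0 - p[l]))
            )
            if math.log(up[t, l]) < d:
                p[l] = pn
                ll[l, 0] = l0
                ll[l, 1] = l1
                accp[l] += 1

            # --- locus effect (only when included) ------------------------
            if delta[l] == 1:
                atta[l] += 1
                an = al + wa[l] * za[t, l]
                l0 = _cell_ll(a[l, 0], n[l, 0], p[l], an + beta[0])
                l1 = _cell_ll(a[l, 1], n[l, 1], p[l], an + beta[1])
                d = (
                    l0
                    + l1
                    - ll[l, 0]
                    - ll[l, 1]
                    + 0.5 * (al * al - an * an) / (sa * sa)
                )
                if math.log(ua[t, l]) < d:
                    alpha[l] = an
                    al = an
                    ll[l, 0] = l0
                    ll[l, 1] = l1
                    acca[l] += 1

            # --- reversible jump on the inclusion indicator ---------------
            attr[l] += 1
            if delta[l] == 0:
                an = rjm[l] + rjs[l] * zr[t, l]
                l0 = _cell_ll(a[l, 0], n[l, 0], p[l], an + beta[0])
                l1 = _cell_ll(a[l, 1], n[l, 1], p[l], an + beta[1])
                d = (
                    l0
                    + l1
                    - ll[l, 0]
                    - ll[l, 1]
                    - 0.5 * (an / sa) * (an / sa)
                    - math.log(sa)
                    + lpr
                    + 0.5 * ((an - rjm[l]) / rjs[l]) * ((an - rjm[l]) / rjs[l])
                    + math.log(rjs[l])
                )
                if math.log(ur[t, l]) < d:
                    delta[l] = 1
                    alpha[l] = an
                    ll[l, 0] = l0
                    ll[l, 1] = l1
                    accr[l] += 1
            else:
                l0 = _cell_ll(a[l, 0], n[l, 0], p[l], beta[0])
                l1 = _cell_ll(a[l, 1], n[l, 1], p[l], beta[1])
                d = (
                    l0
                    + l1
                    - ll[l, 0]
                    - ll[l, 1]
                    + 0.5 * (al / sa) * (al / sa)
                    + math.log(sa)
                    - lpr
                    - 0.5 * ((al - rjm[l]) / rjs[l]) * ((al - rjm[l]) / rjs[l])
                    - math.log(rjs[l])
                )
                if math.log(ur[t, l]) < d:
                    delta[l] = 0
                    alpha[l] = 0.0
                    ll[l, 0] = l0
                    ll[l, 1] = l1
                    accr[l] += 1

            if delta[l] == 1:
                asum[l] += alpha[l]
                asumsq[l] += alpha[l] * alpha[l]
                acnt[l] += 1

        # --- population effects -------------------------------------------
        for j in range(n_pops):
            bn = beta[j] + wb[j] * zb[t, j]
            s = 0.0
            for l in range(L):
                v = _cell_ll(a[l, j], n[l, j], p[l], alpha[l] + bn)
                scratch[l] = v
                s += v - ll[l, j]
            d = s + 0.5 * (
                (beta[j] - bm) * (beta[j] - bm) - (bn - bm) * (bn - bm)
            ) / (bs * bs)
            if math.log(ub[t, j]) < d:
                beta[j] = bn
                for l in range(L):
                    ll[l, j] = scratch[l]
                accb[j] += 1

        # --- retained-sample accumulation ---------------------------------
        if accum_every > 0 and (t + 1) % accum_every == 0:
            for l in range(L):
                sdelta[l] += delta[l]
                salpha[l] += alpha[l]
                f = 0.0
                for j in range(n_pops):
                    f += 1.0 / (1.0 + math.exp(-(alpha[l] + beta[j])))
                sfst[l] += f / n_pops
            for j in range(n_pops):
                sbeta[j] += beta[j]


# ---------------------------------------------------------------------------
# chain orchestration
# ---------------------------------------------------------------------------


def _locus_key(snp_id: str) -> int:
    """Stable 64-bit stream key from a marker name."""
    return int.from_bytes(hashlib.sha256(snp_id.encode()).digest()[:8], "little")


def _is_monomorphic(a_row: np.ndarray, n_row: np.ndarray) -> bool:
    """No differentiation information: zero calls, or one allele everywhere."""
    n_tot = int(n_row.sum())
    a_tot = int(a_row.sum())
    return n_tot == 0 or a_tot == 0 or a_tot == n_tot


class _ChainState:
    """Mutable state and draw streams for one pair scan."""

    def __init__(self, a: np.ndarray, n: np.ndarray, keys: list[int], config: MCMCConfig):
        L = a.shape[0]
        self.a = a.astype(np.float64)
        self.n = n.astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            p0 = (a.sum(axis=1) + 1.0) / (n.sum(axis=1) + 2.0)
        self.p = np.clip(p0, 0.02, 0.98)
        self.alpha = np.zeros(L)
        self.delta = np.ones(L, dtype=np.uint8)
        self.beta = np.full(2, config.beta_prior_mean)
        self.scratch = np.zeros(L)
        self.wp = np.full(L, 0.6)
        self.wa = np.full(L, 0.6)
        self.wb = np.full(2, 0.2)
        self.rjm = np.zeros(L)
        self.rjs = np.full(L, config.alpha_prior_sd)
        self.asum = np.zeros(L)
        self.asumsq = np.zeros(L)
        self.acnt = np.zeros(L)
        self.sdelta = np.zeros(L)
        self.salpha = np.zeros(L)
        self.sfst = np.zeros(L)
        self.sbeta = np.zeros(2)
        self.config = config
        # per-locus streams keyed by (seed, marker hash); one shared
        # pair-level stream for the population effects
        self.locus_rngs = [
            np.random.Generator(np.random.PCG64(np.random.SeedSequence((config.seed, k))))
            for k in keys
        ]
        self.beta_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((config.seed, 0x9E3779B9)))
        )
        self.ll = np.zeros((L, 2))
        for l in range(L):
            for j in range(2):
                self.ll[l, j] = _cell_ll(
                    self.a[l, j], self.n[l, j], self.p[l],
                    self.alpha[l] + self.beta[j],
                )
        self._counters_reset()

    def _counters_reset(self) -> None:
        L = len(self.p)
        self.accp = np.zeros(L, dtype=np.int64)
        self.atta = np.zeros(L, dtype=np.int64)
        self.acca = np.zeros(L, dtype=np.int64)
        self.attr = np.zeros(L, dtype=np.int64)
        self.accr = np.zeros(L, dtype=np.int64)
        self.accb = np.zeros(2, dtype=np.int64)
        self.sweeps_in_phase = 0

    def run(self, n_sweeps: int, accum_every: int = 0, block: int = 2048) -> None:
        cfg = self.config
        L = len(self.p)
        done = 0
        while done < n_sweeps:
            B = min(block, n_sweeps - done)
            zp = np.empty((B, L))
            up = np.empty((B, L))
            za = np.empty((B, L))
            ua = np.empty((B, L))
            zr = np.empty((B, L))
            ur = np.empty((B, L))
            for l, g in enumerate(self.locus_rngs):
                z = g.standard_normal((B, 3))
                u = g.random((B, 3))
                zp[:, l] = z[:, 0]
                za[:, l] = z[:, 1]
                zr[:, l] = z[:, 2]
                up[:, l] = u[:, 0]
                ua[:, l] = u[:, 1]
                ur[:, l] = u[:, 2]
            zb = self.beta_rng.standard_normal((B, 2))
            ub = self.beta_rng.random((B, 2))
            _run_block(
                self.a, self.n, self.p, self.alpha, self.delta, self.beta,
                self.ll, self.scratch,
                self.wp, self.wa, self.wb, self.rjm, self.rjs,
                cfg.alpha_prior_sd, cfg.beta_prior_mean, cfg.beta_prior_sd,
                -math.log(cfg.prior_odds),
                zp, up, za, ua, zr, ur, zb, ub,
                self.accp, self.atta, self.acca, self.attr, self.accr,
                self.accb,
                self.asum, self.asumsq, self.acnt,
                accum_every, self.sdelta, self.salpha, self.sfst, self.sbeta,
            )
            done += B
            self.sweeps_in_phase += B

    def adapt(self) -> None:
        """Rescale proposal widths toward acceptance in [0.25, 0.45] and
        refresh the reversible-jump proposal from pilot alpha moments."""
        n = max(self.sweeps_in_phase, 1)
        rp = self.accp / n
        self.wp *= np.where(rp < 0.25, 0.7, np.where(rp > 0.45, 1.4, 1.0))
        ra = self.acca / np.maximum(self.atta, 1)
        considered = self.atta >= 20
        self.wa *= np.where(
            considered & (ra < 0.25), 0.7,
            np.where(considered & (ra > 0.45), 1.4, 1.0),
        )
        rb = self.accb / n
        self.wb *= np.where(rb < 0.25, 0.7, np.where(rb > 0.45, 1.4, 1.0))
        self.wp = np.clip(self.wp, 1e-3, 10.0)
        self.wa = np.clip(self.wa, 1e-3, 10.0)
        self.wb = np.clip(self.wb, 1e-4, 10.0)
        enough = self.acnt >= 20
        m = np.where(enough, self.asum / np.maximum(self.acnt, 1), 0.0)
        var = np.where(
            enough,
            self.asumsq / np.maximum(self.acnt, 1) - m * m,
            self.config.alpha_prior_sd**2,
        )
        self.rjm = m
        self.rjs = np.clip(np.sqrt(np.maximum(var, 0.0)), 0.15, 3.0)
        self._counters_reset()

    def acceptance_summary(self) -> dict[str, float]:
        n = max(self.sweeps_in_phase, 1)
        return {
            "p": float(self.accp.mean() / n),
            "alpha": float(self.acca.sum() / max(self.atta.sum(), 1)),
            "rj": float(self.accr.sum() / max(self.attr.sum(), 1)),
            "beta": float(self.accb.mean() / n),
        }


def compute_q_values(peps: "np.ndarray | list[float]") -> np.ndarray:
    """q-values from posterior error probabilities.

    Sorted ascending, the q-value at rank k is the running mean of the k
    smallest PEPs (the minimum FDR incurred by calling the top k loci
    significant); tied PEPs share the q of their last tied rank.  Values
    are returned in the original input order.
    """
    peps = np.asarray(peps, dtype=float)
    if peps.size == 0:
        return np.empty(0)
    if ((peps < 0) | (peps > 1)).any():
        raise ValueError("PEPs must lie in [0, 1]")
    order = np.argsort(peps, kind="stable")
    sorted_peps = peps[order]
    ranks = np.arange(1, peps.size + 1)
    q_sorted = np.cumsum(sorted_peps) / ranks
    # ties share the q of the last tied rank: walk runs from the back
    q_tied = q_sorted.copy()
    i = peps.size - 1
    while i >= 0:
        j = i
        while j > 0 and sorted_peps[j - 1] == sorted_peps[i]:
            j -= 1
        q_tied[j : i + 1] = q_sorted[i]
        i = j - 1
    out = np.empty_like(q_tied)
    out[order] = q_tied
    return out


def significant_loci(
    posteriors: list[LocusPosterior], q_threshold: float = 0.05
) -> set[str]:
    """Markers whose q-value is strictly below the threshold."""
    return {lp.snp_id for lp in posteriors if lp.q_value < q_threshold}


def run_mcmc(counts: AlleleCountTable, config: MCMCConfig | None = None) -> list[LocusPosterior]:
    """Scan one population pair; returns one :class:`LocusPosterior` per locus.

    Loci with no called alleles, or carrying a single allele across both
    populations, hold no differentiation information and are reported with
    gamma 0 and PEP 1 without entering the sampler.
    """
    config = config or MCMCConfig()
    if len(counts.populations) != 2:
        raise ValueError("run_mcmc requires exactly 2 populations")
    L = counts.n_loci
    if L == 0:
        return []

    poly = np.array(
        [not _is_monomorphic(counts.a[l], counts.n[l]) for l in range(L)]
    )
    snp_ids = [loc.snp_id for loc in counts.loci]
    keys = np.array([_locus_key(s) for s in snp_ids], dtype=np.uint64)

    gamma = np.zeros(L)
    alpha_mean = np.zeros(L)
    fst_mean = np.full(L, np.nan)

    idx = np.flatnonzero(poly)
    if idx.size:
        # canonical stream-key order makes results independent of input order
        idx = idx[np.argsort(keys[idx], kind="stable")]
        a_sub = counts.a[idx]
        n_sub = counts.n[idx]
        chain = _ChainState(a_sub, n_sub, [int(keys[i]) for i in idx], config)
        for _ in range(config.n_pilot):
            chain.run(config.pilot_length)
            chain.adapt()
        chain.run(config.burn_in)
        chain._counters_reset()
        chain.run(config.n_samples * config.thinning, accum_every=config.thinning)
        acc = chain.acceptance_summary()
        for name, rate in acc.items():
            if not (0.01 < rate < 0.9) and name != "rj":
                logger.warning(
                    "acceptance rate for %s updates is %.3f (outside (0.01, 0.9))",
                    name,
                    rate,
                )
        n_kept = config.n_samples
        gamma[idx] = chain.sdelta / n_kept
        alpha_mean[idx] = chain.salpha / n_kept
        fst_mean[idx] = chain.sfst / n_kept
        if not np.isfinite(chain.ll).all():
            bad = int(np.flatnonzero(~np.isfinite(chain.ll).all(axis=1))[0])
            raise RuntimeError(f"non-finite log-likelihood at locus index {bad}")
        run_mcmc.last_beta_mean = chain.sbeta / n_kept  # diagnostics hook

    pep = 1.0 - gamma
    qvals = compute_q_values(pep)
    # uninformative loci are never significant at any threshold
    qvals[~poly] = 1.0
    return [
        LocusPosterior(
            snp_id=snp_ids[l],
            gamma=float(gamma[l]),
            pep=float(pep[l]),
            q_value=float(qvals[l]),
            alpha_mean=float(alpha_mean[l]),
            fst_mean=float(fst_mean[l]),
        )
        for l in range(L)
    ]


def write_posteriors(posteriors: list[LocusPosterior], path) -> None:
    """TSV with one row per locus: snp_id, gamma, pep, q_value, alpha_mean, fst_mean."""
    with open(path, "wt") as fh:
        fh.write("snp_id\tgamma\tpep\tq_value\talpha_mean\tfst_mean\n")
        for lp in posteriors:
            fh.write(
                f"{lp.snp_id}\t{lp.gamma:.17g}\t{lp.pep:.17g}\t{lp.q_value:.17g}"
                f"\t{lp.alpha_mean:.17g}\t{lp.fst_mean:.17g}\n"
            )


def read_posteriors(path) -> list[LocusPosterior]:
    out: list[LocusPosterior] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("snp_id"):
            raise ValueError(f"{path}: not a posterior TSV")
        for line in fh:
            s, g, pep, q, am, fm = line.rstrip("\n").split("\t")
            out.append(
                LocusPosterior(
                    snp_id=s, gamma=float(g), pep=float(pep), q_value=float(q),
                    alpha_mean=float(am), fst_mean=float(fm),
                )
            )
    return out
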