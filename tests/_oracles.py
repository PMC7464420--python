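"""Independent brute-force oracles used to validate the implementation.

Each oracle computes its quantity by a route unrelated to the package's
own code path: dense numerical quadrature for the F-model posterior, a
base-pair bitmap for interval unions, and all-pairs scans for overlap and
q-value checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import betaln


def _bb_logpmf(a, n, p, x):
    """Beta-binomial log-pmf (no binomial coefficient) at logit-F_ST ``x``."""
    theta = np.exp(-np.clip(x, -25, 25))
    tp = theta * p
    tq = theta - tp
    return betaln(a + tp, n - a + tq) - betaln(tp, tq)


def grid_posterior(
    a: np.ndarray,
    n: np.ndarray,
    alpha_sd: float = 1.0,
    beta_mean: float = -1.0,
    beta_sd: float = 1.8,
    prior_odds: float = 10.0,
    nb: int = 61,
    na: int = 41,
    np_nodes: int = 48,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact posterior inclusion probabilities and posterior mean population
    effects by dense quadrature over (alpha, beta_1, beta_2, p) for every
    inclusion configuration.  Tractable for <= 3 loci, 2 populations."""
    L = a.shape[0]
    bgrid = np.linspace(beta_mean - 6 * beta_sd, beta_mean + 6 * beta_sd, nb)
    wb = np.gradient(bgrid)
    agrid = np.linspace(-5 * alpha_sd, 5 * alpha_sd, na)
    wa = np.gradient(agrid)
    xg, wg = leggauss(np_nodes)
    pg = 0.5 * (xg + 1.0)
    wp = 0.5 * wg
    phi_b = np.exp(-0.5 * ((bgrid - beta_mean) / beta_sd) ** 2) / (
        np.sqrt(2 * np.pi) * beta_sd
    )
    phi_a = np.exp(-0.5 * (agrid / alpha_sd) ** 2) / (np.sqrt(2 * np.pi) * alpha_sd)
    pi1 = 1.0 / (1.0 + prior_odds)
    pi0 = 1.0 - pi1

    m0 = np.empty((L, nb, nb))
    m1 = np.empty((L, nb, nb))
    for i in range(L):
        ll1 = _bb_logpmf(
            a[i, 0], n[i, 0], pg[None, None, :], agrid[:, None, None] + bgrid[None, :, None]
        )
        ll2 = _bb_logpmf(
            a[i, 1], n[i, 1], pg[None, None, :], agrid[:, None, None] + bgrid[None, :, None]
        )
        joint = np.einsum("abp,acp,p->abc", np.exp(ll1), np.exp(ll2), wp)
        m1[i] = np.einsum("abc,a->bc", joint, phi_a * wa)
        l01 = _bb_logpmf(a[i, 0], n[i, 0], pg[None, :], bgrid[:, None])
        l02 = _bb_logpmf(a[i, 1], n[i, 1], pg[None, :], bgrid[:, None])
        m0[i] = np.einsum("bp,cp,p->bc", np.exp(l01), np.exp(l02), wp)

    wB = np.einsum("b,c->bc", phi_b * wb, phi_b * wb)
    gamma = np.zeros(L)
    beta_num = np.zeros(2)
    total = 0.0
    for config in itertools.product([0, 1], repeat=L):
        prod = np.ones((nb, nb))
        prior = 1.0
        for i, d in enumerate(config):
            prod = prod * (m1[i] if d else m0[i])
            prior *= pi1 if d else pi0
        weighted = prior * prod * wB
        ev = float(weighted.sum())
        total += ev
        beta_num[0] += float((weighted.sum(axis=1) * bgrid).sum())
        beta_num[1] += float((weighted.sum(axis=0) * bgrid).sum())
        for i, d in enumerate(config):
            if d:
                gamma[i] += ev
    return gamma / total, beta_num / total


def qvalues_bruteforce(peps: np.ndarray) -> np.ndarray:
    """Spreadsheet-style q-values: for each locus, the minimum over all
    cutoffs that include it of the mean PEP among included loci."""
    peps = np.asarray(peps, dtype=float)
    out = np.empty_like(peps)
    for i, pep_i in enumerate(peps):
        qs = []
        for cutoff in np.unique(peps):
            if pep_i <= cutoff:
                included = peps[peps <= cutoff]
                qs.append(included.mean())
        out[i] = min(qs)
    return out


def merge_bitmap(intervals: list[tuple[int, int]], size: int) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals via an explicit base-pair bitmap."""
    bits = np.zeros(size + 2, dtype=bool)
    for s, e in intervals:
        bits[s : e + 1] = True
    # book-ended intervals are contiguous runs of bits, so a plain run scan
    # reproduces the adjacency-merging semantics
    out = []
    i = 1
    while i <= size:
        if bits[i]:
            j = i
            while j + 1 <= size and bits[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def overlaps_quadratic(regions, genes):
    """All-pairs overlap on 1-based inclusive coordinates."""
    out = []
    for r in regions:
        hits = [
            g
            for g in genes
            if g.chrom == r.chrom and g.start_bp <= r.end_bp and r.start_bp <= g.end_bp
        ]
        hits.sort(key=lambda g: (g.start_bp, g.end_bp, g.symbol))
        out.append([g.symbol for g in hits])
    return out
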