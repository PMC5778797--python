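"""hapFLK: haplotype-cluster differentiation scan.

Local haplotype structure is summarized by the Scheet–Stephens cluster
model: each haplotype is a mosaic of K latent clusters following a hidden
Markov chain along the chromosome.  Cluster k has an allele-B frequency
theta[k, s] at SNP s; between consecutive SNPs the chain jumps with
probability rho[s] and, on a jump, re-draws the cluster from the local
weights alpha[:, s].  Fitting is by EM with forward–backward E-steps, on
phased haplotypes (haploid chain) or unphased genotypes (diploid chain over
cluster pairs).

hapFLK is the FLK quadratic form applied to the population cluster
frequencies at each SNP, with the singular cluster-simplex covariance
handled by a Moore–Penrose pseudoinverse.  Because the statistic's null
distribution depends on the fitted cluster model, p-values are obtained by
fitting a scaled chi-squared distribution to the genome-wide empirical
distribution of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeTable, fdr_qvalues
from .popstruct import KinshipF

THETA_FLOOR = 1e-4
ALPHA_FLOOR = 1e-6
RHO_FLOOR = 1e-6


@dataclass
class ClusterModel:
    """Fitted haplotype-cluster HMM parameters.

    theta: (K, S) cluster allele-B frequencies, floored away from {0, 1}.
    alpha: (K, S) cluster weights, a simplex over K at each SNP; column 0
        doubles as the initial state distribution.
    rho: (S,) jump probability between SNP s-1 and s; rho[0] is unused.
    """

    theta: np.ndarray
    alpha: np.ndarray
    rho: np.ndarray
    log_likelihoods: list[float]

    @property
    def K(self) -> int:
        return self.theta.shape[0]

    @property
    def n_snps(self) -> int:
        return self.theta.shape[1]

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihoods[-1]


def _as_haplotypes(data) -> np.ndarray:
    h = np.asarray(data)
    if h.ndim != 2:
        raise ValueError("haplotypes must be a 2-d array")
    return h


# ---------------------------------------------------------------------------
# haploid chain
# ---------------------------------------------------------------------------


def _haploid_emissions(h: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(n, K, S) emission probabilities; missing observations emit 1."""
    ht = h[:, None, :]
    return np.where(ht == 1, theta[None, :, :],
                    np.where(ht == 0, 1 - theta[None, :, :], 1.0))


try:  # JIT-compiled forward/backward; the pure-numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn

        return deco


@_njit(cache=False)
def _haploid_fb_kernel(h, thetaT, alphaT, rho):  # pragma: no cover - via wrapper
    """Fused forward-backward for the haploid chain.

    Layout (n, S, K) keeps the cluster axis contiguous; emissions are
    computed on the fly and the M-step sufficient statistics (expected
    allele counts, jump landings, jump totals) are accumulated in place so
    no (n, K, S) temporaries other than gamma are materialized.
    Returns (loglik, gamma, num, den, land, tot_jump).
    """
    n, S = h.shape
    K = thetaT.shape[1]
    gamma = np.empty((n, S, K))
    f = np.empty((S, K))
    b = np.empty(K)
    bnext = np.empty(K)
    c = np.empty(S)
    num = np.zeros((S, K))
    den = np.zeros((S, K))
    land = np.zeros((S, K))
    tot_jump = np.zeros(S)
    loglik = 0.0
    for i in range(n):
        # forward
        tot = 0.0
        for k in range(K):
            th = thetaT[0, k]
            hv = h[i, 0]
            e = th if hv == 1 else (1.0 - th if hv == 0 else 1.0)
            v = alphaT[0, k] * e
            f[0, k] = v
            tot += v
        c[0] = tot
        inv = 1.0 / tot
        for k in range(K):
            f[0, k] *= inv
        for s in range(1, S):
            r = rho[s]
            tot = 0.0
            for k in range(K):
                th = thetaT[s, k]
                hv = h[i, s]
                e = th if hv == 1 else (1.0 - th if hv == 0 else 1.0)
                v = ((1.0 - r) * f[s - 1, k] + r * alphaT[s, k]) * e
                f[s, k] = v
                tot += v
            c[s] = tot
            inv = 1.0 / tot
            for k in range(K):
                f[s, k] *= inv
            loglik += np.log(tot)
        loglik += np.log(c[0])
        # backward, accumulating gamma and jump statistics
        for k in range(K):
            b[k] = 1.0
        for s in range(S - 1, 0, -1):
            r = rho[s]
            cinv = 1.0 / c[s]
            hv = h[i, s]
            # gamma at s
            gtot = 0.0
            for k in range(K):
                g = f[s, k] * b[k]
                gamma[i, s, k] = g
                gtot += g
            ginv = 1.0 / gtot
            for k in range(K):
                gamma[i, s, k] *= ginv
            if hv == 0 or hv == 1:
                for k in range(K):
                    den[s, k] += gamma[i, s, k]
                    if hv == 1:
                        num[s, k] += gamma[i, s, k]
            # jump posteriors and next backward message
            mix = 0.0
            for k in range(K):
                th = thetaT[s, k]
                e = th if hv == 1 else (1.0 - th if hv == 0 else 1.0)
                eb = e * b[k]
                bnext[k] = eb  # reuse as e*b buffer
                mix += eb * alphaT[s, k]
            tj = 0.0
            for k in range(K):
                jp = r * alphaT[s, k] * bnext[k] * cinv
                land[s, k] += jp
                tj += jp
                b[k] = ((1.0 - r) * bnext[k] + r * mix) * cinv
            tot_jump[s] += tj
        # s = 0
        gtot = 0.0
        for k in range(K):
            g = f[0, k] * b[k]
            gamma[i, 0, k] = g
            gtot += g
        ginv = 1.0 / gtot
        hv = h[i, 0]
        for k in range(K):
            gamma[i, 0, k] *= ginv
        if hv == 0 or hv == 1:
            for k in range(K):
                den[0, k] += gamma[i, 0, k]
                if hv == 1:
                    num[0, k] += gamma[i, 0, k]
    return loglik, gamma, num, den, land, tot_jump


def _haploid_e_step(h, theta, alpha, rho):
    """Forward–backward over all haplotypes at once.

    Returns (loglik, gamma (n,K,S), jump (n,K,S)) with jump[n,k,s] the
    posterior probability that the chain jumped between s-1 and s and landed
    in cluster k (jump[:, :, 0] is zero).  Kept as the readable reference
    path; the EM driver uses the fused kernel via _haploid_em_pass.
    """
    n, S = h.shape
    K = theta.shape[0]
    e = _haploid_emissions(h, theta)
    f = np.empty((n, K, S))
    c = np.empty((n, S))
    fs = alpha[:, 0][None, :] * e[:, :, 0]
    c[:, 0] = fs.sum(axis=1)
    f[:, :, 0] = fs / c[:, 0][:, None]
    for s in range(1, S):
        pred = (1 - rho[s]) * f[:, :, s - 1] + rho[s] * alpha[:, s][None, :]
        fs = pred * e[:, :, s]
        c[:, s] = fs.sum(axis=1)
        f[:, :, s] = fs / c[:, s][:, None]
    b = np.empty((n, K, S))
    b[:, :, S - 1] = 1.0
    for s in range(S - 1, 0, -1):
        eb = e[:, :, s] * b[:, :, s]
        b[:, :, s - 1] = ((1 - rho[s]) * eb + rho[s] * (eb * alpha[:, s][None, :]).sum(
            axis=1, keepdims=True)) / c[:, s][:, None]
    gamma = f * b
    gamma /= gamma.sum(axis=1, keepdims=True)
    jump = np.zeros((n, K, S))
    for s in range(1, S):
        jump[:, :, s] = rho[s] * alpha[:, s][None, :] * e[:, :, s] * b[:, :, s] / c[
            :, s][:, None]
    loglik = float(np.log(c).sum())
    return loglik, gamma, jump


def _haploid_em_pass(h, theta, alpha, rho):
    """One fused E-step returning the M-step sufficient statistics.

    Returns (loglik, gamma (n,K,S), num, den (K,S expected B-allele counts /
    totals), land (K,S jump landings), tot_jump (S,)).
    """
    h8 = np.ascontiguousarray(h, dtype=np.int8)
    loglik, gamma, num, den, land, tot = _haploid_fb_kernel(
        h8,
        np.ascontiguousarray(theta.T),
        np.ascontiguousarray(alpha.T),
        np.ascontiguousarray(rho),
    )
    return float(loglik), gamma.transpose(0, 2, 1), num.T, den.T, land.T, tot


def _haploid_m_step(h, gamma, jump, theta_prev):
    n, K, S = gamma.shape
    obs = (h != MISSING) & (h >= 0)
    x = np.where(obs, h, 0).astype(float)
    num = np.einsum("nks,ns->ks", gamma, x * obs)
    den = np.einsum("nks,ns->ks", gamma, obs.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den > 0, num / den, theta_prev)
    theta = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
    total_jumps = jump.sum(axis=(0, 1))  # (S,)
    rho = np.clip(total_jumps / n, RHO_FLOOR, 1 - RHO_FLOOR)
    rho[0] = 1.0
    alpha = np.empty((K, S))
    land = jump.sum(axis=0)  # (K, S)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(total_jumps[None, :] > 0, land / total_jumps[None, :],
                         1.0 / K)
    alpha[:, 0] = gamma[:, :, 0].mean(axis=0)
    alpha = np.clip(alpha, ALPHA_FLOOR, None)
    alpha /= alpha.sum(axis=0, keepdims=True)
    return theta, alpha, rho


# ---------------------------------------------------------------------------
# diploid chain (unphased genotypes)
# ---------------------------------------------------------------------------


def _diploid_emissions(g, theta, s):
    """(n, K, K) emission matrix at SNP s for genotypes g[:, s]."""
    t = theta[:, s]
    gaa = np.outer(1 - t, 1 - t)
    gab = np.outer(t, 1 - t) + np.outer(1 - t, t)
    gbb = np.outer(t, t)
    n = g.shape[0]
    E = np.ones((n, theta.shape[0], theta.shape[0]))
    gs = g[:, s]
    E[gs == 0] = gaa
    E[gs == 1] = gab
    E[gs == 2] = gbb
    return E


def _diploid_e_step(g, theta, alpha, rho):
    """Forward–backward on ordered cluster pairs, factorized transitions."""
    n, S = g.shape
    K = theta.shape[0]
    f = np.empty((n, K, K, S))
    c = np.empty((n, S))
    a0 = alpha[:, 0]
    E = _diploid_emissions(g, theta, 0)
    fs = a0[None, :, None] * a0[None, None, :] * E
    c[:, 0] = fs.sum(axis=(1, 2))
    f[:, :, :, 0] = fs / c[:, 0][:, None, None]
    for s in range(1, S):
        T = (1 - rho[s]) * np.eye(K) + rho[s] * np.ones((K, 1)) @ alpha[:, s][None, :]
        pred = np.einsum("ab,nac,cd->nbd", T, f[:, :, :, s - 1], T)
        E = _diploid_emissions(g, theta, s)
        fs = pred * E
        c[:, s] = fs.sum(axis=(1, 2))
        f[:, :, :, s] = fs / c[:, s][:, None, None]
    b = np.empty((n, K, K, S))
    b[:, :, :, S - 1] = 1.0
    jump1 = np.zeros((n, K, K, S))
    jump2 = np.zeros((n, K, K, S))
    for s in range(S - 1, 0, -1):
        T = (1 - rho[s]) * np.eye(K) + rho[s] * np.ones((K, 1)) @ alpha[:, s][None, :]
        E = _diploid_emissions(g, theta, s)
        eb = E * b[:, :, :, s]
        b[:, :, :, s - 1] = np.einsum("ab,nbd,cd->nac", T, eb, T) / c[:, s][:, None, None]
        # chain-1 jump: lands in a with prob rho*alpha_a, chain 2 moves by T
        fprev = f[:, :, :, s - 1]
        fcol = fprev.sum(axis=1)  # (n, K) marginal of chain 2
        m2 = fcol @ T  # (n, K)
        jump1[:, :, :, s] = (rho[s] * alpha[:, s][None, :, None]
                             * m2[:, None, :] * eb) / c[:, s][:, None, None]
        frow = fprev.sum(axis=2)
        m1 = frow @ T
        jump2[:, :, :, s] = (rho[s] * alpha[:, s][None, None, :]
                             * m1[:, :, None] * eb) / c[:, s][:, None, None]
    gamma = f * b
    gamma /= gamma.sum(axis=(1, 2), keepdims=True)
    loglik = float(np.log(c).sum())
    return loglik, gamma, jump1, jump2


def _diploid_m_step(g, theta_prev, gamma, jump1, jump2):
    n, K, _, S = gamma.shape
    theta = np.empty((K, S))
    num = np.zeros((K, S))
    den = np.zeros((K, S))
    for s in range(S):
        gs = g[:, s]
        G = gamma[:, :, :, s]
        obs = (gs == 0) | (gs == 1) | (gs == 2)
        Go = G[obs]
        row = Go.sum(axis=2)  # allele carried by chain-1 cluster
        col = Go.sum(axis=1)
        den[:, s] = row.sum(axis=0) + col.sum(axis=0)
        gso = gs[obs]
        t = theta_prev[:, s]
        # expected B alleles per cluster
        hom = gso == 2
        num[:, s] += row[hom].sum(axis=0) + col[hom].sum(axis=0)
        het = gso == 1
        if het.any():
            # share of the single B allele between the two cluster chains
            pa = np.outer(t, 1 - t)
            pb = np.outer(1 - t, t)
            with np.errstate(invalid="ignore", divide="ignore"):
                share1 = np.where(pa + pb > 0, pa / (pa + pb), 0.5)
            Gh = G[obs][het]
            num[:, s] += np.einsum("nab,ab->a", Gh, share1)
            num[:, s] += np.einsum("nab,ab->b", Gh, 1 - share1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den > 0, num / den, theta_prev)
    theta = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
    total = jump1.sum(axis=(0, 1, 2)) + jump2.sum(axis=(0, 1, 2))
    rho = np.clip(total / (2 * n), RHO_FLOOR, 1 - RHO_FLOOR)
    rho[0] = 1.0
    land = jump1.sum(axis=(0, 2)) + jump2.sum(axis=(0, 1))  # (K, S)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(total[None, :] > 0, land / total[None, :], 1.0 / K)
    alpha[:, 0] = (gamma[:, :, :, 0].sum(axis=2)
                   + gamma[:, :, :, 0].sum(axis=1)).mean(axis=0) / 2
    alpha = np.clip(alpha, ALPHA_FLOOR, None)
    alpha /= alpha.sum(axis=0, keepdims=True)
    return theta, alpha, rho


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def fit_cluster_model(
    data,
    K: int,
    n_iter: int = 50,
    seed: int = 0,
    phased: bool | None = None,
    tol: float = 1e-6,
    n_restarts: int = 5,
    restart_iter: int = 10,
    init: str = "anchor",
) -> ClusterModel:
    """Fit the cluster HMM by EM.

    ``data`` is either phased haplotypes (values 0/1, one row per haplotype)
    or unphased genotypes (0/1/2/MISSING, one row per individual); set
    ``phased`` explicitly or it is inferred from the value range.  EM is
    sensitive to initialization, so ``n_restarts`` short runs of
    ``restart_iter`` iterations are raced and the best log-likelihood is
    continued for the full ``n_iter``.  The observed-data log-likelihood is
    checked to be non-decreasing at every iteration (within ``tol``), as EM
    guarantees.
    """
    if n_restarts > 1:
        rng0 = np.random.default_rng(seed)
        # candidate inits: a k-means partition of the sequences (usually the
        # right basin) raced against random-anchor starts; best short-run
        # log-likelihood is continued for the full fit
        cands: list[tuple[int, str]] = [(int(rng0.integers(2**31 - 1)), "kmeans")]
        cands += [(int(rng0.integers(2**31 - 1)), "anchor")
                  for _ in range(n_restarts - 1)]
        short = [
            fit_cluster_model(data, K, n_iter=restart_iter, seed=s,
                              phased=phased, tol=tol, n_restarts=1,
                              init=kind)
            for s, kind in cands
        ]
        s_best, kind_best = cands[int(np.argmax([m.log_likelihood for m in short]))]
        return fit_cluster_model(data, K, n_iter=n_iter, seed=s_best,
                                 phased=phased, tol=tol, n_restarts=1,
                                 init=kind_best)
    x = _as_haplotypes(data)
    if K < 1:
        raise ValueError("K must be >= 1")
    if x.shape[0] < 2:
        raise ValueError("need at least two sequences")
    if K > x.shape[0]:
        import warnings

        warnings.warn(f"K={K} exceeds the number of sequences", stacklevel=2)
    if phased is None:
        phased = not np.any(x == 2)
    n, S = x.shape
    rng = np.random.default_rng(seed)

    obs = (x != MISSING) & (x >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        base = np.where(obs, x, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    if not phased:
        base = base / 2
    alpha = np.full((K, S), 1.0 / K)
    if init == "kmeans" and K > 1 and n > K:
        # partition the sequences; each cluster starts at its group mean
        from sklearn.cluster import KMeans

        filled = np.where(obs, x / (1.0 if phased else 2.0), base[None, :])
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2**31 - 1))).fit(filled)
        theta = np.empty((K, S))
        sizes = np.zeros(K)
        for k in range(K):
            members = km.labels_ == k
            sizes[k] = members.sum()
            theta[k] = filled[members].mean(axis=0) if members.any() else base
        theta = np.clip(0.9 * theta + 0.1 * base[None, :],
                        THETA_FLOOR, 1 - THETA_FLOOR)
        w = np.clip(sizes / n, ALPHA_FLOOR, None)
        alpha = np.tile((w / w.sum())[:, None], (1, S))
    else:
        # anchor each cluster on a randomly chosen observed sequence,
        # smoothed toward the mean frequency (keeps EM from collapsing)
        picks = rng.choice(n, size=K, replace=K > n)
        anchor = np.where(obs[picks], x[picks] / (1.0 if phased else 2.0),
                          base[None, :])
        theta = np.clip(0.7 * anchor + 0.3 * base[None, :]
                        + rng.uniform(-0.05, 0.05, size=(K, S)),
                        THETA_FLOOR, 1 - THETA_FLOOR)
    rho = np.full(S, 0.05)
    rho[0] = 1.0

    if K == 1:
        # no hidden structure: theta is the observed frequency, closed form
        denom = np.maximum(obs.sum(axis=0), 1) * (1 if phased else 2)
        theta = (np.where(obs, x, 0).sum(axis=0) / denom)[None, :]
        theta = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
        if phased:
            ll = float(np.where(obs, np.where(x == 1, np.log(theta), np.log(1 - theta)), 0.0).sum())
        else:
            t = theta[0]
            logp = {0: np.log((1 - t) ** 2), 1: np.log(2 * t * (1 - t)), 2: np.log(t**2)}
            ll = float(sum(np.where(obs & (x == gval), lp[None, :], 0.0).sum()
                           for gval, lp in logp.items()))
        return ClusterModel(theta, np.ones((1, S)), rho, [ll])

    logliks: list[float] = []
    for it in range(n_iter):
        if phased:
            ll, gamma, num, den, land, tot = _haploid_em_pass(x, theta, alpha, rho)
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = np.where(den > 0, num / den, theta)
            theta = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
            rho = np.clip(tot / n, RHO_FLOOR, 1 - RHO_FLOOR)
            rho[0] = 1.0
            with np.errstate(invalid="ignore", divide="ignore"):
                alpha = np.where(tot[None, :] > 0, land / tot[None, :], 1.0 / K)
            alpha[:, 0] = gamma[:, :, 0].mean(axis=0)
            alpha = np.clip(alpha, ALPHA_FLOOR, None)
            alpha /= alpha.sum(axis=0, keepdims=True)
        else:
            ll, gamma, j1, j2 = _diploid_e_step(x, theta, alpha, rho)
            theta, alpha, rho = _diploid_m_step(x, theta, gamma, j1, j2)
        if logliks and ll < logliks[-1] - tol * max(1.0, abs(logliks[-1])):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{logliks[-1]:.6f} -> {ll:.6f}"
            )
        logliks.append(ll)
    return ClusterModel(theta, alpha, rho, logliks)


def cluster_frequencies(
    model: ClusterModel, data, populations: list[str]
) -> tuple[list[str], np.ndarray]:
    """Population cluster frequencies q[pop, k, s] from posterior memberships.

    ``populations`` gives one label per row of ``data`` (haplotype or
    individual).  For the diploid chain each individual contributes its two
    chains' marginal memberships, averaged.
    """
    x = _as_haplotypes(data)
    if len(populations) != x.shape[0]:
        raise ValueError("one population label per sequence required")
    phased = not np.any(x == 2)
    if phased:
        _, gamma, *_ = _haploid_em_pass(x, model.theta, model.alpha, model.rho)
        member = gamma  # (n, K, S)
    else:
        _, gamma, _, _ = _diploid_e_step(x, model.theta, model.alpha, model.rho)
        member = (gamma.sum(axis=2) + gamma.sum(axis=1)) / 2
    pops = list(dict.fromkeys(populations))
    q = np.empty((len(pops), model.K, model.n_snps))
    for i, p in enumerate(pops):
        ix = [j for j, l in enumerate(populations) if l == p]
        if not ix:
            raise ValueError(f"population {p!r} has no sequences")
        q[i] = member[ix].mean(axis=0)
    return pops, q


# ---------------------------------------------------------------------------
# hapFLK statistic
# ---------------------------------------------------------------------------


def hapflk_statistic(q: np.ndarray, F: KinshipF | np.ndarray,
                     rcond: float = 1e-2) -> np.ndarray:
    """Per-SNP hapFLK: FLK quadratic form on cluster frequencies.

    ``q`` has shape (n_pops, K, S).  At each SNP the centered cluster
    frequency matrix C = q - 1 q0' (q0 the F-weighted ancestral cluster
    frequencies) is scored against the Kronecker covariance
    F x (diag(q0) - q0 q0'), the singular cluster part handled with the
    Moore–Penrose pseudoinverse.

    ``rcond`` is the relative eigenvalue cutoff of that pseudoinverse.  The
    drift covariance of a cluster with near-zero local frequency is itself
    near zero, while the estimated frequency still carries finite-sample
    noise, so near-null covariance directions turn into wild outliers if
    inverted; dropping eigenvalues below ``rcond`` x the largest removes
    exactly those directions (clusters below about 1% local weight).
    """
    Fm = F.values if isinstance(F, KinshipF) else np.asarray(F, dtype=float)
    P, K, S = q.shape
    if Fm.shape[0] != P:
        raise ValueError("q and F disagree on the number of populations")
    if P < 2:
        raise ValueError("hapFLK needs at least two populations")
    Fi = np.linalg.inv(Fm + 1e-12 * np.eye(P))
    w = Fi.sum(axis=0) / Fi.sum()
    stat = np.empty(S)
    for s in range(S):
        qs = q[:, :, s]
        q0 = w @ qs
        B = np.diag(q0) - np.outer(q0, q0)
        Bp = np.linalg.pinv(B, rcond=rcond, hermitian=True)
        C = qs - q0[None, :]
        stat[s] = float(np.einsum("pk,pr,rl,lk->", C, Fi, C, Bp))
    return stat


# ---------------------------------------------------------------------------
# empirical chi-squared recalibration
# ---------------------------------------------------------------------------


def fit_scaled_chi2(statistics, trim: float = 0.02):
    """Fit c * chi2(d) to the empirical distribution of a statistic.

    Scale and degrees of freedom are estimated by matching empirical
    quantiles to the scaled chi-squared quantiles over the 2nd to
    (100 - 100*trim)-th percentiles: the top ``trim`` fraction is excluded
    so genuine selection signals do not inflate the null fit, while the
    upper usable quantiles still anchor the fit where significance is
    decided.  For fixed d the optimal c is linear least squares; d is found
    by a bounded 1-d search.  Returns ``(c, d, p_values)`` with upper-tail
    chi-squared(d) p-values of ``statistics / c``.
    """
    x = np.asarray(statistics, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 500:
        raise ValueError("need at least 500 finite statistics to recalibrate")
    if np.var(x) == 0:
        raise ValueError("degenerate input: zero variance")
    u = np.linspace(0.02, 1 - trim, 49)
    qe = np.quantile(x, u)

    def fit_at(logd):
        d = float(np.exp(logd))
        qc = stats.chi2.ppf(u, d)
        c = float(qe @ qc / (qc @ qc))
        return float(((qe - c * qc) ** 2).sum()), c, d

    res = optimize.minimize_scalar(
        lambda ld: fit_at(ld)[0],
        bounds=(np.log(0.2), np.log(500)), method="bounded",
        options={"xatol": 1e-8},
    )
    _, c, d = fit_at(res.x)
    if c <= 0:
        raise ValueError("degenerate input: non-positive fitted scale")
    pvals = stats.chi2.sf(np.asarray(statistics, dtype=float) / c, df=d)
    return c, d, pvals


# ---------------------------------------------------------------------------
# scan driver
# ---------------------------------------------------------------------------


def run_hapflk_scan(
    data,
    populations: list[str],
    F: KinshipF,
    snp_ids=None,
    chromosomes=None,
    positions=None,
    K: int = 30,
    n_em_runs: int = 5,
    n_iter: int = 30,
    fdr: float = 0.05,
    seed: int = 0,
    qvalue_method: str = "storey",
) -> pd.DataFrame:
    """Full hapFLK scan: EM fits, run-averaged statistic, recalibration, FDR.

    ``data`` rows are haplotypes (phased) or individuals (genotypes), in the
    same order as ``populations``.  ``n_em_runs`` cluster models are fitted
    with distinct seeds and the per-SNP statistic is averaged over runs
    before the scaled-chi-squared recalibration.
    """
    x = _as_haplotypes(data)
    S = x.shape[1]
    stats_runs = np.empty((n_em_runs, S))
    rng = np.random.default_rng(seed)
    run_seeds = [int(rng.integers(2**31 - 1)) for _ in range(n_em_runs)]
    for r, s_r in enumerate(run_seeds):
        model = fit_cluster_model(x, K=K, n_iter=n_iter, seed=s_r)
        pops, q = cluster_frequencies(model, x, populations)
        qF = q[[pops.index(p) for p in F.populations]]
        stats_runs[r] = hapflk_statistic(qF, F)
    raw = stats_runs.mean(axis=0)
    c, d, pvals = fit_scaled_chi2(raw)
    qvals = fdr_qvalues(pvals, method=qvalue_method)
    out = pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"snp{j}" for j in range(S)],
            "chrom": chromosomes if chromosomes is not None else ["1"] * S,
            "pos": positions if positions is not None else np.arange(1, S + 1),
            "hapflk_raw": raw,
            "scale": c,
            "dof": d,
            "pvalue": pvals,
            "qvalue": qvals,
            "significant": (qvals < fdr).astype(int),
        }
    )
    out.attrs["fdr"] = fdr
    out.attrs["run_seeds"] = run_seeds
    return out


def genotype_hapflk_input(G: GenotypeTable):
    """Convenience: (calls, populations, ids, chroms, positions) from a table."""
    return G.calls, list(G.populations), list(G.snp_ids), list(G.chromosomes), G.positions
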