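"""Bayesian admixture-model clustering by Markov chain Monte Carlo.

The model is the classic admixture mixture for multilocus genotypes: each
individual ``i`` carries membership proportions ``q_i`` over ``K`` clusters,
each allele copy descends from cluster ``k`` with probability ``q_ik`` and is
then an i.i.d. draw from that cluster's allele frequencies at its locus.

Two frequency priors are available:

``independent``
    each cluster-locus frequency vector has a flat Dirichlet(1) prior;
``correlated`` (F-model)
    cluster frequencies drift from shared ancestral frequencies ``pi_l``
    with per-cluster intensity ``F_k``:
    ``p_kl ~ Dirichlet(pi_l * (1 - F_k) / F_k)``.

Updates: allele-copy origins ``z`` and (given ``z``) ``q`` and the cluster
frequencies are conjugate Gibbs draws; the ancestral frequencies, the drift
parameters ``F_k`` and the admixture concentration ``alpha`` move by
random-walk Metropolis. Missing genotypes contribute nothing to the
likelihood. The data log-probability is summarized with the mean-minus-
half-variance approximation of the posterior log-likelihood samples, the
same heuristic the field's standard program reports; it is an approximation
to ln Pr(X|K), not a marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import GenotypeTable

_FREQ_FLOOR = 1e-12


@dataclass
class QMatrix:
    """Result of one admixture MCMC run."""

    K: int
    q: np.ndarray  # (n, K) posterior-mean membership proportions
    ln_prob_data: float
    sample_ids: list[str]
    seed: int = 0
    mcmc_settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape[1] != self.K:
            raise ValueError("q column count must equal K")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("q rows must sum to 1")
        if ((self.q < -1e-12) | (self.q > 1 + 1e-12)).any():
            raise ValueError("q entries must lie in [0, 1]")
        if not np.isfinite(self.ln_prob_data):
            raise ValueError("ln_prob_data must be finite")

    @property
    def n(self) -> int:
        return self.q.shape[0]

    def home_cluster(self) -> np.ndarray:
        return self.q.argmax(axis=1)


class _PaddedData:
    """Genotypes encoded as dense allele codes, padded to a common width."""

    def __init__(self, table: GenotypeTable):
        codes, n_alleles, _ = table.encode()
        keep = np.flatnonzero(n_alleles > 0)  # drop all-missing loci
        self.locus_index = keep
        self.codes = codes[:, keep, :]  # (n, L, 2), missing = -1
        self.n_alleles = n_alleles[keep]
        self.n, self.L = self.codes.shape[0], len(keep)
        self.A = int(self.n_alleles.max()) if self.L else 1
        self.obs = self.codes >= 0  # (n, L, 2)
        # allele-validity mask (L, A)
        self.valid = np.arange(self.A)[None, :] < self.n_alleles[:, None]
        # overall observed frequencies, for initialization
        counts = np.zeros((self.L, self.A))
        lidx = np.broadcast_to(np.arange(self.L)[None, :, None], self.codes.shape)
        np.add.at(counts, (lidx[self.obs], self.codes[self.obs]), 1.0)
        tot = counts.sum(axis=1, keepdims=True)
        self.overall_freqs = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
        self._lidx = lidx
        self._iidx = np.broadcast_to(
            np.arange(self.n)[:, None, None], self.codes.shape
        )


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Sample Dirichlet rows for padded parameter arrays (invalid cells -> 0)."""
    g = np.where(valid, rng.gamma(np.maximum(alpha, 1e-9)), 0.0)
    g = np.maximum(g, np.where(valid, _FREQ_FLOOR, 0.0))
    return g / g.sum(axis=-1, keepdims=True)


def fit_admixture(
    table: GenotypeTable,
    K: int,
    iterations: int = 50_000,
    burn_in: int = 10_000,
    freq_model: str = "correlated",
    seed: int = 0,
    alpha_init: float = 1.0,
    lambda_prior: float = 1.0,
) -> QMatrix:
    """Run the admixture Gibbs sampler and return posterior-mean memberships.

    ``iterations`` counts total MCMC sweeps; the first ``burn_in`` are
    discarded. Desk-scale defaults favour interactive use; the long chains
    used for publication-grade runs are available through
    ``PipelineConfig.paper_faithful``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > table.n_samples:
        raise ValueError(f"K={K} exceeds the {table.n_samples} individuals")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if freq_model not in ("independent", "correlated"):
        raise ValueError("freq_model must be 'independent' or 'correlated'")

    rng = np.random.default_rng(seed)
    data = _PaddedData(table)
    n, L, A = data.n, data.L, data.A
    if L == 0:
        raise ValueError("no informative loci (all calls missing)")

    # state ---------------------------------------------------------------
    q = np.full((n, K), 1.0 / K)
    anc = np.where(data.valid, np.maximum(data.overall_freqs, _FREQ_FLOOR), 0.0)
    anc /= anc.sum(axis=1, keepdims=True)
    F = np.full(K, 0.1)
    alpha = float(alpha_init)
    # initial frequencies: perturbed overall frequencies per cluster
    freqs = _dirichlet_rows(
        rng,
        np.broadcast_to(1.0 + 50 * anc[:, None, :], (L, K, A)),
        np.broadcast_to(data.valid[:, None, :], (L, K, A)),
    )

    q_sum = np.zeros((n, K))
    ll_samples: list[float] = []
    n_kept = 0
    lidx, iidx, obs, codes = data._lidx, data._iidx, data.obs, data.codes
    safe_codes = np.where(codes >= 0, codes, 0)

    for sweep in range(iterations):
        # --- z: cluster of origin of each allele copy (Gibbs) ------------
        fg = freqs[np.arange(L)[None, :, None], :, safe_codes]  # (n, L, 2, K)
        P = q[:, None, None, :] * fg
        tot = P.sum(axis=-1)
        ll = float(np.log(tot[obs]).sum())
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite likelihood at sweep {sweep} (K={K}, seed={seed})"
            )
        u = rng.random((n, L, 2)) * tot
        z = np.minimum((P.cumsum(axis=-1) < u[..., None]).sum(axis=-1), K - 1)

        C = np.zeros((n, K))
        np.add.at(C, (iidx[obs], z[obs]), 1.0)
        acounts = np.zeros((L, K, A))
        np.add.at(acounts, (lidx[obs], z[obs], codes[obs]), 1.0)

        # --- q | z (Gibbs, Dirichlet-conjugate) ---------------------------
        if K > 1:
            q = _dirichlet_rows(rng, alpha + C, np.ones((n, K), dtype=bool))
        # --- cluster frequencies | z (Gibbs) ------------------------------
        if freq_model == "independent":
            prior = np.where(data.valid, lambda_prior, 0.0)[:, None, :]
        else:
            prior = anc[:, None, :] * ((1 - F) / F)[None, :, None]
        freqs = _dirichlet_rows(
            rng, prior + acounts, np.broadcast_to(data.valid[:, None, :], (L, K, A))
        )

        if freq_model == "correlated":
            anc = _update_ancestral(rng, anc, freqs, F, data)
            F = _update_drift(rng, anc, freqs, F, data)
        if K > 1:
            alpha = _update_alpha(rng, alpha, q)

        if sweep >= burn_in:
            q_sum += q
            ll_samples.append(ll)
            n_kept += 1

    q_mean = q_sum / n_kept
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    ll_arr = np.asarray(ll_samples)
    ln_prob = float(ll_arr.mean() - ll_arr.var() / 2.0)
    return QMatrix(
        K=K,
        q=q_mean,
        ln_prob_data=ln_prob,
        sample_ids=list(table.sample_ids),
        seed=seed,
        mcmc_settings={
            "iterations": iterations,
            "burn_in": burn_in,
            "freq_model": freq_model,
        },
    )


def _update_ancestral(
    rng: np.random.Generator,
    anc: np.ndarray,
    freqs: np.ndarray,
    F: np.ndarray,
    data: _PaddedData,
    step: float = 0.05,
) -> np.ndarray:
    """Metropolis move of ancestral frequencies: shift mass between two alleles.

    The Dirichlet(1) prior on the ancestral vector is uniform, and the total
    concentration (1-F_k)/F_k is unchanged by a mass shift, so the acceptance
    ratio involves only the two affected alleles of each locus.
    """
    L = anc.shape[0]
    multi = data.n_alleles >= 2
    if not multi.any():
        return anc
    a = rng.integers(0, data.n_alleles)
    b = (a + 1 + rng.integers(0, np.maximum(data.n_alleles - 1, 1))) % data.n_alleles
    eps = rng.random(L) * step
    new_a = anc[np.arange(L), a] - eps
    new_b = anc[np.arange(L), b] + eps
    ok = multi & (new_a > _FREQ_FLOOR)

    r = ((1 - F) / F)[None, :]  # (1, K)
    la = np.arange(L)
    logf_a = np.log(np.maximum(freqs[la, :, a], _FREQ_FLOOR))  # (L, K)
    logf_b = np.log(np.maximum(freqs[la, :, b], _FREQ_FLOOR))
    va, vb = anc[la, a][:, None] * r, anc[la, b][:, None] * r
    va2, vb2 = new_a[:, None] * r, new_b[:, None] * r
    delta = (
        gammaln(np.maximum(va, _FREQ_FLOOR))
        + gammaln(np.maximum(vb, _FREQ_FLOOR))
        - gammaln(np.maximum(va2, _FREQ_FLOOR))
        - gammaln(np.maximum(vb2, _FREQ_FLOOR))
        + (va2 - va) * logf_a
        + (vb2 - vb) * logf_b
    ).sum(axis=1)
    accept = ok & (np.log(rng.random(L)) < delta)
    out = anc.copy()
    out[la[accept], a[accept]] = new_a[accept]
    out[la[accept], b[accept]] = new_b[accept]
    return out


def _update_drift(
    rng: np.random.Generator,
    anc: np.ndarray,
    freqs: np.ndarray,
    F: np.ndarray,
    data: _PaddedData,
    step: float = 0.05,
    bounds: tuple[float, float] = (0.001, 0.5),
) -> np.ndarray:
    """Random-walk Metropolis on each cluster's drift F_k, uniform prior."""
    K = len(F)
    logf = np.log(np.maximum(freqs, _FREQ_FLOOR))  # (L, K, A)
    out = F.copy()
    for k in range(K):
        prop = out[k] + (rng.random() - 0.5) * 2 * step
        if not bounds[0] <= prop <= bounds[1]:
            continue
        r_old, r_new = (1 - out[k]) / out[k], (1 - prop) / prop
        v_old, v_new = anc * r_old, anc * r_new
        valid = data.valid
        # per locus: lgamma(sum v) - sum lgamma(v_j) + sum (v_j - 1) log f
        term_new = (
            gammaln(r_new)
            - np.where(valid, gammaln(np.maximum(v_new, _FREQ_FLOOR)), 0.0).sum(axis=1)
            + (np.where(valid, v_new, 0.0) * np.where(valid, logf[:, k, :], 0.0)).sum(axis=1)
        )
        term_old = (
            gammaln(r_old)
            - np.where(valid, gammaln(np.maximum(v_old, _FREQ_FLOOR)), 0.0).sum(axis=1)
            + (np.where(valid, v_old, 0.0) * np.where(valid, logf[:, k, :], 0.0)).sum(axis=1)
        )
        delta = (term_new - term_old).sum()
        if np.log(rng.random()) < delta:
            out[k] = prop
    return out


def _update_alpha(
    rng: np.random.Generator,
    alpha: float,
    q: np.ndarray,
    step: float = 0.1,
    upper: float = 10.0,
) -> float:
    """Random-walk Metropolis on the symmetric admixture concentration."""
    prop = alpha + (rng.random() - 0.5) * 2 * step
    if not 0 < prop <= upper:
        return alpha
    n, K = q.shape
    logq_sum = float(np.log(np.maximum(q, _FREQ_FLOOR)).sum())
    def _ll(a: float) -> float:
        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * logq_sum
    if np.log(rng.random()) < _ll(prop) - _ll(alpha):
        return prop
    return alpha


def k1_log_marginal(table: GenotypeTable, lambda_prior: float = 1.0) -> float:
    """Exact ln Pr(X | K=1) under the independent-frequency model.

    With a single cluster the allele frequencies integrate out analytically:
    per locus the marginal likelihood of the observed gene copies is
    Dirichlet-multinomial. Serves as a brute-force oracle for the MCMC
    estimate on tiny tables (the genotype ordering constant is identical for
    both and omitted).
    """
    codes, n_alleles, _ = table.encode()
    total = 0.0
    for l in range(table.n_loci):
        A = int(n_alleles[l])
        if A == 0:
            continue
        col = codes[:, l, :]
        obs = col[col >= 0]
        counts = np.bincount(obs, minlength=A).astype(float)
        a0 = lambda_prior * A
        total += float(
            gammaln(a0)
            - gammaln(a0 + counts.sum())
            + (gammaln(lambda_prior + counts) - gammaln(lambda_prior)).sum()
        )
    return total
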