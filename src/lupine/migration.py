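"""Bayesian inference of recent migration rates among fixed groups.

The model follows the multilocus genotype assignment approach for
*recent* (last two generations) migration: each individual sampled in group
``l`` is a resident, a first-generation migrant from some group ``q``, or a
second-generation migrant (one parent from ``q``). Migration rates ``m[l][q]``
are the expected fractions of group ``l`` made up of migrants from ``q`` per
generation, with the model constraint that first- and second-generation
classes each occur with probability ``m[l][q]``, so the total non-resident
share of a group is at most 1/3 and ``m[l][l] >= 2/3``.

Genotype likelihoods: residents follow inbreeding-adjusted Hardy-Weinberg
proportions in their home group's allele frequencies, first-generation
migrants the source group's, and second-generation migrants draw one allele
copy per locus from each of home and source. Missing genotypes contribute
nothing. Sampling is Metropolis-within-Gibbs over the migration matrix
(uniform prior on the constrained simplex), per-group allele frequencies
(flat Dirichlet prior), per-group inbreeding coefficients (uniform prior)
and per-individual ancestry states. The three ``delta`` parameters are the
proposal step sizes of the frequency, inbreeding and migration moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeTable

_P_FLOOR = 1e-9
_DIAG_MIN = 2.0 / 3.0


@dataclass
class MigrationEstimate:
    """Posterior summary of the migration MCMC."""

    groups: list[str]
    m_mean: np.ndarray  # (K, K); m[l][q] = fraction of l from q
    m_ci_low: np.ndarray
    m_ci_high: np.ndarray
    inbreeding_mean: np.ndarray  # (K,)
    inbreeding_ci: np.ndarray  # (K, 2)
    ancestry_posterior: pd.DataFrame  # per individual, per state
    acceptance: dict[str, float]
    m_samples: np.ndarray  # (S, K, K) retained thinned samples
    mcmc_settings: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.groups)


class _MigData:
    def __init__(self, table: GenotypeTable, labels: list[str]):
        codes, n_alleles, _ = table.encode()
        keep = np.flatnonzero(n_alleles > 0)
        self.codes = codes[:, keep, :]
        self.n_alleles = n_alleles[keep]
        self.n, self.L = self.codes.shape[0], len(keep)
        self.A = int(self.n_alleles.max()) if self.L else 1
        self.obs = self.codes[:, :, 0] >= 0  # (n, L)
        self.het = self.obs & (self.codes[:, :, 0] != self.codes[:, :, 1])
        self.a0 = np.where(self.codes[:, :, 0] >= 0, self.codes[:, :, 0], 0)
        self.a1 = np.where(self.codes[:, :, 1] >= 0, self.codes[:, :, 1], 0)
        self.valid = np.arange(self.A)[None, :] < self.n_alleles[:, None]
        names = sorted(set(labels))
        self.groups = names
        gmap = {g: i for i, g in enumerate(names)}
        self.home = np.array([gmap[g] for g in labels])
        self.K = len(names)


def _loglik_rows(
    data: _MigData,
    rows: np.ndarray,
    src: np.ndarray,
    gen: np.ndarray,
    freqs: np.ndarray,
    inbr: np.ndarray,
    loci: np.ndarray | None = None,
) -> np.ndarray:
    """Log-likelihood of the given individuals' genotypes under their states.

    ``src``/``gen`` are the states of exactly those individuals (aligned with
    ``rows``). ``loci`` restricts the computation to a locus subset.
    """
    home = data.home[rows]
    lsel = np.arange(data.L) if loci is None else np.atleast_1d(loci)
    a0 = data.a0[np.ix_(rows, lsel)]
    a1 = data.a1[np.ix_(rows, lsel)]
    obs = data.obs[np.ix_(rows, lsel)]
    het = data.het[np.ix_(rows, lsel)]
    m = len(rows)
    lidx = np.broadcast_to(lsel[None, :], a0.shape)

    # per-copy frequencies in the "draw" groups
    g_first = np.where(gen == 2, home, src)  # group of copy 1
    g_second = src  # group of copy 2
    p1 = freqs[g_first[:, None], lidx, a0]
    p2 = freqs[g_second[:, None], lidx, a1]
    p1b = freqs[g_first[:, None], lidx, a1]  # copy-swapped for 2nd-gen hets
    p2b = freqs[g_second[:, None], lidx, a0]

    out = np.zeros(a0.shape)
    hw_like = gen[:, None] <= 1  # resident or first generation: HW in one group
    F = inbr[np.where(gen == 1, src, home)][:, None]
    hom = hw_like & obs & ~het
    out[hom] = np.log(np.maximum(F * p1 + (1 - F) * p1 * p1, _P_FLOOR)[hom])
    hetc = hw_like & obs & het
    out[hetc] = np.log(np.maximum((1 - F) * 2 * p1 * p2, _P_FLOOR)[hetc])
    # second generation: one copy from home, one from source
    sg = (gen[:, None] == 2) & obs
    sg_hom = sg & ~het
    out[sg_hom] = np.log(np.maximum(p1 * p2, _P_FLOOR)[sg_hom])
    sg_het = sg & het
    out[sg_het] = np.log(np.maximum(p1 * p2 + p1b * p2b, _P_FLOOR)[sg_het])
    return out.sum(axis=1)


def _state_log_prior(m_mat: np.ndarray, home: np.ndarray, src: np.ndarray, gen: np.ndarray) -> np.ndarray:
    pri = np.where(
        gen == 0,
        2 * m_mat[home, home] - 1,
        m_mat[home, src],
    )
    return np.log(np.maximum(pri, _P_FLOOR))


def fit_migration(
    table: GenotypeTable,
    labels: list[str] | np.ndarray,
    iterations: int = 4000,
    burn_in: int = 1000,
    thinning: int = 5,
    delta_alleles: float = 0.3,
    delta_inbreeding: float = 0.7,
    delta_migration: float = 0.6,
    seed: int = 0,
) -> MigrationEstimate:
    """Run the migration MCMC and summarize the posterior.

    One iteration is a full sweep: an exact Gibbs draw of every individual's
    ancestry state (states are conditionally independent given the other
    parameters), one Metropolis move per migration-matrix row, per group's
    allele frequencies, and per group's inbreeding coefficient. Desk-scale
    defaults (4000 sweeps, 1000 burn-in, thinning 5) suit small datasets;
    publication-length chains are available through
    ``PipelineConfig.paper_faithful``.

    Every individual must carry a group label; K >= 2 groups required.
    """
    labels = [str(x) for x in labels]
    if len(labels) != table.n_samples:
        raise ValueError("one group label per individual required")
    data = _MigData(table, labels)
    if data.K < 2:
        raise ValueError("migration inference requires K >= 2 groups")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    rng = np.random.default_rng(seed)
    n, K, L = data.n, data.K, data.L

    # --- initial state ----------------------------------------------------
    m_mat = np.full((K, K), (1.0 / 3.0) * 0.5 / max(K - 1, 1))
    np.fill_diagonal(m_mat, 0.0)
    np.fill_diagonal(m_mat, 1.0 - m_mat.sum(axis=1))
    freqs = np.zeros((K, L, data.A))
    for g in range(K):
        rows = np.flatnonzero(data.home == g)
        for l in range(L):
            sub = data.codes[rows, l, :]
            obsr = sub[:, 0] >= 0
            cnt = np.bincount(sub[obsr].ravel(), minlength=data.A).astype(float)
            cnt += np.where(data.valid[l], 1.0, 0.0)  # flat prior pseudocount
            freqs[g, l] = cnt / cnt.sum()
    inbr = np.full(K, 0.1)
    src = data.home.copy()
    gen = np.zeros(n, dtype=int)

    prop_counts = {"state": 0, "migration": 0, "freq": 0, "inbreeding": 0}
    acc_counts = dict.fromkeys(prop_counts, 0)
    m_samples = []
    f_samples = []
    n_states = 2 * K - 1
    state_counts = np.zeros((n, n_states))  # resident | (q,1) | (q,2) layout

    # state enumeration: s=0 resident; s=1+2*off+(t-1) is generation t from
    # source (home + 1 + off) mod K
    all_rows = np.arange(n)
    src_by_state = np.empty((n_states, n), dtype=int)
    gen_by_state = np.empty((n_states, n), dtype=int)
    src_by_state[0] = data.home
    gen_by_state[0] = 0
    for off in range(K - 1):
        s_src = (data.home + 1 + off) % K
        for t in (1, 2):
            s = 1 + 2 * off + (t - 1)
            src_by_state[s] = s_src
            gen_by_state[s] = t

    def current_state_index() -> np.ndarray:
        off = (src - data.home) % K - 1
        return np.where(gen == 0, 0, 1 + 2 * off + (gen - 1))

    for it in range(iterations):
        # --- all ancestry states: exact Gibbs (conditionally independent) --
        logpost = np.empty((n, n_states))
        for s in range(n_states):
            logpost[:, s] = _loglik_rows(
                data, all_rows, src_by_state[s], gen_by_state[s], freqs, inbr
            ) + _state_log_prior(m_mat, data.home, src_by_state[s], gen_by_state[s])
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        u = rng.random(n)
        s_new = (post.cumsum(axis=1) < u[:, None]).sum(axis=1)
        s_new = np.minimum(s_new, n_states - 1)
        src = src_by_state[s_new, all_rows]
        gen = gen_by_state[s_new, all_rows]
        prop_counts["state"] += n
        acc_counts["state"] += n  # Gibbs draw always accepted

        # --- migration matrix: one Metropolis edge per row -----------------
        for l_grp in range(K):
            q_grp = int(rng.integers(K - 1))
            q_grp = q_grp if q_grp < l_grp else q_grp + 1
            step = (rng.random() - 0.5) * delta_migration
            new_val = m_mat[l_grp, q_grp] + step
            off_sum = (
                m_mat[l_grp].sum() - m_mat[l_grp, l_grp] - m_mat[l_grp, q_grp] + new_val
            )
            prop_counts["migration"] += 1
            if new_val >= 0 and off_sum <= 1 - _DIAG_MIN:
                old_row = m_mat[l_grp].copy()
                m_mat[l_grp, q_grp] = new_val
                m_mat[l_grp, l_grp] = 1.0 - (m_mat[l_grp].sum() - m_mat[l_grp, l_grp])
                members = np.flatnonzero(data.home == l_grp)
                lp_new = _state_log_prior(
                    m_mat, data.home[members], src[members], gen[members]
                ).sum()
                m_old = m_mat.copy()
                m_old[l_grp] = old_row
                lp_old = _state_log_prior(
                    m_old, data.home[members], src[members], gen[members]
                ).sum()
                if np.log(rng.random()) < lp_new - lp_old:
                    acc_counts["migration"] += 1
                else:
                    m_mat[l_grp] = old_row

        # --- allele frequencies: one symmetric mass-shift move per group ---
        for g in range(K):
            l = int(rng.integers(L))
            A_l = int(data.n_alleles[l])
            prop_counts["freq"] += 1
            if A_l < 2:
                continue
            a = int(rng.integers(A_l))
            b = int(rng.integers(A_l - 1))
            b = b if b < a else b + 1
            eps = rng.random() * delta_alleles * 0.1
            if freqs[g, l, a] - eps <= _P_FLOOR:
                continue
            affected = np.flatnonzero(
                ((gen == 0) & (data.home == g))
                | ((gen >= 1) & (src == g))
                | ((gen == 2) & (data.home == g))
            )
            affected = affected[data.obs[affected, l]]
            old_ll = (
                _loglik_rows(data, affected, src[affected], gen[affected], freqs,
                             inbr, loci=np.array([l]))
                if len(affected)
                else np.zeros(0)
            )
            new_row = freqs[g, l].copy()
            freqs[g, l, a] -= eps
            freqs[g, l, b] += eps
            new_ll = (
                _loglik_rows(data, affected, src[affected], gen[affected], freqs,
                             inbr, loci=np.array([l]))
                if len(affected)
                else np.zeros(0)
            )
            if np.log(rng.random()) < float(new_ll.sum() - old_ll.sum()):
                acc_counts["freq"] += 1
            else:
                freqs[g, l] = new_row

        # --- inbreeding: one random-walk move per group ---------------------
        for g in range(K):
            newF = inbr[g] + (rng.random() - 0.5) * delta_inbreeding
            prop_counts["inbreeding"] += 1
            if not 1e-6 < newF < 1 - 1e-6:
                continue
            affected = np.flatnonzero(
                ((gen == 0) & (data.home == g)) | ((gen == 1) & (src == g))
            )
            if not len(affected):
                inbr[g] = newF
                acc_counts["inbreeding"] += 1
                continue
            old_ll = _loglik_rows(data, affected, src[affected], gen[affected], freqs, inbr)
            old_val = inbr[g]
            inbr[g] = newF
            new_ll = _loglik_rows(data, affected, src[affected], gen[affected], freqs, inbr)
            if np.log(rng.random()) < float(new_ll.sum() - old_ll.sum()):
                acc_counts["inbreeding"] += 1
            else:
                inbr[g] = old_val

        # --- record --------------------------------------------------------
        if it >= burn_in and (it - burn_in) % thinning == 0:
            assert abs(m_mat.sum(axis=1).max() - 1) < 1e-9
            assert (np.diag(m_mat) >= _DIAG_MIN - 1e-12).all()
            m_samples.append(m_mat.copy())
            f_samples.append(inbr.copy())
            state_counts[all_rows, current_state_index()] += 1

    m_arr = np.asarray(m_samples)
    f_arr = np.asarray(f_samples)
    acc = {k: acc_counts[k] / max(prop_counts[k], 1) for k in prop_counts}
    for k, rate in acc.items():
        if not 0.1 <= rate <= 0.9 and k != "state":
            warnings.warn(
                f"{k} move acceptance rate {rate:.2f} outside [0.1, 0.9]; "
                "consider adjusting the corresponding delta",
                stacklevel=2,
            )

    state_cols = ["resident"]
    for off in range(K - 1):
        state_cols += [f"first_gen_src{off}", f"second_gen_src{off}"]
    post = state_counts / state_counts.sum(axis=1, keepdims=True)
    ancestry = pd.DataFrame(post, index=table.sample_ids, columns=state_cols)
    ancestry.insert(0, "group", [data.groups[h] for h in data.home])

    return MigrationEstimate(
        groups=data.groups,
        m_mean=m_arr.mean(axis=0),
        m_ci_low=np.percentile(m_arr, 2.5, axis=0),
        m_ci_high=np.percentile(m_arr, 97.5, axis=0),
        inbreeding_mean=f_arr.mean(axis=0),
        inbreeding_ci=np.stack(
            [np.percentile(f_arr, 2.5, axis=0), np.percentile(f_arr, 97.5, axis=0)], axis=1
        ),
        ancestry_posterior=ancestry,
        acceptance=acc,
        m_samples=m_arr,
        mcmc_settings={
            "iterations": iterations,
            "burn_in": burn_in,
            "thinning": thinning,
            "deltas": (delta_alleles, delta_inbreeding, delta_migration),
            "seed": seed,
        },
    )


def migrant_posterior(est: MigrationEstimate) -> pd.DataFrame:
    """Collapse the ancestry posterior to P(resident), P(first-gen), P(second-gen)."""
    df = est.ancestry_posterior
    first = df[[c for c in df.columns if c.startswith("first_gen")]].sum(axis=1)
    second = df[[c for c in df.columns if c.startswith("second_gen")]].sum(axis=1)
    return pd.DataFrame(
        {"group": df["group"], "resident": df["resident"], "first_gen": first,
         "second_gen": second}
    )


def significant_edges(est: MigrationEstimate, zero_threshold: float = 1e-4) -> pd.DataFrame:
    """Directed migration edges whose 95% credible interval excludes zero.

    Since the prior support excludes exact zero, "does not include zero" is
    operationalized as a lower CI bound above ``zero_threshold``. Rows are
    Table-shaped: source -> destination, posterior mean and CI half-width.
    """
    rows = []
    K = est.K
    for l in range(K):
        for q in range(K):
            if l == q:
                continue
            if est.m_ci_low[l, q] > zero_threshold:
                mean = est.m_mean[l, q]
                rows.append(
                    {
                        "source": est.groups[q],
                        "destination": est.groups[l],
                        "rate_mean": float(mean),
                        "ci_low": float(est.m_ci_low[l, q]),
                        "ci_high": float(est.m_ci_high[l, q]),
                        "ci_half_width": float(
                            (est.m_ci_high[l, q] - est.m_ci_low[l, q]) / 2
                        ),
                    }
                )
    return pd.DataFrame(rows)
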