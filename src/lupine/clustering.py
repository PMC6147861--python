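"""Replicate handling and model-choice tools around the admixture sampler.

Covers label-switching alignment across replicate runs (greedy CLUMPP-style
maximum-weight bipartite matching), the Evanno second-order rate-of-change
statistic for choosing the number of clusters, hierarchical re-clustering of
inferred clusters, and a model-free PCA + k-means partitioning with a BIC
curve (the approach popularized as DAPC).

The number of clusters is never auto-decided for the user: the tools report
ln Pr(X|K), the Evanno table and replicate-consistency diagnostics, and the
caller picks K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .admixture import QMatrix, fit_admixture
from .data import GenotypeTable

# ---------------------------------------------------------------------------
# replicate alignment
# ---------------------------------------------------------------------------

def _column_similarity(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Pairwise column similarity: Pearson correlation, with a squared-error
    fallback for constant columns."""
    K = qa.shape[1]
    sim = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            x, y = qa[:, a], qb[:, b]
            if x.std() > 1e-12 and y.std() > 1e-12:
                sim[a, b] = float(np.corrcoef(x, y)[0, 1])
            else:
                sim[a, b] = -float(np.mean((x - y) ** 2))
    return sim


def align_replicates(runs: list[QMatrix]) -> tuple[list[np.ndarray], QMatrix, float]:
    """Align replicate runs to the first and average them.

    Each run's cluster columns are permuted to best match the first run by
    maximum-weight bipartite matching on column-wise similarity.

    Returns
    -------
    permutations : per run, the column order applied (``q[:, perm]``)
    averaged : a QMatrix whose q is the mean of the aligned runs
    similarity : mean pairwise between-run similarity in [0, 1], where 1
        means identical membership matrices (defined as
        ``1 - mean |q_a - q_b| / 2``)
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    n = runs[0].n
    for r in runs:
        if r.K != K:
            raise ValueError(f"mismatched K across runs: {r.K} != {K}")
        if r.n != n or r.sample_ids != runs[0].sample_ids:
            raise ValueError("runs must share the same individuals in the same order")

    ref = runs[0].q
    permutations: list[np.ndarray] = []
    aligned: list[np.ndarray] = []
    for r in runs:
        sim = _column_similarity(r.q, ref)
        rows, cols = linear_sum_assignment(-sim)
        perm = np.empty(K, dtype=int)
        perm[cols] = rows  # column `cols[j]` of the reference <- run column rows[j]
        permutations.append(perm)
        aligned.append(r.q[:, perm])

    stack = np.stack(aligned)
    mean_q = stack.mean(axis=0)
    mean_q /= mean_q.sum(axis=1, keepdims=True)
    m = len(runs)
    if m > 1:
        # |q_a - q_b| summed over K columns is in [0, 2] per individual
        sims = [
            1.0 - float(np.abs(stack[a] - stack[b]).sum(axis=1).mean()) / 2.0
            for a in range(m)
            for b in range(a + 1, m)
        ]
        similarity = float(np.mean(sims))
    else:
        similarity = 1.0
    averaged = QMatrix(
        K=K,
        q=mean_q,
        ln_prob_data=float(np.mean([r.ln_prob_data for r in runs])),
        sample_ids=list(runs[0].sample_ids),
        seed=runs[0].seed,
        mcmc_settings={"averaged_over": m, **runs[0].mcmc_settings},
    )
    return permutations, averaged, similarity


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class EvannoTable:
    """Per-K summary of replicate data log-probabilities and the ΔK statistic.

    ΔK(K) = |L''(K)| / sd(L(K)) with L'(K) = L(K) - L(K-1) and
    |L''(K)| = |L'(K+1) - L'(K)|; defined only for interior K. Entries that
    cannot be computed are NaN and flagged, never zero-filled; a zero
    replicate standard deviation yields ΔK = +inf with a warning.
    """

    K_values: np.ndarray
    mean_ln_prob: np.ndarray
    sd_ln_prob: np.ndarray
    l_prime: np.ndarray  # L'(K); NaN at the first K
    l_double_prime: np.ndarray  # |L''(K)|; NaN at the boundary Ks
    delta_k: np.ndarray  # NaN where undefined
    flags: list[str] = field(default_factory=list)

    def best_k(self) -> int:
        """K with the largest defined ΔK (ties -> smallest K)."""
        finite = np.where(np.isnan(self.delta_k), -np.inf, self.delta_k)
        if np.all(np.isinf(finite) & (finite < 0)):
            raise ValueError("delta-K undefined for every K")
        return int(self.K_values[int(np.argmax(finite))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "K": self.K_values,
                "mean_lnP": self.mean_ln_prob,
                "sd_lnP": self.sd_ln_prob,
                "L_prime": self.l_prime,
                "abs_L_double_prime": self.l_double_prime,
                "delta_K": self.delta_k,
            }
        )


def evanno_table(ln_prob_by_k: dict[int, list[float]]) -> EvannoTable:
    """Compute the Evanno table from replicate ln Pr(X|K) values.

    Requires a contiguous K range and >= 2 replicates per K for the standard
    deviation (a single replicate yields sd 0 and an infinity flag).
    """
    ks = np.array(sorted(ln_prob_by_k))
    if len(ks) == 0:
        raise ValueError("empty input")
    if not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    mean = np.array([float(np.mean(ln_prob_by_k[k])) for k in ks])
    sd = np.array([float(np.std(ln_prob_by_k[k], ddof=1)) if len(ln_prob_by_k[k]) > 1 else 0.0 for k in ks])

    m = len(ks)
    l_prime = np.full(m, np.nan)
    l_dbl = np.full(m, np.nan)
    delta = np.full(m, np.nan)
    flags: list[str] = []
    for i in range(1, m):
        l_prime[i] = mean[i] - mean[i - 1]
    for i in range(1, m - 1):
        l_dbl[i] = abs(l_prime[i + 1] - l_prime[i])
        if sd[i] == 0.0:
            delta[i] = np.inf
            flags.append(f"K={ks[i]}: zero replicate sd, delta-K reported as +inf")
            warnings.warn(flags[-1], stacklevel=2)
        else:
            delta[i] = l_dbl[i] / sd[i]
    if m < 3:
        flags.append("fewer than three K values: delta-K undefined everywhere")
    return EvannoTable(ks, mean, sd, l_prime, l_dbl, delta, flags)


# ---------------------------------------------------------------------------
# hierarchical re-clustering
# ---------------------------------------------------------------------------

@dataclass
class HierNode:
    """One node of the hierarchical partition tree."""

    sample_ids: list[str]
    chosen_k: int
    qmatrix: QMatrix | None
    children: list["HierNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["HierNode"]:
        if self.is_leaf:
            return [self]
        out: list[HierNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def depth(self) -> int:
        return 0 if self.is_leaf else 1 + max(c.depth() for c in self.children)


def hierarchical_partition(
    table: GenotypeTable,
    k_max_per_level: int = 5,
    replicates: int = 3,
    iterations: int = 2000,
    burn_in: int = 500,
    freq_model: str = "correlated",
    seed: int = 0,
    min_subset: int = 6,
) -> tuple[HierNode, dict[str, int]]:
    """Recursively re-cluster inferred clusters until no further split is
    supported.

    At each node the sampler is run for K = 1..k_max (replicated), and the
    split K is taken from the Evanno ΔK argmax. The node becomes a leaf when
    mean ln Pr(X|K) is maximized at K = 1, when the ΔK-selected K does not
    improve mean ln Pr(X|K) over K = 1, or when the subset is smaller than
    twice ``min_subset`` (subsets below the floor are never split).

    Returns the tree and the flat leaf-level partition (sample id -> leaf
    index).
    """
    if table.n_samples == 0:
        raise ValueError("empty table")
    rng = np.random.default_rng(seed)

    def _build(sub: GenotypeTable) -> HierNode:
        n = sub.n_samples
        if n < 2 * min_subset:
            return HierNode(list(sub.sample_ids), 1, None)
        k_hi = min(k_max_per_level, max(2, n // min_subset))
        ln_by_k: dict[int, list[float]] = {}
        runs_by_k: dict[int, list[QMatrix]] = {}
        for k in range(1, k_hi + 1):
            runs = [
                fit_admixture(
                    sub, k, iterations=iterations, burn_in=burn_in,
                    freq_model=freq_model, seed=int(rng.integers(2**31)),
                )
                for _ in range(replicates)
            ]
            runs_by_k[k] = runs
            ln_by_k[k] = [r.ln_prob_data for r in runs]
        means = {k: float(np.mean(v)) for k, v in ln_by_k.items()}
        if max(means, key=means.get) == 1:
            return HierNode(list(sub.sample_ids), 1, None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = evanno_table(ln_by_k)
        try:
            k_star = ev.best_k()
        except ValueError:
            k_star = max(means, key=means.get)
        if k_star < 2 or means[k_star] <= means[1]:
            return HierNode(list(sub.sample_ids), 1, None)
        _, avg, _ = align_replicates(runs_by_k[k_star])
        labels = avg.home_cluster()
        node = HierNode(list(sub.sample_ids), k_star, avg)
        for k in range(k_star):
            ids = [sid for sid, lab in zip(sub.sample_ids, labels) if lab == k]
            if not ids:
                continue
            child_table = sub.subset(ids)
            if len(ids) < min_subset:
                node.children.append(HierNode(ids, 1, None))
            else:
                node.children.append(_build(child_table))
        return node

    root = _build(table)
    flat = {
        sid: leaf_idx
        for leaf_idx, leaf in enumerate(root.leaves())
        for sid in leaf.sample_ids
    }
    return root, flat


# ---------------------------------------------------------------------------
# PCA + k-means (DAPC-style) partitioning
# ---------------------------------------------------------------------------

@dataclass
class DAPCResult:
    bic: dict[int, float]
    best_k: int
    assignment: np.ndarray  # hard labels at best_k
    membership: np.ndarray  # (n, best_k) discriminant membership probabilities
    pc_scores: np.ndarray


def allele_count_matrix(table: GenotypeTable) -> np.ndarray:
    """Individuals x alleles matrix of allele-copy counts (0/1/2), with
    missing genotypes imputed to the column mean."""
    codes, n_alleles, _ = table.encode()
    cols = int(n_alleles.sum())
    X = np.full((table.n_samples, cols), np.nan)
    offset = 0
    for l in range(table.n_loci):
        A = int(n_alleles[l])
        if A == 0:
            continue
        g = codes[:, l, :]
        obs = g[:, 0] >= 0
        block = np.zeros((table.n_samples, A))
        for copy in range(2):
            idx = g[obs, copy]
            block[np.flatnonzero(obs), idx] += 1
        block[~obs] = np.nan
        X[:, offset : offset + A] = block
        offset += A
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    return X


def dapc_partition(
    table: GenotypeTable,
    n_pcs: int = 80,
    k_range: range | list[int] = range(1, 21),
    kmeans_starts: int = 10,
    seed: int = 0,
) -> DAPCResult:
    """Model-free clustering: PCA of allele counts, k-means over a K grid,
    BIC(K) = n ln(WSS/n) + K ln(n), discriminant membership probabilities at
    the BIC-optimal K."""
    from sklearn.cluster import KMeans
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X = allele_count_matrix(table)
    n = X.shape[0]
    k_range = [k for k in k_range if k <= n]
    if not k_range:
        raise ValueError("no feasible K in range")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-9 * s[0]).sum()) if len(s) else 0
    n_pcs = max(1, min(n_pcs, rank))
    scores = U[:, :n_pcs] * s[:n_pcs]

    bic: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    total_var = float((scores**2).sum())
    for k in k_range:
        if k == 1:
            wss = total_var - float((scores.mean(axis=0) ** 2).sum()) * n
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=kmeans_starts, random_state=seed).fit(scores)
            wss = float(km.inertia_)
            labels = km.labels_
        wss = max(wss, 1e-12)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
        assignments[k] = labels

    best_k = min(bic, key=bic.get)
    labels = assignments[best_k]
    if best_k == 1 or len(np.unique(labels)) < 2:
        membership = np.ones((n, 1))
    else:
        lda = LinearDiscriminantAnalysis()
        lda.fit(scores, labels)
        membership = lda.predict_proba(scores)
    return DAPCResult(bic=bic, best_k=best_k, assignment=labels, membership=membership,
                      pc_scores=scores)
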