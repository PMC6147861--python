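"""Recovery and calibration experiments for the pipeline's core methods.

These are self-contained, seed-driven experiments on synthetic data: model
selection (ΔK) recovery, membership recovery, migration credible-interval
calibration, disperser detection and telemetry-overlap checks, and the
type-I behaviour of the Monte-Carlo tests. They are used both by the test
suite and by the reproduction script, with problem sizes scaled to run on a
single desktop core in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np

from .admixture import QMatrix, fit_admixture
from .classify import classify_individuals, detect_cutoffs
from .clustering import evanno_table
from .data import GenotypeTable
from .migration import fit_migration
from .popgen import hwe_exact_test, mantel_test
from .simulate import SimConfig, simulate_dataset, simulate_tracks
from .spatial import build_group_polygons, track_mcp_overlap


def _truth_qmatrix(table: GenotypeTable, truth) -> QMatrix:
    q = np.maximum(truth.true_q, 1e-12)
    return QMatrix(
        K=q.shape[1], q=q / q.sum(axis=1, keepdims=True), ln_prob_data=0.0,
        sample_ids=list(table.sample_ids),
    )


def delta_k_recovery(
    n_seeds: int = 20,
    k_true: int = 3,
    n_per_cluster: int = 20,
    n_loci: int = 20,
    drift: float = 0.2,
    k_max: int = 5,
    replicates: int = 3,
    iterations: int = 2000,
    burn_in: int = 600,
    freq_model: str = "correlated",
    seed: int = 0,
) -> list[int]:
    """ΔK-selected K on datasets with a known number of clusters.

    Returns the chosen K for each seed. The generator uses the package's
    default drift; chain lengths are sized so that replicate ln Pr(X|K)
    estimates are stable enough for the ΔK denominator.
    """
    picks = []
    master = np.random.default_rng(seed)
    for _ in range(n_seeds):
        data_seed = int(master.integers(2**31))
        cfg = SimConfig(
            K_true=k_true, n_per_cluster=[n_per_cluster] * k_true, n_loci=n_loci,
            alleles_per_locus=6, drift_F=drift, admixed_fraction=0.1,
            n_dispersers=0, missing_rate=0.02, seed=data_seed,
        )
        table, _, _ = simulate_dataset(cfg)
        ln: dict[int, list[float]] = {}
        for k in range(1, k_max + 1):
            ln[k] = [
                fit_admixture(
                    table, k, iterations=iterations, burn_in=burn_in,
                    freq_model=freq_model, seed=int(master.integers(2**31)),
                ).ln_prob_data
                for _ in range(replicates)
            ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            picks.append(evanno_table(ln).best_k())
    return picks


def q_recovery_correlations(
    n_seeds: int = 10,
    drift: float = 0.3,
    n_per_cluster: int = 30,
    n_loci: int = 20,
    iterations: int = 1200,
    burn_in: int = 400,
    seed: int = 0,
) -> list[float]:
    """|corr(fitted q, true q)| for two-cluster datasets, one value per seed."""
    master = np.random.default_rng(seed)
    out = []
    for _ in range(n_seeds):
        cfg = SimConfig(
            K_true=2, n_per_cluster=[n_per_cluster] * 2, n_loci=n_loci,
            alleles_per_locus=6, drift_F=drift, admixed_fraction=0.1,
            n_dispersers=0, missing_rate=0.02, seed=int(master.integers(2**31)),
        )
        table, _, truth = simulate_dataset(cfg)
        q = fit_admixture(table, 2, iterations=iterations, burn_in=burn_in,
                          freq_model="correlated", seed=int(master.integers(2**31)))
        out.append(abs(float(np.corrcoef(q.q[:, 0], truth.true_q[:, 0])[0, 1])))
    return out


def simulate_from_migration_model(
    m_true: np.ndarray,
    n_per_group: int,
    n_loci: int,
    drift: float = 0.3,
    seed: int = 0,
) -> tuple[GenotypeTable, list[str]]:
    """Simulate genotypes from the migration model's own generative process.

    Each individual of group l is a resident w.p. 1 - 2*sum(off-diag m[l]),
    or a first-/second-generation migrant from q, each w.p. m[l][q];
    genotypes follow the corresponding per-state likelihood (no inbreeding).
    """
    rng = np.random.default_rng(seed)
    K = m_true.shape[0]
    cfg = SimConfig(
        K_true=K, n_per_cluster=[n_per_group] * K, n_loci=n_loci,
        alleles_per_locus=6, drift_F=drift, admixed_fraction=0.0,
        n_dispersers=0, missing_rate=0.0, seed=int(rng.integers(2**31)),
    )
    _, _, truth = simulate_dataset(cfg)
    freqs = truth.cluster_freqs  # per locus (K, A)
    A = freqs[0].shape[1]
    sizes = 100 + 2 * np.arange(A)
    n = n_per_group * K
    calls = np.zeros((n, n_loci, 2), dtype=np.int64)
    labels = []
    i = 0
    for g in range(K):
        off = [q for q in range(K) if q != g]
        probs = [1.0 - 2 * sum(m_true[g][q] for q in off)]
        states: list[tuple[int, int]] = [(g, 0)]
        for q in off:
            probs += [m_true[g][q], m_true[g][q]]
            states += [(q, 1), (q, 2)]
        for _ in range(n_per_group):
            s_src, s_gen = states[rng.choice(len(states), p=np.asarray(probs))]
            for l in range(n_loci):
                if s_gen <= 1:
                    draw_from = s_src
                    calls[i, l] = sizes[rng.choice(A, size=2, p=freqs[l][draw_from])]
                else:
                    calls[i, l, 0] = sizes[rng.choice(A, p=freqs[l][g])]
                    calls[i, l, 1] = sizes[rng.choice(A, p=freqs[l][s_src])]
            labels.append(str(g))
            i += 1
    table = GenotypeTable([f"m{j}" for j in range(n)],
                          [f"L{j}" for j in range(n_loci)], calls)
    return table, labels


def migration_ci_coverage(
    n_replicates: int = 20,
    m_offdiag: float = 0.08,
    n_per_group: int = 25,
    n_loci: int = 12,
    iterations: int = 1500,
    burn_in: int = 400,
    seed: int = 0,
) -> float:
    """Fraction of off-diagonal 95% CIs covering the true migration rate on
    data drawn from the model's own generative process (two groups)."""
    master = np.random.default_rng(seed)
    m_true = np.array([[1 - m_offdiag, m_offdiag], [m_offdiag, 1 - m_offdiag]])
    hits = total = 0
    for _ in range(n_replicates):
        table, labels = simulate_from_migration_model(
            m_true, n_per_group, n_loci, seed=int(master.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = fit_migration(table, labels, iterations=iterations,
                                burn_in=burn_in, thinning=3,
                                seed=int(master.integers(2**31)))
        for l, q in ((0, 1), (1, 0)):
            total += 1
            if est.m_ci_low[l, q] <= m_true[l, q] <= est.m_ci_high[l, q]:
                hits += 1
    return hits / total


def disperser_detection(
    n_seeds: int = 5, seed: int = 0
) -> tuple[list[float], list[int]]:
    """Recall and false-positive counts of the disperser detector on
    wolf-shaped simulations with 7 planted dispersers (true memberships)."""
    master = np.random.default_rng(seed)
    recalls, fps = [], []
    for _ in range(n_seeds):
        cfg = SimConfig(seed=int(master.integers(2**31)))
        table, metadata, truth = simulate_dataset(cfg)
        qm = _truth_qmatrix(table, truth)
        part = classify_individuals(qm, detect_cutoffs(qm))
        geom = build_group_polygons(part, metadata)
        detected = {d.sample_id for d in geom.dispersers}
        planted = {table.sample_ids[i] for i in np.flatnonzero(truth.is_disperser)}
        recalls.append(len(detected & planted) / len(planted))
        fps.append(len(detected - planted))
    return recalls, fps


def telemetry_overlap_exactness(n_seeds: int = 5, seed: int = 0) -> list[bool]:
    """Whether the overlap counter flags exactly the planted excursion
    animals, per seed (85 collars, expected 2 excursions)."""
    master = np.random.default_rng(seed)
    out = []
    for _ in range(n_seeds):
        cfg = SimConfig(seed=int(master.integers(2**31)))
        table, metadata, truth = simulate_dataset(cfg)
        qm = _truth_qmatrix(table, truth)
        part = classify_individuals(qm, detect_cutoffs(qm))
        geom = build_group_polygons(part, metadata)
        tracks, planted = simulate_tracks(
            truth, min(85, table.n_samples), excursion_rate=2 / 85,
            seed=int(master.integers(2**31)), return_truth=True,
        )
        overlap = track_mcp_overlap(tracks, geom)
        flagged = set(overlap.index[overlap.n_groups_overlapped > 1])
        out.append(flagged == set(planted))
    return out


def hwe_type_one_rate(
    n_tests: int = 400,
    n_individuals: int = 25,
    n_alleles: int = 4,
    reps: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the Monte-Carlo HWE test on data simulated under
    exact Hardy-Weinberg proportions."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_tests):
        p = rng.dirichlet(np.ones(n_alleles) * 2)
        geno = rng.choice(n_alleles, size=(n_individuals, 2), p=p)
        pval = hwe_exact_test(geno, n_alleles, reps=reps,
                              seed=int(rng.integers(2**31)))
        if pval <= alpha:
            rejections += 1
    return rejections / n_tests


def mantel_null_pvalues(
    n_runs: int = 120, n: int = 20, n_perm: int = 199, seed: int = 0
) -> np.ndarray:
    """Mantel p-values for independent random distance matrices (null)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_runs):
        a = rng.random((n, 2))
        b = rng.random((n, 2))
        da = np.hypot(a[:, None, 0] - a[None, :, 0], a[:, None, 1] - a[None, :, 1])
        db = np.hypot(b[:, None, 0] - b[None, :, 0], b[:, None, 1] - b[None, :, 1])
        _, p = mantel_test(da, db, n_perm=n_perm, seed=int(rng.integers(2**31)))
        out.append(p)
    return np.asarray(out)
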