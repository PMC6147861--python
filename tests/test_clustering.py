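"""Replicate alignment, Evanno table, hierarchical and DAPC clustering."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lupine import (
    QMatrix,
    SimConfig,
    align_replicates,
    dapc_partition,
    evanno_table,
    hierarchical_partition,
    simulate_dataset,
)


def _qm(q, K=None):
    q = np.asarray(q, dtype=float)
    return QMatrix(K=K or q.shape[1], q=q, ln_prob_data=-100.0,
                   sample_ids=[f"s{i}" for i in range(len(q))])


def test_planted_permutation_recovered_exactly():
    rng = np.random.default_rng(0)
    q = rng.dirichlet(np.full(4, 0.3), size=30)
    perm = np.array([2, 3, 1, 0])
    runs = [_qm(q), _qm(q[:, perm])]
    perms, avg, similarity = align_replicates(runs)
    assert np.allclose(runs[1].q[:, perms[1]], q)
    assert similarity == pytest.approx(1.0)
    assert np.allclose(avg.q, q)


def test_mirrored_k2_runs_align():
    rng = np.random.default_rng(1)
    q = rng.dirichlet(np.ones(2), size=20)
    runs = [_qm(q), _qm(1 - q)]  # column swap == mirroring for K=2
    _, _, similarity = align_replicates(runs)
    assert similarity == pytest.approx(1.0)


@given(seed=st.integers(0, 500))
def test_alignment_invariant_under_any_permutation(seed):
    rng = np.random.default_rng(seed)
    K = int(rng.integers(2, 5))
    q = rng.dirichlet(np.full(K, 0.4), size=15)
    perm = rng.permutation(K)
    _, avg, similarity = align_replicates([_qm(q), _qm(q[:, perm])])
    assert similarity == pytest.approx(1.0)
    assert np.allclose(avg.q, q, atol=1e-12)


def test_noisy_replicates_average_back_to_source():
    rng = np.random.default_rng(2)
    q = rng.dirichlet(np.full(3, 0.5), size=40)
    runs = []
    for j in range(20):
        noisy = np.maximum(q + rng.normal(0, 0.005, q.shape), 1e-9)
        noisy /= noisy.sum(axis=1, keepdims=True)
        # alignment is relative to the first run, so keep it unpermuted
        perm = np.arange(3) if j == 0 else rng.permutation(3)
        runs.append(_qm(noisy[:, perm]))
    _, avg, _ = align_replicates(runs)
    assert np.abs(avg.q - q).max() < 1e-2


def test_mismatched_k_rejected():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError, match="mismatched K"):
        align_replicates([
            _qm(rng.dirichlet(np.ones(2), size=5)),
            _qm(rng.dirichlet(np.ones(3), size=5)),
        ])


def test_evanno_hand_computation():
    s2 = np.sqrt(2.0)
    ln = {
        1: [-1000.0, -1000.0],
        2: [-800 + s2, -800 - s2],  # mean -800, sd 2
        3: [-750 + s2, -750 - s2],
        4: [-745.0, -745.0],
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ev = evanno_table(ln)
    assert ev.l_prime[1:].tolist() == pytest.approx([200.0, 50.0, 5.0])
    assert ev.l_double_prime[1] == pytest.approx(150.0)
    assert ev.delta_k[1] == pytest.approx(75.0)
    assert np.isnan(ev.delta_k[0]) and np.isnan(ev.delta_k[-1])
    assert ev.best_k() == 2


def test_identical_lnp_all_flagged():
    ln = {k: [-500.0, -500.0] for k in range(1, 5)}
    with pytest.warns(UserWarning, match="zero replicate sd"):
        ev = evanno_table(ln)
    inner = ev.delta_k[1:-1]
    assert np.all(np.isinf(inner))
    assert ev.flags


def test_non_contiguous_k_rejected():
    with pytest.raises(ValueError, match="contiguous"):
        evanno_table({1: [-10.0], 3: [-8.0]})


def test_hierarchical_single_population_is_a_leaf():
    cfg = SimConfig(K_true=1, n_per_cluster=[24], n_loci=10, alleles_per_locus=5,
                    admixed_fraction=0.0, n_dispersers=0, missing_rate=0.0, seed=4)
    table, _, _ = simulate_dataset(cfg)
    root, flat = hierarchical_partition(table, k_max_per_level=3, replicates=2,
                                        iterations=800, burn_in=250, seed=0)
    assert root.depth() == 0
    assert set(flat.values()) == {0}


def test_hierarchical_recovers_nested_structure():
    """Two macro-clusters each split in two (drift 0.1 within, 0.25 between):
    the leaf partition matches the 4 true groups (adjusted Rand >= 0.8)."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(5)
    # nested F-model: macro ancestral -> macro clusters -> sub-clusters
    L, A, n_sub = 14, 5, 12
    anc = rng.dirichlet(np.ones(A), size=L)
    calls = np.zeros((4 * n_sub, L, 2), dtype=np.int64)
    truth = np.repeat(np.arange(4), n_sub)
    macro_freqs = []
    for m in range(2):
        macro_freqs.append(np.stack([
            rng.dirichlet(anc[l] * (1 - 0.25) / 0.25) for l in range(L)
        ]))
    sub_freqs = []
    for s in range(4):
        macro = macro_freqs[s // 2]
        sub_freqs.append(np.stack([
            rng.dirichlet(macro[l] * (1 - 0.1) / 0.1) for l in range(L)
        ]))
    for i in range(4 * n_sub):
        f = sub_freqs[truth[i]]
        for l in range(L):
            calls[i, l] = rng.choice(A, size=2, p=f[l]) + 100
    from lupine import GenotypeTable

    table = GenotypeTable([f"s{i}" for i in range(4 * n_sub)],
                          [f"L{j}" for j in range(L)], calls)
    _, flat = hierarchical_partition(table, k_max_per_level=3, replicates=2,
                                     iterations=1200, burn_in=400, seed=1,
                                     min_subset=6)
    labels = [flat[s] for s in table.sample_ids]
    assert adjusted_rand_score(truth, labels) >= 0.8


def test_dapc_separable_clusters():
    cfg = SimConfig(K_true=2, n_per_cluster=[20, 20], n_loci=20,
                    alleles_per_locus=5, drift_F=0.4, admixed_fraction=0.0,
                    n_dispersers=0, missing_rate=0.0, seed=6)
    table, _, truth = simulate_dataset(cfg)
    # retain most PCs: in high dimension splitting noise barely reduces WSS,
    # so the BIC bottoms out at the true K (with few PCs it keeps decreasing)
    res = dapc_partition(table, n_pcs=30, k_range=range(1, 6), seed=0)
    assert res.best_k == 2
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth.true_cluster, res.assignment) == 1.0
    assert res.membership.shape == (40, 2)


def test_dapc_single_k():
    cfg = SimConfig(K_true=1, n_per_cluster=[15], n_loci=8, alleles_per_locus=4,
                    admixed_fraction=0.0, n_dispersers=0, missing_rate=0.1, seed=7)
    table, _, _ = simulate_dataset(cfg)
    res = dapc_partition(table, n_pcs=5, k_range=[1], seed=0)
    assert res.best_k == 1
    assert np.all(res.assignment == 0)


def test_dapc_wolf_shaped_bic_bottoms_in_plausible_range(wolf_shaped):
    _, table, _, truth = wolf_shaped
    res = dapc_partition(table, n_pcs=60, k_range=range(1, 16), seed=0)
    assert 6 <= res.best_k <= 15
    # BIC decreases steeply early, then flattens near the optimum
    bic = res.bic
    assert bic[2] < bic[1]
    assert bic[res.best_k] <= bic[2]
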