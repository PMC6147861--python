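"""Population-genetic statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lupine import (
    GenotypeTable,
    diversity_summary,
    hwe_ld_tests,
    mantel_test,
    pairwise_differentiation,
    rarefied_richness,
    relatedness_matrix,
    wc_theta,
)
from lupine.popgen import hwe_exact_test, pair_relatedness


def _table(genos, locus_count=None):
    """Build a table from per-individual lists of (a, b) tuples."""
    calls = np.array(genos)
    return GenotypeTable([f"s{i}" for i in range(len(genos))],
                         [f"L{j}" for j in range(calls.shape[1])], calls)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_he_closed_form_half():
    # one locus with allele frequencies (0.5, 0.5)
    t = _table([[(1, 1)], [(2, 2)], [(1, 2)], [(2, 1)]])
    div = diversity_summary(t, ["g"] * 4)
    assert div.loc["g", "He"] == pytest.approx(0.5)


def test_monomorphic_group_has_no_f():
    t = _table([[(1, 1)], [(1, 1)], [(1, 1)]])
    div = diversity_summary(t, ["g"] * 3)
    assert div.loc["g", "He"] == 0.0
    assert div.loc["g", "Ho"] == 0.0
    assert np.isnan(div.loc["g", "F"])


def _oracle_he_ho(genos):
    """Scalar brute-force He/Ho over loci for one group."""
    L = len(genos[0])
    hes, hos = [], []
    for l in range(L):
        alleles = [a for g in genos for a in g[l] if a >= 0]
        if not alleles:
            continue
        freqs = {a: alleles.count(a) / len(alleles) for a in set(alleles)}
        hes.append(1 - sum(p**2 for p in freqs.values()))
        obs = [g[l] for g in genos if g[l][0] >= 0]
        hos.append(sum(1 for a, b in obs if a != b) / len(obs))
    return float(np.mean(hos)), float(np.mean(hes))


def test_diversity_matches_bruteforce_oracle():
    genos = [
        [(100, 102), (140, 144)],
        [(100, 100), (140, 140)],
        [(102, 104), (144, 144)],
        [(104, 104), (140, 144)],
    ]
    t = _table(genos)
    div = diversity_summary(t, ["g"] * 4)
    ho, he = _oracle_he_ho(genos)
    assert div.loc["g", "Ho"] == pytest.approx(ho)
    assert div.loc["g", "He"] == pytest.approx(he)


def test_diversity_invariant_to_allele_relabelling_and_order():
    rng = np.random.default_rng(3)
    calls = rng.choice([100, 102, 104], size=(8, 3, 2))
    t1 = GenotypeTable([f"s{i}" for i in range(8)], list("ABC"), calls)
    relabel = {100: 7, 102: 350, 104: 41}
    calls2 = np.vectorize(relabel.get)(calls)
    t2 = GenotypeTable([f"s{i}" for i in range(8)], list("ABC"), calls2)
    labels = ["x"] * 4 + ["y"] * 4
    d1 = diversity_summary(t1, labels)
    d2 = diversity_summary(t2, labels)
    assert np.allclose(d1[["Ho", "He", "uHe"]], d2[["Ho", "He", "uHe"]])
    perm = rng.permutation(8)
    t3 = t1.subset([t1.sample_ids[i] for i in perm])
    d3 = diversity_summary(t3, [labels[i] for i in perm])
    assert np.allclose(d1[["Ho", "He"]], d3[["Ho", "He"]])


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def _enumerate_ar_par(group_copies: dict[str, list[int]], g: int):
    """Exhaustive AR/pAR by enumerating every g-subset of gene copies."""
    present_prob = {}
    for name, copies in group_copies.items():
        n = len(copies)
        subsets = list(itertools.combinations(range(n), g))
        alleles = set(copies)
        present_prob[name] = {
            a: sum(any(copies[i] == a for i in s) for s in subsets) / len(subsets)
            for a in alleles
        }
    ar = {name: sum(pp.values()) for name, pp in present_prob.items()}
    par = {}
    for name in group_copies:
        total = 0.0
        for a, p in present_prob[name].items():
            absent_elsewhere = 1.0
            for other, pp in present_prob.items():
                if other != name:
                    absent_elsewhere *= 1.0 - pp.get(a, 0.0)
            total += p * absent_elsewhere
        par[name] = total
    return ar, par


def test_ar_par_two_group_toy_vs_enumeration():
    # group A alleles {a:6, b:2}, group B {a:8}, one locus, g=4
    ga = [[(1, 1)]] * 3 + [[(2, 2)]]  # 6 copies of 1, 2 copies of 2
    gb = [[(1, 1)]] * 4
    t = _table(ga + gb)
    labels = ["A"] * 4 + ["B"] * 4
    out = rarefied_richness(t, labels, g=4)
    ar, par = _enumerate_ar_par({"A": [1] * 6 + [2] * 2, "B": [1] * 8}, g=4)
    assert out.loc["A", "AR"] == pytest.approx(ar["A"])
    assert out.loc["B", "AR"] == pytest.approx(ar["B"])
    assert out.loc["A", "pAR"] == pytest.approx(par["A"])
    assert out.loc["B", "pAR"] == pytest.approx(par["B"])


def test_ar_identities():
    t = _table([[(1, 2)], [(2, 3)], [(1, 3)]])
    # g = N: AR equals the observed allele count
    out = rarefied_richness(t, ["g"] * 3, g=6)
    assert out.loc["g", "AR"] == pytest.approx(3.0)
    # g = 1: one copy shows exactly one allele
    out1 = rarefied_richness(t, ["g"] * 3, g=1)
    assert out1.loc["g", "AR"] == pytest.approx(1.0)


@given(st.data())
def test_ar_par_random_tables_vs_enumeration(data):
    rng_seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(rng_seed)
    nA = int(rng.integers(2, 4))
    nB = int(rng.integers(2, 4))
    calls = rng.choice([1, 2, 3], size=(nA + nB, 1, 2))
    t = GenotypeTable([f"s{i}" for i in range(nA + nB)], ["L0"], calls)
    labels = ["A"] * nA + ["B"] * nB
    g = int(rng.integers(1, 2 * min(nA, nB) + 1))
    out = rarefied_richness(t, labels, g=g)
    copies = {
        "A": [int(a) for row in calls[:nA, 0] for a in row],
        "B": [int(a) for row in calls[nA:, 0] for a in row],
    }
    ar, par = _enumerate_ar_par(copies, g)
    for name in ("A", "B"):
        assert out.loc[name, "AR"] == pytest.approx(ar[name], abs=1e-9)
        assert out.loc[name, "pAR"] == pytest.approx(par[name], abs=1e-9)


# ---------------------------------------------------------------------------
# Lynch-Ritland relatedness
# ---------------------------------------------------------------------------

def test_identical_genotypes_have_r_one():
    rng = np.random.default_rng(1)
    calls = rng.choice([1, 2, 3, 4], size=(1, 10, 2))
    dup = np.concatenate([calls, calls], axis=0)
    # a background group so reference frequencies are not degenerate
    bg = rng.choice([1, 2, 3, 4], size=(6, 10, 2))
    t = GenotypeTable([f"s{i}" for i in range(8)], [f"L{j}" for j in range(10)],
                      np.concatenate([dup, bg], axis=0))
    mats, _ = relatedness_matrix(t, ["g"] * 8)
    assert mats["g"].iloc[0, 1] == pytest.approx(1.0)


def test_unrelated_sample_mean_near_zero():
    means = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(np.ones(5), size=12)
        calls = np.stack(
            [rng.choice(5, size=(60, 2), p=freqs[l]) for l in range(12)], axis=1
        )
        t = GenotypeTable([f"s{i}" for i in range(60)], [f"L{j}" for j in range(12)],
                          calls + 100)
        _, m = relatedness_matrix(t, ["g"] * 60)
        means.append(m["g"])
    # group-referenced estimator centres unrelated pairs near -1/(n-1)
    assert abs(np.mean(means) + 1 / 59) < 0.02


def test_parent_offspring_relatedness_near_half():
    rng = np.random.default_rng(7)
    L, A = 20, 6
    freqs = rng.dirichlet(np.ones(A), size=L)
    vals = []
    n_pairs = 40
    calls = np.zeros((2 * n_pairs, L, 2), dtype=int)
    for p in range(n_pairs):
        for l in range(L):
            parent = rng.choice(A, size=2, p=freqs[l])
            child = [parent[rng.integers(2)], rng.choice(A, p=freqs[l])]
            calls[2 * p, l] = parent
            calls[2 * p + 1, l] = child
    t = GenotypeTable([f"s{i}" for i in range(2 * n_pairs)],
                      [f"L{j}" for j in range(L)], calls + 100)
    codes, n_alleles, _ = t.encode()
    # reference frequencies: the generating ones, to isolate the estimator
    pad = np.zeros((L, int(n_alleles.max())))
    _, _, values = t.encode()
    for l in range(L):
        for k, v in enumerate(values[l]):
            pad[l, k] = freqs[l][int(v) - 100]
    rs = [pair_relatedness(codes[2 * p], codes[2 * p + 1], pad) for p in range(n_pairs)]
    assert np.mean(rs) == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _oracle_wc_theta(genos_by_group):
    """Direct per-locus, per-allele transcription of the 1984 variance
    components (scalar arithmetic throughout)."""
    L = len(next(iter(genos_by_group.values()))[0])
    sum_a = sum_abc = 0.0
    for l in range(L):
        pops = []
        for genos in genos_by_group.values():
            obs = [g[l] for g in genos if g[l][0] >= 0]
            if obs:
                pops.append(obs)
        r = len(pops)
        if r < 2:
            continue
        ni = [len(p) for p in pops]
        nbar = sum(ni) / r
        if nbar <= 1:
            continue
        nc = (sum(ni) - sum(x**2 for x in ni) / sum(ni)) / (r - 1)
        alleles = sorted({a for p in pops for g in p for a in g})
        for allele in alleles:
            p_i = [sum(g.count(allele) for g in pop) / (2 * n) for pop, n in zip(pops, ni)]
            h_i = [
                sum(1 for g in pop if allele in g and g[0] != g[1]) / n
                for pop, n in zip(pops, ni)
            ]
            pbar = sum(n * p for n, p in zip(ni, p_i)) / sum(ni)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ni, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ni, h_i)) / sum(ni)
            term = pbar * (1 - pbar) - (r - 1) / r * s2
            a = (nbar / nc) * (s2 - (term - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (term - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


def test_theta_matches_scalar_oracle_on_printed_fixture():
    genos_by_group = {
        "A": [[(1, 1), (3, 4)], [(1, 2), (3, 3)], [(1, 1), (4, 4)]],
        "B": [[(2, 2), (3, 3)], [(2, 2), (3, 4)], [(1, 2), (3, 3)]],
        "C": [[(1, 2), (4, 4)], [(2, 2), (4, 4)]],
    }
    genos = sum(genos_by_group.values(), [])
    t = _table(genos)
    labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 2
    codes, n_alleles, _ = t.encode()
    groups = [np.arange(3), np.arange(3, 6), np.arange(6, 8)]
    assert wc_theta(codes, n_alleles, groups) == pytest.approx(
        _oracle_wc_theta(genos_by_group)
    )


def test_fixed_alternative_alleles_maximal_differentiation():
    t = _table([[(1, 1)] * 2] * 4 + [[(2, 2)] * 2] * 4)
    labels = ["A"] * 4 + ["B"] * 4
    diff = pairwise_differentiation(t, labels, n_perm=999, seed=0)
    assert diff.phi_st.loc["A", "B"] == pytest.approx(1.0)
    assert diff.jost_d.loc["A", "B"] == pytest.approx(1.0)
    # the exact permutation p is 2/C(8,4) ~ 0.029 (only the two perfectly
    # sorted label permutations reach theta = 1)
    assert diff.p_value.loc["A", "B"] < 0.05


def test_duplicated_group_is_undifferentiated():
    # theta has a small negative O(1/n) bias on identical groups, so the
    # |theta| < 0.01 bound needs a decent per-group sample size
    rng = np.random.default_rng(5)
    calls = rng.choice([1, 2, 3], size=(100, 6, 2))
    both = np.concatenate([calls, calls], axis=0)
    t = GenotypeTable([f"s{i}" for i in range(200)], [f"L{j}" for j in range(6)], both)
    labels = ["A"] * 100 + ["B"] * 100
    diff = pairwise_differentiation(t, labels, n_perm=199, seed=1)
    assert abs(diff.phi_st.loc["A", "B"]) < 0.01
    assert diff.p_value.loc["A", "B"] > 0.05


def test_theta_monotone_in_drift():
    from lupine import SimConfig, simulate_dataset

    thetas = []
    for drift in (0.05, 0.15, 0.3):
        vals = []
        for seed in range(3):
            cfg = SimConfig(K_true=2, n_per_cluster=[25, 25], n_loci=10,
                            alleles_per_locus=5, drift_F=drift,
                            admixed_fraction=0.0, n_dispersers=0,
                            missing_rate=0.0, seed=seed)
            table, _, truth = simulate_dataset(cfg)
            codes, n_alleles, _ = table.encode()
            groups = [np.flatnonzero(truth.true_cluster == k) for k in range(2)]
            vals.append(wc_theta(codes, n_alleles, groups))
        thetas.append(np.mean(vals))
    assert thetas[0] < thetas[1] < thetas[2]


# ---------------------------------------------------------------------------
# HWE / LD
# ---------------------------------------------------------------------------

def test_all_heterozygotes_reject_hwe():
    geno = np.array([[0, 1]] * 20)
    p = hwe_exact_test(geno, A=2, reps=999, seed=0)
    assert p < 0.01


def test_duplicated_locus_shows_complete_ld():
    rng = np.random.default_rng(4)
    one = rng.choice([1, 2, 3, 4], size=(20, 1, 2))
    calls = np.concatenate([one, one], axis=1)
    t = GenotypeTable([f"s{i}" for i in range(20)], ["L1", "L2"], calls)
    _, ld = hwe_ld_tests(t, ["g"] * 20, reps=199, seed=0)
    assert ld["p"].iloc[0] <= 2 / 200  # at or near the +1-smoothing floor


def test_bonferroni_never_flags_more_than_unadjusted():
    rng = np.random.default_rng(9)
    calls = rng.choice([1, 2, 3], size=(15, 4, 2))
    t = GenotypeTable([f"s{i}" for i in range(15)], [f"L{j}" for j in range(4)], calls)
    hwe, ld = hwe_ld_tests(t, ["g"] * 15, reps=199, seed=1)
    assert hwe["significant_bonferroni"].sum() <= (hwe["p"] <= 0.05).sum()
    assert ld["significant_bonferroni"].sum() <= (ld["p"] <= 0.05).sum()


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def test_mantel_identical_matrices():
    rng = np.random.default_rng(0)
    pts = rng.random((10, 2))
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    r, p = mantel_test(d, d.copy(), n_perm=199, seed=1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 200)


def test_mantel_requires_three_individuals(tiny_table, tiny_metadata):
    from lupine import mantel_ibd

    t2 = tiny_table.subset(["W1", "W2"])
    with pytest.raises(ValueError):
        mantel_ibd(t2, tiny_metadata[:2])


def test_clustered_data_masquerades_as_ibd(wolf_shaped):
    from lupine import mantel_ibd

    _, table, metadata, _ = wolf_shaped
    sub_ids = table.sample_ids[::3]
    r, p = mantel_ibd(table.subset(sub_ids),
                      [m for m in metadata if m.sample_id in set(sub_ids)],
                      n_perm=99, seed=0)
    assert r > 0
    assert p < 0.05
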