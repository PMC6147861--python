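"""Diversity, rarefaction, relatedness, differentiation and equilibrium
statistics for grouped diploid microsatellite genotypes.

All statistics treat a missing genotype as missing at that locus only
(locus-wise deletion) and are invariant to allele relabelling and to the
order of individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import GenotypeTable, SampleMetadata


def _group_arrays(labels: list[str] | np.ndarray, sample_ids: list[str]) -> dict[str, np.ndarray]:
    labels = list(labels)
    if len(labels) != len(sample_ids):
        raise ValueError("one label per sample required")
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(str(lab), []).append(i)
    return {g: np.array(idx) for g, idx in groups.items()}


def _allele_counts(codes: np.ndarray, n_alleles: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Allele-copy counts (L, A_max) for the given individuals."""
    L = codes.shape[1]
    A = int(n_alleles.max()) if len(n_alleles) else 1
    counts = np.zeros((L, max(A, 1)))
    sub = codes[rows]  # (m, L, 2)
    obs = sub >= 0
    lidx = np.broadcast_to(np.arange(L)[None, :, None], sub.shape)
    np.add.at(counts, (lidx[obs], sub[obs]), 1.0)
    return counts


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def diversity_summary(table: GenotypeTable, labels: list[str] | np.ndarray) -> pd.DataFrame:
    """Per-group diversity: n, mean alleles/locus, Ho, He, unbiased He and the
    fixation index F = 1 - Ho/He averaged over polymorphic loci.

    Per locus, He = 1 - sum p_i^2 from the group's allele frequencies and the
    unbiased variant multiplies by 2n/(2n-1) gene copies; Ho is the fraction
    of heterozygous genotypes among non-missing ones. Loci with no data in a
    group are skipped with a warning.
    """
    codes, n_alleles, _ = table.encode()
    groups = _group_arrays(labels, table.sample_ids)
    rows = []
    for g, idx in sorted(groups.items()):
        if len(idx) < 2:
            warnings.warn(f"group {g!r}: n < 2, diversity not computed", stacklevel=2)
            continue
        counts = _allele_counts(codes, n_alleles, idx)
        copies = counts.sum(axis=1)  # non-missing gene copies per locus
        usable = copies > 0
        if not usable.all():
            warnings.warn(
                f"group {g!r}: {int((~usable).sum())} all-missing locus(es) skipped",
                stacklevel=2,
            )
        he = np.full(table.n_loci, np.nan)
        uhe = np.full(table.n_loci, np.nan)
        ho = np.full(table.n_loci, np.nan)
        n_all = np.full(table.n_loci, np.nan)
        sub = codes[idx]
        het = (sub[:, :, 0] != sub[:, :, 1]) & (sub[:, :, 0] >= 0)
        obs = sub[:, :, 0] >= 0
        for l in np.flatnonzero(usable):
            p = counts[l] / copies[l]
            he[l] = 1.0 - float((p**2).sum())
            uhe[l] = he[l] * copies[l] / (copies[l] - 1) if copies[l] > 1 else np.nan
            ho[l] = het[:, l].sum() / obs[:, l].sum()
            n_all[l] = (counts[l] > 0).sum()
        poly = usable & (he > 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f_vals = 1.0 - ho[poly] / he[poly]
        rows.append(
            {
                "group": g,
                "n": len(idx),
                "mean_alleles": float(np.nanmean(n_all)),
                "Ho": float(np.nanmean(ho)),
                "He": float(np.nanmean(he)),
                "uHe": float(np.nanmean(uhe)),
                "F": float(np.mean(f_vals)) if poly.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def _log_absent(N: float, Ni: float, g: int) -> float:
    """log of C(N-Ni, g)/C(N, g): probability that allele i misses a
    subsample of g gene copies."""
    if N - Ni < g:
        return -np.inf
    return float(
        gammaln(N - Ni + 1)
        - gammaln(N - Ni - g + 1)
        - gammaln(N + 1)
        + gammaln(N - g + 1)
    )


def rarefied_richness(
    table: GenotypeTable,
    labels: list[str] | np.ndarray,
    g: int,
) -> pd.DataFrame:
    """Rarefied allelic richness AR(g) and private allelic richness pAR(g).

    AR(g) per locus is the expected number of distinct alleles in a random
    subsample of ``g`` gene copies; pAR(g) the expected number present in the
    focal group's subsample while absent from independent g-copy subsamples
    of every other group. A locus is skipped for AR in a group whose
    non-missing copies fall below g (and for pAR when any group falls below),
    with a warning. Means are over usable loci.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    codes, n_alleles, _ = table.encode()
    groups = _group_arrays(labels, table.sample_ids)
    names = sorted(groups)
    counts = {gr: _allele_counts(codes, n_alleles, groups[gr]) for gr in names}
    copies = {gr: counts[gr].sum(axis=1) for gr in names}

    rows = []
    for gr in names:
        ar_per_locus = []
        par_per_locus = []
        skipped_ar = skipped_par = 0
        for l in range(table.n_loci):
            N = copies[gr][l]
            if N < g:
                skipped_ar += 1
                skipped_par += 1
                continue
            cl = counts[gr][l]
            present = np.flatnonzero(cl > 0)
            p_present = np.array(
                [1.0 - np.exp(_log_absent(N, cl[a], g)) for a in present]
            )
            ar_per_locus.append(float(p_present.sum()))
            if any(copies[other][l] < g for other in names if other != gr):
                skipped_par += 1
                continue
            par = 0.0
            for a, pp in zip(present, p_present):
                log_abs_elsewhere = 0.0
                for other in names:
                    if other == gr:
                        continue
                    log_abs_elsewhere += _log_absent(
                        copies[other][l], counts[other][l][a], g
                    )
                par += pp * np.exp(log_abs_elsewhere)
            par_per_locus.append(par)
        if skipped_ar or skipped_par:
            warnings.warn(
                f"group {gr!r}: {skipped_ar} locus(es) skipped for AR, "
                f"{skipped_par} for pAR (fewer than g={g} gene copies)",
                stacklevel=2,
            )
        rows.append(
            {
                "group": gr,
                "AR": float(np.mean(ar_per_locus)) if ar_per_locus else np.nan,
                "pAR": float(np.mean(par_per_locus)) if par_per_locus else np.nan,
                "loci_AR": len(ar_per_locus),
                "loci_pAR": len(par_per_locus),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def default_rarefaction_g(table: GenotypeTable, labels: list[str] | np.ndarray) -> int:
    """Rarefaction standard 'smallest sample size', read as gene copies:
    2 x the smallest group's individual count."""
    groups = _group_arrays(labels, table.sample_ids)
    return 2 * min(len(idx) for idx in groups.values())


# ---------------------------------------------------------------------------
# Lynch-Ritland relatedness
# ---------------------------------------------------------------------------

def _lr_directional(
    ax: np.ndarray, bx: np.ndarray, cy: np.ndarray, dy: np.ndarray, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Lynch-Ritland r and weight with (a,b) the reference genotype.

    freqs: (L, A) group allele frequencies. Returns (r_l, w_l) with NaN where
    the locus is uninformative (reference allele fixed) or data missing.
    """
    L = len(ax)
    li = np.arange(L)
    valid = (ax >= 0) & (cy >= 0)
    a = np.where(valid, ax, 0)
    b = np.where(valid, bx, 0)
    c = np.where(valid, cy, 0)
    d = np.where(valid, dy, 0)
    pa = freqs[li, a]
    pb = freqs[li, b]
    d_ab = (a == b).astype(float)
    num = (
        pa * ((b == c).astype(float) + (b == d).astype(float))
        + pb * ((a == c).astype(float) + (a == d).astype(float))
        - 4 * pa * pb
    )
    den = (1 + d_ab) * (pa + pb) - 4 * pa * pb
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
        w = den / (2 * pa * pb)
    bad = ~valid | (np.abs(den) < 1e-12) | ~np.isfinite(w)
    r[bad] = np.nan
    w[bad] = np.nan
    return r, w


def pair_relatedness(
    codes_x: np.ndarray, codes_y: np.ndarray, freqs: np.ndarray
) -> float:
    """Multilocus Lynch-Ritland relatedness of one pair (mean of the two
    reference orderings); codes are (L, 2) with -1 missing."""
    vals = []
    for (ga, gb) in ((codes_x, codes_y), (codes_y, codes_x)):
        r, w = _lr_directional(ga[:, 0], ga[:, 1], gb[:, 0], gb[:, 1], freqs)
        ok = np.isfinite(r) & np.isfinite(w)
        if ok.any() and np.nansum(w[ok]) > 0:
            vals.append(float(np.sum(w[ok] * r[ok]) / np.sum(w[ok])))
    return float(np.mean(vals)) if vals else np.nan


def relatedness_matrix(
    table: GenotypeTable,
    labels: list[str] | np.ndarray,
    freq_reference: str = "group",
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Within-group pairwise Lynch-Ritland relatedness.

    Reference allele frequencies come from the group's own members
    (``freq_reference='group'``, the default) or from the whole table
    (``'total'``); group-internal references centre the mean of unrelated
    pairs near -1/(n-1), total references preserve absolute relatedness of
    groups of relatives. Returns per-group pairwise matrices and the
    per-group mean over all unordered pairs.
    """
    if freq_reference not in ("group", "total"):
        raise ValueError("freq_reference must be 'group' or 'total'")
    codes, n_alleles, _ = table.encode()
    groups = _group_arrays(labels, table.sample_ids)
    total_freqs = None
    if freq_reference == "total":
        counts = _allele_counts(codes, n_alleles, np.arange(table.n_samples))
        tot = counts.sum(axis=1, keepdims=True)
        total_freqs = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
    matrices: dict[str, pd.DataFrame] = {}
    means: dict[str, float] = {}
    for gname, idx in sorted(groups.items()):
        if len(idx) < 2:
            continue
        if total_freqs is not None:
            freqs = total_freqs
        else:
            counts = _allele_counts(codes, n_alleles, idx)
            tot = counts.sum(axis=1, keepdims=True)
            freqs = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
        m = len(idx)
        mat = np.full((m, m), np.nan)
        vals = []
        for i in range(m):
            for j in range(i + 1, m):
                r = pair_relatedness(codes[idx[i]], codes[idx[j]], freqs)
                mat[i, j] = mat[j, i] = r
                if np.isfinite(r):
                    vals.append(r)
        ids = [table.sample_ids[i] for i in idx]
        matrices[gname] = pd.DataFrame(mat, index=ids, columns=ids)
        means[gname] = float(np.mean(vals)) if vals else np.nan
    return matrices, pd.Series(means, name="mean_r")


# ---------------------------------------------------------------------------
# differentiation: Weir-Cockerham theta (= AMOVA phi_ST) and Jost's D
# ---------------------------------------------------------------------------

def _wc_components(
    codes: np.ndarray, n_alleles: np.ndarray, group_rows: list[np.ndarray]
) -> tuple[float, float]:
    """Sum of Weir-Cockerham (1984) variance components over loci and alleles.

    Returns (sum_a, sum_a + sum_b + sum_c); theta = ratio. Vectorized over
    loci and alleles; loci with fewer than two groups observed, a mean sample
    size <= 1 or a non-positive n_c correction are excluded.
    """
    G = len(group_rows)
    L = codes.shape[1]
    A = int(n_alleles.max()) if len(n_alleles) else 1
    ni = np.zeros((G, L))  # individuals with data, per group x locus
    acnt = np.zeros((G, L, A))  # allele-copy counts
    hcnt = np.zeros((G, L, A))  # heterozygous carriers of each allele
    for gi, rows in enumerate(group_rows):
        sub = codes[rows]  # (m, L, 2)
        obs = sub[:, :, 0] >= 0
        ni[gi] = obs.sum(axis=0)
        lidx = np.broadcast_to(np.arange(L)[None, :, None], sub.shape)
        mask = np.broadcast_to(obs[:, :, None], sub.shape)
        np.add.at(acnt[gi], (lidx[mask], sub[mask]), 1.0)
        het = obs & (sub[:, :, 0] != sub[:, :, 1])
        hetmask = np.broadcast_to(het[:, :, None], sub.shape)
        np.add.at(hcnt[gi], (lidx[hetmask], sub[hetmask]), 1.0)

    present = ni > 0
    r_eff = present.sum(axis=0)  # (L,)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = acnt / np.maximum(2 * ni, 1)[:, :, None]
        h = hcnt / np.maximum(ni, 1)[:, :, None]
        nbar = ni.sum(axis=0) / np.maximum(r_eff, 1)
        nc = (ni.sum(axis=0) - (ni**2).sum(axis=0) / np.maximum(ni.sum(axis=0), 1)) / np.maximum(
            r_eff - 1, 1
        )
        w = ni[:, :, None]  # weights
        denom = (r_eff * nbar)[:, None]
        pbar = (w * p).sum(axis=0) / np.maximum(denom, 1e-300)  # (L, A)
        s2 = (w * (p - pbar[None, :, :]) ** 2).sum(axis=0) / np.maximum(
            ((r_eff - 1) * nbar)[:, None], 1e-300
        )
        hbar = (w * h).sum(axis=0) / np.maximum(denom, 1e-300)
        term = pbar * (1 - pbar) - ((r_eff - 1) / np.maximum(r_eff, 1))[:, None] * s2
        a_comp = (nbar / np.where(nc > 0, nc, np.nan))[:, None] * (
            s2 - (term - hbar / 4) / np.maximum(nbar - 1, 1e-300)[:, None]
        )
        b_comp = (nbar / np.maximum(nbar - 1, 1e-300))[:, None] * (
            term - ((2 * nbar - 1) / np.maximum(4 * nbar, 1e-300))[:, None] * hbar
        )
        c_comp = hbar / 2
    usable = (r_eff >= 2) & (nbar > 1) & (nc > 0)
    allele_ok = np.arange(A)[None, :] < n_alleles[:, None]
    sel = usable[:, None] & allele_ok
    sum_a = float(np.nansum(a_comp[sel]))
    sum_abc = float(np.nansum((a_comp + b_comp + c_comp)[sel]))
    return sum_a, sum_abc


def wc_theta(
    table_codes: np.ndarray, n_alleles: np.ndarray, group_rows: list[np.ndarray]
) -> float:
    """Multilocus Weir-Cockerham theta (phi_ST) for the given groups."""
    sa, sabc = _wc_components(table_codes, n_alleles, group_rows)
    return sa / sabc if sabc != 0 else np.nan


def _jost_d(
    codes: np.ndarray,
    n_alleles: np.ndarray,
    group_rows: list[np.ndarray],
    pooling: str = "arithmetic",
) -> float:
    """Jost's D with Nei-Chesser bias-corrected Hs and Ht (harmonic-mean
    sample size); per-locus D averaged arithmetically by default, or computed
    from locus-averaged Hs/Ht when pooling='mean_h'."""
    r = len(group_rows)
    L = codes.shape[1]
    d_vals, hs_vals, ht_vals = [], [], []
    for l in range(L):
        ni, p_rows, ho_rows = [], [], []
        A = int(n_alleles[l])
        for rows in group_rows:
            sub = codes[rows, l, :]
            obs = sub[:, 0] >= 0
            sub = sub[obs]
            if len(sub) == 0:
                continue
            ni.append(len(sub))
            cnt = np.bincount(sub.ravel(), minlength=A).astype(float)
            p_rows.append(cnt / (2 * len(sub)))
            ho_rows.append(float((sub[:, 0] != sub[:, 1]).mean()))
        if len(ni) < 2:
            continue
        r_eff = len(ni)
        p = np.stack(p_rows)
        n_harm = r_eff / np.sum(1.0 / np.asarray(ni, dtype=float))
        ho = float(np.mean(ho_rows))
        hs_raw = 1.0 - float(np.mean((p**2).sum(axis=1)))
        hs = (n_harm / (n_harm - 1)) * (hs_raw - ho / (2 * n_harm)) if n_harm > 1 else np.nan
        pbar = p.mean(axis=0)
        ht_raw = 1.0 - float((pbar**2).sum())
        ht = ht_raw + hs / (r_eff * n_harm) - ho / (2 * r_eff * n_harm)
        if not np.isfinite(hs) or hs >= 1:
            continue
        hs_vals.append(hs)
        ht_vals.append(ht)
        d_vals.append((r_eff / (r_eff - 1)) * (ht - hs) / (1 - hs))
    if not d_vals:
        return np.nan
    if pooling == "mean_h":
        hs_m, ht_m = float(np.mean(hs_vals)), float(np.mean(ht_vals))
        return (r / (r - 1)) * (ht_m - hs_m) / (1 - hs_m)
    return float(np.mean(d_vals))


@dataclass
class DifferentiationMatrix:
    groups: list[str]
    phi_st: pd.DataFrame
    p_value: pd.DataFrame
    jost_d: pd.DataFrame

    def mean_offdiagonal(self) -> pd.Series:
        vals = {}
        for g in self.groups:
            row = self.phi_st.loc[g].drop(g)
            vals[g] = float(row.mean())
        return pd.Series(vals, name="mean_phi_st")


def pairwise_differentiation(
    table: GenotypeTable,
    labels: list[str] | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    jost_pooling: str = "arithmetic",
) -> DifferentiationMatrix:
    """Pairwise Weir-Cockerham theta (phi_ST), permutation p-values, and
    Jost's D for every group pair.

    p-values use the +1 smoothing convention: p = (1 + #{theta_perm >=
    theta_obs}) / (n_perm + 1), so a result never reports p = 0.
    """
    codes, n_alleles, _ = table.encode()
    groups = _group_arrays(labels, table.sample_ids)
    names = []
    for g in sorted(groups):
        if len(groups[g]) < 2:
            warnings.warn(f"group {g!r}: n=1, excluded from differentiation", stacklevel=2)
        else:
            names.append(g)
    G = len(names)
    if G < 2:
        raise ValueError("at least two groups with n >= 2 required")
    rng = np.random.default_rng(seed)
    phi = np.zeros((G, G))
    pval = np.ones((G, G))
    jd = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            rows_i, rows_j = groups[names[i]], groups[names[j]]
            obs = wc_theta(codes, n_alleles, [rows_i, rows_j])
            pooled = np.concatenate([rows_i, rows_j])
            n_i = len(rows_i)
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                t = wc_theta(codes, n_alleles, [perm[:n_i], perm[n_i:]])
                if np.isfinite(t) and t >= obs:
                    exceed += 1
            p = (1 + exceed) / (n_perm + 1)
            d = _jost_d(codes, n_alleles, [rows_i, rows_j], pooling=jost_pooling)
            phi[i, j] = phi[j, i] = obs
            pval[i, j] = pval[j, i] = p
            jd[i, j] = jd[j, i] = d
    return DifferentiationMatrix(
        groups=names,
        phi_st=pd.DataFrame(phi, index=names, columns=names),
        p_value=pd.DataFrame(pval, index=names, columns=names),
        jost_d=pd.DataFrame(jd, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg and linkage-disequilibrium tests
# ---------------------------------------------------------------------------

def _log_hwe_prob(geno: np.ndarray, A: int) -> float:
    """log conditional probability of a genotype table given allele counts
    (Levene/Haldane exact distribution)."""
    n = len(geno)
    allele_counts = np.bincount(geno.ravel(), minlength=A)
    pairs = np.sort(geno, axis=1)
    _, geno_counts = np.unique(pairs, axis=0, return_counts=True)
    n_het = int((geno[:, 0] != geno[:, 1]).sum())
    return float(
        gammaln(n + 1)
        - gammaln(geno_counts + 1).sum()
        + n_het * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(geno: np.ndarray, A: int, reps: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one locus.

    ``geno``: (n, 2) allele codes, no missing rows. Gene copies are shuffled
    into random genotype tables with the same allele counts; p is the
    +1-smoothed fraction of tables no more probable than the observed one.
    """
    rng = np.random.default_rng(seed)
    obs_logp = _log_hwe_prob(geno, A)
    copies = geno.ravel().copy()
    hits = 0
    for _ in range(reps):
        rng.shuffle(copies)
        perm = copies.reshape(-1, 2)
        if _log_hwe_prob(perm, A) <= obs_logp + 1e-12:
            hits += 1
    return (1 + hits) / (reps + 1)


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """G statistic for association between two categorical vectors."""
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    obs = np.zeros((len(xs), len(ys)))
    np.add.at(obs, (xi, yi), 1.0)
    tot = obs.sum()
    exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / tot
    nz = obs > 0
    return float(2.0 * (obs[nz] * np.log(obs[nz] / exp[nz])).sum())


def hwe_ld_tests(
    table: GenotypeTable,
    labels: list[str] | np.ndarray,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    ld_pairs: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HWE (per group x locus) and LD (per group x locus pair) Monte-Carlo
    tests with Bonferroni flags within each test family.

    LD permutes one locus's genotypes across individuals of the group and
    compares the G statistic of the two-locus genotype table. Monomorphic
    loci are skipped.
    """
    codes, n_alleles, _ = table.encode()
    groups = _group_arrays(labels, table.sample_ids)
    rng = np.random.default_rng(seed)
    hwe_rows, ld_rows = [], []
    for gname, idx in sorted(groups.items()):
        sub = codes[idx]
        for l in range(table.n_loci):
            g = sub[:, l, :]
            g = g[g[:, 0] >= 0]
            if len(g) < 2 or len(np.unique(g)) < 2:
                continue
            p = hwe_exact_test(g, int(n_alleles[l]), reps=reps, seed=int(rng.integers(2**31)))
            hwe_rows.append({"group": gname, "locus": table.locus_ids[l], "p": p})
        if ld_pairs:
            for l1 in range(table.n_loci):
                for l2 in range(l1 + 1, table.n_loci):
                    both = (sub[:, l1, 0] >= 0) & (sub[:, l2, 0] >= 0)
                    if both.sum() < 4:
                        continue
                    g1 = np.sort(sub[both, l1, :], axis=1)
                    g2 = np.sort(sub[both, l2, :], axis=1)
                    c1 = g1[:, 0] * (n_alleles[l1] + 1) + g1[:, 1]
                    c2 = g2[:, 0] * (n_alleles[l2] + 1) + g2[:, 1]
                    if len(np.unique(c1)) < 2 or len(np.unique(c2)) < 2:
                        continue
                    obs = _g_statistic(c1, c2)
                    local = np.random.default_rng(int(rng.integers(2**31)))
                    hits = 0
                    for _ in range(reps):
                        if _g_statistic(c1, local.permutation(c2)) >= obs - 1e-12:
                            hits += 1
                    ld_rows.append(
                        {
                            "group": gname,
                            "locus1": table.locus_ids[l1],
                            "locus2": table.locus_ids[l2],
                            "p": (1 + hits) / (reps + 1),
                        }
                    )
    hwe = pd.DataFrame(hwe_rows)
    ld = pd.DataFrame(ld_rows)
    if len(hwe):
        hwe["significant_bonferroni"] = hwe["p"] <= alpha / len(hwe)
    if len(ld):
        ld["significant_bonferroni"] = ld["p"] <= alpha / len(ld)
    return hwe, ld


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance test
# ---------------------------------------------------------------------------

def shared_allele_distance(table: GenotypeTable) -> np.ndarray:
    """Pairwise genetic distance 1 - mean proportion of shared alleles
    (Dps); loci missing in either member of a pair are excluded."""
    codes, _, _ = table.encode()
    srt = np.sort(codes, axis=2)
    a1, a2 = srt[:, :, 0], srt[:, :, 1]  # (n, L)
    obs = a1 >= 0
    x1, y1 = a1[:, None, :], a1[None, :, :]
    x2, y2 = a2[:, None, :], a2[None, :, :]
    exact = (x1 == y1) & (x2 == y2)
    anymatch = (x1 == y1) | (x1 == y2) | (x2 == y1) | (x2 == y2)
    shared = np.where(exact, 2, np.where(anymatch, 1, 0)).astype(float)
    both = obs[:, None, :] & obs[None, :, :]
    with np.errstate(invalid="ignore"):
        prop = np.where(both, shared, 0.0).sum(axis=2) / (2.0 * both.sum(axis=2))
    dist = 1.0 - prop
    np.fill_diagonal(dist, 0.0)
    return dist


def mantel_ibd(
    table: GenotypeTable,
    metadata: list[SampleMetadata],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between shared-allele genetic distance and planar
    Euclidean geographic distance, with a one-tailed permutation p-value."""
    if table.n_samples < 3:
        raise ValueError("Mantel test requires at least 3 individuals")
    meta = {m.sample_id: m for m in metadata}
    xy = np.array([(meta[s].x, meta[s].y) for s in table.sample_ids])
    geo = np.hypot(
        xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1]
    )
    gen = shared_allele_distance(table)
    return mantel_test(gen, geo, n_perm=n_perm, seed=seed)


def mantel_test(
    d1: np.ndarray, d2: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Mantel r between two square distance matrices; one-tailed p by
    permuting rows/columns of the first matrix (+1 smoothing)."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = d1[iu], d2[iu]
    valid = np.isfinite(x) & np.isfinite(y)
    if x[valid].std() < 1e-15 or y[valid].std() < 1e-15:
        return np.nan, np.nan
    r_obs = float(np.corrcoef(x[valid], y[valid])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = d1[np.ix_(perm, perm)][iu]
        v = np.isfinite(xp) & np.isfinite(y)
        r = float(np.corrcoef(xp[v], y[v])[0, 1])
        if r >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)
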