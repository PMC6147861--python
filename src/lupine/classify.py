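"""Gap-based cut-offs on membership proportions and admixed classification.

For each cluster a cut-off is placed in the largest gap of the sorted
membership proportions of its members (a reproducible stand-in for the
visual "gap in the distribution" rule): individuals at or above the cut-off
fully belong to the cluster ("non-admixed"), individuals below it have
ancestry in more than one cluster ("admixed"), and individuals whose largest
membership does not exceed 0.5 cannot be attributed at all ("unassigned").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .admixture import QMatrix

NON_ADMIXED = "non_admixed"
ADMIXED = "admixed"
UNASSIGNED = "unassigned"


@dataclass
class CutoffResult:
    cutoffs: np.ndarray  # per-cluster cut-off in (0.5, 1)
    flags: list[str] = field(default_factory=list)  # clusters that fell back


@dataclass
class ClusterPartition:
    """Per-individual labels and per-cluster composition derived from a Q-matrix."""

    K: int
    sample_ids: list[str]
    cutoffs: np.ndarray
    home_cluster: np.ndarray  # argmax q
    labels: list[str]  # NON_ADMIXED / ADMIXED / UNASSIGNED
    q: np.ndarray
    mean_membership: np.ndarray  # (K, K): mean q of each home set vs all clusters
    flags: list[str] = field(default_factory=list)

    def admixed_counts(self) -> np.ndarray:
        out = np.zeros(self.K, dtype=int)
        for home, lab in zip(self.home_cluster, self.labels):
            if lab == ADMIXED:
                out[home] += 1
        return out

    def group_sizes(self) -> np.ndarray:
        """Members per cluster (non-admixed + admixed; unassigned excluded)."""
        out = np.zeros(self.K, dtype=int)
        for home, lab in zip(self.home_cluster, self.labels):
            if lab != UNASSIGNED:
                out[home] += 1
        return out

    def non_admixed_ids(self, cluster: int) -> list[str]:
        return [
            sid
            for sid, home, lab in zip(self.sample_ids, self.home_cluster, self.labels)
            if home == cluster and lab == NON_ADMIXED
        ]


def detect_cutoffs(
    q: QMatrix,
    min_gap: float = 0.05,
    fallback: float = 0.80,
) -> CutoffResult:
    """Place a per-cluster cut-off in the largest gap of membership values.

    For cluster k the candidate values are the q_ik of individuals whose
    largest membership is k, plus any individual with q_ik > 0.5. The values
    are sorted descending and the cut-off is the midpoint of the widest gap
    whose endpoints both exceed 0.5. Degenerate distributions (fewer than 3
    members, or no gap >= ``min_gap``) fall back to ``fallback`` and are
    flagged.
    """
    if q.K < 2:
        raise ValueError("cut-off detection requires K >= 2")
    if not 0.5 < fallback < 1:
        raise ValueError("fallback cut-off must lie in (0.5, 1)")
    home = q.home_cluster()
    cutoffs = np.full(q.K, fallback)
    flags: list[str] = []
    for k in range(q.K):
        vals = q.q[(home == k) | (q.q[:, k] > 0.5), k]
        if len(vals) < 3:
            flags.append(f"cluster {k}: <3 members, fallback cut-off {fallback}")
            continue
        vals = np.sort(vals)[::-1]
        upper = vals[:-1]
        lower = vals[1:]
        gaps = upper - lower
        eligible = (upper > 0.5) & (lower > 0.5)
        if not eligible.any() or gaps[eligible].max() < min_gap:
            flags.append(f"cluster {k}: no gap >= {min_gap}, fallback cut-off {fallback}")
            continue
        gaps = np.where(eligible, gaps, -np.inf)
        j = int(np.argmax(gaps))
        cutoffs[k] = float((upper[j] + lower[j]) / 2.0)
    return CutoffResult(cutoffs=cutoffs, flags=flags)


def classify_individuals(q: QMatrix, cutoffs: np.ndarray | CutoffResult) -> ClusterPartition:
    """Label each individual non-admixed / admixed / unassigned.

    An individual is non-admixed when its membership in its home cluster
    (argmax) reaches that cluster's cut-off, unassigned when no membership
    exceeds 0.5, admixed otherwise.
    """
    flags: list[str] = []
    if isinstance(cutoffs, CutoffResult):
        flags = list(cutoffs.flags)
        cutoffs = cutoffs.cutoffs
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.shape != (q.K,):
        raise ValueError(f"expected {q.K} cutoffs, got shape {cutoffs.shape}")
    home = q.home_cluster()
    qmax = q.q.max(axis=1)
    labels = []
    for i in range(q.n):
        if qmax[i] <= 0.5:
            labels.append(UNASSIGNED)
        elif q.q[i, home[i]] >= cutoffs[home[i]]:
            labels.append(NON_ADMIXED)
        else:
            labels.append(ADMIXED)

    mean_membership = np.full((q.K, q.K), np.nan)
    for k in range(q.K):
        members = (home == k) & (qmax > 0.5)
        if members.any():
            row = q.q[members].mean(axis=0)
            mean_membership[k] = row / row.sum()
    return ClusterPartition(
        K=q.K,
        sample_ids=list(q.sample_ids),
        cutoffs=cutoffs,
        home_cluster=home,
        labels=labels,
        q=q.q,
        mean_membership=mean_membership,
        flags=flags,
    )
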