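"""Synthetic microsatellite datasets with known cluster structure.

The generator follows the correlated-allele-frequency (F-model) generative
process: each cluster's allele frequencies drift away from shared ancestral
frequencies with cluster-specific intensity ``F_k``, individuals carry
admixture proportions ``q`` (one-hot for non-admixed individuals, Dirichlet
draws for an admixed minority), and every allele copy is sampled by first
choosing its cluster of origin from ``q`` and then an allele from that
cluster's frequencies. Territories are discs around per-cluster centroids;
planted dispersers keep a foreign one-hot ``q`` but are placed inside another
cluster's disc, giving the downstream disperser detector a known truth set.

Defaults mirror the structure of the north-west Iberian wolf dataset the
pipeline was designed around: 11 clusters of 6-53 individuals (207 total),
46 microsatellite loci, moderate drift, a minority of admixed individuals,
and rare dispersers.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .data import MISSING, GenotypeTable, SampleMetadata, TrackRecord, ValidationError

#: group sizes of the 11 fine-scale wolf clusters (Alto Minho .. E Asturias)
WOLF_GROUP_SIZES = [13, 17, 21, 12, 14, 6, 53, 30, 11, 11, 19]


def _default_centroids(k: int, radius: float, gap: float = 60.0) -> list[tuple[float, float]]:
    """Territory layout: centroids on a square grid with a fixed edge-to-edge
    gap between discs.

    The default 60 km gap keeps neighbouring territories distinct at the
    spatial-adjacency scale used downstream (50 km single-linkage), so that a
    planted disperser is, by construction, spatially separate from its own
    group's core.
    """
    cols = math.ceil(math.sqrt(k))
    spacing = 2 * radius + gap
    return [((i % cols) * spacing, (i // cols) * spacing) for i in range(k)]


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset draw."""

    K_true: int = 11
    n_per_cluster: list[int] = field(default_factory=lambda: list(WOLF_GROUP_SIZES))
    n_loci: int = 46
    alleles_per_locus: int = 6
    drift_F: float | list[float] = 0.2
    admixture_alpha: float = 0.3
    admixed_fraction: float = 0.3
    n_dispersers: int = 7
    territory_centroids: list[tuple[float, float]] | None = None
    territory_radius: float = 40.0
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValidationError("K_true must be >= 1")
        if len(self.n_per_cluster) != self.K_true:
            raise ValidationError("n_per_cluster length must equal K_true")
        if any(n < 1 for n in self.n_per_cluster):
            raise ValidationError("cluster sizes must be >= 1")
        drift = self.drift_vector()
        if not np.all((drift > 0) & (drift < 1)):
            raise ValidationError("drift_F must lie in (0, 1)")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValidationError("missing_rate must lie in [0, 0.5]")
        if self.n_dispersers > 0 and self.K_true < 2:
            raise ValidationError("dispersers require at least two clusters")
        if self.territory_centroids is None:
            self.territory_centroids = _default_centroids(self.K_true, self.territory_radius)
        if len(self.territory_centroids) != self.K_true:
            raise ValidationError("territory_centroids length must equal K_true")
        if len({tuple(c) for c in self.territory_centroids}) != self.K_true:
            raise ValidationError("territory centroids must be pairwise distinct")

    def drift_vector(self) -> np.ndarray:
        if np.isscalar(self.drift_F):
            return np.full(self.K_true, float(self.drift_F))
        return np.asarray(self.drift_F, dtype=float)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset (for recovery tests)."""

    ancestral_freqs: list[np.ndarray]  # per locus (A,)
    cluster_freqs: list[np.ndarray]  # per locus (K, A)
    true_q: np.ndarray  # (n, K)
    true_cluster: np.ndarray  # (n,) argmax cluster of origin
    is_disperser: np.ndarray  # (n,) bool
    host_cluster: np.ndarray  # (n,) disc the individual lives in
    territory_polygons: list[Polygon]
    centroids: list[tuple[float, float]]
    territory_radius: float


def _disc_point(rng: np.random.Generator, cx: float, cy: float, radius: float) -> tuple[float, float]:
    r = radius * math.sqrt(rng.random())
    theta = rng.random() * 2 * math.pi
    return cx + r * math.cos(theta), cy + r * math.sin(theta)


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeTable, list[SampleMetadata], SimTruth]:
    """Draw one dataset from the F-model generative process.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    K, L, A = config.K_true, config.n_loci, config.alleles_per_locus
    drift = config.drift_vector()
    n = int(sum(config.n_per_cluster))

    ancestral = [rng.dirichlet(np.ones(A)) for _ in range(L)]
    cluster_freqs = []
    for l in range(L):
        rows = np.empty((K, A))
        for k in range(K):
            rows[k] = rng.dirichlet(ancestral[l] * (1 - drift[k]) / drift[k])
        cluster_freqs.append(rows)

    centroids_arr = np.asarray(config.territory_centroids, dtype=float)
    true_cluster = np.repeat(np.arange(K), config.n_per_cluster)
    true_q = np.zeros((n, K))
    admixed = rng.random(n) < config.admixed_fraction
    for i in range(n):
        if admixed[i] and K > 1:
            # admixed ancestry: dominant home component (mean ~0.6) with the
            # external mass biased toward the geographically nearest cluster,
            # emulating admixture between parapatric neighbours
            home = true_cluster[i]
            alpha = np.full(K, config.admixture_alpha)
            alpha[home] += 9.0
            d = np.hypot(*(centroids_arr - centroids_arr[home]).T)
            d[home] = np.inf
            alpha[int(np.argmin(d))] += 2.0
            true_q[i] = rng.dirichlet(alpha)
        else:
            true_q[i, true_cluster[i]] = 1.0

    # plant dispersers among the non-admixed
    is_disperser = np.zeros(n, dtype=bool)
    host_cluster = true_cluster.copy()
    if config.n_dispersers:
        eligible = np.flatnonzero(~admixed)
        if len(eligible) < config.n_dispersers:
            raise ValidationError("not enough non-admixed individuals to plant dispersers")
        chosen = rng.choice(eligible, size=config.n_dispersers, replace=False)
        for i in chosen:
            others = [k for k in range(K) if k != true_cluster[i]]
            host_cluster[i] = rng.choice(others)
            is_disperser[i] = True

    # genotypes: cluster of origin per allele copy, then allele
    calls = np.empty((n, L, 2), dtype=np.int64)
    allele_sizes = 100 + 2 * np.arange(A)
    for l in range(L):
        origins = np.array(
            [[rng.choice(K, p=true_q[i]) for _ in range(2)] for i in range(n)]
        )
        u = rng.random((n, 2))
        cum = np.cumsum(cluster_freqs[l], axis=1)
        codes = (cum[origins] < u[:, :, None]).sum(axis=2)
        calls[:, l, :] = allele_sizes[codes]

    sample_ids = [f"W{i + 1:03d}" for i in range(n)]
    locus_ids = [f"FH{l + 1:02d}" for l in range(L)]
    table = GenotypeTable(sample_ids, locus_ids, calls)
    if config.missing_rate > 0:
        table = inject_missing(table, config.missing_rate, int(rng.integers(2**31)))

    centroids = [tuple(map(float, c)) for c in config.territory_centroids]
    base_date = _dt.date(1995, 1, 1)
    metadata = []
    for i in range(n):
        cx, cy = centroids[host_cluster[i]]
        x, y = _disc_point(rng, cx, cy, config.territory_radius)
        metadata.append(
            SampleMetadata(
                sample_ids[i],
                sex="F" if rng.random() < 0.5 else "M",
                age_class="adult" if rng.random() < 0.6 else "juvenile",
                collection_date=base_date + _dt.timedelta(days=int(rng.integers(0, 7300))),
                x=x,
                y=y,
            )
        )

    territories = [Point(c).buffer(config.territory_radius, quad_segs=32) for c in centroids]
    truth = SimTruth(
        ancestral_freqs=ancestral,
        cluster_freqs=cluster_freqs,
        true_q=true_q,
        true_cluster=true_cluster,
        is_disperser=is_disperser,
        host_cluster=host_cluster,
        territory_polygons=territories,
        centroids=centroids,
        territory_radius=config.territory_radius,
    )
    return table, metadata, truth


def simulate_tracks(
    truth: SimTruth,
    n_collars: int,
    locations_per_animal: int = 50,
    excursion_rate: float = 0.0,
    seed: int = 0,
    return_truth: bool = False,
) -> list[TrackRecord] | tuple[list[TrackRecord], list[str]]:
    """Simulate collar tracks confined to each animal's home territory.

    With probability ``excursion_rate`` an animal also receives a batch of
    locations inside the geographically nearest other territory, to exercise
    the downstream overlap counter. With ``return_truth=True`` the ids of the
    animals that received an excursion are returned alongside the tracks.
    """
    n = len(truth.true_cluster)
    if n_collars > n:
        raise ValidationError(f"n_collars={n_collars} exceeds {n} individuals")
    if not 0 <= excursion_rate <= 1:
        raise ValidationError("excursion_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    animals = rng.choice(n, size=n_collars, replace=False)
    centroids = np.asarray(truth.centroids)
    tracks = []
    excursion_ids: list[str] = []
    base_date = _dt.date(2005, 1, 1)
    for idx, i in enumerate(animals):
        home = truth.host_cluster[i]
        cx, cy = truth.centroids[home]
        n_loc = locations_per_animal
        points = [_disc_point(rng, cx, cy, truth.territory_radius) for _ in range(n_loc)]
        if len(centroids) > 1 and rng.random() < excursion_rate:
            excursion_ids.append(f"C{idx + 1:03d}")
            dists = np.hypot(*(centroids - centroids[home]).T)
            dists[home] = np.inf
            neighbour = int(np.argmin(dists))
            nx, ny = truth.centroids[neighbour]
            n_exc = max(3, n_loc // 5)
            points += [_disc_point(rng, nx, ny, truth.territory_radius) for _ in range(n_exc)]
        locations = [
            (base_date + _dt.timedelta(days=j), float(x), float(y))
            for j, (x, y) in enumerate(points)
        ]
        tracks.append(
            TrackRecord(
                f"C{idx + 1:03d}",
                locations,
                collar_type="GPS" if rng.random() < 0.65 else "VHF",
            )
        )
    if return_truth:
        return tracks, excursion_ids
    return tracks


def inject_missing(table: GenotypeTable, rate: float, seed: int = 0) -> GenotypeTable:
    """Set each genotype call missing independently with probability ``rate``."""
    if not 0 <= rate <= 0.5:
        raise ValidationError(f"missing rate {rate} outside [0, 0.5]")
    if rate == 0:
        return GenotypeTable(list(table.sample_ids), list(table.locus_ids), table.calls.copy())
    rng = np.random.default_rng(seed)
    calls = table.calls.copy()
    mask = rng.random((table.n_samples, table.n_loci)) < rate
    calls[mask] = MISSING
    return GenotypeTable(list(table.sample_ids), list(table.locus_ids), calls)
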