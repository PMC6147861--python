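"""Relative-avoidance and quality filters for building an analysis sample set.

Samples collected close together in space (closer than a pair distance, or
inside the same circular pack buffer) likely come from the same pack; to
avoid close family structure, at most ``max_per_window`` samples are kept per
multi-year temporal window within each spatial conflict set, preferring
adults, then lower missingness, then earlier collection. Samples with too
much missing genotype data are dropped first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import GenotypeTable, SampleMetadata, ValidationError, metadata_index

#: fixed epoch for window binning: keeps windows stable under re-runs
_EPOCH_YEAR = 1900


@dataclass
class SelectionParams:
    pack_buffer_area: float = 100.0  # km^2, circular buffer around pack centroids
    pair_distance_km: float = 10.0
    window_years: int = 5
    max_per_window: int = 2
    max_missing: float = 0.20
    annual_cycle_start_month: int = 5  # May-to-May annual cycle
    mode: str = "window"  # or "pairwise"

    def __post_init__(self) -> None:
        for name in ("pack_buffer_area", "pair_distance_km", "window_years", "max_per_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.max_missing < 1:
            raise ValidationError("max_missing must lie in (0, 1)")
        if not 1 <= self.annual_cycle_start_month <= 12:
            raise ValidationError("annual_cycle_start_month must be a month number")
        if self.mode not in ("window", "pairwise"):
            raise ValidationError("mode must be 'window' or 'pairwise'")

    @property
    def buffer_radius_km(self) -> float:
        return math.sqrt(self.pack_buffer_area / math.pi)


def _cycle_year(date, start_month: int) -> int:
    """Year of the annual cycle the date falls in (cycles run start-month to
    start-month)."""
    return date.year if date.month >= start_month else date.year - 1


def select_samples(
    genotypes: GenotypeTable,
    metadata: list[SampleMetadata],
    pack_centroids: list[tuple[float, float]] | None = None,
    params: SelectionParams | None = None,
    user_excluded: set[str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Apply the quality and relative-avoidance filters.

    Returns the kept sample ids (in input order) and a machine-readable
    exclusion reason for every dropped sample. Samples lacking metadata are
    excluded with an error reason, never silently dropped. The result is
    independent of input order and idempotent (re-running on the kept set
    removes nothing).
    """
    params = params or SelectionParams()
    pack_centroids = pack_centroids or []
    user_excluded = user_excluded or set()
    meta = metadata_index(metadata)
    reasons: dict[str, str] = {}
    missing_frac = dict(zip(genotypes.sample_ids, genotypes.missing_fraction()))

    candidates: list[str] = []
    for sid in genotypes.sample_ids:
        if sid in user_excluded:
            reasons[sid] = "user_excluded"
        elif sid not in meta:
            reasons[sid] = "metadata_error:no_record"
        elif meta[sid].collection_date is None:
            reasons[sid] = "metadata_error:no_collection_date"
        elif missing_frac[sid] > params.max_missing:
            reasons[sid] = f"missing>{params.max_missing:.2f}"
        else:
            candidates.append(sid)

    # conflict sets: single linkage over spatial conflicts
    idx = {sid: i for i, sid in enumerate(candidates)}
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    xy = np.array([(meta[s].x, meta[s].y) for s in candidates]).reshape(-1, 2)
    r_buf = params.buffer_radius_km
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if np.hypot(*(xy[i] - xy[j])) < params.pair_distance_km:
                union(i, j)
    for cx, cy in pack_centroids:
        inside = [
            i for i in range(len(candidates))
            if np.hypot(xy[i, 0] - cx, xy[i, 1] - cy) <= r_buf
        ]
        for a, b in zip(inside, inside[1:]):
            union(a, b)

    sets: dict[int, list[str]] = {}
    for sid in candidates:
        sets.setdefault(find(idx[sid]), []).append(sid)

    kept: set[str] = set()
    for members in sets.values():
        if len(members) == 1:
            kept.add(members[0])
            continue
        # total preference order: adults first, then low missingness,
        # then earliest date, then id (for determinism)
        def rank(sid: str):
            m = meta[sid]
            return (
                0 if m.age_class == "adult" else 1,
                missing_frac[sid],
                m.collection_date,
                sid,
            )

        ordered = sorted(members, key=rank)
        if params.mode == "window":
            taken: dict[int, int] = {}
            for sid in ordered:
                cy = _cycle_year(meta[sid].collection_date, params.annual_cycle_start_month)
                win = (cy - _EPOCH_YEAR) // params.window_years
                if taken.get(win, 0) < params.max_per_window:
                    kept.add(sid)
                    taken[win] = taken.get(win, 0) + 1
                else:
                    reasons[sid] = "window_quota"
        else:  # pairwise: a kept sample blocks others within window_years
            chosen: list[str] = []
            for sid in ordered:
                cy = _cycle_year(meta[sid].collection_date, params.annual_cycle_start_month)
                near = [
                    s for s in chosen
                    if abs(_cycle_year(meta[s].collection_date, params.annual_cycle_start_month) - cy)
                    < params.window_years
                ]
                if len(near) < params.max_per_window:
                    chosen.append(sid)
                else:
                    reasons[sid] = "pairwise_quota"
            kept.update(chosen)

    kept_ordered = [s for s in genotypes.sample_ids if s in kept]
    # every input sample is either kept or carries a reason
    assert len(kept_ordered) + len(reasons) == genotypes.n_samples
    return kept_ordered, reasons
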