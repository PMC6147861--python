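"""Core in-memory data model for diploid microsatellite datasets.

Genotypes are unordered pairs of integer allele sizes (fragment lengths in
base pairs, as scored on a capillary sequencer). A genotype is either fully
observed (two non-negative integers) or wholly missing; half-missing calls
are not representable and are coerced to missing on input.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: sentinel used internally for a missing allele copy
MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


class ValidationError(ValueError):
    """Raised when a record set violates a data-model invariant."""


@dataclass
class GenotypeTable:
    """Individuals x loci table of diploid allele-size calls.

    Parameters
    ----------
    sample_ids
        Unique, ordered sample identifiers (one per individual).
    locus_ids
        Unique, ordered locus identifiers.
    calls
        Integer array of shape ``(n_samples, n_loci, 2)``; allele sizes are
        non-negative, missing genotypes hold :data:`MISSING` in both slots.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    ploidy: int = field(default=2, init=False, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(loc) for loc in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci x 2"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus_ids")
        # half-missing genotypes are coerced to wholly missing
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            self.calls = self.calls.copy()
            self.calls[half] = MISSING
        if (self.calls < MISSING).any():
            raise ValidationError("allele sizes must be non-negative integers")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) mask of missing genotypes."""
        return self.calls[:, :, 0] == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing genotypes, in [0, 1]."""
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def subset(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeTable(list(sample_ids), list(self.locus_ids), self.calls[rows])

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeTable":
        index = {loc: j for j, loc in enumerate(self.locus_ids)}
        cols = [index[loc] for loc in locus_ids]
        return GenotypeTable(list(self.sample_ids), list(locus_ids), self.calls[:, cols])

    # -- integer encoding for numerical routines -------------------------
    def encode(self) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
        """Map allele sizes to dense per-locus codes 0..A_l-1.

        Returns
        -------
        codes : (n, L, 2) int array, missing = -1
        n_alleles : (L,) number of distinct observed alleles per locus
        allele_values : per locus, sorted array of the original allele sizes
        """
        codes = np.full_like(self.calls, MISSING)
        n_alleles = np.zeros(self.n_loci, dtype=np.int64)
        allele_values: list[np.ndarray] = []
        for j in range(self.n_loci):
            col = self.calls[:, j, :]
            obs = col[col != MISSING]
            values = np.unique(obs)
            allele_values.append(values)
            n_alleles[j] = len(values)
            if len(values):
                lookup = {int(v): k for k, v in enumerate(values)}
                coded = np.array(
                    [lookup[int(a)] if a != MISSING else MISSING for a in col.ravel()],
                    dtype=np.int64,
                ).reshape(col.shape)
                codes[:, j, :] = coded
        return codes, n_alleles, allele_values

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if self.sample_ids != other.sample_ids or self.locus_ids != other.locus_ids:
            return False
        # genotypes are unordered pairs
        return bool(
            np.array_equal(np.sort(self.calls, axis=2), np.sort(other.calls, axis=2))
        )


@dataclass
class SampleMetadata:
    """Per-sample collection record.

    Coordinates are planar/projected, in kilometres; geographic lon/lat must
    be projected upstream (Euclidean distances are computed throughout).
    """

    sample_id: str
    sex: str = "unknown"  # {F, M, unknown}
    age_class: str = "unknown"  # {juvenile, adult, unknown}; adult = >=2 yr
    collection_date: _dt.date | None = None
    x: float = float("nan")
    y: float = float("nan")

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "unknown"):
            raise ValidationError(f"sex must be F/M/unknown, got {self.sex!r}")
        if self.age_class not in ("juvenile", "adult", "unknown"):
            raise ValidationError(
                f"age_class must be juvenile/adult/unknown, got {self.age_class!r}"
            )
        if self.collection_date is not None and not isinstance(
            self.collection_date, _dt.date
        ):
            raise ValidationError("collection_date must be a datetime.date")


@dataclass
class TrackRecord:
    """Telemetry locations of one collared animal, chronologically ordered."""

    animal_id: str
    locations: list[tuple[_dt.date, float, float]]
    collar_type: str = "GPS"  # {VHF, GPS}

    def __post_init__(self) -> None:
        if not self.locations:
            raise ValidationError(f"track {self.animal_id}: at least one location required")
        if self.collar_type not in ("VHF", "GPS"):
            raise ValidationError(f"collar_type must be VHF/GPS, got {self.collar_type!r}")
        self.locations = sorted(self.locations, key=lambda rec: rec[0])

    @property
    def monitoring_days(self) -> int:
        """Days elapsed between first and last location (>= 0)."""
        return (self.locations[-1][0] - self.locations[0][0]).days

    def xy(self) -> np.ndarray:
        return np.array([(x, y) for _, x, y in self.locations], dtype=float)


def check_unique_ids(records: Sequence[SampleMetadata]) -> None:
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicated sample_id(s): {dupes}")


def metadata_index(records: Sequence[SampleMetadata]) -> dict[str, SampleMetadata]:
    check_unique_ids(records)
    return {r.sample_id: r for r in records}
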