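"""Readers and writers for genotype, metadata, telemetry and config files.

Two genotype dialects are supported:

``structure_2row``
    Whitespace-delimited, two rows per individual (one allele copy per row),
    first column the sample id, one column per locus, missing calls written
    as a configurable integer code (default -9). An optional first line may
    carry locus names.
``wide_csv``
    CSV with one row per individual and two columns per locus, headed
    ``<locus>.1`` / ``<locus>.2``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    MISSING,
    FormatError,
    GenotypeTable,
    SampleMetadata,
    TrackRecord,
    ValidationError,
    check_unique_ids,
)

DEFAULT_MISSING_CODE = -9


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    dialect: str = "structure_2row",
    missing_code: int = DEFAULT_MISSING_CODE,
) -> GenotypeTable:
    path = Path(path)
    if dialect == "structure_2row":
        return _read_structure(path, missing_code)
    if dialect == "wide_csv":
        return _read_wide_csv(path, missing_code)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(
    table: GenotypeTable,
    path: str | Path,
    dialect: str = "structure_2row",
    missing_code: int = DEFAULT_MISSING_CODE,
) -> None:
    path = Path(path)
    if dialect == "structure_2row":
        _write_structure(table, path, missing_code)
    elif dialect == "wide_csv":
        _write_wide_csv(table, path, missing_code)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_structure(path: Path, missing_code: int) -> GenotypeTable:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return GenotypeTable([], [], np.empty((0, 0, 2), dtype=np.int64))
    header_tokens = lines[0].split()
    data_lines = lines
    locus_ids: list[str] | None = None

    def _is_int(tok: str) -> bool:
        try:
            int(tok)
            return True
        except ValueError:
            return False

    # header line = locus names only (one fewer token than a data row, or
    # non-integer tokens after the first column in the second line)
    if len(lines) == 1:
        # a lone line cannot hold a two-row individual: header of empty table
        return GenotypeTable(
            [], header_tokens, np.empty((0, len(header_tokens), 2), dtype=np.int64)
        )
    if len(lines) >= 2 and len(header_tokens) == len(lines[1].split()) - 1:
        locus_ids = header_tokens
        data_lines = lines[1:]
    elif not all(_is_int(t) for t in header_tokens[1:]):
        locus_ids = header_tokens
        data_lines = lines[1:]

    if not data_lines:
        return GenotypeTable([], locus_ids or [], np.empty((0, len(locus_ids or []), 2), dtype=np.int64))
    if len(data_lines) % 2:
        raise FormatError(
            f"{path}: odd number of genotype rows ({len(data_lines)}); "
            "structure_2row requires two rows per individual"
        )
    n_loci = len(data_lines[0].split()) - 1
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(n_loci)]
    if len(locus_ids) != n_loci:
        raise FormatError(f"{path}: header has {len(locus_ids)} loci, rows have {n_loci}")

    sample_ids: list[str] = []
    n = len(data_lines) // 2
    calls = np.full((n, n_loci, 2), MISSING, dtype=np.int64)
    for i in range(n):
        pair = []
        for copy in range(2):
            row_no = 2 * i + copy
            tokens = data_lines[row_no].split()
            if len(tokens) != n_loci + 1:
                raise FormatError(
                    f"{path}: row {row_no + 1} has {len(tokens)} columns, expected {n_loci + 1}"
                )
            pair.append(tokens)
        if pair[0][0] != pair[1][0]:
            raise FormatError(
                f"{path}: rows {2 * i + 1}-{2 * i + 2} carry different sample ids "
                f"({pair[0][0]!r} vs {pair[1][0]!r})"
            )
        sample_ids.append(pair[0][0])
        for copy in range(2):
            for j, tok in enumerate(pair[copy][1:]):
                try:
                    val = int(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-integer allele {tok!r} at row {2 * i + copy + 1}, "
                        f"locus column {j + 2}"
                    ) from exc
                calls[i, j, copy] = MISSING if val == missing_code else val
    return GenotypeTable(sample_ids, locus_ids, calls)


def _write_structure(table: GenotypeTable, path: Path, missing_code: int) -> None:
    out = [" ".join(table.locus_ids)]
    for i, sid in enumerate(table.sample_ids):
        for copy in range(2):
            row = [sid]
            for j in range(table.n_loci):
                a = table.calls[i, j, copy]
                row.append(str(missing_code if a == MISSING else int(a)))
            out.append(" ".join(row))
    path.write_text("\n".join(out) + "\n")


def _read_wide_csv(path: Path, missing_code: int) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] == 0 or df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    allele_cols = list(df.columns[1:])
    locus_ids: list[str] = []
    for col in allele_cols:
        base, _, suffix = col.rpartition(".")
        if suffix not in ("1", "2") or not base:
            raise FormatError(f"{path}: allele column {col!r} is not '<locus>.1/2'")
        if suffix == "1":
            locus_ids.append(base)
        elif f"{base}.1" not in df.columns:
            raise FormatError(f"{path}: column {col!r} has no matching {base}.1")
    for loc in locus_ids:
        if f"{loc}.2" not in df.columns:
            raise FormatError(f"{path}: locus {loc!r} lacks a .2 column")

    n = len(df)
    calls = np.full((n, len(locus_ids), 2), MISSING, dtype=np.int64)
    for j, loc in enumerate(locus_ids):
        for copy, col in enumerate((f"{loc}.1", f"{loc}.2")):
            for i, tok in enumerate(df[col]):
                if pd.isna(tok) or str(tok).strip() == "":
                    continue
                try:
                    val = int(str(tok).strip())
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-integer allele {tok!r} in row {i + 2}, column {col}"
                    ) from exc
                calls[i, j, copy] = MISSING if val == missing_code else val
    return GenotypeTable(list(df["sample_id"].astype(str)), locus_ids, calls)


def _write_wide_csv(table: GenotypeTable, path: Path, missing_code: int) -> None:
    cols: dict[str, object] = {"sample_id": table.sample_ids}
    for j, loc in enumerate(table.locus_ids):
        for copy in range(2):
            vals = table.calls[:, j, copy].copy()
            vals[vals == MISSING] = missing_code
            cols[f"{loc}.{copy + 1}"] = vals
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metadata and telemetry
# ---------------------------------------------------------------------------

_SEX_MAP = {"f": "F", "female": "F", "m": "M", "male": "M"}
_AGE_MAP = {"juvenile": "juvenile", "juv": "juvenile", "adult": "adult", "ad": "adult"}


def _parse_date(tok: str, where: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(tok).strip())
    except ValueError as exc:
        raise FormatError(f"{where}: unparseable date {tok!r} (expected YYYY-MM-DD)") from exc


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata CSV.

    Mandatory columns: ``sample_id, x, y``; optional: ``sex, age_class,
    collection_date``. Unknown sex/age are tolerated.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    records = []
    for i, row in df.iterrows():
        where = f"{path}: row {i + 2}"
        try:
            x, y = float(row["x"]), float(row["y"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{where}: unparseable coordinates") from exc
        if not (np.isfinite(x) and np.isfinite(y)):
            raise FormatError(f"{where}: non-finite coordinates")
        sex = _SEX_MAP.get(str(row.get("sex", "")).strip().lower(), "unknown")
        age = _AGE_MAP.get(str(row.get("age_class", "")).strip().lower(), "unknown")
        date = None
        tok = row.get("collection_date")
        if tok is not None and not pd.isna(tok) and str(tok).strip():
            date = _parse_date(tok, where)
        records.append(
            SampleMetadata(str(row["sample_id"]), sex=sex, age_class=age,
                           collection_date=date, x=x, y=y)
        )
    check_unique_ids(records)
    return records


def write_metadata(records: list[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "sex": [r.sex for r in records],
            "age_class": [r.age_class for r in records],
            "collection_date": [
                r.collection_date.isoformat() if r.collection_date else "" for r in records
            ],
            "x": [r.x for r in records],
            "y": [r.y for r in records],
        }
    ).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[TrackRecord]:
    """Read telemetry CSV with columns animal_id, date, x, y[, collar_type]."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("animal_id", "date", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    grouped: dict[str, list[tuple[_dt.date, float, float]]] = {}
    collars: dict[str, str] = {}
    for i, row in df.iterrows():
        where = f"{path}: row {i + 2}"
        date = _parse_date(row["date"], where)
        try:
            x, y = float(row["x"]), float(row["y"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{where}: unparseable coordinates") from exc
        aid = str(row["animal_id"])
        grouped.setdefault(aid, []).append((date, x, y))
        if "collar_type" in df.columns and not pd.isna(row["collar_type"]):
            collars[aid] = str(row["collar_type"]).strip().upper()
    return [
        TrackRecord(aid, locs, collar_type=collars.get(aid, "GPS"))
        for aid, locs in grouped.items()
    ]


def write_tracks(tracks: list[TrackRecord], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for date, x, y in tr.locations:
            rows.append((tr.animal_id, date.isoformat(), x, y, tr.collar_type))
    pd.DataFrame(rows, columns=["animal_id", "date", "x", "y", "collar_type"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated bundle of every downstream tunable.

    The ``desk`` profile uses chain lengths suited to interactive work; the
    ``paper_faithful`` profile restores the long chains used in the original
    wolf study (2M/500k admixture iterations, 20M/2M migration iterations).
    """

    # admixture clustering
    admixture_iterations: int = 50_000
    admixture_burn_in: int = 10_000
    replicates: int = 20
    k_min: int = 1
    k_max: int = 20
    freq_model: str = "correlated"
    # classification
    min_gap: float = 0.05
    fallback_cutoff: float = 0.80
    # spatial
    adjacency_km: float = 50.0
    min_overlap_fraction: float = 0.01
    # statistics
    n_permutations: int = 1000
    # migration (sweep-based sampler: one sweep refreshes every individual)
    migration_iterations: int = 4000
    migration_burn_in: int = 1000
    migration_thinning: int = 5
    delta_alleles: float = 0.3
    delta_inbreeding: float = 0.7
    delta_migration: float = 0.6
    # misc
    seed: int = 0

    _RANGES = {
        "admixture_iterations": (100, 10_000_000),
        "admixture_burn_in": (0, 10_000_000),
        "replicates": (1, 1000),
        "k_min": (1, 100),
        "k_max": (1, 100),
        "min_gap": (0.0, 0.5),
        "fallback_cutoff": (0.5, 1.0),
        "adjacency_km": (0.0, 1e4),
        "min_overlap_fraction": (0.0, 1.0),
        "n_permutations": (1, 10_000_000),
        "migration_iterations": (100, 100_000_000),
        "migration_burn_in": (0, 100_000_000),
        "migration_thinning": (1, 1_000_000),
        "delta_alleles": (0.0, 1.0),
        "delta_inbreeding": (0.0, 1.0),
        "delta_migration": (0.0, 1.0),
        "seed": (0, 2**31 - 1),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ValidationError(f"config {name}={val} outside [{lo}, {hi}]")
        if self.admixture_burn_in >= self.admixture_iterations:
            raise ValidationError("admixture_burn_in must be < admixture_iterations")
        if self.migration_burn_in >= self.migration_iterations:
            raise ValidationError("migration_burn_in must be < migration_iterations")
        if self.k_min > self.k_max:
            raise ValidationError("k_min must be <= k_max")
        if self.freq_model not in ("independent", "correlated"):
            raise ValidationError("freq_model must be independent/correlated")

    @classmethod
    def paper_faithful(cls, **overrides) -> "PipelineConfig":
        base = dict(
            admixture_iterations=2_500_000,
            admixture_burn_in=500_000,
            migration_iterations=100_000,
            migration_burn_in=10_000,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)})
        )
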