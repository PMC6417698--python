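"""Domain types, CSV I/O and summary statistics for station chemistry and chronic toxicity data.

Two measurement matrices are handled, each with fixed units that are never
converted: surface sediments (mg/kg dry weight) and surface seawater (μg/L).
CSV schemas are strict — a header that does not match the documented column
set is rejected outright, and malformed rows are reported with their line
numbers, since silent column drift is the main data-corruption risk in
station-chemistry tables.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """CSV header does not match the documented schema."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


class Metal(str, enum.Enum):
    """The seven heavy metals assessed (GB 18668-2002 / GB 3097-1997 scope)."""

    AS = "As"
    CD = "Cd"
    CR = "Cr"
    CU = "Cu"
    HG = "Hg"
    PB = "Pb"
    ZN = "Zn"

    @classmethod
    def parse(cls, code: str) -> "Metal":
        try:
            return cls(str(code).strip())
        except ValueError:
            raise ValidationError(
                f"unknown metal code {code!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Matrix(str, enum.Enum):
    SEDIMENT = "sediment"
    SEAWATER = "seawater"

    @property
    def units(self) -> str:
        return "mg/kg dw" if self is Matrix.SEDIMENT else "ug/L"

    @classmethod
    def parse(cls, tag: str) -> "Matrix":
        try:
            return cls(str(tag).strip().lower())
        except ValueError:
            raise ValidationError(f"unknown matrix tag {tag!r}") from None


class FunctionalGroup(str, enum.Enum):
    """The six major functional groups of the marine ecosystem."""

    ALGAE = "algae"
    CRUSTACEANS = "crustaceans"
    FISH = "fish"
    INVERTEBRATES = "invertebrates"
    MOLLUSKS = "mollusks"
    WORMS = "worms"

    @classmethod
    def parse(cls, tag: str) -> "FunctionalGroup":
        try:
            return cls(str(tag).strip().lower())
        except ValueError:
            raise ValidationError(f"unknown functional group {tag!r}") from None


class Endpoint(str, enum.Enum):
    """Chronic toxicity endpoints admitted to the effects data model.

    NOEC is the primary endpoint; MATC and LOEC serve as supplements. Acute
    endpoints (EC50, LC50, ...) are outside the chronic-data model and are
    rejected at parse time.
    """

    NOEC = "NOEC"
    MATC = "MATC"
    LOEC = "LOEC"

    @classmethod
    def parse(cls, tag: str) -> "Endpoint":
        try:
            return cls(str(tag).strip().upper())
        except ValueError:
            raise ValidationError(
                f"unknown or non-chronic endpoint {tag!r}; allowed: NOEC, MATC, LOEC"
            ) from None


@dataclass(frozen=True)
class ConcentrationRecord:
    """One replicate concentration measurement at one station.

    ``value`` is mg/kg dry weight for sediment and μg/L for seawater; the
    matrix fixes the units and they are never auto-converted.
    """

    station_id: str
    season: str
    matrix: Matrix
    metal: Metal
    replicate: int
    value: float
    longitude: float | None = None
    latitude: float | None = None

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(
                f"non-positive concentration {self.value!r} for metal "
                f"{self.metal.value} at station {self.station_id!r}"
            )
        if int(self.replicate) < 1:
            raise ValidationError(
                f"replicate index must be >= 1, got {self.replicate!r}"
            )

    @property
    def units(self) -> str:
        return self.matrix.units


@dataclass(frozen=True)
class ToxicityRecord:
    """One chronic toxicity endpoint for one species, in μg/L."""

    species: str
    functional_group: FunctionalGroup
    metal: Metal
    endpoint: Endpoint
    duration_days: float
    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(
                f"non-positive toxicity value {self.value!r} for {self.species!r}"
            )
        if not self.duration_days > 0:
            raise ValidationError(
                f"non-positive exposure duration {self.duration_days!r} "
                f"for {self.species!r}"
            )


@dataclass(frozen=True)
class ConcentrationSummary:
    """Range / mean / SD summary of one (matrix, season, metal) stratum."""

    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValidationError("summary violates min <= mean <= max")
        if self.sd < 0:
            raise ValidationError("summary SD must be >= 0")


CONCENTRATION_COLUMNS = (
    "station_id",
    "longitude",
    "latitude",
    "season",
    "matrix",
    "metal",
    "replicate",
    "value",
)
TOXICITY_COLUMNS = (
    "species",
    "functional_group",
    "metal",
    "endpoint",
    "duration_days",
    "value_ugL",
)


def _check_header(frame: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(expected)}"
        )


def read_concentrations(
    path: str | Path, matrix: Matrix | str | None = None
) -> list[ConcentrationRecord]:
    """Read a station-concentration CSV, validating every row.

    Parameters
    ----------
    path
        CSV file with header ``station_id, longitude, latitude, season,
        matrix, metal, replicate, value``.
    matrix
        If given, every row must carry this matrix tag; a mismatch is a
        validation error.

    Raises
    ------
    SchemaError
        If the header does not match the documented schema.
    ValidationError
        Listing every malformed row with its 1-based file line number.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_header(frame, CONCENTRATION_COLUMNS, path)
    want = Matrix.parse(matrix) if matrix is not None else None

    records: list[ConcentrationRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            m = Matrix.parse(row["matrix"])
            if want is not None and m is not want:
                raise ValidationError(
                    f"matrix {m.value!r} does not match requested {want.value!r}"
                )
            records.append(
                ConcentrationRecord(
                    station_id=str(row["station_id"]),
                    longitude=None if pd.isna(row["longitude"]) else float(row["longitude"]),
                    latitude=None if pd.isna(row["latitude"]) else float(row["latitude"]),
                    season=str(row["season"]),
                    matrix=m,
                    metal=Metal.parse(row["metal"]),
                    replicate=int(row["replicate"]),
                    value=float(row["value"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))

    keys = [(r.station_id, r.season, r.matrix, r.metal, r.replicate) for r in records]
    if len(set(keys)) != len(keys):
        raise ValidationError(
            f"{path}: duplicate (station, season, matrix, metal, replicate) key(s)"
        )
    return records


def write_concentrations(records: Iterable[ConcentrationRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "longitude": r.longitude,
                "latitude": r.latitude,
                "season": r.season,
                "matrix": r.matrix.value,
                "metal": r.metal.value,
                "replicate": r.replicate,
                "value": r.value,
            }
            for r in records
        ],
        columns=list(CONCENTRATION_COLUMNS),
    )
    # repr gives the shortest float representation that round-trips exactly
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_toxicity(path: str | Path) -> list[ToxicityRecord]:
    """Read a chronic-toxicity CSV (columns ``species, functional_group,
    metal, endpoint, duration_days, value_ugL``) with closed-set validation
    of functional group and endpoint."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_header(frame, TOXICITY_COLUMNS, path)

    records: list[ToxicityRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        try:
            records.append(
                ToxicityRecord(
                    species=str(row["species"]),
                    functional_group=FunctionalGroup.parse(row["functional_group"]),
                    metal=Metal.parse(row["metal"]),
                    endpoint=Endpoint.parse(row["endpoint"]),
                    duration_days=float(row["duration_days"]),
                    value=float(row["value_ugL"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records


def write_toxicity(records: Iterable[ToxicityRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "species": r.species,
                "functional_group": r.functional_group.value,
                "metal": r.metal.value,
                "endpoint": r.endpoint.value,
                "duration_days": r.duration_days,
                "value_ugL": r.value,
            }
            for r in records
        ],
        columns=list(TOXICITY_COLUMNS),
    )
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def summarize(records: Sequence[ConcentrationRecord]) -> ConcentrationSummary:
    """Range / arithmetic mean / sample SD of a single (matrix, metal, season) stratum.

    The SD uses the n−1 denominator; a single value gets SD 0 by convention.
    Mixed strata are rejected so a summary can never silently pool seasons,
    matrices or metals.
    """
    if not records:
        raise ValidationError("cannot summarize an empty record set")
    strata = {(r.matrix, r.metal, r.season) for r in records}
    if len(strata) > 1:
        raise ValidationError(f"mixed strata in summarize: {sorted(map(str, strata))}")
    values = np.asarray([r.value for r in records], dtype=float)
    sd = 0.0 if values.size == 1 else float(values.std(ddof=1))
    return ConcentrationSummary(
        n=values.size,
        minimum=float(values.min()),
        maximum=float(values.max()),
        mean=float(values.mean()),
        sd=sd,
    )


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log x)); defined for strictly positive values only."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric mean of an empty sequence")
    if np.any(arr <= 0):
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def collapse_replicates(
    records: Sequence[ConcentrationRecord], policy: str = "mean"
) -> list[ConcentrationRecord]:
    """Combine replicate measurements per station.

    ``policy="mean"`` (default) averages the replicates of each (station,
    season, matrix, metal) into a single record; ``policy="pooled"`` returns
    the records unchanged so that every replicate enters downstream fitting.
    """
    if policy == "pooled":
        return list(records)
    if policy != "mean":
        raise ValueError(f"unknown replicate policy {policy!r}")
    grouped: dict[tuple, list[ConcentrationRecord]] = {}
    for r in records:
        grouped.setdefault((r.station_id, r.season, r.matrix, r.metal), []).append(r)
    out = []
    for (station, season, matrix, metal), group in grouped.items():
        out.append(
            ConcentrationRecord(
                station_id=station,
                season=season,
                matrix=matrix,
                metal=metal,
                replicate=1,
                value=float(np.mean([g.value for g in group])),
                longitude=group[0].longitude,
                latitude=group[0].latitude,
            )
        )
    return out


def values_of(records: Sequence[ConcentrationRecord]) -> np.ndarray:
    return np.asarray([r.value for r in records], dtype=float)


def stratify(
    records: Sequence[ConcentrationRecord],
) -> dict[tuple[str, Metal], list[ConcentrationRecord]]:
    """Group records by (season, metal); callers filter by matrix first."""
    out: dict[tuple[str, Metal], list[ConcentrationRecord]] = {}
    for r in records:
        out.setdefault((r.season, r.metal), []).append(r)
    return out
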