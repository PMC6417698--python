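"""Synthetic station-chemistry and toxicity data with the structure the pipeline assumes.

The raw per-station measurements and the ECOTOX toxicity extraction behind
the bundled western Laizhou Bay survey scenario are not deposited anywhere;
what is published are per-stratum summaries (range, mean, SD for each
matrix × season × metal) and per-group toxicity record counts. The
generator emulates exactly those summaries:

* station values are drawn from a normal law with the stratum mean and SD,
  truncated to the printed range (matching printed mean/SD/range is the
  goal, not asserting the field data's true law — the fitting stage then
  chooses its own family, exactly as the real workflow does);
* each station gets replicate measurements with a small multiplicative
  jitter (2% relative SD, truncated to the stratum range), standing in for
  analytical repeatability that the source summaries never quantify;
* species tolerances are drawn from a declared "true" SSD per metal, with
  functional-group record counts and screening-compliant durations.

Everything is deterministic under a seed, and a scenario round-trips
through YAML so a run can be archived with its exact generating conditions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .core import (
    ConcentrationRecord,
    Endpoint,
    FunctionalGroup,
    Matrix,
    Metal,
    ToxicityRecord,
    ValidationError,
)
from .distributions import Family, FittedDistribution

SEASON_SPRING = "spring_2016_05"
SEASON_AUTUMN = "autumn_2016_09"


def _dms(d: int, m: int, s: float) -> float:
    return round(d + m / 60.0 + s / 3600.0, 6)


#: Station roster: id, longitude, latitude, and whether sediment was collected.
#: Ten of the twenty stations carry sediment samples.
STATION_ROSTER: tuple[tuple[str, float, float, bool], ...] = (
    ("1", _dms(119, 7, 34.07), _dms(37, 33, 6.75), True),
    ("2", _dms(119, 20, 13.70), _dms(37, 36, 11.78), True),
    ("3", _dms(119, 0, 5.21), _dms(37, 28, 25.78), False),
    ("4", _dms(119, 9, 0.39), _dms(37, 30, 2.15), False),
    ("5", _dms(119, 15, 37.47), _dms(37, 31, 30.81), False),
    ("6", _dms(119, 0, 48.36), _dms(37, 25, 13.91), False),
    ("7", _dms(119, 11, 9.88), _dms(37, 27, 17.26), True),
    ("8", _dms(119, 22, 57.71), _dms(37, 29, 44.59), True),
    ("9", _dms(118, 55, 3.08), _dms(37, 21, 3.78), True),
    ("10", _dms(119, 0, 13.83), _dms(37, 22, 2.02), True),
    ("11", _dms(119, 4, 28.48), _dms(37, 23, 27.69), False),
    ("12", _dms(119, 10, 22.40), _dms(37, 24, 49.92), True),
    ("13", _dms(119, 18, 21.48), _dms(37, 26, 29.29), False),
    ("14", _dms(119, 2, 14.68), _dms(37, 20, 12.38), True),
    ("15", _dms(119, 8, 4.29), _dms(37, 21, 24.34), True),
    ("16", _dms(119, 14, 50.00), _dms(37, 22, 32.87), False),
    ("17", _dms(119, 25, 28.78), _dms(37, 24, 25.94), False),
    ("18", _dms(119, 6, 7.75), _dms(37, 16, 50.22), False),
    ("19", _dms(119, 12, 49.15), _dms(37, 18, 57.00), False),
    ("20", _dms(119, 21, 1.18), _dms(37, 21, 10.63), True),
)


@dataclass(frozen=True)
class StratumSpec:
    """Target mean/SD/range for one (matrix, season, metal) stratum."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        # min ≤ mean ≤ max (equality allowed: published summaries are
        # rounded, and a printed mean can coincide with a printed bound).
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValidationError(f"stratum violates min <= mean <= max: {self}")
        if not self.sd > 0:
            raise ValidationError(f"stratum SD must be > 0: {self}")


@dataclass(frozen=True)
class ConcentrationScenario:
    """Generating conditions for station concentration tables.

    ``strata`` maps (matrix tag, season, metal code) to a
    :class:`StratumSpec`; ``n_stations`` fixes the roster size per matrix.
    """

    strata: Mapping[tuple[str, str, str], StratumSpec]
    n_stations: Mapping[str, int] = field(
        default_factory=lambda: {"sediment": 10, "seawater": 20}
    )
    n_replicates: int = 3
    replicate_rel_sd: float = 0.02

    def to_dict(self) -> dict:
        return {
            "strata": {
                "|".join(key): {
                    "mean": s.mean,
                    "sd": s.sd,
                    "minimum": s.minimum,
                    "maximum": s.maximum,
                }
                for key, s in self.strata.items()
            },
            "n_stations": dict(self.n_stations),
            "n_replicates": self.n_replicates,
            "replicate_rel_sd": self.replicate_rel_sd,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ConcentrationScenario":
        return cls(
            strata={
                tuple(k.split("|")): StratumSpec(**v) for k, v in raw["strata"].items()
            },
            n_stations=dict(raw["n_stations"]),
            n_replicates=int(raw["n_replicates"]),
            replicate_rel_sd=float(raw["replicate_rel_sd"]),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "ConcentrationScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class ToxicityScenario:
    """Generating conditions for chronic toxicity tables.

    ``true_ssd`` declares, per metal code, the family and parameters of the
    species sensitivity distribution the tolerances are drawn from;
    ``group_counts`` fixes the per-functional-group record counts;
    durations are drawn uniformly inside per-group ranges (compliant with
    the screening floors by default); endpoints are assigned NOEC-heavy.
    """

    true_ssd: Mapping[str, tuple[str, tuple[float, ...]]]
    group_counts: Mapping[str, Mapping[str, int]]
    duration_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "algae": (1.0, 10.0),
            "invertebrates": (1.0, 10.0),
            "crustaceans": (4.0, 30.0),
            "fish": (4.0, 60.0),
            "mollusks": (4.0, 30.0),
            "worms": (4.0, 30.0),
        }
    )
    endpoint_weights: Mapping[str, float] = field(
        default_factory=lambda: {"NOEC": 0.7, "MATC": 0.15, "LOEC": 0.15}
    )

    def __post_init__(self) -> None:
        for metal, counts in self.group_counts.items():
            if any(c < 0 for c in counts.values()):
                raise ValidationError(f"negative group count for {metal}")

    def to_dict(self) -> dict:
        return {
            "true_ssd": {
                m: {"family": fam, "params": list(params)}
                for m, (fam, params) in self.true_ssd.items()
            },
            "group_counts": {m: dict(c) for m, c in self.group_counts.items()},
            "duration_ranges": {g: list(r) for g, r in self.duration_ranges.items()},
            "endpoint_weights": dict(self.endpoint_weights),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ToxicityScenario":
        return cls(
            true_ssd={
                m: (v["family"], tuple(v["params"])) for m, v in raw["true_ssd"].items()
            },
            group_counts={m: dict(c) for m, c in raw["group_counts"].items()},
            duration_ranges={g: tuple(r) for g, r in raw["duration_ranges"].items()},
            endpoint_weights=dict(raw["endpoint_weights"]),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "ToxicityScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def ssd_distribution(self, metal: Metal | str) -> FittedDistribution:
        code = metal.value if isinstance(metal, Metal) else metal
        fam, params = self.true_ssd[code]
        return FittedDistribution(family=Family(fam), params=tuple(params))


def _truncnorm(spec: StratumSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    a = (spec.minimum - spec.mean) / spec.sd
    b = (spec.maximum - spec.mean) / spec.sd
    acceptance = stats.norm.cdf(b) - stats.norm.cdf(a)
    if acceptance < 0.01:
        raise ValidationError(
            f"infeasible truncation (acceptance {acceptance:.2e} < 1%) for {spec}"
        )
    return stats.truncnorm.rvs(
        a, b, loc=spec.mean, scale=spec.sd, size=size, random_state=rng
    )


def gen_concentrations(
    scenario: ConcentrationScenario, seed: int
) -> list[ConcentrationRecord]:
    """Generate one concentration table per the scenario, deterministically.

    Per stratum: station base values from the truncated normal; per
    replicate, a multiplicative jitter (relative SD ``replicate_rel_sd``)
    re-truncated to the stratum range so every emitted value stays inside
    the printed bounds.
    """
    rng = np.random.default_rng(seed)
    roster = {
        Matrix.SEDIMENT.value: [s for s in STATION_ROSTER if s[3]],
        Matrix.SEAWATER.value: list(STATION_ROSTER),
    }
    records: list[ConcentrationRecord] = []
    for key in sorted(scenario.strata):
        matrix_tag, season, metal_code = key
        spec = scenario.strata[key]
        stations = roster[matrix_tag][: scenario.n_stations[matrix_tag]]
        base = _truncnorm(spec, len(stations), rng)
        for (station_id, lon, lat, _), value in zip(stations, base):
            jitter_sd = max(scenario.replicate_rel_sd * value, 1e-12)
            a = (spec.minimum - value) / jitter_sd
            b = (spec.maximum - value) / jitter_sd
            reps = stats.truncnorm.rvs(
                a, b, loc=value, scale=jitter_sd,
                size=scenario.n_replicates, random_state=rng,
            )
            for i, rep_value in enumerate(reps, start=1):
                records.append(
                    ConcentrationRecord(
                        station_id=station_id,
                        longitude=lon,
                        latitude=lat,
                        season=season,
                        matrix=Matrix(matrix_tag),
                        metal=Metal(metal_code),
                        replicate=i,
                        value=float(rep_value),
                    )
                )
    return records


def gen_toxicity(scenario: ToxicityScenario, seed: int) -> list[ToxicityRecord]:
    """Generate chronic toxicity records per the scenario, deterministically.

    Each record is its own species (one tolerance per species), named by
    metal, group and index; tolerances come from the metal's true SSD,
    durations from the per-group ranges, endpoints from the weight mix.
    """
    rng = np.random.default_rng(seed)
    endpoints = sorted(scenario.endpoint_weights)
    weights = np.asarray([scenario.endpoint_weights[e] for e in endpoints], dtype=float)
    weights = weights / weights.sum()
    records: list[ToxicityRecord] = []
    for metal_code in sorted(scenario.group_counts):
        ssd = scenario.ssd_distribution(metal_code)
        counts = scenario.group_counts[metal_code]
        for group_tag in sorted(counts):
            n = counts[group_tag]
            if n == 0:
                continue
            lo, hi = scenario.duration_ranges[group_tag]
            tolerances = ssd.sample(n, rng)
            durations = rng.uniform(lo, hi, size=n)
            chosen = rng.choice(len(endpoints), size=n, p=weights)
            for i in range(n):
                records.append(
                    ToxicityRecord(
                        species=f"{metal_code}_{group_tag}_sp{i + 1:02d}",
                        functional_group=FunctionalGroup(group_tag),
                        metal=Metal(metal_code),
                        endpoint=Endpoint(endpoints[chosen[i]]),
                        duration_days=float(durations[i]),
                        value=float(tolerances[i]),
                    )
                )
    return records


# --- Bundled western Laizhou Bay survey scenario ---------------------------

_SEDIMENT_STRATA = {
    # metal: (spring mean, sd, min, max), (autumn mean, sd, min, max) — mg/kg dw
    "As": ((11.49, 0.71, 10.70, 12.70), (10.50, 0.78, 9.20, 11.90)),
    "Cd": ((0.14, 0.02, 0.11, 0.18), (0.17, 0.01, 0.16, 0.18)),
    "Cr": ((26.51, 1.87, 23.60, 29.80), (34.30, 1.71, 31.50, 37.00)),
    "Cu": ((21.75, 2.25, 18.00, 25.50), (19.30, 0.88, 17.60, 20.50)),
    "Hg": ((0.011, 0.002, 0.009, 0.016), (0.025, 0.005, 0.022, 0.035)),
    "Pb": ((20.53, 2.35, 17.50, 24.60), (14.80, 0.93, 13.40, 15.80)),
    "Zn": ((27.42, 3.91, 21.50, 35.50), (39.00, 2.81, 34.40, 43.50)),
}

_SEAWATER_STRATA = {
    # metal: (spring mean, sd, min, max), (autumn mean, sd, min, max) — μg/L
    "As": ((3.43, 0.26, 3.01, 3.87), (3.57, 0.16, 3.27, 3.84)),
    "Cd": ((0.14, 0.02, 0.11, 0.19), (0.18, 0.01, 0.16, 0.20)),
    "Cr": ((5.12, 0.63, 4.16, 6.17), (5.01, 0.12, 4.78, 5.19)),
    "Cu": ((2.38, 0.38, 1.31, 2.96), (2.58, 0.12, 2.44, 2.82)),
    "Hg": ((0.03, 0.01, 0.01, 0.04), (0.02, 0.002, 0.02, 0.03)),
    "Pb": ((1.91, 0.49, 1.29, 2.87), (1.58, 0.11, 1.36, 1.79)),
    "Zn": ((40.48, 5.35, 30.90, 49.80), (39.85, 1.67, 36.80, 43.60)),
}

#: Per-group chronic toxicity record counts for the survey's screened
#: ECOTOX extraction (totals: As 23, Cd 51, Cr 38, Cu 123, Hg 20, Pb 29,
#: Zn 52; grand total 336).
TOXICITY_GROUP_COUNTS: dict[str, dict[str, int]] = {
    "As": {"algae": 12, "crustaceans": 5, "fish": 4, "invertebrates": 1, "mollusks": 1, "worms": 0},
    "Cd": {"algae": 12, "crustaceans": 2, "fish": 9, "invertebrates": 6, "mollusks": 16, "worms": 6},
    "Cr": {"algae": 16, "crustaceans": 10, "fish": 3, "invertebrates": 4, "mollusks": 3, "worms": 2},
    "Cu": {"algae": 38, "crustaceans": 27, "fish": 9, "invertebrates": 15, "mollusks": 25, "worms": 9},
    "Hg": {"algae": 6, "crustaceans": 2, "fish": 1, "invertebrates": 3, "mollusks": 6, "worms": 2},
    "Pb": {"algae": 8, "crustaceans": 6, "fish": 1, "invertebrates": 1, "mollusks": 11, "worms": 2},
    "Zn": {"algae": 10, "crustaceans": 18, "fish": 4, "invertebrates": 2, "mollusks": 15, "worms": 3},
}

#: Survey-reported HC5 values (μg/L) used as fixture anchors for the
#: synthetic true SSDs; they are inputs to the generator, never fitting
#: targets.
HC5_FIXTURE: dict[str, float] = {
    "As": 9.33,
    "Cd": 2.57,
    "Cr": 1.16,
    "Cu": 0.87,
    "Hg": 1.08,
    "Pb": 9.53,
    "Zn": 29.09,
}

_TRUE_SSD_BETA = 2.0  # log-logistic shape for every synthetic SSD


def laizhou_scenario() -> tuple[ConcentrationScenario, ToxicityScenario]:
    """The packaged defaults for the western Laizhou Bay survey.

    Concentration strata encode the printed range/mean/SD of both seasonal
    campaigns for both matrices (10 sediment stations, 20 seawater
    stations, 3 replicates each). The synthetic true SSD of each metal is a
    log-logistic with shape β = 2 and scale chosen so its 5th percentile
    equals the survey's reported HC5 (α = HC5 · 19^(1/β)).
    """
    strata: dict[tuple[str, str, str], StratumSpec] = {}
    for metal, (spring, autumn) in _SEDIMENT_STRATA.items():
        strata[("sediment", SEASON_SPRING, metal)] = StratumSpec(*spring)
        strata[("sediment", SEASON_AUTUMN, metal)] = StratumSpec(*autumn)
    for metal, (spring, autumn) in _SEAWATER_STRATA.items():
        strata[("seawater", SEASON_SPRING, metal)] = StratumSpec(*spring)
        strata[("seawater", SEASON_AUTUMN, metal)] = StratumSpec(*autumn)
    conc = ConcentrationScenario(strata=strata)

    true_ssd = {
        metal: (
            Family.LOG_LOGISTIC.value,
            (hc5 * 19.0 ** (1.0 / _TRUE_SSD_BETA), _TRUE_SSD_BETA),
        )
        for metal, hc5 in HC5_FIXTURE.items()
    }
    tox = ToxicityScenario(true_ssd=true_ssd, group_counts=TOXICITY_GROUP_COUNTS)
    return conc, tox
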