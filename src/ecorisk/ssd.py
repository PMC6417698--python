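"""Species sensitivity distributions: screening, aggregation, fitting, HC5 and PNEC.

Chronic toxicity records are screened for adequate exposure duration
(group-specific floors: ≥1 d for algae and invertebrates, ≥4 d for
crustaceans, fish, mollusks and worms) and allowed endpoints (NOEC primary;
MATC and LOEC as supplements, all entering equally once admitted). Each
species is then collapsed to a single tolerance (geometric mean by
default), and the four candidate families are fitted to the tolerances;
the winner — chosen by Anderson–Darling p-value with AIC tie-break — is
the SSD. HC5, its 5th percentile, is the concentration hazardous to 5% of
species; dividing by a safety factor (default 5) yields the PNEC.

Adequacy follows the usual regulatory floor of at least eight species
spanning at least three functional groups (the data model carries
functional groups rather than Linnaean families/classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Endpoint, FunctionalGroup, Metal, ToxicityRecord, ValidationError, geometric_mean
from .distributions import (
    ALL_FAMILIES,
    Family,
    FitError,
    FittedDistribution,
    GofReport,
    select_model,
)

logger = logging.getLogger(__name__)

MIN_SPECIES = 8
MIN_GROUPS = 3


def _default_duration_floors() -> dict[FunctionalGroup, float]:
    return {
        FunctionalGroup.ALGAE: 1.0,
        FunctionalGroup.INVERTEBRATES: 1.0,
        FunctionalGroup.CRUSTACEANS: 4.0,
        FunctionalGroup.FISH: 4.0,
        FunctionalGroup.MOLLUSKS: 4.0,
        FunctionalGroup.WORMS: 4.0,
    }


@dataclass(frozen=True)
class ScreeningRules:
    """Duration floors (days) per functional group and the allowed endpoints."""

    min_duration: Mapping[FunctionalGroup, float] = field(
        default_factory=_default_duration_floors
    )
    allowed_endpoints: tuple[Endpoint, ...] = (Endpoint.NOEC, Endpoint.MATC, Endpoint.LOEC)

    def __post_init__(self) -> None:
        if any(not d > 0 for d in self.min_duration.values()):
            raise ValidationError("duration floors must be > 0")
        if not self.allowed_endpoints:
            raise ValidationError("at least one endpoint must be allowed")


DEFAULT_RULES = ScreeningRules()


def screen_toxicity(
    records: Sequence[ToxicityRecord], rules: ScreeningRules = DEFAULT_RULES
) -> list[ToxicityRecord]:
    """Keep records meeting the group-specific duration floor and an allowed endpoint.

    Counts removed per rule are logged; an empty result is allowed but
    warned about.
    """
    kept: list[ToxicityRecord] = []
    removed_duration = 0
    removed_endpoint = 0
    for r in records:
        if r.endpoint not in rules.allowed_endpoints:
            removed_endpoint += 1
            continue
        floor = rules.min_duration.get(r.functional_group, 0.0)
        if r.duration_days < floor:
            removed_duration += 1
            continue
        kept.append(r)
    logger.info(
        "screening: kept %d of %d records (removed %d for duration, %d for endpoint)",
        len(kept),
        len(records),
        removed_duration,
        removed_endpoint,
    )
    if not kept and records:
        logger.warning("screening removed every record")
    return kept


def aggregate_by_species(
    records: Sequence[ToxicityRecord], policy: str = "geometric_mean"
) -> dict[str, tuple[float, FunctionalGroup]]:
    """Collapse a single metal's screened records to one tolerance per species.

    Returns ``{species: (tolerance μg/L, functional group)}``. Policies:
    ``geometric_mean`` (default, standard SSD practice), ``minimum``
    (most conservative single value).
    """
    metals = {r.metal for r in records}
    if len(metals) > 1:
        raise ValidationError(
            f"aggregate_by_species expects a single metal, got {sorted(m.value for m in metals)}"
        )
    grouped: dict[str, list[ToxicityRecord]] = {}
    for r in records:
        grouped.setdefault(r.species, []).append(r)
    out: dict[str, tuple[float, FunctionalGroup]] = {}
    for species, recs in grouped.items():
        values = [r.value for r in recs]
        if len(values) == 1:
            tol = float(values[0])
        elif policy == "geometric_mean":
            tol = geometric_mean(values)
        elif policy == "minimum":
            tol = float(min(values))
        else:
            raise ValueError(f"unknown aggregation policy {policy!r}")
        out[species] = (tol, recs[0].functional_group)
    return out


@dataclass(frozen=True)
class SSDModel:
    """A fitted species sensitivity distribution with its HC5."""

    metal: Metal
    fitted: FittedDistribution
    n_species: int
    n_records: int
    hc5: float
    gof: GofReport
    ranking: tuple[GofReport, ...] = ()
    aggregation_policy: str = "geometric_mean"

    def __post_init__(self) -> None:
        if self.n_species > self.n_records:
            raise ValidationError("n_species cannot exceed n_records")


def fit_ssd(
    tolerances: Sequence[float],
    groups: Sequence[FunctionalGroup] | None = None,
    metal: Metal | None = None,
    families: Sequence[Family] = ALL_FAMILIES,
    n_boot: int = 999,
    seed: int | None = 0,
    n_records: int | None = None,
    aggregation_policy: str = "geometric_mean",
) -> SSDModel:
    """Fit an SSD to per-species tolerances and derive HC5.

    All candidate families are attempted; the Anderson–Darling p-value
    (parametric bootstrap, ``n_boot`` resamples) selects the winner, with
    AIC breaking ties. The adequacy floor — at least 8 species and, when
    group labels are supplied, at least 3 functional groups — is enforced
    before any fitting.
    """
    tol = np.asarray(tolerances, dtype=float)
    if tol.size < MIN_SPECIES:
        raise ValidationError(
            f"SSD adequacy violated: {tol.size} species < required {MIN_SPECIES}"
        )
    if groups is not None:
        n_groups = len(set(groups))
        if n_groups < MIN_GROUPS:
            raise ValidationError(
                f"SSD adequacy violated: {n_groups} functional group(s) < required {MIN_GROUPS}"
            )
    best, ranking = select_model(
        tol, families=families, criterion="ad_p_and_aic", n_boot=n_boot, seed=seed
    )
    hc5 = float(best.quantile(0.05))
    return SSDModel(
        metal=metal if metal is not None else Metal.CU,
        fitted=best,
        n_species=int(tol.size),
        n_records=int(n_records if n_records is not None else tol.size),
        hc5=hc5,
        gof=ranking[0],
        ranking=tuple(ranking),
        aggregation_policy=aggregation_policy,
    )


def build_ssd(
    records: Sequence[ToxicityRecord],
    rules: ScreeningRules = DEFAULT_RULES,
    policy: str = "geometric_mean",
    families: Sequence[Family] = ALL_FAMILIES,
    n_boot: int = 999,
    seed: int | None = 0,
) -> SSDModel:
    """Screen → aggregate → fit, for one metal's toxicity records."""
    metals = {r.metal for r in records}
    if len(metals) != 1:
        raise ValidationError(
            f"build_ssd expects records for exactly one metal, got "
            f"{sorted(m.value for m in metals)}"
        )
    (metal,) = metals
    screened = screen_toxicity(records, rules)
    species = aggregate_by_species(screened, policy=policy)
    tolerances = [v for v, _ in species.values()]
    groups = [g for _, g in species.values()]
    return fit_ssd(
        tolerances,
        groups=groups,
        metal=metal,
        families=families,
        n_boot=n_boot,
        seed=seed,
        n_records=len(screened),
        aggregation_policy=policy,
    )


def pnec(hc5: float, safety_factor: float) -> float:
    """Predicted no effect concentration = HC5 / safety factor (μg/L)."""
    if not hc5 > 0:
        raise ValidationError(f"HC5 must be > 0, got {hc5}")
    if not safety_factor > 0:
        raise ValidationError(f"safety factor must be > 0, got {safety_factor}")
    return hc5 / safety_factor
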