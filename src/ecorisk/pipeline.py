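"""End-to-end orchestration of the sediment and aquatic risk tracks.

The drivers under ``analysis/`` and the command-line interface are thin
wrappers over these functions, so every reported number is computed by the
package and is reproducible from a seed. Seasons are always analyzed
separately; the two campaigns are never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aquatic as aq
from . import sediment as sed
from .core import (
    ConcentrationRecord,
    Matrix,
    Metal,
    ToxicityRecord,
    ValidationError,
    collapse_replicates,
    geometric_mean,
    stratify,
    values_of,
)
from .distributions import ALL_FAMILIES, Family, FittedDistribution, GofReport, select_model
from .reference import ReferenceTable, DEFAULT_REFERENCE
from .ssd import DEFAULT_RULES, SSDModel, ScreeningRules, build_ssd, pnec

logger = logging.getLogger(__name__)

_METAL_ORDER = [m for m in Metal]


def _child_seed(seed: int, *tags: str) -> int:
    """Deterministic sub-seed derived from a base seed and string tags.

    Uses a stable digest (not the builtin ``hash``, which is randomized
    per process) so reruns of the same configuration match exactly.
    """
    import hashlib

    digest = hashlib.sha256("|".join(tags).encode()).digest()
    ss = np.random.SeedSequence([seed, int.from_bytes(digest[:4], "big")])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_exposure_distributions(
    records: Sequence[ConcentrationRecord],
    matrix: Matrix,
    families: Sequence[Family] = ALL_FAMILIES,
    replicate_policy: str = "mean",
) -> dict[tuple[str, Metal], tuple[FittedDistribution, list[GofReport]]]:
    """Fit and select a concentration distribution per (season, metal).

    Replicates are combined per station first (default: station means);
    the naive Kolmogorov–Smirnov p-value ranks the candidate families,
    with Burr III limit cases excluded automatically.
    """
    subset = [r for r in records if r.matrix is matrix]
    collapsed = collapse_replicates(subset, policy=replicate_policy)
    out = {}
    for (season, metal), recs in sorted(
        stratify(collapsed).items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        if len(recs) < 3:
            raise ValidationError(
                f"need >= 3 stations to fit {metal.value} / {season}, got {len(recs)}"
            )
        best, ranking = select_model(values_of(recs), families=families, criterion="ks_p")
        logger.info(
            "%s %s %s: selected %s (KS p=%.3f)",
            matrix.value, season, metal.value, best.family.value, ranking[0].ks_p,
        )
        out[(season, metal)] = (best, ranking)
    return out


@dataclass
class SedimentReport:
    """Per-metal risk factors with Monte Carlo grade probabilities, plus RI rows."""

    eri_table: pd.DataFrame
    ri_table: pd.DataFrame
    rankings: dict[tuple[str, Metal], list[GofReport]] = field(default_factory=dict)


def sediment_assessment(
    records: Sequence[ConcentrationRecord],
    ref: ReferenceTable = DEFAULT_REFERENCE,
    n_draws: int = 100_000,
    seed: int = 0,
    families: Sequence[Family] = ALL_FAMILIES,
    replicate_policy: str = "mean",
) -> SedimentReport:
    """The full sediment track: fit, point Eri/RI, Monte Carlo grade probabilities.

    The "average" Eri of each metal is computed from the stratum's mean
    station concentration; the grade probabilities come from ``n_draws``
    Monte Carlo propagations of the selected concentration distribution.
    """
    fits = fit_exposure_distributions(
        records, Matrix.SEDIMENT, families=families, replicate_policy=replicate_policy
    )
    seasons = sorted({season for season, _ in fits})

    eri_rows = []
    ri_rows = []
    rankings = {}
    collapsed = [
        r
        for r in collapse_replicates(
            [r for r in records if r.matrix is Matrix.SEDIMENT], policy=replicate_policy
        )
    ]
    strata = stratify(collapsed)
    for season in seasons:
        season_eris = []
        season_dists = {}
        for metal in _METAL_ORDER:
            best, ranking = fits[(season, metal)]
            rankings[(season, metal)] = ranking
            mean_conc = float(np.mean(values_of(strata[(season, metal)])))
            point = sed.eri(mean_conc, metal, ref)
            season_eris.append(point)
            season_dists[metal] = best
            mc = sed.mc_eri(
                best, metal, ref, n_draws=n_draws,
                seed=_child_seed(seed, "eri", season, metal.value),
            )
            eri_rows.append(
                {
                    "season": season,
                    "metal": metal.value,
                    "family": best.family.value,
                    "average_eri": point.eri,
                    "grade": point.grade.value,
                    **{f"p_{g}": p for g, p in mc.grade_probabilities.items()},
                }
            )
        total = sed.ri(season_eris)
        mc_total = sed.mc_ri(
            season_dists, ref, n_draws=n_draws, seed=_child_seed(seed, "ri", season)
        )
        ri_rows.append(
            {
                "season": season,
                "ri": total.ri,
                "grade": total.grade.value,
                **{f"p_{g}": p for g, p in mc_total.grade_probabilities.items()},
            }
        )
    return SedimentReport(
        eri_table=pd.DataFrame(eri_rows),
        ri_table=pd.DataFrame(ri_rows),
        rankings=rankings,
    )


@dataclass
class AquaticReport:
    """SSD/HC5/PNEC per metal, HQ per (metal, season), JPC/ORP per (metal, season)."""

    ssd_table: pd.DataFrame
    hq_table: pd.DataFrame
    orp_table: pd.DataFrame
    ssd_models: dict[Metal, SSDModel] = field(default_factory=dict)
    jpc_curves: dict[tuple[str, Metal], aq.JPCResult] = field(default_factory=dict)


def aquatic_assessment(
    conc_records: Sequence[ConcentrationRecord],
    tox_records: Sequence[ToxicityRecord],
    ref: ReferenceTable = DEFAULT_REFERENCE,
    rules: ScreeningRules = DEFAULT_RULES,
    aggregation_policy: str = "geometric_mean",
    eec_policy: str = "geometric",
    grid_size: int = 10_001,
    ad_boot: int = 199,
    seed: int = 0,
    families: Sequence[Family] = ALL_FAMILIES,
    replicate_policy: str = "mean",
) -> AquaticReport:
    """The full aquatic track: SSD → HC5 → PNEC → HQ → JPC → ORP.

    The EEC of each (metal, season) is the geometric mean of the station
    values by default (``eec_policy="arithmetic"`` switches to the
    arithmetic mean). The JPC pairs each metal's SSD with the seasonal
    exposure distribution selected by the KS criterion.
    """
    if eec_policy not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown EEC policy {eec_policy!r}")

    # Effects side: one SSD per metal.
    ssd_models: dict[Metal, SSDModel] = {}
    ssd_rows = []
    by_metal: dict[Metal, list[ToxicityRecord]] = {}
    for r in tox_records:
        by_metal.setdefault(r.metal, []).append(r)
    for metal in _METAL_ORDER:
        if metal not in by_metal:
            raise ValidationError(f"no toxicity records for {metal.value}")
        model = build_ssd(
            by_metal[metal],
            rules=rules,
            policy=aggregation_policy,
            families=families,
            n_boot=ad_boot,
            seed=_child_seed(seed, "ssd", metal.value),
        )
        ssd_models[metal] = model
        ssd_rows.append(
            {
                "metal": metal.value,
                "family": model.fitted.family.value,
                "n_species": model.n_species,
                "n_records": model.n_records,
                "ad_A2": model.gof.ad_A2,
                "ad_p": model.gof.ad_p,
                "aic": model.gof.aic,
                "hc5_ugL": model.hc5,
                "pnec_ugL": pnec(model.hc5, ref.safety_factor),
            }
        )

    # Exposure side: seasonal fits and EECs.
    exposure_fits = fit_exposure_distributions(
        conc_records, Matrix.SEAWATER, families=families, replicate_policy=replicate_policy
    )
    collapsed = collapse_replicates(
        [r for r in conc_records if r.matrix is Matrix.SEAWATER], policy=replicate_policy
    )
    strata = stratify(collapsed)
    seasons = sorted({season for season, _ in exposure_fits})

    hq_rows = []
    orp_rows = []
    jpc_curves = {}
    for season in seasons:
        for metal in _METAL_ORDER:
            values = values_of(strata[(season, metal)])
            eec = (
                geometric_mean(values)
                if eec_policy == "geometric"
                else float(values.mean())
            )
            model = ssd_models[metal]
            p = pnec(model.hc5, ref.safety_factor)
            hq = aq.hazard_quotient(eec, p, metal=metal, season=season)
            hq_rows.append(
                {
                    "season": season,
                    "metal": metal.value,
                    "eec_ugL": eec,
                    "pnec_ugL": p,
                    "hq": hq.hq,
                    "flag": hq.flag.value,
                }
            )
            exposure, _ = exposure_fits[(season, metal)]
            curve = aq.jpc(model.fitted, exposure, grid_size=grid_size)
            jpc_curves[(season, metal)] = curve
            orp_rows.append(
                {
                    "season": season,
                    "metal": metal.value,
                    "exposure_family": exposure.family.value,
                    "orp": curve.orp,
                    "decision": curve.decision.value,
                }
            )
    return AquaticReport(
        ssd_table=pd.DataFrame(ssd_rows),
        hq_table=pd.DataFrame(hq_rows),
        orp_table=pd.DataFrame(orp_rows),
        ssd_models=ssd_models,
        jpc_curves=jpc_curves,
    )
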