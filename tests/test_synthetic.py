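"""Scenario encoding, generator determinism and closed-loop pipeline behavior."""

import numpy as np
import pytest

from ecorisk.core import FunctionalGroup, Matrix, Metal, ValidationError, collapse_replicates, values_of
from ecorisk.distributions import Family, fit_mle
from ecorisk.reference import DEFAULT_REFERENCE as REF
from ecorisk.sediment import mc_eri
from ecorisk.ssd import DEFAULT_RULES, screen_toxicity
from ecorisk.synthetic import (
    SEASON_AUTUMN,
    SEASON_SPRING,
    ConcentrationScenario,
    StratumSpec,
    ToxicityScenario,
    gen_concentrations,
    gen_toxicity,
    laizhou_scenario,
)


class TestScenarioDefaults:
    def test_seawater_spring_zn_stratum(self, scenarios):
        conc_sc, _ = scenarios
        spec = conc_sc.strata[("seawater", SEASON_SPRING, "Zn")]
        assert (spec.mean, spec.sd) == (40.48, 5.35)
        assert (spec.minimum, spec.maximum) == (30.90, 49.80)

    def test_station_roster_sizes(self, scenarios):
        conc_sc, _ = scenarios
        assert conc_sc.n_stations == {"sediment": 10, "seawater": 20}
        assert conc_sc.n_replicates == 3

    def test_group_counts_totals(self, scenarios):
        _, tox_sc = scenarios
        totals = {m: sum(c.values()) for m, c in tox_sc.group_counts.items()}
        assert totals == {"As": 23, "Cd": 51, "Cr": 38, "Cu": 123, "Hg": 20, "Pb": 29, "Zn": 52}
        assert sum(totals.values()) == 336

    def test_yaml_roundtrip(self, scenarios, tmp_path):
        conc_sc, tox_sc = scenarios
        conc_sc.save(tmp_path / "c.yaml")
        tox_sc.save(tmp_path / "t.yaml")
        assert ConcentrationScenario.load(tmp_path / "c.yaml") == conc_sc
        assert ToxicityScenario.load(tmp_path / "t.yaml") == tox_sc

    def test_invalid_stratum_rejected(self):
        with pytest.raises(ValidationError):
            StratumSpec(mean=5.0, sd=1.0, minimum=6.0, maximum=10.0)
        with pytest.raises(ValidationError):
            StratumSpec(mean=5.0, sd=0.0, minimum=1.0, maximum=10.0)


class TestConcentrationGenerator:
    def test_values_inside_printed_range(self, conc_records, scenarios):
        conc_sc, _ = scenarios
        for r in conc_records:
            spec = conc_sc.strata[(r.matrix.value, r.season, r.metal.value)]
            assert spec.minimum <= r.value <= spec.maximum

    def test_hg_autumn_station_count(self, conc_records):
        hg = [
            r
            for r in conc_records
            if r.matrix is Matrix.SEDIMENT
            and r.season == SEASON_AUTUMN
            and r.metal is Metal.HG
        ]
        assert len({r.station_id for r in hg}) == 10
        assert len(hg) == 30  # 3 replicates each

    def test_same_seed_byte_identical(self, scenarios):
        conc_sc, _ = scenarios
        a = gen_concentrations(conc_sc, seed=21)
        b = gen_concentrations(conc_sc, seed=21)
        assert a == b

    def test_vanishing_sd_limit(self):
        sc = ConcentrationScenario(
            strata={("seawater", "s", "Cu"): StratumSpec(2.0, 1e-6, 1.0, 3.0)},
            n_replicates=1,
        )
        vals = values_of(gen_concentrations(sc, seed=1))
        # residual spread comes only from the 2% replicate jitter
        assert np.allclose(vals, 2.0, rtol=0.1)
        assert abs(vals.mean() - 2.0) < 0.02

    def test_infeasible_truncation_rejected(self):
        sc = ConcentrationScenario(
            strata={("seawater", "s", "Cu"): StratumSpec(1.5, 100.0, 1.0, 2.0)},
        )
        with pytest.raises(ValidationError, match="infeasible truncation"):
            gen_concentrations(sc, seed=1)

    def test_sample_mean_tracks_target(self, scenarios):
        """Median relative error of the stratum mean stays under 15% at n=10."""
        conc_sc, _ = scenarios
        errs = []
        for seed in range(50):
            recs = gen_concentrations(
                ConcentrationScenario(
                    strata={
                        ("sediment", SEASON_AUTUMN, "Hg"): conc_sc.strata[
                            ("sediment", SEASON_AUTUMN, "Hg")
                        ]
                    },
                    n_replicates=1,
                ),
                seed=seed,
            )
            errs.append(abs(values_of(recs).mean() - 0.025) / 0.025)
        assert np.median(errs) < 0.15


class TestToxicityGenerator:
    def test_cu_counts_and_groups(self, tox_records):
        cu = [r for r in tox_records if r.metal is Metal.CU]
        assert len(cu) == 123
        assert {r.functional_group for r in cu} == set(FunctionalGroup)

    def test_screening_compliant_by_construction(self, tox_records):
        assert len(screen_toxicity(tox_records, DEFAULT_RULES)) == len(tox_records)

    def test_deterministic_under_seed(self, scenarios):
        _, tox_sc = scenarios
        assert gen_toxicity(tox_sc, seed=9) == gen_toxicity(tox_sc, seed=9)

    def test_closed_loop_hc5_recovery(self, scenarios):
        """Fitting SSDs to generated Cu data recovers the scenario's HC5 within 25%."""
        from ecorisk.ssd import build_ssd

        _, tox_sc = scenarios
        true_hc5 = tox_sc.ssd_distribution("Cu").quantile(0.05)
        errs = []
        for seed in range(10):
            cu = [r for r in gen_toxicity(tox_sc, seed=seed) if r.metal is Metal.CU]
            model = build_ssd(cu, n_boot=19, seed=seed)
            errs.append(abs(model.hc5 - true_hc5) / true_hc5)
        assert np.median(errs) < 0.25


class TestClosedLoopSediment:
    def test_autumn_hg_moderate_tail_structure(self, scenarios):
        """Generated sediment reproduces the qualitative risk structure:
        every stratum 100% low except a sub-0.5% moderate tail for autumn Hg."""
        conc_sc, _ = scenarios
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            recs = gen_concentrations(conc_sc, seed=seed)
            sed = [r for r in recs if r.matrix is Matrix.SEDIMENT]
            good = True
            for season in (SEASON_SPRING, SEASON_AUTUMN):
                for metal in Metal:
                    vals = values_of(
                        collapse_replicates(
                            [r for r in sed if r.season == season and r.metal is metal]
                        )
                    )
                    fit = fit_mle(Family.LOG_LOGISTIC, vals)
                    mc = mc_eri(fit, metal, REF, n_draws=20_000, seed=seed)
                    probs = mc.grade_probabilities
                    if season == SEASON_AUTUMN and metal is Metal.HG:
                        good &= probs["low"] >= 99.5 and probs["moderate"] <= 0.5
                    else:
                        good &= probs["low"] == 100.0
            ok += good
        assert ok >= 0.8 * n_seeds
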