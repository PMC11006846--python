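import numpy as np
import pandas as pd
import pytest

import hemobayes as hb
from hemobayes.panel import SummaryStats
from hemobayes.simulate import (
    PANEL_CALIBRATION,
    reconstruct_calibration_sample,
)


def _stats(mn, q25, q50, q75, mx, n, mean=None, sd=None):
    x = np.interp(np.arange(n) / (n - 1), [0, 0.25, 0.5, 0.75, 1], [mn, q25, q50, q75, mx])
    return SummaryStats(
        variable="x",
        treatment="Bas",
        min=mn,
        q25=q25,
        mean=float(x.mean()) if mean is None else mean,
        q50=q50,
        sd=float(x.std(ddof=1)) if sd is None else sd,
        q75=q75,
        max=mx,
        n_obs=n,
    )


class TestReconstruct:
    def test_exact_five_point_case(self):
        out = hb.reconstruct_from_quantiles(_stats(0, 1, 2, 3, 4, 5))
        np.testing.assert_allclose(out, [0, 1, 2, 3, 4], atol=1e-9)

    def test_median_matches_for_valid_inputs(self):
        for n in (7, 20, 73):
            out = hb.reconstruct_from_quantiles(_stats(-2, 0.5, 1.0, 1.8, 6.0, n))
            assert np.median(out) == pytest.approx(1.0, abs=0.15)

    def test_ph_basal_row_matches_printed_mean_and_sd(self):
        out = reconstruct_calibration_sample("pH", "Bas")
        row = PANEL_CALIBRATION["pH"]["Bas"]
        assert out.size == 73
        assert out.mean() == pytest.approx(7.53, abs=0.02)
        assert out.std(ddof=1) == pytest.approx(row.sd, abs=0.01)
        assert out.min() == row.min and out.max() == row.max
        assert np.quantile(out, 0.25) == pytest.approx(row.q25, abs=0.01)

    def test_non_monotone_summary_rejected(self):
        with pytest.raises(hb.DomainError):
            hb.reconstruct_from_quantiles(_stats(0, 2, 1, 3, 4, 10))


class TestCohortGeneration:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = hb.default_study_config(seed=33)
        a, b = hb.generate_cohort(cfg), hb.generate_cohort(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        hb.write_study_table(a, pa)
        hb.write_study_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_all_sixteen_variables_present(self):
        table = hb.generate_cohort(hb.default_study_config(seed=1))
        assert set(table.df["variable"]) == set(hb.PANEL_VARIABLES)

    def test_subsample_sizes_match_configuration(self):
        cfg = hb.default_study_config(seed=2)
        table = hb.generate_cohort(cfg)
        for name, spec in cfg.variables.items():
            assert len(table.values(name, "Bas")) == spec.n_basal
            assert len(table.values(name, "CO2")) == spec.n_treated

    def test_pairing_integrity(self):
        table = hb.generate_cohort(hb.default_study_config(seed=3))
        for v in hb.PANEL_VARIABLES:
            bas = set(table.df[(table.df.variable == v) & (table.df.treatment == "Bas")].animal_id)
            co2 = set(table.df[(table.df.variable == v) & (table.df.treatment == "CO2")].animal_id)
            assert co2 <= bas

    def test_null_design_has_no_systematic_shift(self):
        cfg = hb.default_study_config(seed=4, outlier_rate=0.0)
        spec = cfg.variables["pH"]
        from dataclasses import replace

        cfg.variables["pH"] = replace(spec, shift=0.0, scale_mult=1.0)
        diffs = []
        for seed in range(10):
            cfg.seed = seed
            table = hb.generate_cohort(cfg)
            diffs.append(hb.build_differences(table, "pH").d.mean())
        # pooled mean difference within 3 SEs of zero
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-12

    def test_ph_paired_differences_negative(self):
        table = hb.generate_cohort(hb.default_study_config(seed=5))
        assert hb.build_differences(table, "pH").d.mean() < 0

    def test_tco2_effect_sign_positive(self):
        means = []
        for seed in range(5):
            t = hb.generate_cohort(hb.default_study_config(seed=seed))
            means.append(t.values("TCO2", "CO2").mean() - t.values("TCO2", "Bas").mean())
        assert np.mean(means) > 0

    def test_calibration_of_generated_means(self):
        """Screened per-stratum means track the published calibration
        targets within half a published sd, averaged over seeds."""
        errs = {(v, t): [] for v in PANEL_CALIBRATION for t in ("Bas", "CO2")}
        for seed in range(10):
            table = hb.generate_cohort(hb.default_study_config(seed=100 + seed))
            screened, _ = hb.screen_table(table)
            for v, strata in PANEL_CALIBRATION.items():
                for t in ("Bas", "CO2"):
                    errs[(v, t)].append(screened.values(v, t).mean() - strata[t].mean)
        for (v, t), e in errs.items():
            assert abs(np.mean(e)) <= 0.5 * PANEL_CALIBRATION[v][t].sd, (v, t, np.mean(e))

    def test_pco2_basal_mean_close_to_target(self):
        # the calibration targets are outlier-removed summaries, so
        # screen the generated strata the same way before comparing
        means = []
        for s in range(10):
            table = hb.generate_cohort(hb.default_study_config(seed=200 + s))
            screened, _ = hb.screen_table(table)
            means.append(screened.values("pCO2", "Bas").mean())
        assert np.mean(means) == pytest.approx(23.77, abs=2.0)

    def test_outlier_injection_recovered_by_screening(self):
        from dataclasses import replace

        injected, recovered = 0, 0
        for seed in range(20):
            cfg = hb.default_study_config(
                seed=400 + seed, outlier_rate=0.1, variables=["pH"]
            )
            cfg.variables["pH"] = replace(cfg.variables["pH"], n_basal=70, n_treated=20)
            table = hb.generate_cohort(cfg)
            _, audit = hb.screen_table(table)
            injected += sum(table.provenance["n_outliers_injected"].values())
            recovered += len(audit)
        assert injected > 0
        assert recovered >= 0.8 * injected

    def test_invalid_configs_rejected(self):
        with pytest.raises(hb.ConfigError):
            hb.VariableSimSpec("pH", "normal", (7.5, 0.05), n_basal=10, n_treated=20)
        with pytest.raises(hb.ConfigError):
            hb.VariableSimSpec("pH", "normal", (7.5, 0.05), 10, 5, outlier_rate=0.5)
        with pytest.raises(hb.ConfigError):
            hb.VariableSimSpec("nope", "normal", (0, 1), 10, 5)
        with pytest.raises(hb.ConfigError):
            hb.CohortConfig(n_animals=10, variables={
                "pH": hb.VariableSimSpec("pH", "normal", (7.5, 0.05), 20, 5)
            })


class TestSimulatePaired:
    def test_mean_difference_matches_construction(self):
        s = hb.simulate_paired("pH", 2000, 7.53, 0.05, 7.15, 0.21, rho=0.5, seed=6)
        assert s.d.mean() == pytest.approx(-0.38, abs=0.02)

    def test_correlation_structure(self):
        gen_seed = 7
        s = hb.simulate_paired("pH", 5000, 0.0, 1.0, 0.0, 1.0, rho=0.8, seed=gen_seed)
        # var(d) = 2(1 - rho) for equal unit sds
        assert s.d.var(ddof=1) == pytest.approx(0.4, abs=0.05)


class TestConfigSerialisation:
    def test_yaml_round_trip(self, tmp_path):
        cfg = hb.default_study_config(seed=12)
        p = tmp_path / "cohort.yaml"
        hb.save_cohort_config(cfg, p)
        back = hb.load_cohort_config(p)
        assert back.n_animals == cfg.n_animals and back.seed == cfg.seed
        assert back.variables == cfg.variables
        pd.testing.assert_frame_equal(
            hb.generate_cohort(back).df, hb.generate_cohort(cfg).df
        )

    def test_malformed_config_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("variables:\n  pH: {family: normal}\n")
        with pytest.raises(hb.ConfigError):
            hb.load_cohort_config(p)
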