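"""Replication orchestration, aggregation, reports, and CLI."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mocasim import (
    RunConfig,
    ScoreGenParams,
    apply_correction,
    auc,
    fit_normative,
    generate_raw_scores,
    get_equation,
    run_replication,
    run_simulation,
    sample_cohort,
    write_reports,
)
from mocasim.engine import PRESETS

SMALL = dict(n_dev=1000, n_val=4000, n_reps=3)


class TestRunConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            RunConfig(n_reps=0)
        with pytest.raises(ValueError):
            RunConfig(residual_sd=-1.0)
        with pytest.raises(KeyError):
            RunConfig(equation="unknown")

    def test_presets(self):
        assert RunConfig.with_preset("eq3").equation == "santangelo"
        assert RunConfig.with_preset("rounded").round_and_clip
        assert RunConfig.with_preset("sd34").residual_sd == 3.4
        assert RunConfig.with_preset("sd34", n_reps=7).n_reps == 7


class TestRunReplication:
    def test_same_seed_is_bit_identical(self, table):
        cfg = RunConfig(**SMALL, master_seed=3)
        a = run_replication(cfg, 123, table=table)
        b = run_replication(cfg, 123, table=table)
        assert a.scalars == b.scalars
        pd.testing.assert_frame_equal(a.strata, b.strata)

    def test_perfect_separation_limit(self, table):
        cfg = RunConfig(
            n_dev=500, n_val=2000, n_reps=1, residual_sd=1e-6,
            offset_mci=100.0, offset_dementia=200.0,
        )
        res = run_replication(cfg, 0, table=table)
        assert res.scalars["auc_raw_impaired"] == 1.0
        assert res.scalars["auc_raw_mci"] == 1.0
        assert res.scalars["auc_corrected_impaired"] == 1.0

    def test_no_covariate_effect_makes_correction_inert(self, table, rng):
        # with zero age/education coefficients the correction is an additive
        # constant up to noise, so the AUC difference vanishes within MC error
        flat = dataclasses.replace(
            get_equation("montemurro"), age_coefficient=0.0, edu_coefficient=0.0
        )
        params = ScoreGenParams()
        dev = generate_raw_scores(sample_cohort(table, 5000, rng), flat, params, rng)
        val = generate_raw_scores(sample_cohort(table, 30_000, rng), flat, params, rng)
        model = fit_normative(dev, flat)
        val = apply_correction(val, model)
        healthy = val["status"] == "healthy"
        raw = val["raw_score"].to_numpy()
        corr = val["corrected_score"].to_numpy()
        d = auc(raw[~healthy], raw[healthy]) - auc(corr[~healthy], corr[healthy])
        assert abs(d) < 0.005

    def test_scalar_metrics_complete_and_bounded(self, table):
        res = run_replication(RunConfig(**SMALL), 5, table=table)
        for contrast in ["impaired", "mci"]:
            for st in ["raw", "corrected"]:
                assert 0.5 < res.scalars[f"auc_{st}_{contrast}"] <= 1.0
        for st in ["raw", "corrected"]:
            for c in ["spec977", "spec841", "sens841"]:
                assert 0.0 <= res.scalars[f"se_{st}_{c}"] <= 1.0
                assert 0.0 <= res.scalars[f"sp_{st}_{c}"] <= 1.0
        assert len(res.strata) == 35 * 6


class TestRunSimulation:
    def test_single_rep_summary_collapses(self, table):
        cfg = RunConfig(n_dev=800, n_val=3000, n_reps=1, master_seed=11)
        summary = run_simulation(cfg, table=table)
        rep = run_replication(
            cfg, np.random.SeedSequence(11, spawn_key=(0,)), table=table
        )
        for name, value in rep.scalars.items():
            row = summary.scalars.loc[name]
            assert row["mean"] == pytest.approx(value, abs=1e-12)
            assert row["p2.5"] == pytest.approx(value, abs=1e-12)
            assert row["p97.5"] == pytest.approx(value, abs=1e-12)

    def test_percentiles_bracket_mean(self, table):
        summary = run_simulation(RunConfig(**{**SMALL, "n_reps": 5}), table=table)
        s = summary.scalars.dropna()
        assert (s["p2.5"] <= s["mean"] + 1e-12).all()
        assert (s["mean"] <= s["p97.5"] + 1e-12).all()

    def test_summary_reproducible_from_master_seed(self, table):
        cfg = RunConfig(**SMALL, master_seed=99)
        a = run_simulation(cfg, table=table)
        b = run_simulation(cfg, table=table)
        pd.testing.assert_frame_equal(a.scalars, b.scalars)
        pd.testing.assert_frame_equal(a.strata, b.strata)

    @pytest.mark.parametrize("equation", ["aiello", "conti", "santangelo", "montemurro"])
    def test_raw_auc_exceeds_corrected_under_every_equation(self, table, equation):
        cfg = RunConfig(
            equation=equation, n_dev=1000, n_val=5000, n_reps=50, master_seed=4
        )
        summary = run_simulation(cfg, table=table)
        assert summary.scalars.loc["auc_diff_impaired", "mean"] > 0
        assert summary.scalars.loc["auc_diff_mci", "mean"] > 0

    def test_raw_stratum_sensitivity_follows_risk_gradient(self, table):
        # at the specificity-84.1% cutoff the raw-score sensitivity rises
        # with age and falls with education, while corrected-score stratum
        # sensitivities are homogeneous
        cfg = RunConfig(n_dev=2000, n_val=30_000, n_reps=60, master_seed=8)
        summary = run_simulation(cfg, table=table)
        st = summary.strata.set_index(["score_type", "cutoff", "age_low", "edu_years"])
        raw = st.loc[("raw", "spec841")]["sensitivity_mean"]
        assert raw.loc[(85, 5)] > raw.loc[(55, 5)]  # increases with age
        assert raw.loc[(55, 5)] > raw.loc[(55, 17)]  # decreases with education
        corr = st.loc[("corrected", "spec841")]["sensitivity_mean"].dropna()
        # homogeneous up to sampling noise; the sparsest strata see only a
        # handful of MCI cases per replication
        assert corr.max() - corr.min() < 0.12


class TestPerStratumCutoffs:
    def test_per_stratum_cutoffs_equalize_raw_and_corrected(self, table, rng):
        # when the cutoff is the same quantile of each stratum's own healthy
        # development scores, the correction (an additive shift per covariate
        # cell) cannot change who screens positive; with age fixed within
        # each stratum the equivalence is exact
        params = ScoreGenParams()
        eq = get_equation("aiello")
        dev = sample_cohort(table, 5000, rng)
        val = sample_cohort(table, 10_000, rng)
        for df in (dev, val):
            df["age"] = df["age_low"] + 2.5
        dev = generate_raw_scores(dev, eq, params, rng)
        val = generate_raw_scores(val, eq, params, rng)
        model = fit_normative(dev, eq)
        dev = apply_correction(dev, model)
        val = apply_correction(val, model)
        for score in ["raw_score", "corrected_score"]:
            cuts = (
                dev[dev["status"] == "healthy"]
                .groupby(["age_low", "edu_years"])[score]
                .quantile(1 - 0.841)
            )
            val[f"pos_{score}"] = val[score] < cuts.reindex(
                pd.MultiIndex.from_frame(val[["age_low", "edu_years"]])
            ).to_numpy()
        eva = val[val["status"] != "dementia"]
        pd.testing.assert_series_equal(
            eva["pos_raw_score"], eva["pos_corrected_score"], check_names=False
        )


class TestWriteReports:
    def test_report_schema_and_determinism(self, table, tmp_path):
        cfg = RunConfig(**SMALL, master_seed=13)
        summary = run_simulation(cfg, table=table)
        paths = write_reports(summary, tmp_path / "a")
        assert set(paths) == {
            "auc_summary", "marginal_sens_spec", "stratum_sens_spec", "manifest", "log",
        }
        auc_df = pd.read_csv(paths["auc_summary"])
        assert set(auc_df["metric"]) == {
            "auc_raw_impaired", "auc_corrected_impaired", "auc_diff_impaired",
            "auc_raw_mci", "auc_corrected_mci", "auc_diff_mci",
        }
        strata = pd.read_csv(paths["stratum_sens_spec"])
        assert len(strata) == 7 * 5 * 3 * 2
        marg = pd.read_csv(paths["marginal_sens_spec"])
        assert len(marg) == 18  # 6 se + 6 sp + 6 cutoffs
        paths2 = write_reports(run_simulation(cfg, table=table), tmp_path / "b")
        for name in ["auc_summary", "marginal_sens_spec", "stratum_sens_spec", "manifest"]:
            assert paths[name].read_text() == paths2[name].read_text()


class TestCli:
    def test_simulate_end_to_end(self, tmp_path):
        from click.testing import CliRunner

        from mocasim.cli import main

        cfgfile = tmp_path / "cfg.yaml"
        cfgfile.write_text("n_dev: 600\nn_val: 2000\n")
        result = CliRunner().invoke(
            main,
            [
                "simulate", "--config", str(cfgfile), "--reps", "2",
                "--seed", "5", "--out", str(tmp_path / "out"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "auc_summary.csv").exists()
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_preset_flag_overrides(self, tmp_path):
        from click.testing import CliRunner

        from mocasim.cli import main

        result = CliRunner().invoke(
            main,
            [
                "simulate", "--preset", "sd34", "--reps", "1", "--n-dev", "600",
                "--n-val", "1500", "--seed", "2", "--out", str(tmp_path / "o"),
            ],
        )
        assert result.exit_code == 0, result.output
        import json

        manifest = json.loads((tmp_path / "o" / "manifest.json").read_text())
        assert manifest["config"]["residual_sd"] == 3.4
        assert manifest["config"]["n_reps"] == 1

    def test_unknown_config_key_rejected(self, tmp_path):
        from click.testing import CliRunner

        from mocasim.cli import main

        cfgfile = tmp_path / "cfg.yaml"
        cfgfile.write_text("bogus: 1\n")
        result = CliRunner().invoke(main, ["simulate", "--config", str(cfgfile)])
        assert result.exit_code != 0
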