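import numpy as np
import pandas as pd
import pytest

from opsweep import (GeneratorConfig, allocate_cells, generate_cohort,
                     repeated_measures, sample_record)
from opsweep import tables
from opsweep.exceptions import ConfigurationError
from opsweep.synthetic import OutcomeSurfaces


class TestAllocation:
    def test_reference_allocation_exact(self):
        alloc = allocate_cells(903, "table3_exact")
        expected_totals = {("I", "hypo"): 102, ("I", "nor"): 109,
                           ("I", "hyper"): 106, ("II", "hypo"): 85,
                           ("II", "nor"): 107, ("II", "hyper"): 101,
                           ("III", "hypo"): 103, ("III", "nor"): 103,
                           ("III", "hyper"): 87}
        assert {c: sum(v) for c, v in alloc.items()} == expected_totals
        assert sum(f for f, _ in alloc.values()) == 550
        assert sum(m for _, m in alloc.values()) == 353

    def test_reference_allocation_requires_903(self):
        with pytest.raises(ConfigurationError):
            allocate_cells(900, "table3_exact")

    def test_uniform_nine(self):
        alloc = allocate_cells(9, "uniform")
        assert all(sum(v) == 1 for v in alloc.values())

    def test_proportional_matches_reference_within_one(self):
        alloc = allocate_cells(300, "proportional")
        totals = {c: sum(v) for c, v in alloc.items()}
        assert sum(totals.values()) == 300
        for c in tables.CELLS:
            quota = 300 * tables.cell_count(c) / 903
            assert abs(totals[c] - quota) <= 1.0

    def test_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            allocate_cells(100, "stratified")


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = GeneratorConfig(n=90, allocation="proportional", seed=5)
        a, ta = generate_cohort(cfg)
        b, tb = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seed_differs(self):
        a, _ = generate_cohort(GeneratorConfig(n=90, allocation="proportional",
                                               seed=5))
        b, _ = generate_cohort(GeneratorConfig(n=90, allocation="proportional",
                                               seed=6))
        assert not a.to_frame().drop(columns=["id", "sex"]).equals(
            b.to_frame().drop(columns=["id", "sex"]))


class TestDegenerate:
    def test_all_sds_zero_gives_cell_means(self, degenerate_config, rng):
        cfg = degenerate_config()
        for cell in (("I", "hypo"), ("III", "hyper")):
            rec = sample_record(cell, cfg, rng)
            for f in tables.INPUT_FEATURES:
                assert getattr(rec, f) == pytest.approx(
                    cfg.feature_stats[f][cell][0])
            assert rec.SNB == pytest.approx(rec.SNA - rec.ANB, abs=1e-9)

    def test_forced_snop_worked_examples_exact_under_hybrid(
            self, degenerate_config, rng):
        cfg = degenerate_config("hybrid")
        rec = sample_record(("I", "hypo"), cfg, rng, overrides={"SN_OP": 14.0})
        assert rec.FHR == pytest.approx(73.07 - 0.28 * 14, abs=1e-9)
        rec = sample_record(("III", "hypo"), cfg, rng,
                            overrides={"SN_OP": 11.2})
        assert rec.FA == pytest.approx(96.78 - 0.47 * 11.2, abs=1e-9)

    def test_additive_surface_within_interaction_residual(
            self, degenerate_config, rng):
        """The default additive surface drops the (small) sagittal x
        vertical interaction of the coefficient tables; at the cell-mean
        anatomy the intercept deviates by at most ~0.35 outcome units."""
        cfg = degenerate_config("additive")
        rec = sample_record(("I", "hypo"), cfg, rng, overrides={"SN_OP": 14.0})
        assert rec.FHR == pytest.approx(73.07 - 0.28 * 14, abs=0.4)
        rec = sample_record(("III", "hypo"), cfg, rng,
                            overrides={"SN_OP": 11.2})
        assert rec.FA == pytest.approx(96.78 - 0.47 * 11.2, abs=0.4)

    def test_unknown_cell_rejected(self, degenerate_config, rng):
        with pytest.raises(ConfigurationError):
            sample_record(("IV", "nor"), degenerate_config(), rng)


class TestGeneratingModel:
    def test_snop_derivative_equals_slope_surface(self, default_cohort):
        """Numerically differentiating the noise-free generating mean with
        respect to SN-OP returns the local slope surface value exactly
        (the intercept surface and couplings do not involve SN-OP)."""
        cohort, truth = default_cohort
        surf = OutcomeSurfaces(GeneratorConfig(seed=cohort.seed))
        X = cohort.inputs().to_numpy()[:25]
        j = list(tables.INPUT_FEATURES).index("SN_OP")
        for outcome, col in (("FHR", "k_FHR"), ("FA", "k_FA")):
            hi, lo = X.copy(), X.copy()
            hi[:, j] += 0.5
            lo[:, j] -= 0.5
            deriv = (surf.mean_outcome(hi, outcome)
                     - surf.mean_outcome(lo, outcome))
            np.testing.assert_allclose(deriv, truth[col].to_numpy()[:25],
                                       atol=1e-9)

    def test_truth_table_intercepts_reproduce_means(self, default_cohort):
        """b in the truth table is the record's effective intercept:
        noise-free mean = b + k * SN_OP."""
        cohort, truth = default_cohort
        surf = OutcomeSurfaces(GeneratorConfig(seed=cohort.seed))
        X = cohort.inputs().to_numpy()[:50]
        s = X[:, list(tables.INPUT_FEATURES).index("SN_OP")]
        mean = surf.mean_outcome(X, "FA")
        expect = truth["b_FA"].to_numpy()[:50] + truth["k_FA"].to_numpy()[:50] * s
        np.testing.assert_allclose(mean, expect, atol=1e-9)

    def test_generating_slopes_calibrated_per_cell(self, default_cohort):
        """Cell means of the generating slopes track the calibration
        targets (moment-matched in expectation; sampled at n ~ 100)."""
        _, truth = default_cohort
        g = truth.groupby(["sagittal", "vertical"])[["k_FHR", "k_FA"]].mean()
        for cell in tables.CELLS:
            assert g.loc[cell, "k_FHR"] == pytest.approx(
                tables.FHR_COEFFICIENTS[cell][0], abs=0.04)
            assert g.loc[cell, "k_FA"] == pytest.approx(
                tables.FA_COEFFICIENTS[cell][0], abs=0.04)

    def test_cell_feature_means_match_calibration(self, default_cohort):
        """Per-cell sample means of the (band-free) sampled features sit
        within 3 standard errors of the calibrated means."""
        cohort, _ = default_cohort
        df = cohort.to_frame()
        for field in ("SN_OP", "S_Go", "Go_Po", "SNA"):
            for cell in tables.CELLS:
                mu, sd = tables.FEATURE_STATS[field][cell]
                sub = df[(df.sagittal == cell[0]) & (df.vertical == cell[1])]
                se = sd / np.sqrt(len(sub))
                assert abs(sub[field].mean() - mu) < 3 * se + 1e-9, \
                    (field, cell)

    def test_truncation_respects_bands(self, default_cohort):
        cohort, _ = default_cohort
        df = cohort.to_frame()
        ii = df[df.sagittal == "II"]
        assert (ii["ANB"] > 5.0).all()
        hyper = df[df.vertical == "hyper"]
        assert (hyper["SN_MP"] > 36.0).all()
        assert (hyper["FH_MP"] > 30.0).all()


class TestRepeatedMeasures:
    def test_zero_noise_reproduces_truth(self, small_cohort):
        cohort, _ = small_cohort
        ratings, fields = repeated_measures(cohort, noise_fraction=0.0,
                                            seed=1)
        truth = cohort.to_frame()[list(fields)].to_numpy(float)
        assert np.allclose(ratings, truth[None, None])

    def test_deterministic_given_seed(self, small_cohort):
        cohort, _ = small_cohort
        a, _ = repeated_measures(cohort, seed=3)
        b, _ = repeated_measures(cohort, seed=3)
        assert np.array_equal(a, b)

    def test_variance_components_recovered(self):
        """Method-of-moments check: with explicit noise SDs the replicate
        variance matches the configured component within 10%."""
        cohort, _ = generate_cohort(
            GeneratorConfig(n=1000, allocation="proportional", seed=42))
        noise = {f: 2.0 for f in tables.ALL_FIELDS}
        ratings, fields = repeated_measures(cohort, n_raters=3, n_sessions=2,
                                            noise_sd=noise, seed=9)
        flat = ratings.reshape(6, len(cohort), len(fields))
        within = flat.var(axis=0, ddof=1).mean(axis=0)  # per field
        assert np.all(np.abs(within - 4.0) < 0.4)

    def test_parameter_validation(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ConfigurationError):
            repeated_measures(cohort, n_raters=0)
        with pytest.raises(ConfigurationError):
            repeated_measures(cohort, noise_fraction=-0.1)


def test_config_yaml_round_trip(tmp_path):
    cfg = GeneratorConfig(n=100, allocation="proportional", seed=9,
                          sigma_fhr=0.3, surface_form="hybrid")
    path = tmp_path / "gen.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert (back.n, back.allocation, back.seed) == (100, "proportional", 9)
    assert back.sigma_fhr == 0.3
    assert back.surface_form == "hybrid"
    assert back.feature_stats == cfg.feature_stats
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(back)
    pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(n=500).validate()  # table3_exact needs 903
    with pytest.raises(ConfigurationError):
        GeneratorConfig(sigma_fhr=-1.0, n=90,
                        allocation="proportional").validate()
    with pytest.raises(ConfigurationError):
        GeneratorConfig(surface_form="cubic").validate()
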