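import itertools

import numpy as np
import pandas as pd
import pytest

from opsweep import (build_table56, compare_groups, icc, normality_screen,
                     repeated_measures)
from opsweep import tables
from opsweep.exceptions import ConfigurationError
from opsweep.stats import dunn_test, reliability_report


class TestNormalityScreen:
    def test_gaussian_sample_passes(self, rng):
        res = normality_screen(rng.normal(size=500))
        assert res.normal and res.p_lilliefors > 0.05

    def test_uniform_sample_fails(self, rng):
        res = normality_screen(rng.uniform(size=200))
        assert not res.normal

    def test_constant_sample_degenerate(self):
        res = normality_screen(np.full(20, 3.0))
        assert res.degenerate and not res.normal

    def test_reports_both_p_values(self, rng):
        res = normality_screen(rng.normal(size=100))
        assert 0.0 <= res.p_lilliefors <= 1.0
        assert 0.0 <= res.p_ks <= 1.0


class TestCompareGroups:
    def test_shifted_group_flagged(self, rng):
        groups = {"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100),
                  "c": rng.normal(3, 1, 100)}
        rep = compare_groups(groups)
        sig = {frozenset(p) for p in rep.significant_pairs()}
        assert frozenset(("a", "c")) in sig
        assert frozenset(("b", "c")) in sig
        assert frozenset(("a", "b")) not in sig

    def test_identical_groups_have_no_markers(self):
        base = np.arange(30.0)
        rep = compare_groups({"a": base, "b": base.copy()})
        assert rep.significant_pairs() == []

    def test_bonferroni_cap_formula(self, rng):
        groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(0.4, 1, 40),
                  "c": rng.normal(0.8, 1, 40)}
        rep = compare_groups(groups)
        np.testing.assert_allclose(
            rep.pairwise["p_adj"],
            np.minimum(1.0, 3 * rep.pairwise["p_raw"]))
        assert (rep.pairwise["p_adj"] >= rep.pairwise["p_raw"] - 1e-15).all()

    def test_route_follows_screening(self, rng):
        normal = {k: rng.normal(0, 1, 60) for k in "abc"}
        assert compare_groups(normal).route == "anova_bonferroni"
        skewed = {k: rng.exponential(1.0, 60) for k in "abc"}
        assert compare_groups(skewed).route == "kruskal_dunn"

    def test_small_group_excluded(self, rng):
        rep = compare_groups({"a": rng.normal(size=30),
                              "b": rng.normal(size=30), "tiny": [1.0, 2.0]})
        assert rep.excluded == ["tiny"]
        with pytest.raises(ConfigurationError):
            compare_groups({"a": rng.normal(size=30), "tiny": [1.0]})

    def test_family_wise_error_under_null(self):
        """FWER of the full two-branch procedure stays at or below alpha
        over 1000 null simulations with three equal groups."""
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = {k: rng.normal(0.0, 1.0, 10) for k in "abc"}
            if compare_groups(groups).significant_pairs():
                hits += 1
        assert hits / reps <= 0.05


class TestDunn:
    def test_matches_brute_force_ranks(self, rng):
        """Dunn z statistics agree with an explicit rank reimplementation
        (loops, no shared code) to 1e-10 on small samples with ties."""
        groups = {"a": np.round(rng.normal(0, 1, 12), 1),
                  "b": np.round(rng.normal(0.5, 1, 15), 1),
                  "c": np.round(rng.normal(1.0, 1, 9), 1)}
        out = dunn_test(groups).set_index(["group_1", "group_2"])

        pooled = np.concatenate(list(groups.values()))
        order = np.argsort(pooled, kind="stable")
        ranks = np.empty(len(pooled))
        i = 0
        while i < len(pooled):
            j = i
            while j + 1 < len(pooled) and \
                    pooled[order[j + 1]] == pooled[order[i]]:
                j += 1
            for t in range(i, j + 1):
                ranks[order[t]] = (i + j) / 2.0 + 1.0
            i = j + 1
        N = len(pooled)
        T = 0.0
        for v in set(pooled.tolist()):
            t = int(np.sum(pooled == v))
            T += t**3 - t
        start = 0
        mean_rank = {}
        for name, vals in groups.items():
            mean_rank[name] = ranks[start:start + len(vals)].mean()
            start += len(vals)
        for a, b in itertools.combinations(groups, 2):
            var = (N * (N + 1) / 12.0 - T / (12.0 * (N - 1))) * \
                (1.0 / len(groups[a]) + 1.0 / len(groups[b]))
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
            assert out.loc[(a, b), "z"] == pytest.approx(z, abs=1e-10)


class TestICC:
    def test_identical_raters_give_one(self):
        M = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert icc(M).value == pytest.approx(1.0)
        assert icc(M, "two-way-mixed-consistency").value == pytest.approx(1.0)

    def test_consistency_closed_form(self, rng):
        """ICC(3,1) converges to sigma_b^2 / (sigma_b^2 + sigma_e^2)."""
        n = 4000
        subj = rng.normal(0.0, 3.0, n)
        M = subj[:, None] + rng.normal(0.0, 1.0, (n, 3))
        est = icc(M, "two-way-mixed-consistency").value
        assert est == pytest.approx(0.9, abs=0.01)

    def test_pure_noise_is_near_zero(self, rng):
        M = rng.normal(size=(2000, 3))
        assert abs(icc(M).value) < 0.05

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        M = rng.normal(0.0, 2.0, (30, 1)) + rng.normal(0.0, 1.0, (30, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 3),
            "rater": np.tile(np.arange(3), 30),
            "score": M.ravel()})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        assert icc(M).value == pytest.approx(
            ref.loc["ICC(A,1)", "ICC"], abs=1e-8)
        assert icc(M, "two-way-mixed-consistency").value == pytest.approx(
            ref.loc["ICC(C,1)", "ICC"], abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc(np.ones((3, 3)))
        bad = np.ones((10, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc(bad)
        with pytest.raises(ConfigurationError):
            icc(np.random.default_rng(0).normal(size=(10, 3)), "one-way")


class TestReliabilityPipeline:
    def test_default_noise_lands_in_reported_bands(self, default_cohort):
        """The reliability emulation at its default noise fraction produces
        ICCs inside the 0.88-0.98 range the analysis targets."""
        cohort, _ = default_cohort
        sub_idx = np.random.default_rng(50).choice(len(cohort), 50,
                                                   replace=False)
        from opsweep.data import Cohort
        sub = Cohort([cohort.records[i] for i in sorted(sub_idx)],
                     provenance="generated")
        ratings, fields = repeated_measures(sub, seed=17)
        rel = reliability_report(ratings, fields)
        lo, hi = rel.inter_range()
        assert 0.88 <= lo and hi <= 0.99
        lo, hi = rel.intra_range()
        assert 0.86 <= lo and hi <= 0.99


class TestTable56:
    @staticmethod
    def synthetic_slopes(coeffs, sd=0.02, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (s, v), (k, b) in coeffs.items():
            for i in range(n):
                rows.append({"sagittal": s, "vertical": v,
                             "k": rng.normal(k, sd),
                             "b": rng.normal(b, sd * 30)})
        return pd.DataFrame(rows)

    def test_flat_slopes_report_ns_everywhere(self):
        flat = {c: (-0.28, 70.0) for c in tables.CELLS}
        df = self.synthetic_slopes(flat, sd=0.04, seed=3)
        res = build_table56(df, "k")
        assert all(v == "N.S" for v in res["inter_row"].values())
        assert "[" not in "".join(res["table"].loc[
            list(tables.SAGITTAL), list(tables.VERTICAL)].to_numpy().ravel())

    def test_fa_pattern_from_reference_coefficients(self):
        """Slopes drawn tightly around the FA calibration reproduce the
        qualitative marker pattern: vertical letters inside every sagittal
        class and inter-group flags B,C on k in every vertical column."""
        df = self.synthetic_slopes(tables.FA_COEFFICIENTS, sd=0.05, seed=1)
        res = build_table56(df, "k")
        for v in tables.VERTICAL:
            assert "B" in res["inter_row"][v] and "C" in res["inter_row"][v]
        for s in ("I", "II"):
            cell_text = res["table"].loc[s, "hyper"]
            assert "b" in cell_text and "c" in cell_text

    def test_single_cell_rejected(self):
        df = self.synthetic_slopes({("I", "hypo"): (-0.4, 95.0)})
        with pytest.raises(ConfigurationError):
            build_table56(df, "k")

    def test_unknown_quantity_rejected(self):
        df = self.synthetic_slopes(tables.FA_COEFFICIENTS)
        with pytest.raises(ConfigurationError):
            build_table56(df, "z")
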