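"""Exclusion rules, mixed models, residual decomposition, Gamma-GLM variability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from octhaze.stats import (
    apply_exclusions,
    boxplot_stats,
    compute_level_residuals,
    failure_summary,
    fit_mean_model,
    fit_variability,
    pairwise_compare,
    recover_variance_components,
    reference_differences,
)
from octhaze.synthetic import (
    PROTOCOL,
    AcquisitionSetting,
    TABLE_COLUMNS,
    VarianceComponents,
    art_arm,
    enumerate_protocol,
    focus_arm,
    generate_study,
    inject_failures,
)


def make_table(rows):
    """rows: (subject, position, art, focus, rep, section, vri, failed)"""
    recs = [
        (sub, pos, art, foc, rep, sec,
         np.nan if failed else vri,
         np.nan if failed else vri * 0.85,
         np.nan if failed else 0.85,
         failed)
        for sub, pos, art, foc, rep, sec, vri, failed in rows
    ]
    return pd.DataFrame.from_records(recs, columns=TABLE_COLUMNS)


def scan_rows(subject, art, rep, vris, failed_sections=()):
    return [
        (subject, "middle", art, 0, rep, sec, v, sec in failed_sections)
        for sec, v in enumerate(vris, start=1)
    ]


class TestExclusions:
    def test_scan_with_two_sections_dropped(self):
        rows = []
        rows += scan_rows(1, 6, 1, [0.04] * 7, failed_sections=(1, 2, 3, 4, 5))
        rows += scan_rows(1, 6, 2, [0.04] * 7)
        rows += scan_rows(1, 6, 3, [0.04] * 7)
        out, log = apply_exclusions(make_table(rows))
        assert set(out["repetition"]) == {2, 3}
        assert any("only 2 of 7 sections" in line for line in log)

    def test_scan_with_three_sections_retained(self):
        rows = []
        rows += scan_rows(1, 6, 1, [0.04] * 7, failed_sections=(1, 2, 3, 4))
        rows += scan_rows(1, 6, 2, [0.04] * 7)
        rows += scan_rows(1, 6, 3, [0.04] * 7)
        out, _ = apply_exclusions(make_table(rows))
        assert set(out["repetition"]) == {1, 2, 3}
        assert (out["repetition"] == 1).sum() == 3

    def test_cell_with_single_surviving_repetition_dropped(self):
        rows = []
        rows += scan_rows(1, 6, 1, [0.04] * 7, failed_sections=(1, 2, 3, 4, 5))
        rows += scan_rows(1, 6, 2, [0.04] * 7, failed_sections=(1, 2, 3, 4, 5))
        rows += scan_rows(1, 6, 3, [0.04] * 7)
        rows += scan_rows(1, 12, 1, [0.05] * 7)
        rows += scan_rows(1, 12, 2, [0.05] * 7)
        out, log = apply_exclusions(make_table(rows))
        assert set(out["art"]) == {12}
        assert any("fewer than 2 surviving repetitions" in line for line in log)

    def test_no_failures_is_identity(self):
        table = generate_study(enumerate_protocol(2, 3, 7), seed=0)
        out, log = apply_exclusions(table)
        pd.testing.assert_frame_equal(out, table)
        assert log == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent(self, seed):
        table = generate_study(enumerate_protocol(3, 3, 7), seed=seed)
        table = inject_failures(table, {s: 0.35 for s in PROTOCOL}, seed=seed)
        once, _ = apply_exclusions(table)
        twice, log2 = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2 == []


@pytest.fixture(scope="module")
def design():
    slots = enumerate_protocol(15, 3, 7)
    return slots, generate_study(slots, seed=9)


class TestFailureSummary:
    def test_printed_failure_rates(self, design):
        """46/1575 -> 3% on the ART arm, 504/1575 -> 32% on the focus arm."""
        slots, table = design
        table = table.copy()
        rng = np.random.default_rng(0)
        art_rows = table.index[(table["position"] == "middle") & (table["focus"] == 0)
                               & (table["art"] != 100)]
        focus_rows = table.index[(table["position"] == "middle") & (table["focus"] != 0)]
        fail = np.concatenate([
            rng.choice(art_rows, 46, replace=False),
            rng.choice(focus_rows, 504, replace=False),
        ])
        table.loc[fail, "vri"] = np.nan
        table.loc[fail, "failed"] = True
        out = failure_summary(slots, table)
        assert out.loc["art", "theoretical"] == 1575
        assert out.loc["art", "failed"] == 46
        assert out.loc["art", "failure_pct"] == 3
        assert out.loc["focus", "failed"] == 504
        assert out.loc["focus", "failure_pct"] == 32

    def test_no_failures_gives_zero_percent(self, design):
        slots, table = design
        out = failure_summary(slots, table)
        assert (out["failed"] == 0).all()
        assert (out["failure_pct"] == 0).all()

    def test_missing_slots_count_as_failed(self, design):
        """Never-acquired scans are failures of the theoretical design."""
        slots, table = design
        trimmed = table[table["subject"] > 1]
        out = failure_summary(slots, trimmed)
        assert out.loc["art", "failed"] == 105  # one subject's ART arm


class TestMeanModel:
    def test_degenerate_zero_variance_recovers_setting_means(self):
        slots = enumerate_protocol(3, 2, 3)
        table = generate_study(slots, vc=VarianceComponents(0, 0, 0), seed=0)
        fit = fit_mean_model(table, "art")
        truth = {6: 0.043, 12: 0.043, 25: 0.043, 50: 0.039, 100: 0.048}
        for lv, mu in truth.items():
            assert fit.estimates[lv] == pytest.approx(mu, abs=1e-12)
        assert fit.var_subject == fit.var_scan == fit.var_residual == 0.0

    def test_balanced_design_estimates_equal_cell_means(self):
        slots = art_arm(enumerate_protocol(6, 2, 3))
        table = generate_study(slots, seed=4)
        fit = fit_mean_model(table, "art")
        cell = table.groupby("art")["vri"].mean()
        for lv in fit.estimates.index:
            assert fit.estimates[lv] == pytest.approx(cell[lv], abs=1e-6)
        assert fit.converged

    def test_focus_effect_detected(self):
        table = generate_study(enumerate_protocol(8, 2, 4), seed=5)
        fit = fit_mean_model(table, "focus")
        assert fit.p_value < 1e-6
        assert fit.estimates[0] == min(fit.estimates)

    def test_alternative_response_variable(self):
        table = generate_study(enumerate_protocol(4, 2, 3), seed=6)
        fit = fit_mean_model(table, "art", response="vitreous_mean")
        assert fit.response == "vitreous_mean"
        # simulated vitreous intensity is 0.85 x VRI
        fit_vri = fit_mean_model(table, "art")
        for lv in fit.estimates.index:
            assert fit.estimates[lv] == pytest.approx(0.85 * fit_vri.estimates[lv], rel=1e-4)

    def test_single_level_rejected(self):
        rows = scan_rows(1, 6, 1, [0.04, 0.05, 0.06]) + scan_rows(2, 6, 1, [0.04, 0.05, 0.06])
        with pytest.raises(ValueError):
            fit_mean_model(make_table(rows), "art")


class TestResiduals:
    def test_within_scan_hand_arithmetic(self):
        rows = scan_rows(1, 50, 1, [0.04, 0.05, 0.06])
        r = compute_level_residuals(make_table(rows), "within_scan")
        assert np.allclose(sorted(r["residual"]), [-0.01, 0.0, 0.01], atol=1e-15)
        assert np.allclose(r["sq_residual"], r["residual"] ** 2)

    def test_constant_table_zero_residuals_at_every_level(self):
        table = generate_study(enumerate_protocol(3, 3, 4),
                               vc=VarianceComponents(0, 0, 0), seed=0)
        for level in ("within_scan", "intra_subject", "inter_subject"):
            r = compute_level_residuals(table, level)
            assert np.allclose(r["residual"], 0.0, atol=1e-15)

    def test_residuals_sum_to_zero_within_groups(self):
        table = generate_study(enumerate_protocol(5, 3, 7), seed=8)
        table = inject_failures(table, {s: 0.2 for s in PROTOCOL}, seed=8)
        table, _ = apply_exclusions(table)

        r1 = compute_level_residuals(table, "within_scan")
        sums = r1.groupby(["subject", "position", "art", "focus", "repetition"])["residual"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

        r2 = compute_level_residuals(table, "intra_subject")
        sums = r2.groupby(["subject", "position", "art", "focus"])["residual"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

        r3 = compute_level_residuals(table, "inter_subject")
        sums = r3.groupby(["position", "art", "focus"])["residual"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

    def test_singleton_groups_flagged(self):
        rows = scan_rows(1, 6, 1, [0.04] * 7) + scan_rows(2, 6, 1, [0.05] * 7)
        r = compute_level_residuals(make_table(rows), "intra_subject")
        assert r["singleton"].all()
        assert np.allclose(r["residual"], 0.0)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            compute_level_residuals(make_table(scan_rows(1, 6, 1, [0.04] * 3)), "bogus")


def random_residual_table(rng, factor_levels, n_per_level):
    frames = []
    for lv in factor_levels:
        sq = rng.gamma(shape=1.5, scale=2e-4, size=n_per_level)
        frames.append(pd.DataFrame(dict(
            subject=np.arange(n_per_level), position="middle", art=lv, focus=0,
            residual=np.sqrt(sq), sq_residual=sq, singleton=False,
            level="within_scan",
        )))
    return pd.concat(frames, ignore_index=True)


class TestVariability:
    def test_constant_squared_residuals_give_sqrt(self):
        c = 1.7e-4
        table = pd.DataFrame(dict(
            subject=range(12), position="middle",
            art=[6, 100] * 6, focus=0,
            residual=np.sqrt(c), sq_residual=c, singleton=False, level="within_scan",
        ))
        fit = fit_variability(table, "art")
        for lv in fit.levels:
            assert fit.variability[lv] == pytest.approx(np.sqrt(c), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_gamma_glm_matches_per_group_rms(self, seed):
        """Single-factor Gamma GLM fitted means == group means of squared residuals."""
        rng = np.random.default_rng(seed)
        levels = [6, 12, 25, 50, 100][: rng.integers(2, 6)]
        table = random_residual_table(rng, levels, int(rng.integers(5, 40)))
        fit = fit_variability(table, "art")
        for lv in levels:
            rms = np.sqrt(table.loc[table["art"] == lv, "sq_residual"].mean())
            assert fit.variability[lv] == pytest.approx(rms, abs=1e-8)

    def test_zero_residuals_dropped_with_count(self):
        rng = np.random.default_rng(0)
        table = random_residual_table(rng, [6, 100], 20)
        table.loc[:4, "sq_residual"] = 0.0
        fit = fit_variability(table, "art")
        assert fit.n_zero_dropped == 5
        assert fit.n_obs == len(table) - 5

    def test_variability_recovery_at_study_scale(self):
        """Within-scan variability ~= sigma_section = 0.010 at 15 x 3 x 7."""
        slots = art_arm(enumerate_protocol(15, 3, 7))
        table = generate_study(slots, vc=VarianceComponents(0, 0, 0.010), seed=21)
        resid = compute_level_residuals(table, "within_scan")
        fit = fit_variability(resid, "art")
        for lv in fit.levels:
            assert 0.008 <= fit.variability[lv] <= 0.012


class TestPairwise:
    def test_two_level_family_equals_unadjusted_p(self):
        rng = np.random.default_rng(3)
        table = random_residual_table(rng, [6, 100], 30)
        fit = fit_variability(table, "art")
        pw = pairwise_compare(fit)
        assert len(pw) == 1
        row = pw.iloc[0]
        p_unadj = 2 * sps.t.sf(abs(row.statistic), fit.df_resid)
        assert row.p_tukey == pytest.approx(p_unadj, abs=1e-4)

    def test_null_levels_rarely_flagged(self):
        """5 identical levels: all Tukey-adjusted p > 0.05 in >=95% of replicates."""
        clean = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            table = random_residual_table(rng, [6, 12, 25, 50, 100], 60)
            fit = fit_variability(table, "art")
            if (pairwise_compare(fit)["p_tukey"] > 0.05).all():
                clean += 1
        assert clean >= int(0.95 * n_rep) - 2  # binomial slack at 40 replicates

    def test_shifted_level_detected(self):
        """A level shifted by 5 generating sds shows up in exactly its contrasts."""
        mu = {s: 0.048 for s in PROTOCOL}
        mu[AcquisitionSetting("middle", 100, 0)] = 0.048 + 5 * 0.012
        slots = art_arm(enumerate_protocol(10, 2, 4))
        table = generate_study(slots, mu, VarianceComponents(0.012, 0.007, 0.010), seed=17)
        fit = fit_mean_model(table, "art")
        pw = pairwise_compare(fit)
        with_100 = pw[(pw["level_a"] == 100) | (pw["level_b"] == 100)]
        without = pw[(pw["level_a"] != 100) & (pw["level_b"] != 100)]
        assert (with_100["p_tukey"] < 0.05).all()
        assert (without["p_tukey"] > 0.05).all()


class TestBoxplot:
    def test_one_to_hundred(self):
        s = boxplot_stats(range(1, 101))
        assert s["median"] == pytest.approx(50.5)
        assert s["outliers"] == []
        assert s["whisker_low"] == 1 and s["whisker_high"] == 100

    def test_constant_data(self):
        s = boxplot_stats([0.3] * 9)
        assert s["iqr"] == 0
        assert s["outliers"] == []

    def test_far_point_flagged(self):
        s = boxplot_stats([1, 2, 3, 4, 100])
        assert s["outliers"] == [100.0]
        assert s["whisker_high"] == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats([])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_matches_matplotlib_oracle(self, values):
        from matplotlib import cbook

        ours = boxplot_stats(values)
        ref = cbook.boxplot_stats(np.asarray(values))[0]
        assert ours["q1"] == pytest.approx(ref["q1"], abs=1e-9)
        assert ours["median"] == pytest.approx(ref["med"], abs=1e-9)
        assert ours["q3"] == pytest.approx(ref["q3"], abs=1e-9)
        assert ours["whisker_low"] == pytest.approx(ref["whislo"], abs=1e-9)
        assert ours["whisker_high"] == pytest.approx(ref["whishi"], abs=1e-9)
        assert sorted(ours["outliers"]) == pytest.approx(sorted(ref["fliers"]), abs=1e-9)


class TestRecoveryAndReporting:
    def test_pooled_rms_recovers_components(self):
        table = generate_study(enumerate_protocol(15, 3, 7),
                               vc=VarianceComponents(0.012, 0.007, 0.010), seed=2)
        rec = recover_variance_components(table)
        assert rec["within_scan"] == pytest.approx(0.010, rel=0.25)
        assert rec["intra_subject"] == pytest.approx(0.007, rel=0.25)
        # the subject level pools only 15 independent effects, so its RMS
        # carries ~19% relative sampling sd (chi^2_14); allow 3 sd
        assert rec["inter_subject"] == pytest.approx(0.012, rel=0.6)

    def test_reference_differences(self):
        means = {-10: 0.162, -5: 0.088, 0: 0.048, 5: 0.192, 10: 0.200}
        diffs = reference_differences(means, reference=0, ndigits=2)
        assert diffs[5] == 0.14
        assert diffs[10] == 0.15
        assert 0 not in diffs

    def test_reference_must_exist(self):
        with pytest.raises(KeyError):
            reference_differences({1: 0.2}, reference=0)
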