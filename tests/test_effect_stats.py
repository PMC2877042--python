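import numpy as np
import pandas as pd
import pytest

from xsmm import effect_stats, reference_data
from xsmm.array_io import IntensityMatrix, ProbeRecord, ValidationError
from xsmm.effect_stats import (
    LogRatioEstimate,
    compare_to_controls,
    contrast_percent,
    estimate_log_ratios,
    pooled_t_test,
    position_count_summary,
    position_profile,
    spread_regression,
    type_group_summary,
)
from xsmm.probe_match import MismatchProbePair

TISSUES = ["cortex", "fibroblast", "pancreas", "testes", "thymus"]


def paired_matrices(pm_values: np.ndarray, mm_values: np.ndarray):
    """Build matching 1-probe matrices over 5 tissues x 2 replicates."""
    def build(values, design, probe_id):
        cols, meta = {}, []
        k = 0
        for tissue in TISSUES:
            for rep in (1, 2):
                aid = f"{design}_{tissue}_r{rep}"
                cols[aid] = [values[k]]
                meta.append({"array_id": aid, "platform": design, "tissue": tissue, "replicate": rep})
                k += 1
        return IntensityMatrix(pd.DataFrame(cols, index=[probe_id]), pd.DataFrame(meta))

    return build(pm_values, "designA", "a1"), build(mm_values, "designB", "b1")


def make_pair():
    pm = ProbeRecord("ps1", "a1", 1, "A" * 25, "designA")
    mm = ProbeRecord("ps1", "b1", 1, "A" * 12 + "G" + "A" * 12, "designB")
    return MismatchProbePair("ps1", pm, mm, 13, "A-G")


def make_estimate(position, value, mismatch_type="A-G", pair_id=None):
    return LogRatioEstimate(
        pair_id=pair_id or f"pair_{position}_{value}",
        position=position,
        mismatch_type=mismatch_type,
        per_tissue_ratio={"t1": value},
        estimate=value,
    )


class TestEstimator:
    def test_identical_signals_give_zero(self, rng):
        values = rng.uniform(50, 500, size=10)
        ma, mb = paired_matrices(values, values)
        (est,) = estimate_log_ratios([make_pair()], ma, mb)
        assert est.estimate == pytest.approx(0.0, abs=1e-12)

    def test_doubled_pm_gives_exactly_one(self, rng):
        values = rng.uniform(50, 500, size=10)
        ma, mb = paired_matrices(2 * values, values)
        (est,) = estimate_log_ratios([make_pair()], ma, mb)
        assert est.estimate == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(list(est.per_tissue_ratio.values()), 1.0)

    def test_matches_ols_oracle(self, rng):
        """The estimate must equal the Tissue + Chip OLS Chip coefficient."""
        import statsmodels.api as sm

        for _ in range(20):
            pm_vals = rng.uniform(10, 1000, size=10)
            mm_vals = rng.uniform(10, 1000, size=10)
            ma, mb = paired_matrices(pm_vals, mm_vals)
            (est,) = estimate_log_ratios([make_pair()], ma, mb)

            # independent route: per-tissue replicate means, then OLS fit
            pm_means = np.log2(pm_vals).reshape(5, 2).mean(axis=1)
            mm_means = np.log2(mm_vals).reshape(5, 2).mean(axis=1)
            y = np.concatenate([pm_means, mm_means])
            tissue = pd.get_dummies(pd.Series(TISSUES * 2), drop_first=True, dtype=float)
            X = sm.add_constant(
                pd.concat([tissue, pd.Series([1.0] * 5 + [0.0] * 5, name="chip")], axis=1)
            )
            coef = sm.OLS(y, X).fit().params["chip"]
            assert est.estimate == pytest.approx(coef, abs=1e-10)

    def test_missing_probe_named_in_error(self, rng):
        values = rng.uniform(50, 500, size=10)
        ma, mb = paired_matrices(values, values)
        pair = make_pair()
        bad = MismatchProbePair(
            "ps1",
            ProbeRecord("ps1", "missing", 1, pair.pm_probe.sequence, "designA"),
            pair.mm_probe,
            13,
            "A-G",
        )
        with pytest.raises(ValidationError, match="missing"):
            estimate_log_ratios([bad], ma, mb)

    def test_estimate_must_equal_tissue_mean(self):
        with pytest.raises(ValidationError, match="mean of"):
            LogRatioEstimate("x", 1, "A-G", {"t1": 1.0, "t2": 2.0}, 2.0)


class TestPositionProfile:
    def test_single_position_summaries(self):
        estimates = [make_estimate(13, 1.0, pair_id=f"p{i}") for i in range(3)]
        profile = position_profile(estimates)
        row = profile.loc[13]
        assert row["n"] == 3
        assert row["mean"] == row["median"] == 1.0
        assert row["mad"] == row["iqr"] == 0.0
        other = profile.drop(index=13)
        assert (other["n"] == 0).all() and other["mean"].isna().all()

    def test_quartile_and_mad_conventions(self):
        """{0,1,2,4}: median 1.5; raw MAD = 1.0; type-7 IQR = 2.5 - 0.75 = 1.75."""
        estimates = [make_estimate(5, v, pair_id=f"p{v}") for v in (0.0, 1.0, 2.0, 4.0)]
        row = position_profile(estimates).loc[5]
        assert row["median"] == 1.5
        assert row["mad"] == 1.0
        assert row["iqr"] == pytest.approx(1.75)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            position_profile([])

    def test_published_count_aggregation(self):
        summary = position_count_summary(reference_data.POSITION_PAIR_COUNTS)
        assert summary == {"total": 15_800, "min_count": 521, "min_position": 13}


class TestSpreadRegression:
    def test_exact_line_recovered(self):
        profile = pd.DataFrame(
            {
                "n": [10] * 25,
                "median": np.linspace(0.2, 1.2, 25),
                "mad": 0.5 * np.linspace(0.2, 1.2, 25) + 0.1,
            },
            index=range(1, 26),
        )
        reg = spread_regression(profile)
        assert reg.slope == pytest.approx(0.5)
        assert reg.intercept == pytest.approx(0.1)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_mad_defined_limit(self):
        profile = pd.DataFrame(
            {"n": [5] * 25, "median": np.linspace(0, 1, 25), "mad": [0.3] * 25},
            index=range(1, 26),
        )
        reg = spread_regression(profile)
        assert reg.slope == 0.0 and reg.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        profile = pd.DataFrame({"n": [4] * 25, "median": x, "mad": y}, index=range(1, 26))
        reg = spread_regression(profile)
        X = np.column_stack([x, np.ones(25)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.slope == pytest.approx(slope, abs=1e-10)
        assert reg.intercept == pytest.approx(intercept, abs=1e-10)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert reg.r_squared == pytest.approx(r2, abs=1e-12)

    def test_r_squared_affine_invariance(self, rng):
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(scale=0.1, size=25)
        base = pd.DataFrame({"n": [4] * 25, "median": x, "mad": y}, index=range(1, 26))
        scaled = pd.DataFrame(
            {"n": [4] * 25, "median": 3.0 * x - 7.0, "mad": 0.2 * y + 11.0},
            index=range(1, 26),
        )
        assert spread_regression(base).r_squared == pytest.approx(
            spread_regression(scaled).r_squared, abs=1e-12
        )

    def test_too_few_positions_rejected(self):
        profile = pd.DataFrame(
            {"n": [1, 1, 0], "median": [0.1, 0.2, np.nan], "mad": [0.1, 0.1, np.nan]},
            index=[1, 2, 3],
        )
        with pytest.raises(ValidationError, match=">= 3"):
            spread_regression(profile)


class TestTypeGroupSummary:
    def test_pooled_t_closed_form(self):
        """{1,2,3} vs {2,3,4}: pooled t = -sqrt(3/2), df = 4."""
        from scipy import stats as ss

        t, p = pooled_t_test(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        t_expected = -np.sqrt(1.5)  # (2-3)/sqrt(1*(1/3+1/3))
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert p == pytest.approx(2 * ss.t.sf(abs(t_expected), df=4), abs=1e-12)
        assert p == pytest.approx(0.2879, abs=2e-4)

    def test_frequencies_conserved_and_means_by_group(self, rng):
        estimates = []
        for i in range(60):
            position = int(rng.integers(1, 26))
            estimates.append(
                make_estimate(position, float(rng.normal()), mismatch_type="C-A", pair_id=f"c{i}")
            )
        for i in range(40):
            estimates.append(
                make_estimate(int(rng.integers(1, 26)), float(rng.normal()), pair_id=f"a{i}")
            )
        summary = type_group_summary(estimates)
        assert summary.table["frequency"].sum() == 100
        profile = position_profile(estimates)
        assert profile["n"].sum() == 100  # conservation across both summaries

    def test_small_cell_contrast_unavailable_and_logged(self):
        estimates = [
            make_estimate(2, 0.1, pair_id="x1"),
            make_estimate(3, 0.2, pair_id="x2"),
            make_estimate(12, 0.5, pair_id="x3"),  # single center value
            make_estimate(20, 0.15, pair_id="x4"),
            make_estimate(21, 0.25, pair_id="x5"),
        ]
        summary = type_group_summary(estimates)
        row = summary.table.set_index("mismatch_type").loc["A-G"]
        assert np.isnan(row["p_center_vs_five_prime"])
        assert not np.isnan(row["p_five_prime_vs_three_prime"])
        assert ("A-G", "center_vs_five_prime") in summary.skipped_contrasts


class TestContrastPercent:
    def test_equal_means_zero_in_both_forms(self):
        assert contrast_percent(0.8, 0.8, form="ratio") == 0.0
        assert contrast_percent(0.8, 0.8, form="log2") == 0.0

    def test_one_log2_unit_is_fifty_percent_ratio_decrease(self):
        assert contrast_percent(1.0, 0.0, form="ratio") == pytest.approx(50.0)

    def test_log2_scale_percent_higher(self):
        assert contrast_percent(1.0, 1.13, form="log2") == pytest.approx(13.0)

    def test_zero_reference_rejected_on_log2_scale(self):
        with pytest.raises(ValidationError):
            contrast_percent(0.0, 1.0, form="log2")


class TestCompareToControls:
    def test_strong_separation_gives_tiny_p(self, rng):
        estimates = [
            make_estimate(13, v, pair_id=f"m{i}")
            for i, v in enumerate(rng.normal(1.0, 0.1, size=500))
        ]
        controls = rng.normal(0.0, 0.1, size=500)
        tests, skipped = compare_to_controls(estimates, controls)
        assert tests.set_index("position").loc[13, "p"] < 1e-6
        assert 13 not in skipped

    def test_undersized_control_sample_skipped(self, rng):
        estimates = [make_estimate(13, float(v), pair_id=f"m{v}") for v in range(5)]
        tests, skipped = compare_to_controls(estimates, np.array([0.1]))
        assert tests.empty and 13 in skipped
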