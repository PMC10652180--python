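"""Statistics layer: transform rule, adjusted models, paired tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lacumorph.cohort import CohortSpec, EffectMap, generate_cohort
from lacumorph.cohort_stats import (
    RegressionResult,
    SingularDesignError,
    choose_transform,
    fit_exposure_model,
    fit_group_model,
    paired_region_test,
    summarize_cohort,
)


def merged_cohort(seed=0, **kw):
    res = generate_cohort(CohortSpec(seed=seed, **kw))
    return res.cohort.join(res.true_params.drop(columns=["subject_id", "group"]))


class TestChooseTransform:
    def test_normal_sample_untransformed(self):
        rng = np.random.default_rng(0)
        assert choose_transform(rng.normal(10, 1, 200)) == "none"

    def test_lognormal_sample_transformed(self):
        rng = np.random.default_rng(1)
        assert choose_transform(np.exp(rng.normal(0, 1, 200))) == "log10"

    def test_too_few_values(self):
        assert choose_transform([1.0, 2.0]) == "none"

    def test_idempotent(self):
        """Data already log10-transformed is not transformed again."""
        rng = np.random.default_rng(2)
        raw = np.exp(rng.normal(3, 1, 200))
        assert choose_transform(raw) == "log10"
        assert choose_transform(np.log10(raw)) == "none"

    def test_nonpositive_values_warn_and_skip(self):
        rng = np.random.default_rng(3)
        skewed = np.exp(rng.normal(0, 1, 200)) - 1.0  # non-normal, crosses zero
        with pytest.warns(UserWarning, match="non-positive"):
            assert choose_transform(skewed) == "none"


class TestGroupModel:
    def test_recovers_log_ratio_effect(self):
        """Mean group-beta over 100 simulated 200-subject cohorts within
        30% of log10(1.077)."""
        betas = [
            fit_group_model(merged_cohort(seed, n_group1=114, n_group2=86),
                            "cort_lcv_um3", transform="log10").beta
            for seed in range(100)
        ]
        target = np.log10(1.077)
        assert abs(np.mean(betas) - target) / target < 0.30

    def test_constant_outcome_flagged(self):
        m = merged_cohort(0)
        m["flat"] = 1.0
        res = fit_group_model(m, "flat", transform="none")
        assert res.flagged and res.beta == 0.0

    def test_single_sex_design_is_singular(self):
        m = merged_cohort(0)
        m["sex"] = "male"
        with pytest.raises(SingularDesignError, match="sex_female"):
            fit_group_model(m, "cort_lcv_um3")

    def test_needs_two_per_group(self):
        m = merged_cohort(0, n_group1=20, n_group2=1)
        with pytest.raises(ValueError, match="2 subjects per group"):
            fit_group_model(m, "cort_lcv_um3")

    def test_type_one_error_calibrated(self):
        """Null group effect, n=35: rejection at p <= 0.05 in [3.5, 6.5]%
        over 400 replicates (the acceptance suite runs 1000)."""
        rej = 0
        n = 400
        for seed in range(n):
            m = merged_cohort(50_000 + seed, effects=EffectMap.null())
            if fit_group_model(m, "cort_lcv_um3", transform="log10").p <= 0.05:
                rej += 1
        assert 0.030 <= rej / n <= 0.070


class TestExposureModel:
    def test_constructed_slope(self):
        """Outcome built as 87 x HbA1c + tiny noise recovers slope 87."""
        rng = np.random.default_rng(0)
        n = 34
        m = merged_cohort(0).iloc[:n].copy()
        m["y"] = 87.0 * m.hba1c_mmol_mol + rng.normal(0, 1e-6, n)
        res = fit_exposure_model(m, "y", transform="none")
        assert res.beta == pytest.approx(87.0, rel=1e-4)

    def test_simulated_slope_recovery(self):
        """Mean slope over 100 seeds (n=34 cohorts) within 30% of the
        embedded 87 mm^-3 per mmol/mol."""
        slopes = [
            fit_exposure_model(merged_cohort(seed, n_group1=19, n_group2=15),
                               "trab_lcnbv_mm3", transform="none").beta
            for seed in range(100)
        ]
        assert abs(np.mean(slopes) - 87.0) / 87.0 < 0.30

    def test_permuted_exposure_calibrated(self):
        rej = 0
        n = 400
        for seed in range(n):
            m = merged_cohort(60_000 + seed)
            rng = np.random.default_rng(seed)
            m["hba1c_mmol_mol"] = rng.permutation(m.hba1c_mmol_mol.to_numpy())
            if fit_exposure_model(m, "trab_lcnbv_mm3", transform="none").p <= 0.05:
                rej += 1
        assert 0.030 <= rej / n <= 0.070


def wilcoxon_enumeration_p(diffs):
    """Exact two-sided signed-rank p by full enumeration of sign flips."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = w_max = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        # two-sided: as or more extreme in distance from the mean
        if abs(w - w_max / 2) >= abs(w_obs - w_max / 2) - 1e-12:
            count += 1
    return count / 2**n


class TestPairedRegionTest:
    def test_identical_vectors_p_one(self):
        v = np.linspace(100, 200, 12)
        p, _, _ = paired_region_test(v, v, transform="none")
        assert p == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="6"):
            paired_region_test([1, 2, 3], [4, 5, 6])

    def test_single_flip_among_concordant(self):
        """33 pairs all central > peripheral except one: p < 0.001."""
        rng = np.random.default_rng(0)
        periph = 129.0 * np.exp(rng.normal(0, 0.05, 33))
        central = periph * 1.25
        central[5] = periph[5] * 0.8
        p, _, _ = paired_region_test(central, periph, transform="log10")
        assert p < 0.001

    @pytest.mark.parametrize("n", [8, 10])
    def test_exact_branch_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        periph = rng.normal(100, 10, n)
        central = periph + rng.normal(2, 6, n)
        p, _, _ = paired_region_test(central, periph, transform="none")
        assert p == pytest.approx(wilcoxon_enumeration_p(central - periph), abs=1e-12)

    def test_study_scale_effect_detected(self):
        """Central/peripheral ratio 166/129 with 10% per-sample noise at
        n=33: p < 0.001 in >= 95% of 100 replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            periph = 129.0 * np.exp(rng.normal(0, 0.10, 33))
            central = 166.0 * np.exp(rng.normal(0, 0.10, 33))
            p, _, _ = paired_region_test(central, periph, transform="log10")
            hits += p < 0.001
        assert hits >= 95

    def test_wilcoxon_type_one_calibrated(self):
        rej = 0
        n = 400
        for seed in range(n):
            rng = np.random.default_rng(70_000 + seed)
            a = rng.normal(0, 1, 35)
            b = rng.normal(0, 1, 35)
            p, _, _ = paired_region_test(a, b, transform="none")
            rej += p <= 0.05
        assert 0.030 <= rej / n <= 0.070


class TestSummaries:
    def test_median_iqr(self):
        vals = np.array([1, 2, 3, 4, 5], float)
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        assert (q1, q2, q3) == (2.0, 3.0, 4.0)
        df = pd.DataFrame(dict(group=["g"] * 5, v=np.exp(vals)))
        # skewed values are summarized as median (IQR) when n allows a test
        out = summarize_cohort(pd.concat([df] * 8, ignore_index=True), ["v"])
        assert "IQR" in out.v.iloc[0] or "SD" in out.v.iloc[0]

    def test_group_percentages(self):
        df = pd.DataFrame(dict(group=["T2D"] * 20 + ["T2D+MVD"] * 15, v=1.0))
        out = summarize_cohort(df, ["v"]).set_index("group")
        assert out.loc["T2D", "pct"] == 57
        assert out.loc["T2D+MVD", "pct"] == 43

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame(columns=["group"]))

    def test_result_dataclass_round_trip(self):
        r = RegressionResult("y", "none", "group", 1.0, 0.5, 0.04, 0.2, 35)
        d = r.as_dict()
        assert d["beta"] == 1.0 and d["n"] == 35
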