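"""Statistics layer: closed-form checks, oracles and recovery simulations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nccv import (
    SubjectRecord,
    association,
    auc_mann_whitney,
    correlation,
    egfr_schwartz,
    granulocyte_from_leukocyte,
    group_t_test,
    per_slice_comparison,
    repeatability_cv,
    roc_auc,
    sidak_level,
)
from nccv.quantify import AreaProfile, SliceAreas
from nccv.stats import records_to_dataframe

from _oracles import brute_force_auc


def _profile(values):
    rows = [
        SliceAreas(i + 1, (i + 1) * 2.8, v, 100.0, v / 100.0)
        for i, v in enumerate(values)
    ]
    return AreaProfile(per_slice=rows)


class TestSidak:
    def test_printed_adjustment_for_78_slices(self):
        assert sidak_level(0.05, 78) == pytest.approx(6.576e-4, rel=1e-2)

    @given(
        alpha=st.floats(1e-4, 0.2),
        m=st.integers(1, 500),
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_closed_form_identity(self, alpha, m):
        """(1 - alpha')^m == 1 - alpha to machine precision."""
        a = sidak_level(alpha, m)
        assert (1 - a) ** m == pytest.approx(1 - alpha, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            sidak_level(0.0, 10)
        with pytest.raises(ValueError):
            sidak_level(0.05, 0)


class TestPerSliceComparison:
    def test_identical_groups_never_flag(self):
        profs = [_profile([1, 2, 3, 4]), _profile([2, 3, 4, 5])]
        out = per_slice_comparison(profs, profs, alpha=0.05)
        assert np.allclose(out["mean_difference"], 0.0)
        assert not out["significant"].any()

    def test_band_restricted_effect_is_flagged_in_band_only(self):
        rng = np.random.default_rng(0)
        m = 20
        effect = np.zeros(m)
        effect[8:13] = 0.2
        pats = [_profile(np.clip(effect + rng.normal(0, 0.01, m), 0, 1) * 100) for _ in range(10)]
        ctls = [_profile(np.clip(rng.normal(0, 0.01, m), 0, 1) * 100) for _ in range(10)]
        out = per_slice_comparison(pats, ctls)
        flagged = set(out.loc[out.significant, "slice_index"])
        assert flagged
        assert flagged <= set(range(9, 14))

    def test_insufficient_group_size(self):
        with pytest.raises(ValueError, match="2 profiles"):
            per_slice_comparison([_profile([1, 2])], [_profile([1, 2]), _profile([1, 2])])


class TestGroupTTest:
    def test_identical_groups(self):
        out = group_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_noiseless_separation_is_degenerate(self):
        out = group_t_test([0, 0, 0, 0], [1, 1, 1, 1])
        assert out["degenerate"]
        assert out["p"] == 0.0

    def test_textbook_welch_on_four_points(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]
        out = group_t_test(a, b)
        # closed form: means 2.5/5.0, vars 5/3 and 20/3
        se = np.sqrt(5 / 12 + 20 / 12)
        assert out["t"] == pytest.approx((2.5 - 5.0) / se, rel=1e-12)
        assert out["mean_patients"] == 2.5
        assert out["sd_controls"] == pytest.approx(np.sqrt(20 / 3))

    def test_monte_carlo_power_at_unit_effect(self):
        """n=30 per group, effect 1 sd: essentially always detected at the
        0.05 level (analytic power ~0.97) and usually at 0.001 (~0.6)."""
        hits_05 = hits_001 = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.0, 1.0, 30)
            b = rng.normal(0.0, 1.0, 30)
            p = group_t_test(a, b)["p"]
            hits_05 += p < 0.05
            hits_001 += p < 1e-3
        assert hits_05 >= 90
        assert hits_001 >= 40

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_t_test([1.0], [1.0, 2.0])


class TestRocAuc:
    def test_perfect_separation(self):
        out = roc_auc([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0], n_boot=100)
        assert out["auc"] == 1.0

    def test_tied_example_brute_forced(self):
        # positives {1,2,3} vs negatives {0,1,2}: 6 wins + 2 ties -> 7/9
        scores = [1, 2, 3, 0, 1, 2]
        labels = [1, 1, 1, 0, 0, 0]
        assert auc_mann_whitney(scores, labels) == pytest.approx(7 / 9)
        assert brute_force_auc(scores, labels) == pytest.approx(7 / 9)

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = np.array([1] * 30 + [0] * 30)
        rng.shuffle(labels)
        out = roc_auc(scores, labels, seed=1)
        assert out["ci_low"] <= 0.5 <= out["ci_high"]

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_oracle_equivalence_with_ties(self, seed):
        """Rank-based AUC equals pairwise enumeration up to n = 50."""
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 26))
        n0 = int(rng.integers(1, 26))
        scores = rng.integers(0, 8, n1 + n0).astype(float)  # heavy ties
        labels = np.array([1] * n1 + [0] * n0)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), rel=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


def _records(n, rng, slope=0.0, binary=False, or_per_sd=None):
    nccv = rng.normal(1000.0, 400.0, n).clip(1.0)
    z = (nccv - nccv.mean()) / nccv.std(ddof=1)
    recs = []
    for i in range(n):
        if binary:
            logit = np.log(or_per_sd) * z[i] - 0.3
            y = rng.random() < 1 / (1 + np.exp(-logit))
            extra = {"hypothyroidism": bool(y)}
        else:
            extra = {"bmi": slope * z[i] + rng.normal(0, 1.0) + 22.0}
        recs.append(
            SubjectRecord(
                subject_id=f"S{i}", group="patient", nccv_um3=float(nccv[i]),
                age_years=float(rng.uniform(5, 50)), **extra,
            )
        )
    return recs


class TestAssociation:
    def test_continuous_slope_recovery(self):
        rng = np.random.default_rng(0)
        recs = _records(200, rng, slope=0.5)
        res = association(recs, "bmi", "continuous")
        assert res.kind == "continuous"
        assert res.effect == pytest.approx(0.5, abs=0.2)
        assert res.ci_low <= res.effect <= res.ci_high
        assert res.n == 200

    def test_logistic_odds_ratio_recovery(self):
        """True OR 3 per SD of nCCV, n=200: median estimate in [2.4, 3.75]."""
        ors = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            recs = _records(200, rng, binary=True, or_per_sd=3.0)
            res = association(recs, "hypothyroidism", "binary")
            if not res.separation_flag:
                ors.append(res.effect)
        assert len(ors) >= 25
        assert 2.4 <= np.median(ors) <= 3.75

    def test_null_outcome_ci_covers_null(self):
        covered = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            recs = _records(60, rng, slope=0.0)
            res = association(recs, "bmi", "continuous")
            if res.ci_low <= 0.0 <= res.ci_high:
                covered += 1
        assert covered >= 32  # ~95% coverage, generous binomial slack

    def test_constant_outcome_flags_separation(self):
        rng = np.random.default_rng(3)
        recs = _records(30, rng, binary=True, or_per_sd=1.0)
        for r in recs:
            r.hypothyroidism = False
        res = association(recs, "hypothyroidism", "binary")
        assert res.separation_flag

    def test_restriction_and_listwise_deletion(self):
        rng = np.random.default_rng(4)
        recs = _records(50, rng, slope=0.3)
        for r in recs[:20]:
            r.bmi = None
        res = association(recs, "bmi", "continuous")
        assert res.n == 30
        res2 = association(
            recs, "bmi", "continuous", restrict=lambda df: df["age_years"] > 20
        )
        assert res2.n < 30

    def test_too_few_records_rejected(self):
        rng = np.random.default_rng(5)
        recs = _records(5, rng, slope=0.0)
        with pytest.raises(ValueError, match="need >= 10"):
            association(recs, "bmi", "continuous")


class TestCorrelation:
    def test_perfect_pearson(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlation(x, x)["r"] == pytest.approx(1.0)

    def test_reversed_ranks_spearman(self):
        out = correlation([1, 2, 3, 4], [8, 6, 4, 2], method="spearman")
        assert out["r"] == pytest.approx(-1.0)

    def test_four_point_spearman_brute_force(self):
        # ranks d = (-1, 1, -1, 1): rho = 1 - 6*4 / (4*15) = 0.6
        out = correlation([1, 2, 3, 4], [2, 1, 4, 3], method="spearman")
        assert out["r"] == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1], [1, 2, 3])


class TestRepeatabilityCv:
    def test_constant_repeats(self):
        assert repeatability_cv([10.0, 10.0, 10.0]) == 0.0

    def test_ten_percent_case(self):
        assert repeatability_cv([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            repeatability_cv([5.0])
        with pytest.raises(ValueError):
            repeatability_cv([-1.0, 1.0])


class TestClinicalConversions:
    @pytest.mark.parametrize(
        "leuko,expected", [(0.0, 0.0), (1.0, 1.95), (2.0, 3.90)]
    )
    def test_granulocyte_conversion(self, leuko, expected):
        assert granulocyte_from_leukocyte(leuko) == pytest.approx(expected)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            granulocyte_from_leukocyte(-0.1)

    def test_schwartz_fixed_points(self):
        assert egfr_schwartz(100.0, 0.413) == pytest.approx(100.0)
        assert egfr_schwartz(141.6, 1.0) == pytest.approx(58.5, abs=0.05)

    def test_schwartz_inverse_in_creatinine(self):
        assert egfr_schwartz(120.0, 2.0) == pytest.approx(
            egfr_schwartz(120.0, 1.0) / 2
        )

    def test_schwartz_domain(self):
        with pytest.raises(ValueError):
            egfr_schwartz(0.0, 1.0)
        with pytest.raises(ValueError):
            egfr_schwartz(100.0, -1.0)


class TestSubjectRecords:
    def test_validation(self):
        with pytest.raises(ValueError):
            SubjectRecord("s", "patient", nccv_um3=-1.0)
        with pytest.raises(ValueError):
            SubjectRecord("s", "patient", nccv_um3=1.0, ckd_stage=7)

    def test_dataframe_round_trip(self):
        recs = [
            SubjectRecord("a", "patient", 100.0, age_years=10.0),
            SubjectRecord("b", "control", 50.0),
        ]
        df = records_to_dataframe(recs)
        assert list(df["subject_id"]) == ["a", "b"]
        assert df.loc[1, "age_years"] is None or np.isnan(df.loc[1, "age_years"])
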