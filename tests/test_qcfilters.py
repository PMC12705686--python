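import numpy as np
import pandas as pd
import pytest

from replidyn import qcfilters
from replidyn.errors import ArgumentError, QCError
from replidyn.qcfilters import (
    detection_rate_curve,
    ercc_correlation,
    mad_fences,
    mad_score,
    manhattan_distances,
    manhattan_outlier_fence,
    mapping_ratio_fence,
    qc_report,
    rna_fences,
    score_range_fence,
)
from replidyn.rtcore import MISSING, REPLICATED, UNREPLICATED


class TestMappingRatioFence:
    def test_quartile_arithmetic_excludes_only_outlier(self):
        ratios = pd.Series({"a": 0.5, "b": 0.51, "c": 0.52, "d": 0.53, "e": 0.05})
        passed = mapping_ratio_fence(ratios)
        assert passed.drop("e").all() and not passed["e"]

    def test_identical_ratios_all_pass(self):
        passed = mapping_ratio_fence(pd.Series([0.5] * 6))
        assert passed.all()

    def test_monotone_shift_preserves_pass_set(self):
        ratios = pd.Series([0.5, 0.51, 0.52, 0.53, 0.05])
        assert mapping_ratio_fence(ratios).equals(mapping_ratio_fence(ratios + 0.2))

    def test_small_cohort_passes_with_warning(self):
        with pytest.warns(UserWarning):
            passed = mapping_ratio_fence(pd.Series([0.5, 0.01]))
        assert passed.all()


class TestMadScore:
    def test_constant_counts_zero(self):
        assert mad_score(np.full(20, 10)) == 0.0

    def test_hand_computation(self):
        # counts {8,8,8,8,32}, median 8 -> x = {0,0,0,0,2}, MAD = 0
        counts = np.array([8, 8, 8, 8, 32] * 4)
        # x has 16 zeros and 4 twos: median(x)=0, median|x-0| = 0
        assert mad_score(counts) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        c = rng.integers(50, 200, 100)
        assert mad_score(c) == pytest.approx(mad_score(7 * c))

    def test_noisier_cell_larger_mad(self):
        rng = np.random.default_rng(1)
        tight = rng.poisson(100, 500)
        r = 2.0
        loose = rng.negative_binomial(r, r / (r + 100), 500)
        assert mad_score(loose) > mad_score(tight)

    def test_too_few_windows_rejected(self):
        with pytest.raises(QCError):
            mad_score(np.array([5, 5, 5]))


class TestMadFences:
    @pytest.mark.parametrize(
        "phase,mad,expected",
        [
            ("G1", 0.35, False),      # above the 0.3 G1 fence
            ("G1", 0.3, True),        # boundary passes (strict >)
            ("MID_S", 0.5, True),     # inside (0.4, 0.8)
            ("MID_S", 0.4, True),     # boundary passes (strict <)
            ("MID_S", 0.8, True),     # boundary passes (strict >)
            ("MID_S", 0.39, False),
            ("MID_S", 0.81, False),
            ("G1_CONTAMINANT", 0.391, False),
            ("G1_CONTAMINANT", 0.39, True),
        ],
    )
    def test_fence_conventions(self, phase, mad, expected):
        assert mad_fences(pd.Series([mad]), phase).iloc[0] == expected

    def test_unknown_phase_rejected(self):
        with pytest.raises(ArgumentError):
            mad_fences(pd.Series([0.1]), "M")


class TestManhattanFence:
    def _clone_cohort(self, n=20, bins=120, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.choice([UNREPLICATED, REPLICATED], bins)
        profiles = {}
        scores = {}
        for i in range(n):
            p = base.copy()
            flip = rng.choice(bins, 3, replace=False)  # light noise
            p[flip] = np.where(p[flip] == REPLICATED, UNREPLICATED, REPLICATED)
            profiles[f"c{i:02d}"] = p
            scores[f"c{i:02d}"] = 50 + i * 0.5
        return pd.DataFrame(profiles).T.astype(np.int8), pd.Series(scores)

    def test_identical_profiles_zero_distance_all_pass(self):
        profiles = pd.DataFrame(
            np.full((8, 50), REPLICATED, dtype=np.int8),
            index=[f"c{i}" for i in range(8)],
        )
        scores = pd.Series(np.linspace(40, 60, 8), index=profiles.index)
        d = manhattan_distances(profiles, scores)
        assert np.allclose(d, 0.0)
        assert manhattan_outlier_fence(profiles, scores).all()

    def test_inverted_cell_fails_alone(self):
        profiles, scores = self._clone_cohort()
        inv = profiles.iloc[0].replace({UNREPLICATED: REPLICATED, REPLICATED: UNREPLICATED})
        profiles.loc["bad"] = inv.astype(np.int8)
        scores["bad"] = 55.0
        passed = manhattan_outlier_fence(profiles, scores)
        assert not passed["bad"]
        assert passed.drop("bad").all()

    def test_missing_padding_does_not_change_distances(self):
        profiles, scores = self._clone_cohort(n=10, bins=80)
        padded = profiles.copy()
        pad = pd.DataFrame(
            np.full((len(profiles), 40), MISSING, dtype=np.int8),
            index=profiles.index,
        )
        padded = pd.concat([padded, pad.rename(columns=lambda c: 1000 + c)], axis=1)
        d1 = manhattan_distances(profiles, scores)
        d2 = manhattan_distances(padded, scores)
        assert np.allclose(d1, d2)

    def test_cohort_too_small_rejected(self):
        profiles = pd.DataFrame(np.zeros((4, 10)))
        with pytest.raises(ArgumentError):
            manhattan_outlier_fence(profiles, pd.Series(np.arange(4.0)))


class TestScoreRangeFence:
    @pytest.mark.parametrize(
        "score,expected",
        [(8.0, False), (10.0, True), (55.0, True), (90.0, True), (90.5, False)],
    )
    def test_boundaries_strict(self, score, expected):
        assert score_range_fence(pd.Series([score])).iloc[0] == expected


class TestRnaFences:
    def _metrics(self):
        # tight cohort: spread well inside the Tukey fences
        n = 20
        jitter = np.linspace(-1, 1, n)
        return pd.DataFrame(
            {
                "unique_reads": 2e6 + 1e4 * jitter,
                "rrna_frac": 0.05 + 0.001 * jitter,
                "mtrna_frac": 0.08 + 0.001 * jitter,
            },
            index=[f"c{i:02d}" for i in range(n)],
        )

    def test_homogeneous_cohort_passes(self):
        out = rna_fences(self._metrics())
        assert out["pass_rna"].all()

    def test_extreme_rrna_cell_fails_rrna_fence(self):
        m = self._metrics()
        m.loc["c00", "rrna_frac"] = 0.5
        out = rna_fences(m)
        assert not out.loc["c00", "pass_rrna"]
        assert out.loc["c00", "pass_unique_reads"]
        assert not out.loc["c00", "pass_rna"]

    def test_joint_failure_reported_per_metric(self):
        m = self._metrics()
        m.loc["c01", "rrna_frac"] = 0.5
        m.loc["c01", "mtrna_frac"] = 0.6
        out = rna_fences(m)
        assert not out.loc["c01", "pass_rrna"] and not out.loc["c01", "pass_mtrna"]


class TestErcc:
    def test_proportional_counts_give_unit_correlation(self):
        conc = pd.Series(np.logspace(-2, 3, 30), index=[f"e{i}" for i in range(30)])
        counts = (conc * 12.0).round()
        res = ercc_correlation(counts, conc)
        assert res.r > 0.99 and res.passed

    def test_permuted_counts_fail(self):
        rng = np.random.default_rng(4)
        conc = pd.Series(np.logspace(-2, 3, 92), index=[f"e{i}" for i in range(92)])
        counts = pd.Series(
            rng.permutation((conc * 10).round().to_numpy()), index=conc.index
        )
        res = ercc_correlation(counts, conc)
        assert not res.passed

    def test_boundary_r_fails_strict(self):
        # monkey-free check of the strict inequality through the threshold arg
        conc = pd.Series(np.logspace(0, 2, 20))
        counts = (conc * 5).round()
        res = ercc_correlation(counts, conc, r_threshold=1.1)
        assert not res.passed

    def test_too_few_detected_fails_with_reason(self):
        conc = pd.Series([1.0, 2, 3, 4, 5, 6])
        counts = pd.Series([0, 0, 3, 0, 0, 0])
        res = ercc_correlation(counts, conc)
        assert not res.passed and "detected" in res.reason


class TestDetectionRate:
    def test_identical_expression_detects_everything(self):
        ref = pd.Series(np.linspace(1, 100, 50), index=[f"g{i}" for i in range(50)])
        expr = pd.DataFrame({"c1": ref, "c2": ref})
        curve, n1 = detection_rate_curve(expr, ref, [0.5, 1, 10])
        assert (curve["mean_fraction"] == 1.0).all()
        assert (n1 == (ref > 1).sum()).all()

    def test_zero_expression_detects_nothing(self):
        ref = pd.Series(np.linspace(1, 100, 50), index=[f"g{i}" for i in range(50)])
        expr = pd.DataFrame({"c1": np.zeros(50)}, index=ref.index)
        curve, _ = detection_rate_curve(expr, ref, [0.5, 1, 10])
        assert (curve["mean_fraction"] == 0.0).all()

    def test_dropout_curve_non_increasing_threshold_fraction(self):
        rng = np.random.default_rng(5)
        ref = pd.Series(
            np.exp(rng.normal(2, 1.5, 400)), index=[f"g{i}" for i in range(400)]
        )
        # fixed dropout: each cell detects a gene with prob rising in level
        detect = rng.random((400, 10)) < 0.9
        expr = pd.DataFrame(
            ref.to_numpy()[:, None] * detect, index=ref.index,
            columns=[f"c{i}" for i in range(10)],
        )
        curve, _ = detection_rate_curve(expr, ref, [0, 1, 5, 20])
        fr = curve["mean_fraction"].to_numpy()
        assert all(b <= a + 0.05 for a, b in zip(fr, fr[1:]))

    def test_empty_reference_rejected(self):
        with pytest.raises(ArgumentError):
            detection_rate_curve(pd.DataFrame({"c": [1.0]}), pd.Series(dtype=float), [1])


class TestQcReport:
    def test_overall_pass_and_first_failure(self):
        flags = pd.DataFrame(
            {
                "pass_mapping_ratio": [True, False, True],
                "pass_mad": [True, False, False],
            },
            index=["a", "b", "c"],
        )
        rep = qc_report(flags)
        assert rep.loc["a", "overall_pass"]
        assert not rep.loc["b", "overall_pass"]
        assert rep.loc["b", "first_failing_rule"] == "pass_mapping_ratio"
        assert rep.loc["c", "first_failing_rule"] == "pass_mad"

    def test_cell_order_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        ratios = pd.Series(rng.normal(0.5, 0.02, 12), index=[f"c{i}" for i in range(12)])
        ratios.iloc[3] = 0.05
        p1 = mapping_ratio_fence(ratios)
        shuffled = ratios.sample(frac=1, random_state=1)
        p2 = mapping_ratio_fence(shuffled)
        assert p1.sort_index().equals(p2.sort_index())
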