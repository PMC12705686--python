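import numpy as np
import pandas as pd
import pytest

from replidyn import rtcore, simdata
from replidyn.errors import ArgumentError, QCError, StructuralError
from replidyn.grid import BinGrid
from replidyn.rtcore import (
    MISSING,
    REPLICATED,
    UNREPLICATED,
    average_mid_s,
    binarize_hmm,
    classify_rt,
    correct_mappability,
    replication_score,
    sort_and_stack,
    uniformity_score,
)


class TestCorrectMappability:
    def test_identity_gives_zero_ratios(self):
        s = np.full(300, 50.0)
        r = correct_mappability(s, s.copy())
        assert np.allclose(r[np.isfinite(r)], 0.0, atol=1e-9)

    def test_uniform_scaling_cancels(self):
        rng = np.random.default_rng(0)
        g = rng.integers(20, 80, 300).astype(float)
        r1 = correct_mappability(g, g)
        r2 = correct_mappability(2 * g, g)
        valid = np.isfinite(r1)
        # CPM scaling makes a uniform doubling invisible (up to the
        # pseudo-count's second-order effect)
        assert np.allclose(r1[valid], r2[valid], atol=0.02)

    def test_blacklisted_bin_missing_regardless_of_counts(self):
        grid = BinGrid.from_chrom_sizes({"chr1": 400_000}, 40_000)
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [40_000]})
        s = np.full(10, 100.0)
        r = correct_mappability(s, s.copy(), grid, blacklist=bl)
        assert np.isnan(r[0]) and np.isfinite(r[1:]).all()

    def test_low_reference_bins_missing(self):
        g = np.full(200, 100.0)
        g[7] = 0.0
        s = np.full(200, 100.0)
        r = correct_mappability(s, g)
        assert np.isnan(r[7])

    def test_empty_pool_rejected(self):
        with pytest.raises(ArgumentError):
            correct_mappability(np.ones(100), np.zeros(100))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            correct_mappability(np.ones(10), np.ones(11))


class TestBinarizeHMM:
    def test_noiseless_two_level_exact_recovery(self):
        x = np.tile(np.repeat([0.0, 1.0], 50), 4)  # clean alternating blocks
        res = binarize_hmm(x)
        expected = np.tile(np.repeat([UNREPLICATED, REPLICATED], 50), 4)
        assert np.array_equal(res.states, expected)
        assert not res.uniform_baseline

    def test_constant_input_no_spurious_replicated_calls(self):
        res = binarize_hmm(np.zeros(500), expected_mode="S_PHASE")
        assert res.uniform_baseline and res.indeterminate
        assert not np.any(res.states == REPLICATED)

    def test_g1_mode_overrides_majority_replicated(self):
        # 80% high state: a G1-gated cell must be declared uniform baseline
        x = np.concatenate([np.zeros(100), np.ones(400)])
        res = binarize_hmm(x, expected_mode="G1_BASELINE")
        assert res.uniform_baseline
        assert not np.any(res.states == REPLICATED)

    def test_location_shift_invariance(self):
        ref = simdata.make_reference_rt(2000, 20, seed=1)
        st = simdata.simulate_sphase_states(ref, 0.5, seed=3)
        counts, _ = simdata.simulate_bin_counts(st, seed=3)
        ratios = np.log2(counts + 0.5) - np.mean(np.log2(counts + 0.5))
        a = binarize_hmm(ratios)
        b = binarize_hmm(ratios + 0.73)
        assert np.array_equal(a.states, b.states)

    def test_missing_bins_stay_missing(self):
        x = np.tile(np.repeat([0.0, 1.0], 50), 2).astype(float)
        x[10:20] = np.nan
        res = binarize_hmm(x)
        assert np.all(res.states[10:20] == MISSING)
        assert np.all(res.states[:10] == UNREPLICATED)

    def test_too_few_bins_rejected(self):
        with pytest.raises(QCError):
            binarize_hmm(np.zeros(50))

    def test_simulated_mid_s_cell_agreement(self, reference_rt, g1_pool):
        st = simdata.simulate_sphase_states(reference_rt, 0.5, seed=3)
        counts, _ = simdata.simulate_bin_counts(st, seed=3)
        ratios = correct_mappability(counts, g1_pool, reference_rt.grid)
        res = binarize_hmm(ratios)
        valid = res.states != MISSING
        agreement = (res.states[valid] == st[valid]).mean()
        assert agreement >= 0.95


class TestReplicationScore:
    def test_direct_formula(self):
        states = np.array([REPLICATED] * 60 + [UNREPLICATED] * 40, dtype=np.int8)
        assert replication_score(states).score == pytest.approx(60.0)

    def test_all_replicated(self):
        states = np.full(50, REPLICATED, dtype=np.int8)
        assert replication_score(states).score == pytest.approx(100.0)

    def test_chromosome_exclusion_hand_count(self):
        # chrX: 30 rep / 30 unrep (excluded); chr1: 10 rep / 30 unrep
        grid = BinGrid.from_chrom_sizes({"chr1": 40 * 40_000, "chrX": 60 * 40_000}, 40_000)
        states = np.empty(100, dtype=np.int8)
        states[:10] = REPLICATED
        states[10:40] = UNREPLICATED
        states[40:70] = REPLICATED
        states[70:] = UNREPLICATED
        r = replication_score(states, grid, exclude_chroms=["chrX"])
        assert r.score == pytest.approx(25.0)
        assert r.n_valid_bins == 40

    def test_missing_excluded_from_both_sides(self):
        states = np.array([REPLICATED, UNREPLICATED, MISSING, MISSING], dtype=np.int8)
        r = replication_score(states)
        assert r.score == pytest.approx(50.0) and r.n_valid_bins == 2

    def test_no_valid_bins_rejected(self):
        with pytest.raises(QCError):
            replication_score(np.zeros(10, dtype=np.int8))


class TestAverageMidS:
    def test_extremes_and_mixture(self):
        # 4 cells, scores all mid-S; 3 bins: all rep, none rep, 3-of-4 rep
        states = np.array(
            [
                [REPLICATED, UNREPLICATED, REPLICATED],
                [REPLICATED, UNREPLICATED, REPLICATED],
                [REPLICATED, UNREPLICATED, REPLICATED],
                [REPLICATED, UNREPLICATED, UNREPLICATED],
            ],
            dtype=np.int8,
        )
        avg, n = average_mid_s(states, np.array([50, 55, 60, 65.0]))
        assert n == 4
        assert avg[0] == pytest.approx(1.0)
        assert avg[1] == pytest.approx(-1.0)
        assert avg[2] == pytest.approx(0.5)

    def test_window_bounds_inclusive(self):
        states = np.full((2, 5), REPLICATED, dtype=np.int8)
        _, n = average_mid_s(states, np.array([40.0, 70.0]))
        assert n == 2

    def test_empty_window_rejected(self):
        states = np.full((2, 5), REPLICATED, dtype=np.int8)
        with pytest.raises(ArgumentError):
            average_mid_s(states, np.array([10.0, 95.0]))

    def test_bin_with_no_informative_cell_missing(self):
        states = np.full((3, 2), MISSING, dtype=np.int8)
        states[:, 0] = REPLICATED
        avg, _ = average_mid_s(states, np.array([50, 50, 50.0]))
        assert np.isnan(avg[1]) and avg[0] == pytest.approx(1.0)

    def test_profile_fidelity_against_reference(self, reference_rt, g1_pool):
        rng = np.random.default_rng(12)
        from scipy.stats import spearmanr

        states = []
        scores = []
        for i in range(22):
            f = rng.uniform(0.42, 0.68)
            st = simdata.simulate_sphase_states(reference_rt, f, seed=300 + i)
            states.append(st)
            scores.append(100 * (st == REPLICATED).mean())
        avg, n = average_mid_s(np.array(states), np.array(scores))
        assert n >= 20
        rho = spearmanr(avg, reference_rt.rt).statistic
        assert rho >= 0.9


class TestClassifyRT:
    def test_nine_fraction_boundaries(self):
        v = np.array([-0.9, 0.9, 0.6, 0.0, -0.5])
        t = classify_rt(v)
        assert t.lower3 == pytest.approx(-0.3)
        assert t.upper7 == pytest.approx(0.5)
        assert list(t.classes) == ["late", "early", "early", "mid", "late"]

    def test_value_at_boundary_is_mid(self):
        v = np.array([-0.9, 0.9, 0.5, -0.3])
        t = classify_rt(v)
        assert t.classes[2] == "mid" and t.classes[3] == "mid"

    def test_printed_haploid_cutoffs_round_trip(self):
        # min/max solved back from the haploid preset cutoffs 0.213 / -0.287
        v = np.array([-0.662, 0.463, 0.0])
        t = classify_rt(v)
        assert t.lower3 == pytest.approx(-0.287, abs=1e-3)
        assert t.upper7 == pytest.approx(0.213, abs=1e-3)

    def test_partition_every_valid_bin(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(-1, 1, 500)
        v[::17] = np.nan
        t = classify_rt(v)
        valid = np.isfinite(v)
        assert all(c in ("early", "mid", "late") for c in t.classes[valid])
        assert all(c is None for c in t.classes[~valid])

    def test_constant_profile_rejected(self):
        with pytest.raises(ArgumentError):
            classify_rt(np.full(10, 0.3))


class TestUniformity:
    @pytest.mark.parametrize(
        "u,r,m,expected",
        [(100, 0, 0, 1.0), (50, 50, 0, 0.0), (30, 10, 10, 0.5)],
    )
    def test_analytic_cases(self, u, r, m, expected):
        states = np.array(
            [UNREPLICATED] * u + [REPLICATED] * r + [MISSING] * m, dtype=np.int8
        )
        assert uniformity_score(states) == pytest.approx(expected)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        states = rng.choice([UNREPLICATED, REPLICATED, MISSING], 200).astype(np.int8)
        swapped = states.copy()
        swapped[states == UNREPLICATED] = REPLICATED
        swapped[states == REPLICATED] = UNREPLICATED
        assert uniformity_score(states) == pytest.approx(uniformity_score(swapped))

    def test_no_valid_bins_rejected(self):
        with pytest.raises(QCError):
            uniformity_score(np.zeros(5, dtype=np.int8))


class TestSortAndStack:
    def test_orders_by_score(self):
        profiles = pd.DataFrame(
            np.eye(3, dtype=np.int8), index=["c1", "c2", "c3"]
        )
        scores = pd.Series({"c1": 30.0, "c2": 10.0, "c3": 20.0})
        out = sort_and_stack(profiles, scores)
        assert list(out.index) == ["c2", "c3", "c1"]
        assert len(out) == 3

    def test_ties_broken_by_cell_id(self):
        profiles = pd.DataFrame(np.zeros((3, 2)), index=["b", "a", "c"])
        scores = pd.Series({"a": 5.0, "b": 5.0, "c": 1.0})
        out = sort_and_stack(profiles, scores)
        assert list(out.index) == ["c", "a", "b"]

    def test_duplicate_ids_rejected(self):
        profiles = pd.DataFrame(np.zeros((2, 2)), index=["a", "a"])
        with pytest.raises(StructuralError):
            sort_and_stack(profiles, pd.Series({"a": 1.0}))
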