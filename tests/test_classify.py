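"""Correlation classification and the circular-shift permutation null."""

import math
import warnings

import numpy as np
import pytest

import boutwise as bw
from boutwise.classify import _admissible_shifts, bout_regressor
from boutwise.errors import ParameterError, ValidationError


def brute_force_permutation_p(z, reg, min_shift_frames):
    """Independent oracle: roll the trace shift by shift, correlate with
    np.corrcoef, count exceedances."""
    T = z.size
    r_obs = np.corrcoef(z, reg)[0, 1]
    shifts = range(min_shift_frames, T - min_shift_frames + 1)
    exceed = sum(
        1 for s in shifts if abs(np.corrcoef(np.roll(z, s), reg)[0, 1]) >= abs(r_obs)
    )
    n = len(list(shifts))
    return (1 + exceed) / (n + 1)


class TestBoutRegressor:
    def test_full_coverage_is_all_ones(self):
        bt = bw.BoutTrack([bw.BoutInterval(0, 10, "c")], (0.0, 10.0))
        assert np.all(bw.bout_regressor(bt, 10.0, 100) == 1.0)

    def test_empty_bouts_all_zero(self):
        bt = bw.BoutTrack([], (0.0, 10.0))
        assert np.all(bw.bout_regressor(bt, 10.0, 100) == 0.0)

    def test_half_open_frames(self):
        bt = bw.BoutTrack([bw.BoutInterval(60, 120, "c")], (0.0, 200.0))
        reg = bw.bout_regressor(bt, 10.0, 2000)
        assert np.flatnonzero(reg).tolist() == list(range(600, 1200))

    def test_bout_outside_trace_span_rejected(self):
        bt = bw.BoutTrack([bw.BoutInterval(60, 120, "c")], (0.0, 200.0))
        with pytest.raises(ValidationError):
            bout_regressor(bt, 10.0, 100)

    def test_kernel_smoothing_delays_mass(self):
        bt = bw.BoutTrack([bw.BoutInterval(5, 10, "c")], (0.0, 30.0))
        raw = bw.bout_regressor(bt, 10.0, 300)
        smooth = bw.bout_regressor(bt, 10.0, 300, smoothing="kernel")
        assert smooth[120] > 0 and raw[120] == 0  # decay tail past bout end


class TestCorrelateCell:
    def test_perfect_correlation(self):
        reg = np.r_[np.zeros(50), np.ones(50)]
        assert bw.correlate_cell(reg.copy(), reg) == pytest.approx(1.0)
        assert bw.correlate_cell(-reg, reg) == pytest.approx(-1.0)

    def test_matches_hand_computed_fraction(self):
        # exact arithmetic: cov = 4, var_x = 10, var_y = 21/10 -> r = 4/sqrt(21)
        x = np.array([0, 1, 2, 3, 2, 1, 0, 0, 1, 0], dtype=float)
        y = np.array([0, 0, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        assert bw.correlate_cell(x, y) == pytest.approx(4 / math.sqrt(21), abs=1e-12)

    def test_constant_regressor_redirects_to_empty_bout_path(self):
        with pytest.raises(ValidationError, match="neutral"):
            bw.correlate_cell(np.arange(10.0), np.ones(10))


class TestPermutationNull:
    def test_exhaustive_equals_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        T, rate = 200, 10.0
        z = rng.normal(size=T).cumsum() * 0.3 + rng.normal(size=T)
        reg = np.zeros(T)
        reg[40:80] = 1.0
        reg[120:140] = 1.0
        min_shift_s = 2.0
        p = bw.permutation_null(
            z, reg, min_shift_s=min_shift_s, frame_rate=rate, shifts="all"
        )
        p_oracle = brute_force_permutation_p(z, reg, int(min_shift_s * rate))
        assert p == pytest.approx(p_oracle, abs=0)

    def test_strong_signal_attains_estimator_floor(self):
        T = 400
        reg = np.zeros(T)
        reg[100:200] = 1.0
        p = bw.permutation_null(reg.copy(), reg, n_perm=99, seed=1,
                                min_shift_s=2.0, frame_rate=10.0)
        assert p == pytest.approx(1 / 100)

    def test_p_support_is_add_one_grid(self):
        rng = np.random.default_rng(5)
        reg = np.zeros(300); reg[50:120] = 1.0
        n_perm = 37
        for _ in range(20):
            z = rng.normal(size=300)
            p = bw.permutation_null(z, reg, n_perm=n_perm, rng=rng,
                                    min_shift_s=1.0, frame_rate=10.0)
            k = p * (n_perm + 1)
            assert k == pytest.approx(round(k)) and 1 <= round(k) <= n_perm + 1

    def test_null_p_values_approximately_uniform(self):
        """White-noise traces: empirical p CDF within a Kolmogorov band."""
        rng = np.random.default_rng(99)
        reg = np.zeros(600); reg[100:200] = 1.0; reg[380:450] = 1.0
        ps = np.array([
            bw.permutation_null(rng.normal(size=600), reg, n_perm=99, rng=rng,
                                min_shift_s=1.0, frame_rate=10.0)
            for _ in range(500)
        ])
        grid = np.sort(ps)
        ecdf = np.arange(1, 501) / 500
        ks = np.max(np.abs(ecdf - grid))
        assert ks < 1.63 / np.sqrt(500)  # 1% Kolmogorov band

    def test_short_trace_rejected(self):
        with pytest.raises(ParameterError):
            _admissible_shifts(100, 60)


class TestClassifyCells:
    def test_recovery_on_planted_population(self, small_session_z):
        session, gt, z, deg = small_session_z
        res = bw.classify_cells(session, z, n_perm=300, seed=1, exclude_cells=deg)
        planted = gt.label_fractions(f"{session.animal_id}/{session.stimulus}")
        for lab in planted:
            assert abs(res.fractions[lab] - planted[lab]) <= 0.08

    def test_negation_swaps_labels_exactly(self, small_session_z):
        session, _, z, deg = small_session_z
        res = bw.classify_cells(session, z, n_perm=100, seed=2, exclude_cells=deg)
        neg_z = bw.TraceMatrix(z.cell_ids, z.frame_rate, -z.values, "zscored")
        res_neg = bw.classify_cells(session, neg_z, n_perm=100, seed=2,
                                    exclude_cells=deg)
        swap = {"positive": "negative", "negative": "positive", "neutral": "neutral"}
        assert [swap[l] for l in res.table["label"]] == list(res_neg.table["label"])
        np.testing.assert_allclose(res.table["r"], -res_neg.table["r"], atol=1e-12)

    def test_alpha_zero_labels_everything_neutral(self, small_session_z):
        session, _, z, deg = small_session_z
        res = bw.classify_cells(session, z, alpha=0.0, n_perm=50, seed=0,
                                exclude_cells=deg)
        assert set(res.table["label"]) == {"neutral"}

    def test_empty_bouts_all_neutral_with_warning(self, small_session_z):
        session, _, z, _ = small_session_z
        empty = bw.Session(
            animal_id=session.animal_id,
            stimulus=session.stimulus,
            traces=session.traces,
            bouts=bw.BoutTrack([], session.bouts.phase_boundaries),
        )
        with pytest.warns(UserWarning, match="no bouts"):
            res = bw.classify_cells(empty, z, n_perm=10, seed=0)
        assert set(res.table["label"]) == {"neutral"}

    def test_gain_monotonicity_of_correlation(self):
        """Mean r of coupled cells rises strictly with the planted gain."""
        mean_r = []
        for gain in [1.5, 2.5, 4.0]:
            rs = []
            for seed in range(3):
                cfg = bw.SessionConfig(
                    n_cells=20, fractions=(1.0, 0.0, 0.0), positive_gain=gain,
                    habituation_s=100, stimulus_s=300,
                )
                session, _ = bw.simulate_session(cfg, seed=seed)
                z, _ = bw.zscore_traces(session.traces, bouts=session.bouts)
                reg = bw.bout_regressor(session.bouts, 10.0, z.n_frames)
                rs.extend(bw.correlate_cell(z.values[i], reg) for i in range(20))
            mean_r.append(np.mean(rs))
        assert mean_r[0] < mean_r[1] < mean_r[2]
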