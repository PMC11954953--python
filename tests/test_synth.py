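"""Synthetic generator: closed-form expectations and planted structure."""

import numpy as np
import pytest

import boutwise as bw
from boutwise.errors import ParameterError
from boutwise.synth import make_paradigm_bouts, sample_bouts


class TestSimulateEvents:
    def test_poisson_expectation_matches_closed_form(self):
        """baseline 0.2 ev/s with gain 3 over 120 s of bouts in 600 s:
        E[total] = 0.2*480 + 0.6*120 = 168."""
        arch = [bw.NeuronArchetype("positive", baseline_rate=0.2, bout_gain=3.0)]
        bouts = bw.BoutTrack(
            [bw.BoutInterval(100, 160, "c"), bw.BoutInterval(300, 360, "c")],
            (0.0, 600.0),
        )
        n_rep = 400
        totals = []
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            totals.append(bw.simulate_events(arch, bouts, 600.0, 10.0, rng).sum())
        expected = 0.2 * 480 + 0.6 * 120
        se = np.sqrt(expected / n_rep)
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_neutral_gain_balances_in_and_out_rates(self, rng):
        arch = [bw.NeuronArchetype("neutral", 1.0, 1.0) for _ in range(10)]
        bouts = bw.BoutTrack([bw.BoutInterval(0, 300, "c")], (0.0, 600.0))
        raster = bw.simulate_events(arch, bouts, 600.0, 10.0, rng)
        in_rate = raster[:, :3000].mean()
        out_rate = raster[:, 3000:].mean()
        se = np.sqrt(raster.mean() / raster[:, :3000].size)
        assert abs(in_rate - out_rate) < 4 * se

    def test_empty_bouts_are_homogeneous(self, rng):
        arch = [bw.NeuronArchetype("neutral", 0.5, 1.0)]
        raster = bw.simulate_events(arch, None, 100.0, 10.0, rng)
        assert raster.shape == (1, 1000)

    def test_duration_must_cover_bouts(self, rng):
        arch = [bw.NeuronArchetype("positive", 0.2, 2.0)]
        bouts = bw.BoutTrack([bw.BoutInterval(50, 90, "c")], (0.0, 100.0))
        with pytest.raises(ParameterError):
            bw.simulate_events(arch, bouts, 80.0, 10.0, rng)


class TestFluorescence:
    def test_zero_events_zero_noise_gives_zero_trace(self):
        tm = bw.events_to_fluorescence(
            np.zeros((2, 100)), bw.CalciumKernel(), noise_sd=0.0, frame_rate=10.0
        )
        assert np.all(tm.values == 0)
        assert tm.unit_tag == "raw"

    def test_single_event_peaks_at_analytic_kernel_max(self):
        kernel = bw.CalciumKernel(tau_rise_s=0.07, tau_decay_s=1.0, amplitude=2.0)
        raster = np.zeros((1, 300))
        k = 50
        raster[0, k] = 1
        tm = bw.events_to_fluorescence(raster, kernel, 0.0, frame_rate=100.0)
        peak_frame = int(np.argmax(tm.values[0]))
        # event onset at frame k; peak should land one analytic peak time later
        assert abs(peak_frame - (k + kernel.peak_time_s * 100.0)) <= 1.5
        assert tm.values[0].max() == pytest.approx(kernel.amplitude, rel=1e-3)

    def test_superposition_of_two_events(self):
        kernel = bw.CalciumKernel()
        a = np.zeros((1, 500)); a[0, 30] = 1
        b = np.zeros((1, 500)); b[0, 200] = 1
        fa = bw.events_to_fluorescence(a, kernel, 0.0, 10.0).values
        fb = bw.events_to_fluorescence(b, kernel, 0.0, 10.0).values
        fab = bw.events_to_fluorescence(a + b, kernel, 0.0, 10.0).values
        np.testing.assert_allclose(fab, fa + fb, atol=1e-9)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ParameterError):
            bw.events_to_fluorescence(np.zeros((1, 10)), bw.CalciumKernel(), -0.1, 10.0)

    def test_kernel_requires_ordered_time_constants(self):
        with pytest.raises(ParameterError):
            bw.CalciumKernel(tau_rise_s=2.0, tau_decay_s=1.0)


class TestSimulateSession:
    def test_all_positive_fractions(self):
        cfg = bw.SessionConfig(n_cells=12, fractions=(1.0, 0.0, 0.0),
                               habituation_s=50, stimulus_s=100)
        _, gt = bw.simulate_session(cfg, seed=0)
        assert set(gt.labels["animal-01/water"]) == {"positive"}

    def test_default_fixture_geometry(self):
        cfg = bw.SessionConfig(n_cells=10)
        session, _ = bw.simulate_session(cfg, seed=0)
        assert session.traces.n_frames == 12000  # 1200 s at 10 Hz
        assert session.bouts.habituation_end_s == 600.0

    def test_habituation_is_bout_free(self):
        session, _ = bw.simulate_session(bw.SessionConfig(n_cells=5), seed=3)
        assert all(iv.start_s >= 600.0 for iv in session.bouts.intervals)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ParameterError, match="sum to 1"):
            bw.SessionConfig(fractions=(0.5, 0.5, 0.5))

    def test_habituation_segment_invariant_to_stimulus_phase(self):
        """Same seed, different stimulus-phase bout draws: the habituation
        segment of every trace is bit-identical (per-phase child streams)."""
        base = dict(n_cells=6, habituation_s=100, stimulus_s=200)
        s1, _ = bw.simulate_session(
            bw.SessionConfig(**base, bout_stats=bw.BoutStatistics()), seed=9
        )
        s2, _ = bw.simulate_session(
            bw.SessionConfig(**base,
                             bout_stats=bw.BoutStatistics(consume_median_s=6.0)),
            seed=9,
        )
        hab = slice(0, 1000)
        assert np.array_equal(s1.traces.values[:, hab], s2.traces.values[:, hab])
        assert not np.array_equal(s1.traces.values, s2.traces.values)


class TestSimulateLongitudinal:
    def test_zero_switch_prob_keeps_all_labels(self):
        cfg = bw.LongitudinalConfig(
            n_cells=30, overlap_rate=1.0, switch_prob=0.0,
            session_cfg=bw.SessionConfig(n_cells=30, habituation_s=20,
                                         stimulus_s=40, simulate_traces=False),
        )
        _, _, gt = bw.simulate_longitudinal(cfg, seed=1)
        assert all(a == b for _, a, b in gt.transitions["animal-01"])

    def test_zero_overlap_shares_no_globals(self):
        cfg = bw.LongitudinalConfig(
            n_cells=20, overlap_rate=0.0,
            session_cfg=bw.SessionConfig(n_cells=20, habituation_s=20,
                                         stimulus_s=40, simulate_traces=False),
        )
        _, lmap, gt = bw.simulate_longitudinal(cfg, seed=1)
        a, b = sorted(gt.labels)
        assert lmap.shared_globals(a, b) == []

    def test_planted_switched_fraction_matches_probability(self):
        cfg = bw.LongitudinalConfig(
            n_cells=200, overlap_rate=1.0, switch_prob=0.6,
            session_cfg=bw.SessionConfig(n_cells=200, habituation_s=20,
                                         stimulus_s=40, simulate_traces=False),
        )
        _, _, gt = bw.simulate_longitudinal(cfg, seed=5)
        switched = sum(a != b for _, a, b in gt.transitions["animal-01"])
        se = np.sqrt(0.6 * 0.4 / 200)
        assert abs(switched / 200 - 0.6) <= max(3 * se, 1 / 200)

    def test_overlap_count_in_map(self):
        cfg = bw.LongitudinalConfig(
            n_cells=200, overlap_rate=0.5,
            session_cfg=bw.SessionConfig(n_cells=200, habituation_s=20,
                                         stimulus_s=40, simulate_traces=False),
        )
        _, lmap, gt = bw.simulate_longitudinal(cfg, seed=2)
        a, b = sorted(gt.labels)
        assert len(lmap.shared_globals(a, b)) == 100


class TestRoiTable:
    def test_planted_ranking_recovered(self):
        df, planted = bw.simulate_roi_table(["r1", "r2", "r3"], seed=4)
        out = bw.quantify_roi_table(df)
        recovered = list(out["region"])
        expected = sorted(planted, key=planted.get, reverse=True)
        assert recovered == expected

    def test_zero_background_means_ctf_equals_density(self):
        df, _ = bw.simulate_roi_table(["r1"], seed=0, background_mean=0.0)
        from boutwise.quantify import ctf_table
        out = ctf_table(df)
        np.testing.assert_allclose(out["ctf"], out["integrated_density"])


class TestBoutSampling:
    def test_bouts_confined_to_window_and_alternating(self, rng):
        ivs = sample_bouts((600.0, 1200.0), bw.BoutStatistics(), rng)
        assert ivs, "expected at least one bout in a 10-min window"
        assert all(600.0 <= iv.start_s < iv.end_s <= 1200.0 for iv in ivs)
        for a, b in zip(ivs, ivs[1:]):
            assert b.start_s > a.end_s
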