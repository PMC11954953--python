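"""Cross-session matching and stable/unstable fraction bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import boutwise as bw
from boutwise.errors import ParameterError, ValidationError
from boutwise.stability import transition_counts


def _class_df(session, labels):
    return pd.DataFrame(
        {
            "cell": [f"c{i}" for i in range(len(labels))],
            "label": labels,
            "session": session,
        }
    )


def _identity_map(session_a, session_b, n):
    lmap = bw.LongitudinalMap()
    for i in range(n):
        lmap.add(session_a, f"c{i}", f"g{i}")
        lmap.add(session_b, f"c{i}", f"g{i}")
    return lmap


class TestMatchLabels:
    def test_identity_map_pairs_everyone(self):
        df_a = _class_df("s1", ["positive"] * 5)
        df_b = _class_df("s2", ["negative"] * 5)
        pairs, info = bw.match_labels(df_a, df_b, _identity_map("s1", "s2", 5),
                                      "s1", "s2")
        assert len(pairs) == 5 == info["n_matched"]
        assert pairs[0] == ("positive", "negative")

    def test_disjoint_map_yields_empty_pairs(self):
        lmap = bw.LongitudinalMap()
        lmap.add("s1", "c0", "gA")
        lmap.add("s2", "c0", "gB")
        pairs, info = bw.match_labels(
            _class_df("s1", ["positive"]), _class_df("s2", ["neutral"]),
            lmap, "s1", "s2",
        )
        assert pairs == [] and info["only_in_a"] == 1

    def test_unknown_cell_in_map_rejected(self):
        lmap = bw.LongitudinalMap()
        lmap.add("s1", "c99", "g0")
        lmap.add("s2", "c0", "g0")
        with pytest.raises(ValidationError, match="c99"):
            bw.match_labels(_class_df("s1", ["positive"]),
                            _class_df("s2", ["positive"]), lmap, "s1", "s2")

    def test_overlap_rate_controls_matched_count(self):
        cfg = bw.LongitudinalConfig(
            n_cells=200, overlap_rate=0.5,
            session_cfg=bw.SessionConfig(n_cells=200, habituation_s=20,
                                         stimulus_s=40, simulate_traces=False),
        )
        _, lmap, gt = bw.simulate_longitudinal(cfg, seed=8)
        ses_a, ses_b = sorted(gt.labels)
        df_a = pd.DataFrame({"cell": [f"cell{i:04d}" for i in range(200)],
                             "label": gt.labels[ses_a]})
        df_b = pd.DataFrame({"cell": [f"cell{i:04d}" for i in range(200)],
                             "label": gt.labels[ses_b]})
        pairs, _ = bw.match_labels(df_a, df_b, lmap, ses_a, ses_b)
        assert len(pairs) == 100


class TestTransitionFractions:
    def test_direct_category_count(self):
        pairs = [("positive", "positive"), ("negative", "negative"),
                 ("positive", "negative"), ("neutral", "positive")]
        rep = bw.transition_fractions(pairs)
        assert rep.stable_fraction == pytest.approx(0.5)
        assert rep.unstable_fraction == pytest.approx(0.5)
        assert rep.denominator == 4 and rep.excluded_neutral_neutral == 0

    def test_neutral_neutral_excluded_from_denominator(self):
        pairs = [("positive", "positive")] * 3 + [("neutral", "neutral")] * 7
        rep = bw.transition_fractions(pairs)
        assert rep.denominator == 3 and rep.excluded_neutral_neutral == 7
        assert rep.stable_fraction == pytest.approx(1.0)

    def test_all_neutral_neutral_returns_sentinel(self):
        rep = bw.transition_fractions([("neutral", "neutral")] * 5)
        assert not rep.defined
        assert rep.stable_fraction is None and rep.unstable_fraction is None

    def test_fractions_sum_to_one_on_declared_denominator(self):
        rng = np.random.default_rng(0)
        labels = ["positive", "negative", "neutral"]
        pairs = [(labels[rng.integers(3)], labels[rng.integers(3)])
                 for _ in range(300)]
        rep = bw.transition_fractions(pairs)
        if rep.defined:
            assert rep.stable_fraction + rep.unstable_fraction == pytest.approx(1.0)

    def test_switch_prob_recovered_via_pipeline(self):
        """Planted switching on all-coupled populations comes back as the
        specializer fraction through match + fraction bookkeeping."""
        for prob in (0.2, 0.8):
            cfg = bw.LongitudinalConfig(
                n_cells=200, overlap_rate=1.0, switch_prob=prob,
                session_cfg=bw.SessionConfig(
                    n_cells=200, fractions=(0.5, 0.5, 0.0), habituation_s=20,
                    stimulus_s=40, simulate_traces=False,
                ),
            )
            _, lmap, gt = bw.simulate_longitudinal(cfg, seed=31)
            ses_a, ses_b = sorted(gt.labels)
            df_a = pd.DataFrame({"cell": [f"cell{i:04d}" for i in range(200)],
                                 "label": gt.labels[ses_a]})
            df_b = pd.DataFrame({"cell": [f"cell{i:04d}" for i in range(200)],
                                 "label": gt.labels[ses_b]})
            pairs, _ = bw.match_labels(df_a, df_b, lmap, ses_a, ses_b)
            rep = bw.transition_fractions(pairs)
            assert rep.unstable_fraction == pytest.approx(prob, abs=0.05)


class TestChordExport:
    def test_single_edge(self):
        counts = transition_counts([("positive", "positive")] * 7)
        chord = bw.chord_export(counts)
        weights = {(e["source"], e["target"]): e["count"] for e in chord["edges"]}
        assert weights[("positive", "positive")] == 7
        assert sum(weights.values()) == 7

    def test_uniform_counts_give_nine_equal_edges(self):
        labels = ["positive", "negative", "neutral"]
        pairs = [(a, b) for a in labels for b in labels] * 4
        chord = bw.chord_export(transition_counts(pairs))
        assert all(e["count"] == 4 for e in chord["edges"])

    def test_edge_sums_match_session_marginals(self):
        rng = np.random.default_rng(3)
        labels = ["positive", "negative", "neutral"]
        pairs = [(labels[rng.integers(3)], labels[rng.integers(3)])
                 for _ in range(100)]
        counts = transition_counts(pairs)
        chord = bw.chord_export(counts)
        for lab in labels:
            out_sum = sum(e["count"] for e in chord["edges"] if e["source"] == lab)
            in_sum = sum(e["count"] for e in chord["edges"] if e["target"] == lab)
            assert out_sum == chord["marginal_earlier"][lab]
            assert in_sum == chord["marginal_later"][lab]
            assert out_sum == sum(1 for a, _ in pairs if a == lab)


class TestCompareFractionGroups:
    def test_identical_groups_p_one(self):
        a = [0.4, 0.5, 0.6, 0.45, 0.55]
        rep = bw.compare_fraction_groups(a, list(a))
        assert rep.p_value == pytest.approx(1.0)
        assert rep.effect_size_d == pytest.approx(0.0)

    def test_group_swap_flips_statistic_sign(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.6, 0.05, 8)
        b = rng.normal(0.4, 0.05, 8)
        r1 = bw.compare_fraction_groups(a, b)
        r2 = bw.compare_fraction_groups(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_planted_group_difference_power(self):
        """0.6 vs 0.4 with small within-animal spread at n=8: significant in
        at least 80% of 100 replicates."""
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(100):
            a = rng.normal(0.6, 0.08, 8)
            b = rng.normal(0.4, 0.08, 8)
            if bw.compare_fraction_groups(a, b).p_value < 0.05:
                hits += 1
        assert hits >= 80

    def test_too_few_animals_rejected(self):
        with pytest.raises(ParameterError):
            bw.compare_fraction_groups([0.5], [0.4, 0.5])
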