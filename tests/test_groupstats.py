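"""Univariate maps, mixed-model dynamics, clustering scores, correlations."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_pool, make_session
from memdyn.features import frequency_grid, tensor_from_simulated
from memdyn.groupstats import (
    behavioral_clustering_scores,
    bootstrap_correlation_difference,
    correlate_neural_behavioral,
    dynamics_mixed_model,
    dynamics_table,
    group_auc_test,
    group_test,
    neural_clustering_scores,
    participant_inclusion,
    univariate_contrast,
)
from memdyn.montage import ROI_NAMES, make_sphere_montage
from memdyn.synthetic import (
    EffectSpec,
    TaskDesign,
    generate_word_pool,
    simulate_behavior,
    simulate_features,
)


class TestUnivariateContrast:
    def _tensors(self, spec, seed=31, lists=10):
        design = TaskDesign(n_sessions=1, lists_per_session=lists)
        pool = generate_word_pool(seed=seed)
        behavior = simulate_behavior(design, pool, seed=seed)
        montage = make_sphere_montage(8)
        sims = [
            simulate_features(b, spec, montage, pool, design=design, seed=seed)
            for b in behavior
        ]
        return [tensor_from_simulated(s, "encoding") for s in sims], montage

    def test_planted_negative_effect_yields_most_negative_t(self):
        freqs = frequency_grid()
        spec = EffectSpec.planted(freqs, 10.0, "RAS", -1.0)
        tensors, montage = self._tensors(spec)
        tmap = univariate_contrast(
            tensors, montage, "recalled", "serial_position"
        )
        fi, ri = np.unravel_index(np.argmin(tmap), tmap.shape)
        assert freqs[fi] == 10.0
        assert ROI_NAMES[ri] == "RAS"

    def test_equal_variance_two_sample_closed_form(self):
        # two groups of two values each: compare to the textbook formula
        values = np.array([[1.0], [3.0], [6.0], [8.0]])[:, :, None]
        events = pd.DataFrame(
            {"recalled": [1, 1, 0, 0], "serial_position": [1, 2, 3, 4]}
        )

        class Tiny:
            pass

        tensor = Tiny()
        tensor.values = values
        tensor.events = events
        montage = make_sphere_montage(8)
        pooled = values[:, :, [0] * 8]  # same value in every ROI channel
        tensor.values = pooled
        tmap = univariate_contrast(
            [tensor], montage, "recalled", "serial_position"
        )
        m1, m2 = 2.0, 7.0
        s2 = (2.0 + 2.0) / 2  # pooled variance of {1,3} and {6,8}
        expected = (m1 - m2) / np.sqrt(s2 * (1 / 2 + 1 / 2))
        assert tmap[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_resampling_flag_changes_event_set(self):
        freqs = frequency_grid()
        spec = EffectSpec.drift_only(freqs, scale=1.0)
        tensors, montage = self._tensors(spec, seed=33)
        t_all = univariate_contrast(
            tensors, montage, "recalled", "serial_position", resample=False
        )
        t_res = univariate_contrast(
            tensors, montage, "recalled", "serial_position", resample=True,
            seed=5,
        )
        assert not np.allclose(t_all, t_res)


class TestGroupTest:
    def test_constant_effect_in_one_cell_detected(self):
        rng = np.random.default_rng(0)
        maps = 0.05 * rng.standard_normal((40, 29, 8))
        maps[:, 3, 2] += 5.0
        res = group_test(maps, freqs=frequency_grid())
        assert res.significant[3, 2]
        assert res.significant.sum() == 1

    def test_fdr_monotone_in_q(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((12, 29, 8))
        maps[:, :4, :] += 0.6
        strict = group_test(maps, q=0.01).significant
        loose = group_test(maps, q=0.05).significant
        assert np.all(loose[strict])  # lowering q never adds cells

    def test_participant_order_invariance(self):
        rng = np.random.default_rng(2)
        maps = rng.standard_normal((10, 29, 8))
        a = group_test(maps)
        b = group_test(maps[rng.permutation(10)])
        assert np.allclose(a.group_t, b.group_t)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            group_test(np.zeros((2, 29, 8)))


class TestGroupAUC:
    def test_identical_distributions_give_zero_t(self):
        obs = np.array([0.55, 0.6, 0.5])
        assert group_auc_test(obs, obs) == (0.0, 0.5)

    def test_constant_shift_flagged_degenerate(self):
        obs = np.array([0.55, 0.6, 0.5])
        with pytest.raises(ValueError):
            group_auc_test(obs + 0.1, obs)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(3)
        obs = 0.5 + 0.05 * rng.random(12)
        null = 0.5 + 0.01 * rng.standard_normal(12)
        t, p = group_auc_test(obs, null)
        d = obs - null
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(expected_t, abs=1e-12)
        from scipy import stats

        assert p == pytest.approx(
            stats.t.sf(expected_t, len(d) - 1), abs=1e-12
        )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            group_auc_test(np.ones(3), np.ones(4))


def _dyn_events(probs_by_cell, n_per_cell=1):
    """Build (probs, events) covering given (subtype, serial_position)."""
    rows, probs = [], []
    for (subtype, pos), p in probs_by_cell.items():
        for _ in range(n_per_cell):
            rows.append({"subtype": subtype, "serial_position": pos})
            probs.append(p)
    return np.array(probs), pd.DataFrame(rows)


class TestDynamicsTable:
    def test_single_event_cell_equals_its_probability(self):
        probs, events = _dyn_events(
            {("TC", 2): 0.8, ("NC", 10): 0.4, ("NR", 22): 0.2}
        )
        table = dynamics_table({"P0": (probs, events)}, "encoding")
        cell = table.set_index(["subtype", "position_group"]).value
        assert cell.loc[("TC", "early")] == pytest.approx(0.8)
        assert cell.loc[("NC", "middle")] == pytest.approx(0.4)
        assert cell.loc[("NR", "late")] == pytest.approx(0.2)
        assert len(table) == 3  # empty cells absent, not zero

    def test_event_order_invariance(self):
        rng = np.random.default_rng(4)
        probs, events = _dyn_events(
            {(s, p): rng.random()
             for s in ("BC", "TC", "NC") for p in (1, 10, 23)},
            n_per_cell=3,
        )
        perm = rng.permutation(len(probs))
        a = dynamics_table({"P0": (probs, events)}, "encoding")
        b = dynamics_table(
            {"P0": (probs[perm], events.iloc[perm].reset_index(drop=True))},
            "encoding",
        )
        pd.testing.assert_frame_equal(
            a.sort_values(["subtype", "position_group"]).reset_index(drop=True),
            b.sort_values(["subtype", "position_group"]).reset_index(drop=True),
        )


def _mixed_table(n_participants=24, subtype_shift=None, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_participants):
        intercept = 0.5 + 0.05 * rng.standard_normal()
        for s in ("BC", "TC", "SC", "NC", "NR"):
            for g in ("early", "middle", "late"):
                v = intercept + noise * rng.standard_normal()
                if subtype_shift and s in subtype_shift:
                    v += subtype_shift[s]
                rows.append((f"P{j}", s, g, v))
    return pd.DataFrame(
        rows, columns=["participant", "subtype", "position_group", "value"]
    )


class TestDynamicsMixedModel:
    def test_constant_table_gives_zero_f(self):
        table = _mixed_table(noise=1e-9, seed=1)
        table["value"] = 0.5
        with pytest.warns(UserWarning):
            res = dynamics_mixed_model(table)
        assert np.all(res.anova.F == 0.0)
        assert np.all(res.anova.p == 1.0)

    def test_planted_subtype_shift_detected_in_emm_contrast(self):
        table = _mixed_table(subtype_shift={"BC": 0.1}, seed=2)
        with pytest.warns(UserWarning):
            res = dynamics_mixed_model(table)
        sub_f = res.anova.set_index("term")
        assert sub_f.loc["C(subtype, Sum)", "p"] < 0.001
        c = res.emm_contrasts.set_index(["a", "b"])
        assert c.loc[("BC", "NC"), "p_bonf"] < 0.001
        assert c.loc[("NC", "SC"), "p_bonf"] > 0.05

    def test_emm_recovers_cell_means(self):
        table = _mixed_table(subtype_shift={"BC": 0.2}, noise=0.001, seed=3)
        with pytest.warns(UserWarning):
            res = dynamics_mixed_model(table)
        emm = res.emm.set_index(["subtype", "position_group"]).emm
        assert emm.loc[("BC", "early")] == pytest.approx(0.7, abs=0.02)
        assert emm.loc[("NC", "late")] == pytest.approx(0.5, abs=0.02)

    def test_single_participant_rejected(self):
        table = _mixed_table(n_participants=1)
        with pytest.raises(ValueError):
            dynamics_mixed_model(table)


class TestBehavioralScores:
    def test_perfect_forward_recall_scores_one(self):
        pool = make_pool(np.eye(24))
        rows = [(0, float(k + 1), k, "correct") for k in range(24)]
        sess = make_session({0: range(24)}, rows)
        t_score, _ = behavioral_clustering_scores([sess], pool)
        assert t_score == 1.0

    def test_single_available_transition_excluded(self):
        pool = make_pool(np.eye(4))
        # recall everything: the final transition has one available item
        rows = [(0, 1.0, 0, "correct"), (0, 2.0, 2, "correct"),
                (0, 3.0, 1, "correct"), (0, 4.0, 3, "correct")]
        sess = make_session({0: range(4)}, rows)
        t_score, _ = behavioral_clustering_scores([sess], pool)
        # transitions scored: 0->2 (avail {1,2,3}), 2->1 (avail {1,3});
        # 1->3 has a single available item and is excluded
        # 0->2: lags from pos1 to {2,3,4} = {1,2,3}; actual 2 -> rank 0.5
        # 2->1: lags from pos3 to {2,4} = {1,1}; actual 1 -> tie -> 0.5
        assert t_score == pytest.approx(0.5)

    def test_matches_exhaustive_enumeration_on_toy_sequence(self):
        pool = make_pool(np.eye(5))
        rows = [(0, 1.0, 1, "correct"), (0, 2.0, 4, "correct"),
                (0, 3.0, 3, "correct"), (0, 4.0, 0, "correct")]
        sess = make_session({0: range(5)}, rows)
        t_score, _ = behavioral_clustering_scores([sess], pool)
        # transition 1(pos2)->4(pos5): avail pos {1,3,4,5}, lags {1,1,2,3},
        #   actual 3 -> worse 0, tied 0 -> 0/3
        # transition 4(pos5)->3(pos4): avail pos {1,4}, lags {4,1},
        #   actual 1 -> worse 1 -> 1/1
        # transition 3(pos4)->0(pos1): avail pos {1,3}, lags {3,1},
        #   actual 3 -> worse 0 -> 0/1
        expected = np.mean([0.0, 1.0, 0.0])
        assert t_score == pytest.approx(expected)

    def test_no_transitions_rejected(self):
        pool = make_pool(np.eye(4))
        sess = make_session({0: range(4)}, [(0, 1.0, 0, "correct")])
        with pytest.raises(ValueError):
            behavioral_clustering_scores([sess], pool)


class TestNeuralScores:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(5)
        probs = rng.random(300)
        subtypes = np.array((["TC"] * 100) + (["SC"] * 100) + (["NC"] * 100))
        t_t, t_s = neural_clustering_scores(probs, subtypes)
        assert abs(t_t) < 2.5 and abs(t_s) < 2.5

    def test_shifted_clustered_outputs_positive(self):
        rng = np.random.default_rng(6)
        probs = np.concatenate(
            [0.6 + 0.1 * rng.standard_normal(80),
             0.5 + 0.1 * rng.standard_normal(80)]
        )
        subtypes = np.array((["TC"] * 80) + (["NC"] * 80))
        t_t, t_s = neural_clustering_scores(probs, subtypes,
                                            allow_missing=True)
        assert t_t > 4
        assert np.isnan(t_s)

    def test_two_point_groups_match_closed_form(self):
        probs = np.array([0.7, 0.9, 0.4, 0.6])
        subtypes = np.array(["TC", "TC", "NC", "NC"])
        t_t, _ = neural_clustering_scores(probs, subtypes, allow_missing=True)
        # groups {0.7, 0.9} and {0.4, 0.6}: mean diff 0.3, pooled var 0.02
        expected = 0.3 / np.sqrt(0.02 * (0.5 + 0.5))
        assert t_t == pytest.approx(expected, abs=1e-12)

    def test_insufficient_events_rejected(self):
        with pytest.raises(ValueError):
            neural_clustering_scores(
                np.array([0.5, 0.6]), np.array(["TC", "NC"])
            )


class TestCorrelation:
    def test_identity_gives_r_one(self):
        x = np.arange(8, dtype=float)
        r, p = correlate_neural_behavioral(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_matches_closed_form_on_fixed_table(self):
        rng = np.random.default_rng(7)
        x = rng.random(10)
        y = rng.random(10)
        r, _ = correlate_neural_behavioral(x, y)
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (
            x.std() * y.std()
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_neural_behavioral(np.ones(6), np.arange(6.0))

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            correlate_neural_behavioral(np.arange(3.0), np.arange(3.0))


class TestBootstrapDifference:
    def _scores(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        b = rng.random(n)
        return pd.DataFrame(
            {"neural": 2 * b + 0.3 * rng.standard_normal(n), "behavioral": b}
        )

    def test_identical_variants_center_on_zero(self):
        a = self._scores()
        mean_diff, ci, _ = bootstrap_correlation_difference(
            a, a.copy(), n_boot=200, seed=1
        )
        assert mean_diff == 0.0
        assert ci[0] <= 0.0 <= ci[1]

    def test_deterministic_given_seed(self):
        a, b = self._scores(1), self._scores(2)
        r1 = bootstrap_correlation_difference(a, b, n_boot=150, seed=3)
        r2 = bootstrap_correlation_difference(a, b, n_boot=150, seed=3)
        assert np.array_equal(r1[2], r2[2])
        assert r1[1] == r2[1]

    def test_replicates_match_manual_resampling(self):
        from memdyn.synthetic import session_rng

        a, b = self._scores(3), self._scores(4)
        _, _, diffs = bootstrap_correlation_difference(a, b, n_boot=100,
                                                       seed=5)
        rng = session_rng(5, 8)
        from scipy import stats

        for i in range(100):
            idx = rng.integers(len(a), size=len(a))
            ra = stats.pearsonr(
                a.neural.to_numpy()[idx], a.behavioral.to_numpy()[idx]
            )[0]
            rb = stats.pearsonr(
                b.neural.to_numpy()[idx], b.behavioral.to_numpy()[idx]
            )[0]
            assert diffs[i] == pytest.approx(ra - rb, abs=1e-12)

    def test_small_n_boot_rejected(self):
        a = self._scores()
        with pytest.raises(ValueError):
            bootstrap_correlation_difference(a, a, n_boot=50, seed=0)


class TestParticipantInclusion:
    def _session_with_rate(self, rate, session):
        n = 24
        n_recalled = int(round(rate * n))
        rows = [(0, float(k + 1), k, "correct") for k in range(n_recalled)]
        return make_session({0: range(n)}, rows, session=session)

    def test_all_sessions_at_half_included(self):
        sessions = [self._session_with_rate(0.5, s) for s in range(24)]
        assert participant_inclusion(sessions)

    def test_nine_qualifying_sessions_excluded(self):
        sessions = [self._session_with_rate(0.5, s) for s in range(9)]
        sessions += [self._session_with_rate(0.95, s) for s in range(9, 24)]
        assert not participant_inclusion(sessions)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(8)
        rates = rng.uniform(0, 1, size=15)
        sessions = [
            self._session_with_rate(r, s) for s, r in enumerate(rates)
        ]
        achieved = np.array([s.recall_rate() for s in sessions])
        expected = np.sum((achieved >= 0.15) & (achieved <= 0.85)) >= 10
        assert participant_inclusion(sessions) == expected

    def test_no_sessions_rejected(self):
        with pytest.raises(ValueError):
            participant_inclusion([])
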