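"""Event labeling, clustering subtypes, and the re-sampling rule."""

import numpy as np
import pytest

from conftest import make_pool, make_session
from memdyn.events import (
    label_clustering_encoding,
    label_clustering_retrieval,
    label_encoding_events,
    label_retrieval_events,
    resample_events,
)
from memdyn.synthetic import generate_word_pool, simulate_behavior, TaskDesign


def orthogonal_pool(n=30):
    """Pool whose words are mutually orthogonal (all similarities 0)."""
    return make_pool(np.eye(n))


class TestEncodingLabels:
    def test_no_recalls_all_unrecalled(self):
        sess = make_session({0: range(24)}, [])
        enc = label_encoding_events(sess)
        assert len(enc) == 24 and enc.recalled.sum() == 0

    def test_duplicate_recall_counts_once(self):
        sess = make_session(
            {0: range(6)},
            [(0, 2.0, 3, "correct"), (0, 5.0, 3, "correct")],
        )
        enc = label_encoding_events(sess)
        assert len(enc) == 6
        assert enc[enc.word_id == 3].recalled.tolist() == [1]
        assert enc.recalled.sum() == 1

    def test_pli_on_later_list_does_not_mark_own_list(self):
        sess = make_session(
            {0: range(6), 1: range(6, 12)},
            [(1, 2.0, 3, "PLI")],  # word 3 studied on list 0
        )
        enc = label_encoding_events(sess)
        assert enc[(enc["list"] == 0) & (enc.word_id == 3)].recalled.item() == 0

    def test_unpresented_correct_recall_rejected(self):
        sess = make_session({0: range(6)}, [(0, 2.0, 99, "correct")])
        with pytest.raises(ValueError, match="unpresented"):
            label_encoding_events(sess)


class TestRetrievalLabels:
    def test_vocalization_spacing_rule(self):
        sess = make_session(
            {0: range(6)},
            [(0, 2.0, 0, "correct"), (0, 2.8, 1, "correct"),
             (0, 5.0, 2, "correct")],
        )
        ret = label_retrieval_events(sess)
        assert ret.included.tolist() == [1, 0, 1]

    def test_exact_one_second_gap_included(self):
        sess = make_session(
            {0: range(6)},
            [(0, 2.0, 0, "correct"), (0, 3.0, 1, "correct")],
        )
        assert label_retrieval_events(sess).included.tolist() == [1, 1]

    def test_repeated_word_excluded(self):
        sess = make_session(
            {0: range(6)},
            [(0, 2.0, 0, "correct"), (0, 8.0, 0, "correct")],
        )
        assert label_retrieval_events(sess).included.tolist() == [1, 0]

    def test_recall_bins(self):
        sess = make_session(
            {0: range(6)},
            [(0, 0.5, 0, "correct"), (0, 7.5, 1, "correct"),
             (0, 74.0, 2, "correct")],
        )
        assert label_retrieval_events(sess).recall_bin.tolist() == [0, 1, 9]

    def test_negative_onset_rejected(self):
        sess = make_session({0: range(6)}, [(0, -1.0, 0, "correct")])
        with pytest.raises(ValueError):
            label_retrieval_events(sess)

    def test_matches_brute_force_spacing_pass(self):
        rng = np.random.default_rng(0)
        rows = []
        for li in range(30):
            onsets = np.sort(rng.uniform(0, 40, size=8))
            onsets += np.arange(8) * 1e-3  # enforce strict increase
            for k, t in enumerate(onsets):
                rows.append((li, float(t), li * 8 + k, "correct"))
        sess = make_session({li: range(li * 8, li * 8 + 8) for li in range(30)},
                            rows)
        ret = label_retrieval_events(sess)
        for li, grp in ret.groupby("list"):
            onsets = grp.sort_values("output_position").onset_time_s.to_numpy()
            expected = [1] + [
                int(onsets[k] - onsets[k - 1] >= 1.0)
                for k in range(1, len(onsets))
            ]
            assert grp.sort_values("output_position").included.tolist() == (
                expected
            )


class TestClusteringEncoding:
    def test_previous_item_rule(self):
        pool = orthogonal_pool()
        # serial positions recalled in order 5, 6, 2 (words are pos-1 ids)
        sess = make_session(
            {0: range(24)},
            [(0, 2.0, 4, "correct"), (0, 4.0, 5, "correct"),
             (0, 6.0, 1, "correct")],
        )
        enc = label_clustering_encoding(sess, pool)
        by_pos = dict(zip(enc.serial_position, enc.subtype))
        assert by_pos[6] == "TC"  # neighbor 5 is its previous list item
        assert by_pos[5] == "NC" and by_pos[2] == "NC"
        assert by_pos[1] == "NR"

    def test_similarity_exactly_at_threshold_is_semantic(self):
        emb = np.eye(3)
        emb[1] = [0.4, np.sqrt(1 - 0.16), 0.0]  # cos(word0, word1) = 0.4
        pool = make_pool(emb)
        sess = make_session(
            {0: [0, 1, 2]},
            [(0, 2.0, 0, "correct"), (0, 4.0, 1, "correct")],
        )
        enc = label_clustering_encoding(sess, pool)
        by_word = dict(zip(enc.word_id, enc.subtype))
        # word 1 follows its previous list item (word 0) -> temporal, and
        # cos = 0.4 >= threshold -> semantic, hence both
        assert by_word[1] == "BC"
        assert by_word[0] == "SC"  # similarity only (position 1, no i-1)

    def test_matches_exhaustive_checker_on_random_lists(self):
        pool = generate_word_pool(n_words=600, embed_dim=8, seed=5)
        design = TaskDesign(n_sessions=4, lists_per_session=25)
        sessions = simulate_behavior(design, pool, seed=17)
        for sess in sessions[:2]:
            enc = label_clustering_encoding(sess, pool)
            recalls = sess.recalls.sort_values(["list", "output_position"])
            for _, row in enc.iterrows():
                li = row["list"]
                seq = recalls[recalls["list"] == li].reset_index(drop=True)
                if not row.recalled:
                    assert row.subtype == "NR"
                    continue
                hits = seq.index[
                    (seq.word_id == row.word_id)
                    & (seq.response_type == "correct")
                ]
                k = hits[0]
                pres = sess.presentations
                prev_item = pres[
                    (pres["list"] == li)
                    & (pres.serial_position == row.serial_position - 1)
                ]
                prev_word = (
                    None if prev_item.empty else prev_item.word_id.item()
                )
                temporal, semantic = False, False
                for j in (k - 1, k + 1):
                    if not 0 <= j < len(seq):
                        continue
                    nb = seq.iloc[j]
                    if (
                        nb.response_type == "correct"
                        and prev_word is not None
                        and nb.word_id == prev_word
                    ):
                        temporal = True
                    if pool.similarity(
                        int(row.word_id), int(nb.word_id)
                    ) >= 0.4:
                        semantic = True
                expected = (
                    "BC" if temporal and semantic
                    else "TC" if temporal
                    else "SC" if semantic
                    else "NC"
                )
                assert row.subtype == expected


class TestClusteringRetrieval:
    def test_adjacent_forward_transition_is_temporal(self):
        pool = orthogonal_pool()
        sess = make_session(
            {0: range(24)},
            [(0, 2.0, 4, "correct"), (0, 4.0, 5, "correct")],  # pos 5 -> 6
        )
        ret = label_clustering_retrieval(sess, pool)
        assert ret.subtype.tolist() == ["TC", "NC"]  # final recall is NC

    def test_semantic_transition(self):
        emb = np.eye(4)
        emb[3] = [0.7, 0.0, 0.0, np.sqrt(1 - 0.49)]
        pool = make_pool(emb)
        sess = make_session(
            {0: [0, 1, 2, 3]},  # transition pos 1 -> pos 4, sim 0.7
            [(0, 2.0, 0, "correct"), (0, 4.0, 3, "correct")],
        )
        ret = label_clustering_retrieval(sess, pool)
        assert ret.subtype.tolist() == ["SC", "NC"]

    def test_intrusions_keep_response_type_and_block_temporal(self):
        pool = orthogonal_pool()
        sess = make_session(
            {0: range(10), 1: range(10, 20)},
            [(1, 2.0, 10, "correct"), (1, 4.0, 3, "PLI"),
             (1, 6.0, 11, "correct")],
        )
        ret = label_clustering_retrieval(sess, pool)
        assert ret.subtype.tolist() == ["NC", "PLI", "NC"]

    def test_matches_transition_table_oracle(self):
        pool = generate_word_pool(n_words=600, embed_dim=8, seed=6)
        design = TaskDesign(n_sessions=2, lists_per_session=25)
        sessions = simulate_behavior(design, pool, seed=19)
        for sess in sessions:
            ret = label_clustering_retrieval(sess, pool)
            pres = sess.presentations
            for li, grp in ret.groupby("list"):
                grp = grp.sort_values("output_position").reset_index(drop=True)
                pos = dict(
                    zip(
                        pres[pres["list"] == li].word_id,
                        pres[pres["list"] == li].serial_position,
                    )
                )
                for k, row in grp.iterrows():
                    if row.response_type != "correct":
                        assert row.subtype == row.response_type
                        continue
                    if k + 1 >= len(grp):
                        assert row.subtype == "NC"
                        continue
                    nxt = grp.iloc[k + 1]
                    temporal = (
                        nxt.response_type == "correct"
                        and abs(pos[nxt.word_id] - pos[row.word_id]) == 1
                    )
                    semantic = nxt.response_type in ("correct", "PLI") and (
                        pool.similarity(int(row.word_id), int(nxt.word_id))
                        >= 0.4
                    )
                    expected = (
                        "BC" if temporal and semantic
                        else "TC" if temporal
                        else "SC" if semantic
                        else "NC"
                    )
                    assert row.subtype == expected


class TestResampling:
    def test_rounding_rule_on_unbalanced_stratum(self):
        # session ratio 1:1; stratum with 3 pos, 1 neg keeps 1 pos, 1 neg
        success = np.array(
            [1, 1, 1, 0] + [0, 0, 1] + [0, 1], dtype=bool
        )
        strata = np.array([1, 1, 1, 1, 2, 2, 2, 3, 3])
        res = resample_events(success, strata, seed=0)
        row = res.strata.set_index("stratum").loc[1]
        assert (row.n_pos_after, row.n_neg_after) == (1, 1)

    def test_balanced_stratum_unchanged(self):
        success = np.array([1, 0, 1, 0, 1, 0], dtype=bool)
        strata = np.array([1, 1, 1, 1, 2, 2])
        res = resample_events(success, strata, seed=0)
        after = res.strata.set_index("stratum")
        assert after.loc[1, "n_pos_after"] == 2
        assert after.loc[1, "n_neg_after"] == 2
        assert after.loc[2, "n_pos_after"] == 1

    def test_single_class_stratum_dropped(self):
        success = np.array([1, 1, 0, 1], dtype=bool)
        strata = np.array([1, 1, 1, 2])  # stratum 2 has positives only
        res = resample_events(success, strata, seed=0)
        assert not np.isin(np.flatnonzero(strata == 2), res.kept).any()

    def test_never_adds_events_and_deterministic(self):
        rng = np.random.default_rng(3)
        success = rng.random(200) < 0.4
        strata = rng.integers(1, 11, size=200)
        a = resample_events(success, strata, seed=42)
        b = resample_events(success, strata, seed=42)
        assert np.array_equal(a.kept, b.kept)
        assert len(a.kept) <= 200
        assert np.all(np.isin(a.kept, np.arange(200)))
        c = resample_events(success, strata, seed=43)
        # different seed: same per-stratum counts, possibly different members
        assert a.strata.equals(c.strata)

    def test_ratio_within_one_event_of_session_ratio(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(60, 200))
            success = rng.random(n) < rng.uniform(0.2, 0.8)
            strata = rng.integers(1, 13, size=n)
            if success.all() or not success.any():
                continue
            r = success.sum() / (~success).sum()
            res = resample_events(success, strata, seed=int(rng.integers(1e6)))
            for _, row in res.strata.iterrows():
                if row.n_pos_after == 0:
                    continue
                kp, kn = row.n_pos_after, row.n_neg_after
                assert min(abs(kp - r * kn), abs(kn - kp / r)) <= 1.0

    def test_removes_label_position_association(self):
        from scipy.stats import linregress

        pool = generate_word_pool(n_words=1940, seed=7)
        design = TaskDesign(n_sessions=1, lists_per_session=80)
        sess = simulate_behavior(design, pool, seed=23)[0]
        enc = label_encoding_events(sess)
        success = enc.recalled.to_numpy() > 0
        strata = enc.serial_position.to_numpy()
        before = linregress(strata, success.astype(float))
        assert before.pvalue < 0.01  # primacy induces a position trend
        res = resample_events(success, strata, seed=1)
        after = linregress(strata[res.kept], success[res.kept].astype(float))
        assert after.pvalue > 0.01

    def test_single_class_session_rejected(self):
        with pytest.raises(ValueError):
            resample_events(np.ones(10, dtype=bool), np.arange(10), seed=0)

    def test_encoding_retrieval_label_agreement(self, behavior, pool):
        for sess in behavior:
            enc = label_encoding_events(sess)
            ret = label_retrieval_events(sess)
            recalled = {
                (li, w)
                for li, w in zip(enc["list"][enc.recalled == 1],
                                 enc.word_id[enc.recalled == 1])
            }
            for _, row in ret[ret.correct == 1].iterrows():
                assert (row["list"], row.word_id) in recalled
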