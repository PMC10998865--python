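"""Event labeling, exclusion rules, clustering subtypes, and re-sampling.

Encoding events are labeled by subsequent recall success; retrieval events
(the pre-vocalization intervals) by response type, with responses starting
less than 1 s after the previous vocalization excluded to avoid speech
artifacts. Recalled items are further sorted into clustering subtypes:

* BC  - both temporally and semantically clustered,
* TC  - temporally clustered only,
* SC  - semantically clustered only,
* NC  - neither,
* NR  - not recalled (encoding only).

Temporal clustering at encoding follows the literal previous-item rule: the
item studied at serial position ``i`` is temporally clustered if one of the
recall responses adjacent to its own recall names the item from position
``i - 1``. Semantic clustering requires embedding cosine similarity >= 0.4
with an adjacent response. At retrieval, subtypes are defined by the
relation of each correct recall to the *next* recall response.

The re-sampling procedure removes the serial-position (or output-time)
confound from classifier training sets: within every stratum the majority
class is down-sampled uniformly at random until the stratum's
positive:negative ratio matches the session-level ratio to within integer
granularity; strata missing a class are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BehaviorSession, WordPool, session_rng

__all__ = [
    "ResampleResult",
    "label_encoding_events",
    "label_retrieval_events",
    "label_clustering_encoding",
    "label_clustering_retrieval",
    "resample_events",
    "RECALL_BIN_S",
]

#: Width of the recall-period output-time bins (seconds).
RECALL_BIN_S: float = 7.5


def label_encoding_events(behavior: BehaviorSession) -> pd.DataFrame:
    """Label every encoding event by subsequent recall success.

    Returns one row per presentation with columns ``list``,
    ``serial_position``, ``word_id`` and ``recalled`` (1 iff the word
    appears among that list's correct recalls; repeated recalls count
    once). Raises if a correct recall names a word not presented on its
    list.
    """
    pres = behavior.presentations
    correct = behavior.recalls[behavior.recalls.response_type == "correct"]
    recalled_by_list: dict[int, set[int]] = {
        li: set(grp.word_id) for li, grp in correct.groupby("list")
    }
    presented_by_list: dict[int, set[int]] = {
        li: set(grp.word_id) for li, grp in pres.groupby("list")
    }
    for li, words in recalled_by_list.items():
        stray = words - presented_by_list.get(li, set())
        if stray:
            raise ValueError(
                f"correct recalls on list {li} name unpresented words: "
                f"{sorted(stray)}"
            )
    out = pres.copy().reset_index(drop=True)
    out["recalled"] = [
        int(w in recalled_by_list.get(li, set()))
        for li, w in zip(out["list"], out["word_id"])
    ]
    return out


def label_retrieval_events(behavior: BehaviorSession) -> pd.DataFrame:
    """Label retrieval events and apply the vocalization-spacing rule.

    Returns one row per recall response with ``recall_bin`` (floor of
    onset / 7.5 s), ``correct`` (1 for correct recalls) and ``included``.
    A response is excluded when its onset follows the previous response's
    onset by strictly less than 1 s (the first response of a list is always
    included), or when it repeats a word already recalled on the same list.
    """
    rec = behavior.recalls.sort_values(["list", "output_position"]).reset_index(
        drop=True
    )
    if (rec.onset_time_s < 0).any():
        raise ValueError("recall onsets must be nonnegative")
    included = np.ones(len(rec), dtype=int)
    for _, idx in rec.groupby("list").groups.items():
        idx = np.asarray(idx)
        onsets = rec.loc[idx, "onset_time_s"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing within list")
        gaps = np.diff(onsets)
        included[idx[1:][gaps < 1.0]] = 0
        seen: set[int] = set()
        for j in idx:
            w = int(rec.loc[j, "word_id"])
            if rec.loc[j, "response_type"] == "correct":
                if w in seen:
                    included[j] = 0
                seen.add(w)
    out = rec.copy()
    out["included"] = included
    out["recall_bin"] = np.floor(
        out.onset_time_s.to_numpy(float) / RECALL_BIN_S
    ).astype(int)
    out["correct"] = (out.response_type == "correct").astype(int)
    return out


def _list_lookup(behavior: BehaviorSession):
    """Per-list fast lookups: word->position, position->word, recall seq."""
    pos_of: dict[int, dict[int, int]] = {}
    word_at: dict[int, dict[int, int]] = {}
    for li, grp in behavior.presentations.groupby("list"):
        words = grp.word_id.to_numpy()
        poss = grp.serial_position.to_numpy()
        pos_of[int(li)] = dict(zip(words.tolist(), poss.tolist()))
        word_at[int(li)] = dict(zip(poss.tolist(), words.tolist()))
    rec = behavior.recalls.sort_values(["list", "output_position"])
    seqs: dict[int, list[tuple[int, str]]] = {}
    for li, grp in rec.groupby("list"):
        seqs[int(li)] = list(
            zip(grp.word_id.astype(int).tolist(), grp.response_type.tolist())
        )
    return pos_of, word_at, seqs


def label_clustering_encoding(
    behavior: BehaviorSession, pool: WordPool, threshold: float = 0.4
) -> pd.DataFrame:
    """Assign subsequent-clustering subtypes to encoding events.

    For each recalled item (first correct recall of the word), the two
    recall responses adjacent in output order are examined. The temporal
    condition holds if either neighbor names the item studied at serial
    position ``i - 1``; the semantic condition holds if either neighbor's
    embedding cosine similarity with the item is >= ``threshold``.
    Non-recalled items are labeled NR. Items at serial position 1 can never
    satisfy the temporal condition.
    """
    enc = label_encoding_events(behavior)
    _, word_at, seqs = _list_lookup(behavior)
    first_hit: dict[tuple[int, int], int] = {}
    for li, seq in seqs.items():
        for k, (wid, rtype) in enumerate(seq):
            if rtype == "correct" and (li, wid) not in first_hit:
                first_hit[(li, wid)] = k
    subtype = []
    for li, pos, wid, recalled in zip(
        enc["list"].astype(int),
        enc.serial_position.astype(int),
        enc.word_id.astype(int),
        enc.recalled,
    ):
        if not recalled:
            subtype.append("NR")
            continue
        seq = seqs[li]
        k = first_hit[(li, wid)]  # first recall occurrence is scored
        prev_word = word_at[li].get(pos - 1)
        temporal = False
        semantic = False
        for j in (k - 1, k + 1):
            if not 0 <= j < len(seq):
                continue
            nb_word, nb_type = seq[j]
            if prev_word is not None and nb_type == "correct" and (
                nb_word == prev_word
            ):
                temporal = True
            if pool.similarity(wid, nb_word) >= threshold:
                semantic = True
        subtype.append(_combine(temporal, semantic))
    out = enc.copy()
    out["subtype"] = subtype
    return out


def _combine(temporal: bool, semantic: bool) -> str:
    if temporal and semantic:
        return "BC"
    if temporal:
        return "TC"
    if semantic:
        return "SC"
    return "NC"


def label_clustering_retrieval(
    behavior: BehaviorSession,
    pool: WordPool,
    threshold: float = 0.4,
    score_intrusion_similarity: bool = True,
) -> pd.DataFrame:
    """Assign clustering subtypes to retrieval events.

    Correct recalls are labeled by their relation to the immediately next
    recall response: temporally clustered if the next response is a correct
    recall whose serial-position lag has absolute value 1, semantically
    clustered if the next response's similarity is >= ``threshold``
    (extra-list words are never scored for similarity; prior-list words are
    scored when ``score_intrusion_similarity``). The final recall of a list
    has no transition and is labeled NC. Intrusions keep their response
    type (PLI/ELI) as subtype.
    """
    ret = label_retrieval_events(behavior)
    pos_of, _, seqs = _list_lookup(behavior)
    # ret rows are already in (list, output_position) order
    within = ret.groupby("list").cumcount().to_numpy()
    subtype = []
    for li, k, wid, rtype in zip(
        ret["list"].astype(int), within, ret.word_id.astype(int),
        ret.response_type,
    ):
        if rtype != "correct":
            subtype.append(rtype)
            continue
        seq = seqs[li]
        if k + 1 >= len(seq):
            subtype.append("NC")  # no next transition
            continue
        nxt_word, nxt_type = seq[k + 1]
        temporal = False
        semantic = False
        if nxt_type == "correct":
            p0 = pos_of[li].get(wid)
            p1 = pos_of[li].get(nxt_word)
            if p0 is not None and p1 is not None and abs(p1 - p0) == 1:
                temporal = True
        scoreable = nxt_type == "correct" or (
            nxt_type == "PLI" and score_intrusion_similarity
        )
        if scoreable and pool.similarity(wid, nxt_word) >= threshold:
            semantic = True
        subtype.append(_combine(temporal, semantic))
    out = ret.copy()
    out["subtype"] = subtype
    return out


@dataclass
class ResampleResult:
    """Outcome of one event re-sampling draw.

    ``kept`` indexes into the input event array; ``strata`` records
    per-stratum before/after class counts; ``seed`` is the substream key
    the draw used.
    """

    kept: np.ndarray
    strata: pd.DataFrame
    seed: int

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def _target_count(n_major: int, ideal: float) -> int:
    """Down-sample target: nearest integer to the ideal count, >= 1."""
    lo, hi = int(np.floor(ideal)), int(np.ceil(ideal))
    best = lo if abs(lo - ideal) <= abs(hi - ideal) else hi
    return int(np.clip(best, 1, n_major))


def resample_events(
    success: np.ndarray,
    strata: np.ndarray,
    seed: int = 0,
) -> ResampleResult:
    """Down-sample the majority class per stratum to the session ratio.

    ``success`` is a boolean label per event and ``strata`` its serial
    position (encoding) or recall bin (retrieval). With session ratio
    ``r = n_pos / n_neg`` over all events, each stratum containing both
    classes keeps all events of its minority side and a uniformly random
    subset of the other side sized so the stratum ratio matches ``r`` to
    within one event (never below one event per class). Strata where a
    class is absent are dropped entirely. Re-sampling never adds events
    and never changes labels; the same seed reproduces the same draw.
    """
    success = np.asarray(success, dtype=bool)
    strata = np.asarray(strata)
    if success.shape != strata.shape:
        raise ValueError("success and strata must align")
    n_pos, n_neg = int(success.sum()), int((~success).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("session has a single class; ratio undefined")
    r = n_pos / n_neg
    rng = session_rng(seed, 5)
    kept: list[np.ndarray] = []
    rows = []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        pos = idx[success[idx]]
        neg = idx[~success[idx]]
        if len(pos) == 0 or len(neg) == 0:
            rows.append((s, len(pos), len(neg), 0, 0))
            continue
        kp, kn = pos, neg
        if len(pos) / len(neg) > r:
            target = _target_count(len(pos), r * len(neg))
            kp = rng.choice(pos, size=target, replace=False)
        elif len(pos) / len(neg) < r:
            target = _target_count(len(neg), len(pos) / r)
            kn = rng.choice(neg, size=target, replace=False)
        kept.append(np.sort(np.concatenate([kp, kn])))
        rows.append((s, len(pos), len(neg), len(kp), len(kn)))
    strata_df = pd.DataFrame(
        rows,
        columns=["stratum", "n_pos_before", "n_neg_before", "n_pos_after",
                 "n_neg_after"],
    )
    kept_all = (
        np.sort(np.concatenate(kept)) if kept else np.array([], dtype=int)
    )
    return ResampleResult(kept=kept_all, strata=strata_df, seed=seed)
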