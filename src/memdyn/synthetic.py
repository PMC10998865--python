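"""Synthetic free-recall behavior and EEG features with planted effects.

This module generates the study-like inputs every downstream stage consumes:

* a word pool with unit-norm embeddings carrying semantic structure
  (topic clusters, so pairwise cosine similarities fall on both sides of
  the 0.4 clustering threshold);
* multi-session free-recall behavior with primacy/recency recall curves,
  temporally and semantically clustered recall transitions, prior-list and
  extra-list intrusions, and recall density that declines over the 75 s
  recall window;
* spectral features (pre-z-score log-power per event x frequency x channel)
  or band-limited time-domain EEG, built from an additive effect model:
  baseline + serial-position/recall-time drift + memory-success effect +
  clustering gain + Gaussian noise.

The behavioral generator is a light retrieval-rule simulator, not a full
context-maintenance model: it sequentially samples recalls with transition
weights mixing temporal adjacency, embedding similarity and uniform noise.
That is sufficient to produce the behavioral regularities the analyses rely
on, while staying cheap enough to regenerate inside tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .montage import ROI_NAMES, Montage

__all__ = [
    "WordPool",
    "TaskDesign",
    "BehaviorParams",
    "BehaviorSession",
    "EffectSpec",
    "SimulatedFeatures",
    "ParticipantData",
    "generate_word_pool",
    "simulate_behavior",
    "simulate_features",
    "sample_participants",
    "simulate_participant",
    "session_rng",
]


def session_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: one independent generator per (seed, key).

    Uses ``SeedSequence`` spawn keys so any substream can be constructed
    without drawing from the others (reproducible under parallel use).
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Word pool
# ---------------------------------------------------------------------------


@dataclass
class WordPool:
    """Pool of words with unit-norm embeddings.

    ``word_id`` 0..n_words-1 are pool words eligible for presentation.
    Ids ``n_words`` .. ``n_words + n_eli - 1`` are reserved extra-list words
    (never presented) with their own random embeddings, so semantic scores
    remain computable for intrusion-adjacent transitions.
    """

    embeddings: np.ndarray  # (n_words + n_eli, dim), unit rows
    n_words: int
    seed: int

    @property
    def n_eli(self) -> int:
        return self.embeddings.shape[0] - self.n_words

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def embedding(self, word_id: int) -> np.ndarray:
        return self.embeddings[word_id]

    def similarity(self, a: int, b: int) -> float:
        """Cosine similarity between two words (pool or reserved ELI ids)."""
        return float(self.embeddings[a] @ self.embeddings[b])

    def high_similarity_fraction(self, threshold: float = 0.4) -> float:
        """Fraction of distinct pool word pairs with cosine >= threshold."""
        emb = self.embeddings[: self.n_words]
        sims = emb @ emb.T
        iu = np.triu_indices(self.n_words, k=1)
        return float(np.mean(sims[iu] >= threshold))


def generate_word_pool(
    n_words: int = 576,
    embed_dim: int = 50,
    seed: int = 0,
    n_topics: int = 48,
    within_topic_spread: float = 0.13,
    n_eli: int = 64,
) -> WordPool:
    """Generate a word pool whose embeddings carry topic structure.

    Words are scattered around ``n_topics`` random unit centers; words of
    the same topic have high cosine similarity (typically above 0.4) while
    cross-topic pairs sit near zero, so the similarity distribution spans
    both sides of the clustering threshold.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if embed_dim < 2:
        raise ValueError("embed_dim must be >= 2")
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    rng = session_rng(seed, 0)
    centers = rng.standard_normal((n_topics, embed_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    topic = rng.integers(n_topics, size=n_words + n_eli)
    emb = centers[topic] + within_topic_spread * rng.standard_normal(
        (n_words + n_eli, embed_dim)
    )
    # reserved ELI words get fully random embeddings (outside the pool)
    if n_eli > 0:
        emb[n_words:] = rng.standard_normal((n_eli, embed_dim))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    return WordPool(embeddings=emb, n_words=n_words, seed=seed)


# ---------------------------------------------------------------------------
# Task design and behavior
# ---------------------------------------------------------------------------


@dataclass
class TaskDesign:
    """Free-recall task structure (durations in seconds)."""

    n_sessions: int = 24
    lists_per_session: int = 24
    list_length: int = 24
    item_duration_s: float = 1.6
    isi_range_s: tuple[float, float] = (0.8, 1.2)
    distractor_s: float = 24.0
    recall_window_s: float = 75.0

    def __post_init__(self) -> None:
        for name in ("item_duration_s", "distractor_s", "recall_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.isi_range_s[0] <= 0 or self.isi_range_s[1] < self.isi_range_s[0]:
            raise ValueError("invalid isi_range_s")
        if min(self.n_sessions, self.lists_per_session, self.list_length) < 1:
            raise ValueError("counts must be positive")


def default_recall_curve(
    list_length: int = 24,
    base: float = 0.32,
    primacy: float = 0.42,
    primacy_tau: float = 2.5,
    recency: float = 0.14,
    recency_tau: float = 1.5,
) -> np.ndarray:
    """Per-position recall probability: strong primacy, small recency."""
    pos = np.arange(1, list_length + 1, dtype=float)
    p = (
        base
        + primacy * np.exp(-(pos - 1) / primacy_tau)
        + recency * np.exp(-(list_length - pos) / recency_tau)
    )
    return np.clip(p, 0.0, 1.0)


@dataclass
class BehaviorParams:
    """Parameters of the retrieval-rule behavioral simulator.

    Transition weights mix three kernels when choosing the next recall:
    temporal adjacency ``exp(-(|lag| - 1) / temporal_tau)``, semantic
    similarity (cosine clipped to [0, 1]), and a uniform floor. Intrusions
    are injected per output attempt at the configured rates. Inter-response
    intervals grow geometrically, producing the declining recall density.
    """

    recall_prob: np.ndarray | None = None  # per serial position; default curve
    temporal_weight: float = 1.6
    temporal_tau: float = 1.2
    semantic_weight: float = 1.2
    uniform_weight: float = 0.6
    first_recall_primacy_tau: float = 1.5
    first_recall_recency_weight: float = 0.35
    pli_rate: float = 0.04
    eli_rate: float = 0.04
    irt_start_s: float = 1.6
    irt_growth: float = 1.22
    irt_jitter_sd: float = 0.25

    def validate(self, list_length: int) -> np.ndarray:
        if self.recall_prob is None:
            p = default_recall_curve(list_length)
        else:
            p = np.asarray(self.recall_prob, dtype=float)
        if p.shape != (list_length,):
            raise ValueError("recall_prob must have one entry per position")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("recall probabilities must lie in [0, 1]")
        for name in ("temporal_weight", "semantic_weight", "uniform_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("pli_rate", "eli_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        return p


@dataclass
class BehaviorSession:
    """One session of free-recall behavior.

    ``presentations`` columns: list, serial_position (1-based), word_id.
    ``recalls`` columns: list, output_position (1-based), onset_time_s,
    word_id, response_type in {correct, PLI, ELI}.
    """

    participant: str
    session: int
    presentations: pd.DataFrame
    recalls: pd.DataFrame

    def recall_rate(self) -> float:
        """Correct recalls of distinct presented words / presented items."""
        n_items = len(self.presentations)
        correct = self.recalls[self.recalls.response_type == "correct"]
        n = correct.drop_duplicates(["list", "word_id"]).shape[0]
        return n / n_items


def _first_recall_weights(positions: np.ndarray, params: BehaviorParams,
                          list_length: int) -> np.ndarray:
    w = np.exp(-(positions - 1) / params.first_recall_primacy_tau)
    w = w + params.first_recall_recency_weight * np.exp(
        -(list_length - positions) / 1.5
    )
    return w


def _transition_weights(
    prev_pos: float | None,
    prev_emb: np.ndarray | None,
    cand_pos: np.ndarray,
    cand_emb: np.ndarray,
    params: BehaviorParams,
) -> np.ndarray:
    n = len(cand_pos)
    if np.isinf(params.temporal_weight) and prev_pos is not None:
        # limit case: deterministically take the nearest serial position,
        # breaking ties forward (+1 before -1)
        lag = cand_pos - prev_pos
        order = np.lexsort((lag < 0, np.abs(lag)))
        w = np.zeros(n)
        w[order[0]] = 1.0
        return w
    w = np.full(n, params.uniform_weight, dtype=float)
    if prev_pos is not None:
        lag = np.abs(cand_pos - prev_pos)
        w += params.temporal_weight * np.exp(-(lag - 1) / params.temporal_tau)
    if prev_emb is not None and params.semantic_weight > 0:
        sims = cand_emb @ prev_emb
        w += params.semantic_weight * np.clip(sims, 0.0, 1.0)
    return w


def simulate_behavior(
    design: TaskDesign,
    pool: WordPool,
    params: BehaviorParams | None = None,
    seed: int = 0,
    participant: str = "P000",
) -> list[BehaviorSession]:
    """Simulate all sessions of one participant's free-recall behavior.

    Recall of each studied item is Bernoulli with a per-position probability
    (primacy-decaying plus a small recency bump). Recall *order* is built
    sequentially: the first recall is biased toward primacy/recency
    positions; each later transition is sampled proportionally to a mixture
    of temporal-adjacency and semantic-similarity kernels plus a uniform
    floor. Intrusions are interleaved at the configured per-attempt rates.
    Onset times accumulate growing inter-response intervals and are
    truncated at the recall window.
    """
    params = params or BehaviorParams()
    p_recall = params.validate(design.list_length)
    total = design.lists_per_session * design.list_length
    if total > pool.n_words:
        raise ValueError("pool too small for one session of unique words")

    sessions: list[BehaviorSession] = []
    for s in range(design.n_sessions):
        rng = session_rng(seed, 1, s)
        words = rng.choice(pool.n_words, size=total, replace=False)
        pres_rows = []
        rec_rows = []
        prior_words: list[int] = []
        for li in range(design.lists_per_session):
            lw = words[li * design.list_length : (li + 1) * design.list_length]
            for j, wid in enumerate(lw):
                pres_rows.append((li, j + 1, int(wid)))
            recalled_mask = rng.random(design.list_length) < p_recall
            avail_pos = list(np.flatnonzero(recalled_mask) + 1)
            t = params.irt_start_s * float(
                np.exp(rng.normal(0.0, params.irt_jitter_sd))
            )
            out = 0
            prev_pos: float | None = None
            prev_emb: np.ndarray | None = None
            recalled_words: set[int] = set()
            attempt = 0
            while t < design.recall_window_s:
                attempt += 1
                u = rng.random()
                made = False
                if u < params.pli_rate and prior_words:
                    cand = [w for w in prior_words if w not in recalled_words]
                    if cand:
                        wid = int(cand[rng.integers(len(cand))])
                        out += 1
                        rec_rows.append((li, out, t, wid, "PLI"))
                        recalled_words.add(wid)
                        prev_pos, prev_emb = None, pool.embedding(wid)
                        made = True
                elif u < params.pli_rate + params.eli_rate and pool.n_eli > 0:
                    wid = int(pool.n_words + rng.integers(pool.n_eli))
                    out += 1
                    rec_rows.append((li, out, t, wid, "ELI"))
                    prev_pos, prev_emb = None, pool.embedding(wid)
                    made = True
                elif avail_pos:
                    cand_pos = np.array(avail_pos, dtype=float)
                    cand_ids = np.array(
                        [lw[int(p) - 1] for p in avail_pos], dtype=int
                    )
                    cand_emb = pool.embeddings[cand_ids]
                    if prev_pos is None and prev_emb is None:
                        w = _first_recall_weights(
                            cand_pos, params, design.list_length
                        )
                    else:
                        w = _transition_weights(
                            prev_pos, prev_emb, cand_pos, cand_emb, params
                        )
                    if not np.any(w > 0):
                        w = np.ones_like(w)
                    k = rng.choice(len(avail_pos), p=w / w.sum())
                    posk = avail_pos.pop(int(k))
                    wid = int(lw[posk - 1])
                    out += 1
                    rec_rows.append((li, out, t, wid, "correct"))
                    recalled_words.add(wid)
                    prev_pos, prev_emb = float(posk), pool.embedding(wid)
                    made = True
                if not made and not avail_pos:
                    break
                irt = (
                    params.irt_start_s
                    * params.irt_growth**attempt
                    * float(np.exp(rng.normal(0.0, params.irt_jitter_sd)))
                )
                t = t + irt
            prior_words.extend(int(w) for w in lw)
        presentations = pd.DataFrame(
            pres_rows, columns=["list", "serial_position", "word_id"]
        )
        recalls = pd.DataFrame(
            rec_rows,
            columns=[
                "list",
                "output_position",
                "onset_time_s",
                "word_id",
                "response_type",
            ],
        )
        sessions.append(
            BehaviorSession(
                participant=participant,
                session=s,
                presentations=presentations,
                recalls=recalls,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Effect model and feature simulation
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """Additive log-power effect model over (frequency x ROI) cells.

    Per event and channel, pre-z-score log-power is::

        baseline[f, roi] + drift[f, roi] * x + effect[f, roi] * success
        + clustering_gain[f, roi] * clustered + N(0, noise_sd^2)

    where ``x`` is the serial position (encoding) or recall onset time
    (retrieval), linearly mapped to [-1, 1], ``success`` indicates
    subsequent recall (encoding) or a correct recall (retrieval), and
    ``clustered`` marks BC/TC events. ``drift`` is the serial-position /
    output-time confound; it is deliberately independent of ``success``.
    """

    freqs: np.ndarray
    baseline: np.ndarray
    drift: np.ndarray
    encoding_effect: np.ndarray
    retrieval_effect: np.ndarray
    clustering_gain: np.ndarray
    noise_sd: float = 1.0
    carriers: tuple[float, ...] = (10.0, 68.0)  # time-domain synthesis bands

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        shape = (len(self.freqs), len(ROI_NAMES))
        for name in (
            "baseline",
            "drift",
            "encoding_effect",
            "retrieval_effect",
            "clustering_gain",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} must have shape (n_freqs, 8), got {arr.shape}"
                )
            setattr(self, name, arr)
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    # -- constructors -------------------------------------------------------

    @classmethod
    def null(cls, freqs: np.ndarray, noise_sd: float = 1.0) -> "EffectSpec":
        """No planted structure at all: pure noise features."""
        z = np.zeros((len(freqs), len(ROI_NAMES)))
        return cls(
            freqs=freqs,
            baseline=z.copy(),
            drift=z.copy(),
            encoding_effect=z.copy(),
            retrieval_effect=z.copy(),
            clustering_gain=z.copy(),
            noise_sd=noise_sd,
        )

    @classmethod
    def planted(
        cls,
        freqs: np.ndarray,
        freq_hz: float,
        roi: str,
        coef: float,
        which: str = "encoding_effect",
        noise_sd: float = 1.0,
    ) -> "EffectSpec":
        """Single planted cell: ``coef`` at (freq_hz, roi) in one field."""
        spec = cls.null(freqs, noise_sd=noise_sd)
        fi = int(np.argmin(np.abs(spec.freqs - freq_hz)))
        ri = ROI_NAMES.index(roi)
        getattr(spec, which)[fi, ri] = coef
        return spec

    @classmethod
    def drift_only(
        cls, freqs: np.ndarray, scale: float = 0.8, noise_sd: float = 1.0
    ) -> "EffectSpec":
        """Serial-position drift in every cell, no item-level memory effect.

        The drift alternates sign across frequencies so the planted
        structure is broadband rather than a single direction.
        """
        spec = cls.null(freqs, noise_sd=noise_sd)
        signs = np.where(np.arange(len(freqs)) % 2 == 0, 1.0, -1.0)
        spec.drift[:] = scale * signs[:, None]
        return spec

    @classmethod
    def realistic(cls, freqs: np.ndarray, amplitude: float = 0.3,
                  noise_sd: float = 1.0) -> "EffectSpec":
        """Spectral signature emulating the canonical memory contrasts.

        Encoding success: low-frequency (alpha/beta) decrease with a
        high-frequency increase; retrieval success: high-frequency
        increase with a milder low-frequency decrease; plus a weak
        position-linked drift (high-frequency power declining and theta
        rising over the list).
        """
        spec = cls.null(freqs, noise_sd=noise_sd)
        f = spec.freqs
        lfa = (f >= 8) & (f <= 30)
        hfa = f >= 64
        theta = f < 8
        spec.encoding_effect[lfa] = -amplitude
        spec.encoding_effect[hfa] = amplitude
        spec.retrieval_effect[hfa] = 1.2 * amplitude
        spec.retrieval_effect[lfa] = -0.5 * amplitude
        spec.clustering_gain[lfa] = -0.4 * amplitude
        spec.drift[hfa] = -0.4 * amplitude
        spec.drift[theta] = 0.4 * amplitude
        return spec

    def scaled(self, amplitude: float) -> "EffectSpec":
        """Copy with memory effects and clustering gain scaled (drift kept)."""
        return replace(
            self,
            encoding_effect=self.encoding_effect * amplitude,
            retrieval_effect=self.retrieval_effect * amplitude,
            clustering_gain=self.clustering_gain * amplitude,
        )


@dataclass
class SimulatedFeatures:
    """Pre-z-score log-power features for one session's events.

    ``encoding_power`` / ``retrieval_power``: (n_events, n_freqs,
    n_channels). Event metadata rows align with the power arrays.
    """

    session: int
    participant: str
    freqs: np.ndarray
    montage: Montage
    encoding_power: np.ndarray
    encoding_events: pd.DataFrame
    retrieval_power: np.ndarray
    retrieval_events: pd.DataFrame


def _roi_index(montage: Montage) -> np.ndarray:
    return np.array([ROI_NAMES.index(r) for r in montage.roi])


def _event_logpower(
    spec: EffectSpec,
    montage: Montage,
    x: np.ndarray,
    success: np.ndarray,
    clustered: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive model evaluated for a batch of events: (n, F, C)."""
    ridx = _roi_index(montage)
    base = spec.baseline[:, ridx]  # (F, C)
    drift = spec.drift[:, ridx]
    gain = spec.clustering_gain[:, ridx]
    n = len(x)
    out = (
        base[None]
        + drift[None] * x[:, None, None]
        + gain[None] * clustered[:, None, None]
    )
    return out + rng.normal(
        0.0, spec.noise_sd, size=(n, base.shape[0], base.shape[1])
    )


def simulate_features(
    behavior: BehaviorSession,
    effect_spec: EffectSpec,
    montage: Montage,
    pool: WordPool,
    design: TaskDesign | None = None,
    mode: str = "feature_space",
    seed: int = 0,
):
    """Generate spectral features (or raw EEG) for one behavioral session.

    ``feature_space`` mode returns :class:`SimulatedFeatures` with
    pre-z-score log-power drawn from the additive effect model.
    ``time_domain`` mode returns a :class:`~memdyn.preprocess.RawEEG`
    whose band-limited oscillation amplitudes follow the same model
    (power multiplicative in ``exp(model)``) on top of 1/f noise.
    """
    if mode not in ("feature_space", "time_domain"):
        raise ValueError(f"unknown mode: {mode}")
    design = design or TaskDesign()
    from .events import label_clustering_encoding

    enc = label_clustering_encoding(behavior, pool)
    half = (design.list_length - 1) / 2 or 1.0
    x_enc = (enc.serial_position.to_numpy(float) - 1 - half) / half
    succ_enc = enc.recalled.to_numpy(float)
    clust_enc = enc.subtype.isin(["BC", "TC"]).to_numpy(float)

    rec = behavior.recalls.sort_values(["list", "output_position"]).reset_index(
        drop=True
    )
    x_ret = (
        rec.onset_time_s.to_numpy(float) - design.recall_window_s / 2
    ) / (design.recall_window_s / 2)
    succ_ret = (rec.response_type == "correct").to_numpy(float)
    clust_ret = np.zeros(len(rec))

    if mode == "feature_space":
        rng = session_rng(seed, 2, behavior.session)
        enc_power = _event_logpower(
            effect_spec, montage, x_enc, succ_enc, clust_enc, rng
        )
        ridx = _roi_index(montage)
        eff = effect_spec.encoding_effect[:, ridx]
        enc_power += eff[None] * succ_enc[:, None, None]
        ret_power = _event_logpower(
            effect_spec, montage, x_ret, succ_ret, clust_ret, rng
        )
        ret_power += (
            effect_spec.retrieval_effect[:, ridx][None]
            * succ_ret[:, None, None]
        )
        enc_meta = enc.copy()
        enc_meta["phase"] = "encoding"
        ret_meta = rec.copy()
        ret_meta["phase"] = "retrieval"
        return SimulatedFeatures(
            session=behavior.session,
            participant=behavior.participant,
            freqs=effect_spec.freqs.copy(),
            montage=montage,
            encoding_power=enc_power,
            encoding_events=enc_meta,
            retrieval_power=ret_power,
            retrieval_events=ret_meta,
        )
    return _simulate_time_domain(
        behavior, effect_spec, montage, design, enc, x_enc, succ_enc,
        clust_enc, rec, x_ret, succ_ret, seed,
    )


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, sfreq: float
) -> np.ndarray:
    """Pink-ish background noise, unit-ish scale."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, 1 / sfreq)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = 1.0 / np.sqrt(f[nz])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _simulate_time_domain(
    behavior, spec, montage, design, enc, x_enc, succ_enc, clust_enc,
    rec, x_ret, succ_ret, seed, sfreq: float = 256.0,
):
    from .preprocess import RawEEG

    rng = session_rng(seed, 3, behavior.session)
    ridx = _roi_index(montage)
    isi_mean = float(np.mean(design.isi_range_s))
    item_slot = design.item_duration_s + isi_mean
    n_lists = int(behavior.presentations.list.max()) + 1
    list_dur = (
        design.list_length * item_slot
        + design.distractor_s
        + design.recall_window_s
        + 2.0
    )
    markers = []
    total_s = n_lists * list_dur + 4.0
    n_samples = int(total_s * sfreq)
    data = 2.0 * _one_over_f_noise(rng, montage.n_channels, n_samples, sfreq)

    carriers = [float(c) for c in spec.carriers]
    cidx = [int(np.argmin(np.abs(spec.freqs - c))) for c in carriers]

    def add_burst(t0: float, dur: float, logp_fc: np.ndarray) -> None:
        s0 = int(t0 * sfreq)
        m = int(dur * sfreq)
        if s0 < 0 or s0 + m > n_samples:
            return
        t = np.arange(m) / sfreq
        for c_hz, fi in zip(carriers, cidx):
            amp = np.exp(0.5 * logp_fc[fi])  # power ~ exp(model)
            phase = rng.uniform(0, 2 * np.pi, size=montage.n_channels)
            data[:, s0 : s0 + m] += amp[:, None] * np.sin(
                2 * np.pi * c_hz * t[None, :] + phase[:, None]
            )

    enc_rows = enc.reset_index(drop=True)
    for li in range(n_lists):
        t_list = 2.0 + li * list_dur
        mask = enc_rows.list.to_numpy() == li
        for k, (_, row) in enumerate(enc_rows[mask].iterrows()):
            onset = t_list + (row.serial_position - 1) * item_slot
            i = int(np.flatnonzero(mask)[k])
            logp = (
                spec.baseline[:, ridx]
                + spec.drift[:, ridx] * x_enc[i]
                + spec.encoding_effect[:, ridx] * succ_enc[i]
                + spec.clustering_gain[:, ridx] * clust_enc[i]
            )
            add_burst(onset, design.item_duration_s, logp)
            markers.append(
                (int(onset * sfreq), "encoding", li,
                 int(row.serial_position), int(row.word_id))
            )
        t_recall = t_list + design.list_length * item_slot + design.distractor_s
        rmask = rec.list.to_numpy() == li
        for k, (_, row) in enumerate(rec[rmask].iterrows()):
            voc = t_recall + row.onset_time_s
            i = int(np.flatnonzero(rmask)[k])
            logp = (
                spec.baseline[:, ridx]
                + spec.drift[:, ridx] * x_ret[i]
                + spec.retrieval_effect[:, ridx] * succ_ret[i]
            )
            add_burst(voc - 0.5, 0.5, logp)
            markers.append(
                (int(voc * sfreq), "vocalization", li,
                 int(row.output_position), int(row.word_id))
            )
    events = pd.DataFrame(
        markers, columns=["sample", "kind", "list", "position", "word_id"]
    )
    b1 = int(n_lists / 3) * list_dur + 2.0
    b2 = int(2 * n_lists / 3) * list_dur + 2.0
    boundaries = (int(b1 * sfreq), int(b2 * sfreq))
    if boundaries[0] <= 0 or boundaries[1] >= n_samples:
        boundaries = (n_samples // 3, 2 * n_samples // 3)
    return RawEEG(
        channels=list(montage.names),
        samples=data,
        sfreq=sfreq,
        partition_boundaries=boundaries,
        events=events,
    )


# ---------------------------------------------------------------------------
# Participant-level generation
# ---------------------------------------------------------------------------


@dataclass
class ParticipantData:
    """All synthetic data for one participant."""

    participant: str
    clustering_propensity: float
    effect_amplitude: float
    behavior: list[BehaviorSession]
    features: list[SimulatedFeatures]


def sample_participants(
    n_participants: int,
    coupling: float = 0.7,
    propensity_sd: float = 0.8,
    amplitude_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-participant clustering propensity and effect amplitude.

    Latent bivariate standard normal (u, v) with correlation ``coupling``;
    propensity = exp(propensity_sd * u) multiplies the behavioral
    temporal/semantic transition weights, amplitude = exp(amplitude_sd * v)
    multiplies the planted memory effects and clustering gain. A positive
    coupling makes strong behavioral clusterers also carry larger neural
    effects, the structure the neural-behavioral correlation analysis is
    designed to recover.
    """
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must lie in [-1, 1]")
    rng = session_rng(seed, 4)
    u = rng.standard_normal(n_participants)
    v = coupling * u + np.sqrt(1 - coupling**2) * rng.standard_normal(
        n_participants
    )
    return pd.DataFrame(
        {
            "participant": [f"P{j:03d}" for j in range(n_participants)],
            "clustering_propensity": np.exp(propensity_sd * u),
            "effect_amplitude": np.exp(amplitude_sd * v),
        }
    )


def simulate_participant(
    participant: str,
    clustering_propensity: float,
    effect_amplitude: float,
    design: TaskDesign,
    pool: WordPool,
    base_params: BehaviorParams,
    base_effects: EffectSpec,
    montage: Montage,
    seed: int,
) -> ParticipantData:
    """Generate behavior plus feature-space EEG for one participant."""
    params = replace(
        base_params,
        temporal_weight=base_params.temporal_weight * clustering_propensity,
        semantic_weight=base_params.semantic_weight * clustering_propensity,
    )
    effects = base_effects.scaled(effect_amplitude)
    behavior = simulate_behavior(
        design, pool, params, seed=seed, participant=participant
    )
    features = [
        simulate_features(
            b, effects, montage, pool, design=design,
            mode="feature_space", seed=seed,
        )
        for b in behavior
    ]
    return ParticipantData(
        participant=participant,
        clustering_propensity=clustering_propensity,
        effect_amplitude=effect_amplitude,
        behavior=behavior,
        features=features,
    )
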