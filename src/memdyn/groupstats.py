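"""Group-level statistics: univariate contrasts, classifier dynamics,
clustering scores, and neural-behavioral correlations.

Univariate spectral contrasts compare successful and unsuccessful memory
events per participant at each frequency x ROI cell (equal-variance
independent t); group effects are one-sample t-tests over the participant
t-statistics with Benjamini-Hochberg FDR across all 29 x 8 cells jointly.
Classifier-output dynamics are summarized per participant as mean
out-of-fold probability by event subtype x item-position group and modeled
with a linear mixed model (participant random intercepts). Behavioral
temporal/semantic clustering scores are percentile-rank factors; neural
scores are t-statistics contrasting classifier output of clustered versus
non-clustered items.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import resample_events
from .montage import ROI_NAMES, Montage
from .synthetic import BehaviorSession, WordPool, session_rng

__all__ = [
    "ActivationMap",
    "DynamicsModelResult",
    "univariate_contrast",
    "group_test",
    "group_auc_test",
    "dynamics_table",
    "dynamics_mixed_model",
    "behavioral_clustering_scores",
    "neural_clustering_scores",
    "correlate_neural_behavioral",
    "bootstrap_correlation_difference",
    "participant_inclusion",
    "ENCODING_POSITION_GROUPS",
    "RETRIEVAL_BIN_GROUPS",
]


def _roi_pool(values: np.ndarray, montage: Montage) -> np.ndarray:
    """Average (events, freqs, channels) over channels within each ROI."""
    out = np.empty((values.shape[0], values.shape[1], len(ROI_NAMES)))
    for ri, name in enumerate(ROI_NAMES):
        cols = np.flatnonzero(montage.roi == name)
        if cols.size == 0:
            raise ValueError(f"montage has no channels in ROI {name}")
        out[:, :, ri] = values[:, :, cols].mean(axis=2)
    return out


def univariate_contrast(
    tensors: list,
    montage: Montage,
    success_col: str,
    strata_col: str,
    resample: bool = False,
    seed: int = 0,
    equal_var: bool = True,
) -> np.ndarray:
    """Per-participant spectral contrast map (n_freqs x 8 ROIs).

    Features are pooled (mean) over channels within each ROI, events pooled
    across the participant's sessions, and an independent two-sample t-test
    compares successful vs unsuccessful events per cell (positive t means
    successful > unsuccessful). With ``resample`` on, events are first
    re-sampled per session to remove the position confound.
    """
    xs, ys = [], []
    for k, tensor in enumerate(tensors):
        pooled = _roi_pool(tensor.values, montage)
        success = tensor.events[success_col].to_numpy() > 0
        if resample:
            strata = tensor.events[strata_col].to_numpy()
            sub = int(
                np.random.SeedSequence(seed, spawn_key=(7, k)).generate_state(1)[0]
                % (2**31)
            )
            res = resample_events(success, strata, seed=sub)
            pooled, success = pooled[res.kept], success[res.kept]
        xs.append(pooled)
        ys.append(success)
    values = np.concatenate(xs)
    success = np.concatenate(ys)
    if success.all() or not success.any():
        raise ValueError("a class is empty; contrast undefined")
    t, _ = stats.ttest_ind(
        values[success], values[~success], axis=0, equal_var=equal_var
    )
    return np.asarray(t)


@dataclass
class ActivationMap:
    """Frequency x ROI map with group statistics.

    ``per_participant`` is (n_participants, n_freqs, 8); ``group_t`` and
    ``p`` are cell-wise one-sample t-tests against zero; ``significant``
    is the Benjamini-Hochberg mask at rate ``q`` computed jointly across
    all cells.
    """

    freqs: np.ndarray
    per_participant: np.ndarray
    group_t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    q: float


def group_test(
    per_participant_maps: np.ndarray,
    freqs: np.ndarray | None = None,
    q: float = 0.05,
) -> ActivationMap:
    """Group-level test of per-participant (freq x ROI) statistics.

    One-sample t against 0 in every cell, then Benjamini-Hochberg FDR at
    rate ``q`` across all cells of the map jointly.
    """
    maps = np.asarray(per_participant_maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("expected (participants, freqs, rois)")
    if maps.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    t, p = stats.ttest_1samp(maps, 0.0, axis=0)
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    if freqs is None:
        freqs = np.arange(maps.shape[1], dtype=float)
    return ActivationMap(
        freqs=np.asarray(freqs, dtype=float),
        per_participant=maps,
        group_t=t,
        p=p,
        significant=reject.reshape(p.shape),
        q=q,
    )


def group_auc_test(
    observed_aucs: np.ndarray, mean_null_aucs: np.ndarray
) -> tuple[float, float]:
    """One-sided paired t: observed AUCs above the mean permutation nulls."""
    obs = np.asarray(observed_aucs, dtype=float)
    null = np.asarray(mean_null_aucs, dtype=float)
    if obs.shape != null.shape:
        raise ValueError("mismatched lengths")
    diff = obs - null
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, 0.5  # identical distributions: no evidence either way
        raise ValueError("zero-variance differences; paired t degenerate")
    t, p = stats.ttest_rel(obs, null, alternative="greater")
    return float(t), float(p)


#: Encoding item-position groups over serial positions 1..24.
ENCODING_POSITION_GROUPS: dict[str, tuple[int, int]] = {
    "early": (1, 4), "middle": (5, 20), "late": (21, 24),
}
#: Retrieval output-time groups over the ten 7.5 s recall bins (0-based).
RETRIEVAL_BIN_GROUPS: dict[str, tuple[int, int]] = {
    "early": (0, 2), "middle": (3, 6), "late": (7, 9),
}


def _position_group(values: np.ndarray, groups: dict[str, tuple[int, int]]
                    ) -> np.ndarray:
    out = np.full(len(values), "", dtype=object)
    for name, (lo, hi) in groups.items():
        out[(values >= lo) & (values <= hi)] = name
    return out


def dynamics_table(
    per_participant: dict[str, tuple[np.ndarray, pd.DataFrame]],
    phase: str,
) -> pd.DataFrame:
    """Mean classifier output per participant x subtype x position group.

    ``per_participant`` maps participant id to (out-of-fold probabilities,
    aligned event metadata with ``subtype`` and ``serial_position`` /
    ``recall_bin``); callers pass only participants whose classifier passed
    the permutation criterion. Empty cells are simply absent from the
    table (missing, not zero).
    """
    if phase == "encoding":
        groups, col = ENCODING_POSITION_GROUPS, "serial_position"
        subtypes = ["BC", "TC", "SC", "NC", "NR"]
    elif phase == "retrieval":
        groups, col = RETRIEVAL_BIN_GROUPS, "recall_bin"
        subtypes = ["BC", "TC", "SC", "NC", "PLI", "ELI"]
    else:
        raise ValueError("phase must be 'encoding' or 'retrieval'")
    rows = []
    for pid, (probs, events) in per_participant.items():
        probs = np.asarray(probs, dtype=float)
        if len(probs) != len(events):
            raise ValueError("probabilities and events must align")
        pg = _position_group(events[col].to_numpy(), groups)
        st = events["subtype"].to_numpy()
        for sub, grp in itertools.product(subtypes, groups):
            m = (st == sub) & (pg == grp)
            if m.any():
                rows.append((pid, sub, grp, float(probs[m].mean())))
    return pd.DataFrame(
        rows, columns=["participant", "subtype", "position_group", "value"]
    )


@dataclass
class DynamicsModelResult:
    """Mixed-model summary: term F tests and pairwise EMM contrasts."""

    anova: pd.DataFrame
    emm: pd.DataFrame
    emm_contrasts: pd.DataFrame
    result: object


def dynamics_mixed_model(table: pd.DataFrame) -> DynamicsModelResult:
    """Linear mixed model of classifier output dynamics.

    Fits ``value ~ subtype * position_group`` with participant random
    intercepts (sum-to-zero coding), reports Type III Wald F tests per
    fixed-effect term, and Bonferroni-corrected pairwise contrasts of the
    estimated marginal means (equal cell weights). Denominator degrees of
    freedom use a residual approximation (a documented stand-in for the
    Satterthwaite method; a warning is emitted).
    """
    import statsmodels.formula.api as smf

    if table["participant"].nunique() < 2:
        raise ValueError("random intercept unidentifiable with 1 participant")
    data = table.copy()
    formula = "value ~ C(subtype, Sum) * C(position_group, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["participant"])
        res = model.fit(reml=True)
    warnings.warn(
        "denominator df use a residual approximation, not Satterthwaite",
        stacklevel=2,
    )
    design_info = res.model.data.design_info
    fe = res.fe_params.to_numpy()
    cov = res.cov_params().to_numpy()[: len(fe), : len(fe)]
    n_obs = len(data)
    df_den = n_obs - len(fe) - data["participant"].nunique()
    rows = []
    for term in design_info.term_names:
        if term == "Intercept":
            continue
        sl = design_info.term_name_slices[term]
        idx = np.arange(len(fe))[sl]
        b = fe[idx]
        V = cov[np.ix_(idx, idx)]
        q = len(idx)
        if np.allclose(b, 0.0, atol=1e-10):
            F, p = 0.0, 1.0  # term absent (e.g. perfectly constant data)
        else:
            try:
                chi2 = float(b @ np.linalg.solve(V, b))
            except np.linalg.LinAlgError:
                chi2 = float(b @ np.linalg.pinv(V) @ b)
            F = chi2 / q
            p = float(stats.f.sf(F, q, df_den))
        rows.append((term, F, q, df_den, p))
    anova = pd.DataFrame(
        rows, columns=["term", "F", "df_num", "df_den", "p"]
    )

    # estimated marginal means on a balanced subtype x position grid
    from patsy import build_design_matrices

    subtypes = sorted(data["subtype"].unique())
    groups = sorted(data["position_group"].unique())
    grid = pd.DataFrame(
        [(s, g) for s in subtypes for g in groups],
        columns=["subtype", "position_group"],
    )
    (D,) = build_design_matrices([design_info], grid)
    D = np.asarray(D)
    emm = grid.copy()
    emm["emm"] = D @ fe
    emm["se"] = np.sqrt(np.einsum("ij,jk,ik->i", D, cov, D))

    crows = []
    pairs = list(itertools.combinations(subtypes, 2))
    for a, b_ in pairs:
        ca = D[(grid.subtype == a).to_numpy()].mean(axis=0)
        cb = D[(grid.subtype == b_).to_numpy()].mean(axis=0)
        c = ca - cb
        est = float(c @ fe)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se
        p = 2 * stats.t.sf(abs(tval), df_den)
        crows.append((a, b_, est, se, tval, min(1.0, p * len(pairs))))
    contrasts = pd.DataFrame(
        crows, columns=["a", "b", "estimate", "se", "t", "p_bonf"]
    )
    return DynamicsModelResult(
        anova=anova, emm=emm, emm_contrasts=contrasts, result=res
    )


def _percentile_rank(actual: float, possible: np.ndarray,
                     smaller_better: bool) -> float | None:
    """Mean-rank percentile of the actual step among possible steps."""
    possible = np.asarray(possible, dtype=float)
    if len(possible) < 2:
        return None  # only one available step: rank undefined
    if smaller_better:
        worse = np.sum(possible > actual)
        tied = np.sum(possible == actual) - 1
    else:
        worse = np.sum(possible < actual)
        tied = np.sum(possible == actual) - 1
    return float((worse + 0.5 * tied) / (len(possible) - 1))


def behavioral_clustering_scores(
    sessions: list[BehaviorSession], pool: WordPool
) -> tuple[float, float]:
    """Participant temporal and semantic clustering scores (chance 0.5).

    Every transition between successive correct recalls (intrusions and
    repeats break the chain) is scored by the percentile rank of the
    actual step among all available steps to not-yet-recalled list items:
    temporal ranks smaller absolute serial-position lags higher, semantic
    ranks larger embedding similarities higher. The participant score is
    the mean rank over transitions; perfect forward serial recall scores
    1.0. Raises when no transition is scorable.
    """
    t_ranks: list[float] = []
    s_ranks: list[float] = []
    for sess in sessions:
        pres = sess.presentations
        for li, seq in sess.recalls.sort_values(
            ["list", "output_position"]
        ).groupby("list"):
            lw = pres[pres["list"] == li]
            pos_of = dict(zip(lw.word_id, lw.serial_position))
            seq = seq.reset_index(drop=True)
            recalled: set[int] = set()
            prev: int | None = None  # word id of previous correct recall
            for _, row in seq.iterrows():
                wid = int(row.word_id)
                if row.response_type != "correct" or wid in recalled:
                    prev = None
                    if row.response_type == "correct":
                        recalled.add(wid)
                    continue
                if prev is not None:
                    avail = [w for w in pos_of if w not in recalled]
                    if wid in avail:
                        p_prev = pos_of[prev]
                        lags = np.abs(
                            np.array([pos_of[w] for w in avail]) - p_prev
                        )
                        actual_lag = abs(pos_of[wid] - p_prev)
                        r = _percentile_rank(actual_lag, lags, True)
                        if r is not None:
                            t_ranks.append(r)
                        sims = np.array(
                            [pool.similarity(prev, w) for w in avail]
                        )
                        actual_sim = pool.similarity(prev, wid)
                        r = _percentile_rank(actual_sim, sims, False)
                        if r is not None:
                            s_ranks.append(r)
                recalled.add(wid)
                prev = wid
    if not t_ranks or not s_ranks:
        raise ValueError("no scorable transitions for this participant")
    return float(np.mean(t_ranks)), float(np.mean(s_ranks))


def neural_clustering_scores(
    probabilities: np.ndarray,
    subtypes: np.ndarray,
    allow_missing: bool = False,
) -> tuple[float, float]:
    """Neural clustering indices: t(TC vs NC) and t(SC vs NC).

    Independent two-sample t-statistics on classifier output; positive
    when clustered items receive higher output than non-clustered items.
    A contrast with fewer than 2 events on a side raises, or yields NaN
    with ``allow_missing``.
    """
    probs = np.asarray(probabilities, dtype=float)
    subtypes = np.asarray(subtypes)
    out = []
    for clustered in ("TC", "SC"):
        a = probs[subtypes == clustered]
        b = probs[subtypes == "NC"]
        if len(a) < 2 or len(b) < 2:
            if allow_missing:
                out.append(float("nan"))
                continue
            raise ValueError(
                f"need >= 2 events in {clustered} and NC for the t-test"
            )
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        out.append(float(t))
    return out[0], out[1]


def correlate_neural_behavioral(
    neural: np.ndarray, behavioral: np.ndarray
) -> tuple[float, float]:
    """Two-sided Pearson correlation across participants."""
    x = np.asarray(neural, dtype=float)
    y = np.asarray(behavioral, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 participants with both scores")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a score; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bootstrap_correlation_difference(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bootstrap difference between two variants' neural-behavioral rs.

    ``scores_a`` / ``scores_b`` carry columns ``neural`` and ``behavioral``
    with one aligned row per participant (variant A and B of the same
    participants). Participants are resampled with replacement; each
    replicate computes Pearson r for both variants and their difference
    (A - B). Returns the mean difference, the percentile 95% CI, and the
    replicate differences.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if len(scores_a) != len(scores_b):
        raise ValueError("variants must cover the same participants")
    n = len(scores_a)
    rng = session_rng(seed, 8)
    diffs = np.empty(n_boot)
    a_n = scores_a["neural"].to_numpy(float)
    a_b = scores_a["behavioral"].to_numpy(float)
    b_n = scores_b["neural"].to_numpy(float)
    b_b = scores_b["behavioral"].to_numpy(float)
    for i in range(n_boot):
        idx = rng.integers(n, size=n)
        ra = stats.pearsonr(a_n[idx], a_b[idx])[0]
        rb = stats.pearsonr(b_n[idx], b_b[idx])[0]
        diffs[i] = ra - rb
    ci = (
        float(np.percentile(diffs, 2.5)),
        float(np.percentile(diffs, 97.5)),
    )
    return float(diffs.mean()), ci, diffs


def participant_inclusion(
    sessions: list[BehaviorSession],
    lo: float = 0.15,
    hi: float = 0.85,
    min_sessions: int = 10,
) -> bool:
    """Include a participant iff >= 10 sessions have recall rate in [15%, 85%]."""
    if not sessions:
        raise ValueError("no sessions")
    rates = np.array([s.recall_rate() for s in sessions])
    return int(np.sum((rates >= lo) & (rates <= hi))) >= min_sessions
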