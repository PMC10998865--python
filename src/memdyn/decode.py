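"""Participant-specific decoding of memory success from spectral features.

The decoder is an L2-penalized logistic regression minimizing

    (1/2) w'w + C * sum_i c_i * log(1 + exp(-y_i (X_i' w + b)))

over weights ``w`` and an unpenalized intercept ``b``, with observation
weights ``c_i = n / (2 * n_{y_i})`` inversely proportional to class
frequencies. Classifiers are trained with leave-one-session-out (LOSO)
cross-validation; every analyzed event receives an out-of-fold probability
from a model that never saw its session. Training sets may be re-sampled
per session (serial-position / recall-bin matched down-sampling) across 20
independent runs; the reported AUC is then the mean of the per-run AUCs.
Significance is assessed against a permutation null in which training-fold
labels are shuffled within session while the held-out session stays intact.
Forward activation maps translate decoder weights into interpretable
feature activations via the training-set feature covariance (a = Cov(X) w).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .events import resample_events
from .montage import Montage
from .synthetic import session_rng

__all__ = [
    "ClassifierModel",
    "SessionData",
    "CVResult",
    "PermutationResult",
    "fit_logistic",
    "logistic_objective",
    "auc",
    "loso_cv",
    "permutation_null",
    "tune_C",
    "hyperparameter_grid",
    "forward_activation",
    "exclude_periocular_channels",
]


@dataclass
class ClassifierModel:
    """Fitted penalized logistic decoder."""

    w: np.ndarray
    intercept: float
    C: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(y = +1 | x)."""
        return 1.0 / (1.0 + np.exp(-self.decision(X)))


@dataclass
class SessionData:
    """Design matrix and labels for one session's analyzed events.

    ``y`` is +/-1 (success = +1); ``strata`` carries the serial position
    (encoding) or recall bin (retrieval) used by event re-sampling.
    """

    X: np.ndarray
    y: np.ndarray
    strata: np.ndarray
    session: int
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.strata = np.asarray(self.strata)
        if set(np.unique(self.y)) - {-1, 1}:
            raise ValueError("labels must be +/-1")
        if not (len(self.X) == len(self.y) == len(self.strata)):
            raise ValueError("X, y and strata must align")


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Per-event weights n / (2 * n_class)."""
    n = len(y)
    n_pos = int(np.sum(y > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single-class training set")
    return np.where(y > 0, n / (2.0 * n_pos), n / (2.0 * n_neg))


def logistic_objective(
    w: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray, C: float,
    class_weights: np.ndarray | None = None,
) -> float:
    """Value of the decoder loss at (w, b)."""
    if class_weights is None:
        class_weights = _class_weights(y)
    margin = -y * (X @ w + intercept)
    loss = np.logaddexp(0.0, margin)  # log(1 + exp(margin)), stable
    return float(0.5 * w @ w + C * np.sum(class_weights * loss))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    class_weight: str | dict | None = "balanced",
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> ClassifierModel:
    """Fit the L2-penalized logistic decoder.

    Backed by scikit-learn's lbfgs solver, whose primal objective is
    exactly the stated loss (unpenalized intercept; ``class_weight=
    'balanced'`` yields the inverse-class-frequency observation weights).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class labels")
    clf = LogisticRegression(
        C=C, class_weight=class_weight, solver="lbfgs",
        tol=tol, max_iter=max_iter,
    )
    clf.fit(X, y)
    # sklearn orders classes ascending; ensure w is for the +1 class
    sign = 1.0 if clf.classes_[-1] == 1 else -1.0
    return ClassifierModel(
        w=sign * clf.coef_.ravel().copy(),
        intercept=float(sign * clf.intercept_[0]),
        C=C,
    )


def auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; ties counted one half.

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(p)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _resampled_training(
    train: list[SessionData], rng_key: tuple[int, ...], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-session re-sampled training matrix (independent draws)."""
    xs, ys = [], []
    for k, sd in enumerate(train):
        sub_seed = int(
            np.random.SeedSequence(seed, spawn_key=rng_key + (k,)).generate_state(1)[0]
            % (2**31)
        )
        res = resample_events(sd.y > 0, sd.strata, seed=sub_seed)
        xs.append(sd.X[res.kept])
        ys.append(sd.y[res.kept])
    return np.concatenate(xs), np.concatenate(ys)


def _activation_increment(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cov(X) @ w without forming the covariance (ddof=1)."""
    Xc = X - X.mean(axis=0)
    return Xc.T @ (Xc @ w) / (len(X) - 1)


@dataclass
class CVResult:
    """Cross-validated decoding outcome for one participant."""

    observed_auc: float
    per_run_auc: np.ndarray
    probabilities: np.ndarray  # run-averaged, one per analyzed event
    y: np.ndarray
    session_index: np.ndarray
    events: pd.DataFrame | None
    activation: np.ndarray  # fold/run-averaged Cov(X_train) @ w
    models: list[ClassifierModel] = field(default_factory=list)
    p_value: float | None = None
    null_aucs: np.ndarray | None = None

    @property
    def significant(self) -> bool:
        """Observed AUC above the 95th percentile of the permutation null."""
        if self.null_aucs is None:
            raise ValueError("no permutation null attached")
        return bool(self.observed_auc > np.percentile(self.null_aucs, 95))


def loso_cv(
    sessions: list[SessionData],
    C: float,
    resample: bool = False,
    n_runs: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
) -> CVResult:
    """Leave-one-session-out cross-validated decoding.

    With ``resample`` on, each of ``n_runs`` runs re-samples every training
    session independently (test sessions always keep all events); the
    observed AUC is the mean of the per-run AUCs and per-event
    probabilities are averaged over runs. Without re-sampling a single run
    uses all training events.
    """
    if len(sessions) < 2:
        raise ValueError("LOSO needs at least 2 sessions")
    n_runs = n_runs if resample else 1
    n_events = sum(len(sd.y) for sd in sessions)
    prob_runs = np.zeros((n_runs, n_events))
    y_all = np.concatenate([sd.y for sd in sessions])
    sess_idx = np.concatenate(
        [np.full(len(sd.y), sd.session) for sd in sessions]
    )
    activation = np.zeros(sessions[0].X.shape[1])
    models: list[ClassifierModel] = []
    n_fits = 0
    for run in range(n_runs):
        offset = 0
        for f, test in enumerate(sessions):
            train = [sd for sd in sessions if sd is not test]
            if resample:
                Xtr, ytr = _resampled_training(train, (run, f), seed)
            else:
                Xtr = np.concatenate([sd.X for sd in train])
                ytr = np.concatenate([sd.y for sd in train])
            model = fit_logistic(Xtr, ytr, C=C, tol=tol)
            n = len(test.y)
            prob_runs[run, offset : offset + n] = model.predict_proba(test.X)
            offset += n
            activation += _activation_increment(Xtr, model.w)
            n_fits += 1
            if run == 0:
                models.append(model)
    activation /= n_fits
    per_run = np.array([auc(prob_runs[r], y_all) for r in range(n_runs)])
    events = None
    if all(sd.events is not None for sd in sessions):
        events = pd.concat(
            [sd.events for sd in sessions], ignore_index=True
        )
    return CVResult(
        observed_auc=float(per_run.mean()),
        per_run_auc=per_run,
        probabilities=prob_runs.mean(axis=0),
        y=y_all,
        session_index=sess_idx,
        events=events,
        activation=activation,
        models=models,
    )


@dataclass
class PermutationResult:
    null_aucs: np.ndarray
    p_value: float | None = None

    def significant(self, observed_auc: float) -> bool:
        return bool(observed_auc > np.percentile(self.null_aucs, 95))


def permutation_null(
    sessions: list[SessionData],
    C: float,
    n_perm: int = 100,
    seed: int = 0,
    resample: bool = False,
    observed_auc: float | None = None,
    tol: float = 1e-6,
) -> PermutationResult:
    """Permutation-null AUC distribution for the LOSO decoder.

    Each repetition reruns the full cross-validation with the training
    labels of every fold shuffled *within session*; held-out test labels
    are never shuffled. With ``resample`` on, each repetition draws one
    round of re-sampling on the shuffled training sets (the null's
    location does not depend on the number of runs). Returns the 100-value
    null distribution and, when the observed AUC is supplied, the p-value
    (1 + #null >= observed) / (1 + n_perm).
    """
    if len(sessions) < 2:
        raise ValueError("LOSO needs at least 2 sessions")
    y_all = np.concatenate([sd.y for sd in sessions])
    nulls = np.empty(n_perm)
    for perm in range(n_perm):
        probs = np.empty(len(y_all))
        offset = 0
        for f, test in enumerate(sessions):
            train = [sd for sd in sessions if sd is not test]
            shuffled = []
            for k, sd in enumerate(train):
                rng = session_rng(seed, 6, perm, f, k)
                y_sh = sd.y[rng.permutation(len(sd.y))]
                shuffled.append(
                    SessionData(
                        X=sd.X, y=y_sh, strata=sd.strata, session=sd.session
                    )
                )
            if resample:
                Xtr, ytr = _resampled_training(
                    shuffled, (10_000 + perm, f), seed
                )
            else:
                Xtr = np.concatenate([sd.X for sd in shuffled])
                ytr = np.concatenate([sd.y for sd in shuffled])
            model = fit_logistic(Xtr, ytr, C=C, tol=tol)
            n = len(test.y)
            probs[offset : offset + n] = model.predict_proba(test.X)
            offset += n
        nulls[perm] = auc(probs, y_all)
    p = None
    if observed_auc is not None:
        p = float((1 + np.sum(nulls >= observed_auc)) / (1 + n_perm))
    return PermutationResult(null_aucs=nulls, p_value=p)


def hyperparameter_grid() -> np.ndarray:
    """The 10 log-spaced inverse-regularization values on [1e-8, 1e-1]."""
    return np.logspace(-8, -1, 10)


def tune_C(
    holdout_sessions: list[SessionData],
    grid: np.ndarray | None = None,
    tol: float = 1e-6,
) -> tuple[float, pd.DataFrame]:
    """Select C by leave-one-participant-out CV on held-out session data.

    ``holdout_sessions`` holds one :class:`SessionData` per participant
    (the final session, excluded from the main analysis). For every grid
    value, a decoder trained on the pooled data of all other participants
    is evaluated (AUC) on the held-out participant; the grid value with
    the highest mean AUC wins. Returns the winner and the score table.
    """
    if grid is None:
        grid = hyperparameter_grid()
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2 or np.any(grid <= 0):
        raise ValueError("degenerate hyperparameter grid")
    if len(holdout_sessions) < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for C in grid:
        scores = []
        for held in holdout_sessions:
            train = [sd for sd in holdout_sessions if sd is not held]
            Xtr = np.concatenate([sd.X for sd in train])
            ytr = np.concatenate([sd.y for sd in train])
            model = fit_logistic(Xtr, ytr, C=C, tol=tol)
            scores.append(auc(model.predict_proba(held.X), held.y))
        rows.append((C, float(np.mean(scores))))
    table = pd.DataFrame(rows, columns=["C", "mean_auc"])
    best = float(table.loc[table.mean_auc.idxmax(), "C"])
    return best, table


def forward_activation(
    models: list[ClassifierModel],
    training_sets: list[np.ndarray],
) -> np.ndarray:
    """Forward-model activation a = Cov(X_train) @ w, averaged over folds.

    Transforms backward decoder weights into interpretable activation
    patterns: with whitened features the activation is proportional to the
    weights; in general it reflects how strongly each feature covaries
    with the decoder's decision axis.
    """
    if len(models) != len(training_sets):
        raise ValueError("one training set per model required")
    acts = []
    for model, X in zip(models, training_sets):
        X = np.asarray(X, dtype=float)
        if len(X) < 2:
            raise ValueError("covariance needs at least 2 training events")
        acts.append(_activation_increment(X, model.w))
    return np.mean(acts, axis=0)


def exclude_periocular_channels(montage: Montage) -> np.ndarray:
    """Indices of channels kept in the decoder's feature space."""
    keep = montage.included_indices()
    if keep.size == 0:
        raise ValueError("all channels flagged periocular")
    return keep


def pool_activation_by_roi(
    activation: np.ndarray,
    montage: Montage,
    channel_indices: np.ndarray,
    n_freqs: int,
) -> np.ndarray:
    """Reshape a flat activation vector to (n_freqs, 8 ROIs) by ROI means.

    ``channel_indices`` are the montage channels the flat vector covers
    (after periocular exclusion), in order.
    """
    from .montage import ROI_NAMES

    a = np.asarray(activation, dtype=float).reshape(n_freqs, len(channel_indices))
    roi_labels = montage.roi[channel_indices]
    out = np.full((n_freqs, len(ROI_NAMES)), np.nan)
    for ri, name in enumerate(ROI_NAMES):
        cols = np.flatnonzero(roi_labels == name)
        if cols.size:
            out[:, ri] = a[:, cols].mean(axis=1)
    return out
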