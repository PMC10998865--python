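# Methods

This note documents the models, procedures, parameter choices, and known
limitations of `memdyn`. Nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task and data model

The simulated task is multi-session delayed free recall: per session, 24
lists of 24 session-unique words drawn from a 576-word pool, each word shown
1.6 s with a 0.8–1.2 s ISI, a 24 s arithmetic distractor, then 75 s of free
spoken recall. All sizes are configurable through `TaskDesign`; tests and
benchmarks use fewer sessions and lists (see *Scaled experiment sizes*).

### Word pool

Embeddings (default 50-d, unit norm) stand in for a word-association space.
Words scatter around 48 random topic centers with within-topic spread 0.13,
so within-topic cosine similarities typically exceed the 0.4 clustering
threshold while cross-topic pairs sit near zero (about 2% of pairs are
"semantically related", enough to make semantic clustering observable
without dominating recall). Reserved extra-list ids carry independent random
embeddings so similarity remains computable for intrusion-adjacent
transitions. No claim is made that this similarity distribution matches any
real association space; it only needs to straddle the threshold.

### Behavioral generator

A light retrieval-rule simulator, deliberately not a full
context-maintenance-and-retrieval model — the package tests the *analysis*,
not a memory theory. Per list:

1. each position recalls with probability
   `base + primacy·exp(−(pos−1)/τp) + recency·exp(−(L−pos)/τr)`
   (defaults 0.32, 0.42, τp = 2.5, 0.14, τr = 1.5: a strong primacy effect,
   a small recency effect, mean recall ≈ 0.38);
2. the first recall is biased toward primacy (and mildly recency) positions;
   each later transition is drawn with probability proportional to
   `w_t·exp(−(|lag|−1)/τ) + w_s·max(cos, 0) + w_u` over not-yet-recalled
   items (defaults 1.6 / 1.2 / 0.6, τ = 1.2), producing temporal and
   semantic clustering;
3. prior-list and extra-list intrusions are injected per output attempt
   (4% + 4%, about 10% of responses, a realistic intrusion load);
4. inter-response intervals grow geometrically (start 1.6 s, ratio 1.22,
   lognormal jitter 0.25) and onsets truncate at 75 s, giving the declining
   recall density.

With infinite temporal weight the generator degenerates to nearest-position
recall (ties broken forward), the limit the tests exercise; with all
transition weights zero, transition lags are uniform over available lags.

### Effect model

Features follow an additive model on log-power per (frequency × ROI) cell:
baseline + drift·x + memory-effect·success + clustering-gain·(BC or TC)
+ N(0, σ²), with x the serial position (encoding) or onset time (retrieval)
mapped to [−1, 1], σ = 1 by default so coefficients are in noise-SD units.
The clustering gain applies to encoding events only — retrieval decoders
are not expected to separate clustering subtypes, so no retrieval-side
gain is planted.
`EffectSpec.realistic` encodes the canonical signatures (encoding: alpha/beta
decrease, gamma increase; retrieval: gamma increase; drift: gamma falling
and theta rising over the list). `feature_space` mode emits this model
directly (bypassing the spectral estimator, for fast downstream tests);
`time_domain` mode synthesizes band-limited oscillations whose amplitude is
`exp(½·model)` on 1/f noise at 256 Hz, so the same contrasts must survive
the real multitaper path. Time-domain synthesis is restricted to a
configurable set of carrier frequencies (default 10 and 68 Hz) for cost.

Participant heterogeneity: a latent bivariate standard normal (u, v) with
correlation ρ (the *coupling*) yields clustering propensity exp(0.8·u)
(multiplying the behavioral transition weights) and effect amplitude
exp(0.5·v) (multiplying memory effects and clustering gain). Coupling > 0 is
the ground truth the neural–behavioral correlation analysis recovers.

Reproducibility: every randomness source derives from one seed through
`SeedSequence` spawn keys (counter-based), so any session's stream can be
reconstructed independently and identical (params, seed) give byte-identical
tables and tensors.

## Preprocessing

0.1 Hz Butterworth high-pass (order 2) and fourth-order 58–62 Hz band-stop,
both applied forward–backward (zero phase) so epoch timing is not shifted;
the pass direction is a package choice. Bad channels: a 0.5 Hz-high-passed
copy is split at the two mid-session breaks; per partition, log-variance and
rescaled-range Hurst exponent are z-scored across (non-EOG) channels, and a
channel is flagged if |z(log-var)| > 3 or z(Hurst) > 3 in any partition. The
Hurst estimator is R/S over dyadic window sizes with a log–log least-squares
slope (the estimator is a package choice; white noise ≈ 0.5, random walk
≈ 1.0). The common average reference averages good channels only but
re-references all channels; bad channels stay in downstream features by
default (a config choice — exclusion is defined only for the reference).

## Spectral features

The frequency grid is {4, 6, …, 26} ∪ {32, 38, …, 128} Hz; 26 Hz is
assigned to the 2 Hz-spaced segment, the only reading that yields 29
distinct frequencies. Power comes from DPSS multitapers on a 500 ms window
(half-bandwidth 4 Hz, i.e. time-bandwidth product 2; tapers with
concentration eigenvalue > 0.9 retained; non-adaptive mean over tapers)
evaluated at exact grid frequencies by direct DFT, sliding in 50 ms steps.
Encoding features average the 23 windows centered 250–1350 ms after word
onset; retrieval features take the single window centered −250 ms before
vocalization onset. Log-power is z-scored across events per frequency ×
channel within each session, separately per phase (population SD; mixing
phases raises). Epochs extending past the recording are dropped with a
logged count.

## Decoding

`fit_logistic` minimizes ½wᵀw + C·Σ cᵢ·log(1+exp(−yᵢ(Xᵢᵀw+b))) with an
unpenalized intercept and inverse-class-frequency weights cᵢ = n/(2n_{yᵢ});
correctness is defined by the objective (verified against a brute-force 2-D
search), not the solver, and scikit-learn's lbfgs provides the optimization.
Cross-validation is leave-one-session-out; with re-sampling, every training
session is independently re-sampled per run (20 runs at full scale), models
are always evaluated on the *full* held-out session, the reported AUC is the
mean of per-run AUCs, and per-event probabilities are run-averaged for the
dynamics analyses. The permutation null re-runs the whole CV 100 times with
training labels shuffled within session; for re-sampled decoders each
permutation uses one fresh re-sampling draw (the null's location does not
depend on the run count; 20 runs per permutation would multiply cost 20×).
A decoder is significant when its observed AUC exceeds the null's 95th
percentile. Hyperparameter search uses 10 log-spaced C values on
[1e−8, 1e−1] with leave-one-participant-out validation on held-out-session
data. Forward activations are Cov(X_train)·w per fold (ddof = 1, computed on
the events the fold's model actually saw, including re-sampling), averaged
over folds and runs, then pooled over channels within each octant ROI.
Periocular (face/neck) channels are excluded from the feature space.

## Event labeling and re-sampling

Encoding success is subsequent correct recall within the list's recall
period (repeats count once). Retrieval events are excluded when their onset
follows the previous response by strictly less than 1 s — the boundary case
of exactly 1 s is included — or when they repeat an already-recalled word.
Recall bins are floor(onset/7.5 s). Encoding clustering subtypes follow the
previous-item rule: the item from position i is temporally clustered if a
recall neighbor (either side, in output order) is the item from position
i−1; semantically clustered if a neighbor's similarity ≥ 0.4 (ties at the
threshold count). Retrieval subtypes are defined by the *next* response:
temporal iff it is a correct recall at |lag| = 1; semantic iff its
similarity ≥ 0.4 (extra-list words are never similarity-scored; prior-list
words are, configurably). A list's final recall has no transition and is
labeled NC. Re-sampling: with session ratio r = n_pos/n_neg, each stratum
keeps its minority class and a uniform random subset of the majority class
sized to the nearest integer matching r (never below 1 per class); strata
missing a class are dropped. Integer granularity means the achieved stratum
ratio is within one event of r, the property the tests recount
independently.

## Group statistics

Univariate maps: features pooled over channels per ROI, equal-variance
independent t per cell (a flag switches to Welch), positive = successful >
unsuccessful; group level is a one-sample t across participants with
Benjamini–Hochberg FDR at q = 0.05 jointly over all 29 × 8 cells of one map.
Dynamics: mean out-of-fold probability per participant × subtype × position
group (encoding positions 1–4/5–20/21–24; retrieval bins 1–3/4–7/8–10),
empty cells missing rather than zero, then a linear mixed model with
sum-coded subtype × position fixed effects and participant random
intercepts. Type III F tests use Wald statistics on the fixed-effect blocks
with a residual denominator-df approximation — statsmodels provides no
Satterthwaite df; a warning marks the substitution, and the package's
validation of this model is calibration-based rather than df-exact. EMM
contrasts use equal cell weights with Bonferroni correction. Behavioral
clustering scores are percentile-rank factors (smaller |lag| / larger
similarity ranks higher, mean rank for ties, transitions with a single
available item excluded, intrusions and repeats break the chain; the
semantic score ranks raw similarities — the 0.4 threshold is only for
subtype labels). Neural scores are independent-t statistics of decoder
output for TC vs NC and SC vs NC items. Cohort-level coupling is assessed
by two-sided Pearson correlation, and variant differences by participant
bootstrap of the correlation difference (percentile 95% CI).

## Scaled experiment sizes

The validation battery runs on one CPU in roughly 15 minutes by scaling the
design down, not by weakening the procedures: montages use 8 channels (one
per ROI, 232 features); null calibration uses 10 sessions × 8 lists (1,920
events) × 20 seeds; confound separation 4 sessions × 12 lists × 20 seeds —
12 lists so each serial-position stratum holds 12 events, since with very
small strata the integer granularity of ratio matching itself leaves a
residual label–position association that the full design's 24-list
sessions do not have; effect recovery (planted −0.8 SD at 10 Hz/left-posterior-
inferior) 5 × 6 × 20 seeds; correlation recovery 40 participants × 3
sessions × 5 lists × 20 seeds per coupling arm, with between-participant
amplitude spread 0.9 (log scale) — a wide but plausible heterogeneity that
also keeps the event-count dependence of the t-based neural score (see
below) a minor share of its variance; re-sampled decoders use 3–5 runs
where the tested property does not depend on the run count. The
experiments use C = 0.001 — the
strong-shrinkage regime a hyperparameter search selects for spectral
decoders with 10²–10³ features — since with weak shrinkage a confounded
decoder wastes capacity on noise directions and the confound-separation
experiment would understate what a tuned decoder can exploit. The
confound-separation experiment also sets the recency term of the recall
curve to zero: its premise is that position predicts recall through a
signal a *linear* decoder can leverage, and the small non-monotone recency
bump would otherwise cancel part of the linear position–label association
by construction rather than through the re-sampling under test.

A caveat on the neural clustering score: because it is a t-statistic, it
grows with the square root of the number of clustered events, and
participants who cluster more behaviorally necessarily contribute more TC
events. Whenever a genuine clustering gain is present, this couples the
neural and behavioral scores slightly even when the generator's
propensity–amplitude coupling is zero: the zero-coupling rejection rate of
the correlation test sits near 8–10% rather than the nominal 5% at these
scales. This is a property of the score definition itself, not of the
implementation.

## What passing tests do and do not show

The generator plants exactly the structure the analyses look for: linear
drifts, additive class effects, Gaussian noise, independent events. Passing
recovery tests therefore demonstrates the pipeline's correctness and
calibration under its own assumptions — they do not certify performance on
real EEG, where artifacts, non-stationarity, volume conduction, oscillatory
bursts and autocorrelated noise all violate the synthetic model. Eye blinks,
speech artifacts and impedance drift are explicitly not simulated, the
behavioral simulator fits no real data, and the synthetic embedding space is
a stand-in. The permutation machinery, however, is assumption-light: its
calibration on synthetic nulls is the property that transfers most directly.

## Numerical choices and degenerate inputs

Z-scoring raises on zero-variance columns rather than dividing silently;
single-class sessions make re-sampling, AUC and decoding undefined and
raise; a perfectly constant dynamics table reports F = 0, p = 1; identical
observed and null AUC vectors give a paired t of 0 (p = 0.5) while a
constant nonzero difference raises as degenerate. AUC counts ties as one
half (Mann–Whitney convention). Re-sampling ties in the rounding rule go to
the nearest integer, and the forward tie-break for infinite temporal bias
prefers the +1 transition. lbfgs tolerances are 1e−8 where the objective is
asserted against the brute-force oracle and 1e−4 inside large simulation
loops, where AUC is rank-based and insensitive to the final digits of w.
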