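"""Classifier-output dynamics by clustering subtype and list position.

Simulates several participants whose recalled items carry a clustering
gain, collects out-of-fold decoder probabilities, builds the subtype x
position-group dynamics table, and fits the linear mixed model (random
participant intercepts) testing subtype and position effects.
"""

import warnings

import numpy as np

from memdyn.benchmarks import SIM_C, derive_seed
from memdyn.decode import SessionData, loso_cv
from memdyn.features import frequency_grid, tensor_from_simulated
from memdyn.groupstats import dynamics_mixed_model, dynamics_table
from memdyn.montage import make_sphere_montage
from memdyn.synthetic import (
    BehaviorParams,
    EffectSpec,
    TaskDesign,
    generate_word_pool,
    simulate_participant,
)

design = TaskDesign(n_sessions=3, lists_per_session=6)
pool = generate_word_pool(seed=0)
montage = make_sphere_montage(8)
effects = EffectSpec.realistic(frequency_grid(), amplitude=0.4)

per_participant = {}
for j in range(8):
    pdata = simulate_participant(
        f"P{j:02d}", clustering_propensity=1.0, effect_amplitude=1.0,
        design=design, pool=pool, base_params=BehaviorParams(),
        base_effects=effects, montage=montage, seed=derive_seed(99, j),
    )
    sessions = []
    for b, sim in zip(pdata.behavior, pdata.features):
        t = tensor_from_simulated(sim, "encoding")
        sessions.append(SessionData(
            X=t.matrix(),
            y=np.where(t.events.recalled.to_numpy() > 0, 1, -1),
            strata=t.events.serial_position.to_numpy(),
            session=b.session,
            events=t.events,
        ))
    cv = loso_cv(sessions, C=SIM_C, resample=True, n_runs=5,
                 seed=derive_seed(99, j))
    per_participant[pdata.participant] = (cv.probabilities, cv.events)

table = dynamics_table(per_participant, "encoding")
print("mean decoder output by subtype (BC/TC carry the clustering gain):")
print(table.groupby("subtype").value.mean().round(3).to_string())
print()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = dynamics_mixed_model(table)
print("mixed-model fixed-effect tests:")
print(model.anova.round(4).to_string(index=False))
print()
print("Bonferroni-corrected subtype contrasts (estimated marginal means):")
print(model.emm_contrasts.round(4).to_string(index=False))
print("A positive BC/TC-vs-NR contrast means the decoder assigns higher "
      "memory-success probability to events that end up clustered.")
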