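"""Simulate multi-session free-recall behavior and inspect its regularities.

Generates one synthetic participant, then prints the serial-position recall
curve (primacy and recency), the recall-density decline over the 75 s
recall window, and the intrusion rates — the behavioral structure every
downstream analysis assumes.
"""

import numpy as np

from memdyn import TaskDesign, generate_word_pool, simulate_behavior
from memdyn.events import RECALL_BIN_S, label_encoding_events

design = TaskDesign(n_sessions=6, lists_per_session=24)
pool = generate_word_pool(seed=0)
sessions = simulate_behavior(design, pool, seed=42)

curve = np.zeros(design.list_length)
n_lists = 0
bins = np.zeros(10)
n_pli = n_eli = n_correct = 0
for sess in sessions:
    enc = label_encoding_events(sess)
    curve += enc.groupby("serial_position").recalled.mean().to_numpy()
    n_lists += 1
    for _, r in sess.recalls.iterrows():
        bins[min(9, int(r.onset_time_s // RECALL_BIN_S))] += 1
        if r.response_type == "correct":
            n_correct += 1
        elif r.response_type == "PLI":
            n_pli += 1
        else:
            n_eli += 1
curve /= n_lists

print("P(recall) by serial position (1..24):")
print("  " + " ".join(f"{p:.2f}" for p in curve))
print("-> early positions are best recalled (primacy), with a small "
      "uptick at the end (recency).")
print()
print("Recall counts per 7.5 s bin of the 75 s recall period:")
print("  " + " ".join(f"{int(b):4d}" for b in bins))
print("-> recall density declines over the retrieval period.")
print()
total = n_correct + n_pli + n_eli
print(f"Responses: {n_correct} correct, {n_pli} prior-list intrusions, "
      f"{n_eli} extra-list intrusions "
      f"({100 * (n_pli + n_eli) / total:.1f}% intrusions).")
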