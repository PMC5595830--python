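"""Directed information flow over the planted contact network.

Shuffle-corrected transfer entropies on 30% trajectory subsamples (averaged
over 3 runs), HITS authority/hub scoring of the directed graph, and
transmitter/receiver/connector classification.  Ground truth: channel 0
drives channel 1; channel 2 is independent.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from actiflow.arrayio import load_array, save_array
from actiflow.infoflow import ContactTrace, classify_roles, hits_scores, te_matrix

contacts, meta = load_array(RESULTS / "contacts")
trace = ContactTrace(nodes=["driver", "follower", "bystander"],
                     blocks=[contacts[i].astype(np.int64) for i in range(contacts.shape[0])])

tem = te_matrix(trace, subsample_fraction=0.3, n_repeats=3, lag=1, seed=SEED)
save_array(RESULTS / "te_matrix", tem.values, {"nodes": trace.nodes})
print("corrected transfer entropy matrix (bits):")
print(tem.to_frame().round(3).to_string())

scores = hits_scores(tem)
roles = classify_roles(scores)
roles.to_csv(RESULTS / "roles.csv", index=False)
for _, r in roles.iterrows():
    print(f"{r['node']}: hub {r['hub']:.2f}, authority {r['authority']:.2f} -> {r['role']}")
print("planted ground truth: driver transmits, follower receives, bystander neither")
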