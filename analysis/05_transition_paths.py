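"""Transition path theory between the closed-like and open-like macrostates.

Committor, reactive flux (with conservation check), flux-ranked pathway
decomposition and the macrostate mean first-passage time matrix.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import FRAME_INTERVAL_NS, MSM_LAG, N_MACROSTATES, N_MICROSTATES, RESULTS

from actiflow.arrayio import load_array
from actiflow.msm import MicrostateAssignment, estimate_msm, pcca_lump
from actiflow.tpt import (
    committor, decompose_pathways, flux_to_dot, mfpt_matrix, reactive_flux,
)

labels_arr, _ = load_array(RESULTS / "assignment")
assignment = MicrostateAssignment([labels_arr[i] for i in range(labels_arr.shape[0])],
                                  N_MICROSTATES, FRAME_INTERVAL_NS)
model = estimate_msm(assignment, lag=MSM_LAG)
macro = pcca_lump(model, N_MACROSTATES)

stats = pd.read_csv(RESULTS / "macrostates.csv")
a_macro = int(stats["distance_mean"].idxmin())
b_macro = int(stats["distance_mean"].idxmax())
q = committor(model, macro.members(a_macro), macro.members(b_macro))
flux = reactive_flux(model, q, macro)
conservation = abs(flux.net[q.source, :].sum() - flux.net[:, q.target].sum())
print(f"total reactive flux {a_macro}->{b_macro}: {flux.total:.3e} per lag step "
      f"(conservation error {conservation:.1e})")

paths = decompose_pathways(flux.macrostate_net, [a_macro], [b_macro], min_fraction=0.01)
paths.to_frame().to_csv(RESULTS / "pathways.csv", index=False)
for (p, f), frac in zip(paths.pathways, paths.fractions):
    print(f"pathway {'->'.join(map(str, p))}: {100 * frac:.1f}% of the flux")

(RESULTS / "flux.dot").write_text(
    flux_to_dot(flux.macrostate_net, [f"M{j}" for j in range(N_MACROSTATES)])
)

table = mfpt_matrix(model, macro)
table.to_csv(RESULTS / "mfpt.csv")
print("macrostate MFPT matrix (ns):")
print(table.round(1).to_string())
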