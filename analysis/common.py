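"""Shared configuration for the numbered analysis scripts.

The scripts walk through the full activation-analysis protocol on synthetic
data with known ground truth: a symmetric double-well conformational
coordinate (wells mapped to an 'inactive-like' 9 A and an 'open' 13 A
TM3-TM6 distance surrogate), a planted driver->follower contact process for
the information-flow stage, and a toy receptor-ligand complex for the
fingerprint stage.  Run the scripts in order; each reads its predecessors'
artifacts from RESULTS.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

SEED = 2024

# conformational ensemble
N_TRAJECTORIES = 20
N_FRAMES = 2000
WELLS = dict(centers=[-1.0, 1.0], depths=[4.0, 4.0], widths=0.4, confinement=1.2,
             kT=1.0, diffusion=1.0, dt=0.01)
EMBED = dict(offset=11.0, scale=2.0)  # distance surrogate: 11 + 2x (A)
FRAME_INTERVAL_NS = 1.0

# model parameters (protocol defaults scaled to the synthetic problem size)
TICA_LAG = 10
N_MICROSTATES = 50
MSM_LAG = 10
ITS_LAGS = [1, 2, 5, 10, 20]
N_MACROSTATES = 2
BOOTSTRAP_SAMPLES = 200
BOOTSTRAP_FRACTION = 0.95

# information-flow stage
TE_N_TRAJ = 10
TE_N_FRAMES = 20_000
TE_NOISE = 0.05
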