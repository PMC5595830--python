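# actiflow

Kinetic dissection of receptor activation from molecular-dynamics
trajectories: featurisation → tICA → Markov state models → metastable
macrostates and activation regions → transition path theory →
transfer-entropy information flow → protein–ligand interaction
fingerprints, with a trajectory-bootstrap error protocol and synthetic-data
generators that provide ground truth for every stage.

## Who this is for

Computational structural biologists analysing large ensembles of MD
trajectories of conformational transitions — the motivating case is class-A
GPCR activation (e.g. the µ-opioid receptor switching between its inactive
and activated states with different agonists bound), where the questions
are: *what are the slow degrees of freedom, which metastable states exist
and how probable are they, along which pathways and how fast does
activation proceed, and which residues transmit or receive information?*

## The models at the core

**tICA.** For mean-centred feature vectors x(t) (Cα–Cα distances, sidechain
and residue–ligand contacts), the instantaneous covariance C = ⟨x xᵀ⟩ and
the symmetrised time-lagged covariance C^tl(τ) = ⟨x(t) x(t+τ)ᵀ⟩ enter the
generalized eigenproblem C^tl U = C U Λ; the eigenvectors with the largest
eigenvalues are the slowest linearly-decorrelating coordinates.

**MSM.** Frames projected onto the leading tICs are discretised by k-means
into microstates; sliding-window transition counts at lag τ′ are turned
into a row-stochastic transition matrix T(τ′) by reversible maximum
likelihood (fixed-point iteration under detailed balance π_i T_ij =
π_j T_ji, restricted to the largest strongly connected state set).  Implied
timescales t_i(τ′) = −τ′ / ln|λ_i(τ′)| guide lag selection; the
Chapman–Kolmogorov test compares T(τ′)^m against models re-estimated at lag
m·τ′.  PCCA+ lumps microstates into metastable macrostates; macrostate
averages of activation order parameters (the TM3–TM6 Cα distance and the
NPxxYA-segment Cα RMSD from the inactive reference) classify each
macrostate into the inactive / intermediate I / intermediate II / active
regions of the activation landscape.

**TPT.** Between two macrostates the forward committor q solves a linear
system with q=0 on the source and q=1 on the target; the reactive flux
f_ij = π_i (1−q_i) T_ij q_j yields a net-flux network that is decomposed
into flux-ranked pathways; mean first-passage times come from first-step
analysis.

**Transfer entropy and HITS.** Each residue's binary contact vector is one
discrete symbol; T_{J→I} measures (in bits) how much residue J's present
reduces the uncertainty of residue I's next state beyond I's own history,
corrected by subtracting the estimate after shuffling J's time indices.
The corrected matrix weights a directed graph; HITS assigns authority
(receiver) and hub (transmitter) scores, thresholded into transmitter /
receiver / connector roles.

**Fingerprints.** Per residue, seven bits encode apolar (4.5 Å), aromatic
face-to-face and edge-to-face (4 Å centroid), protein-donor and
protein-acceptor hydrogen bonds (3.5 Å), and electrostatic contacts with
positive/negative residues (4 Å), using sidechain atoms only.

## Worked example

The numbered scripts under `analysis/` run the complete protocol on a
synthetic ensemble with known ground truth (a symmetric double-well
activation coordinate embedded as an atomic distance, a planted
driver→follower contact process, a toy ligand complex).  Running

```bash
python analysis/01_simulate_synthetic_data.py
python analysis/03_tica_and_msm.py      # after 02_featurize.py
python analysis/04_macrostates_and_regions.py
```

prints, among other lines:

```
slowest implied timescale across lags [1, 2, 5, 10, 20]: 338, 357, 365, 351, 362 ns
Chapman-Kolmogorov: worst |predicted - observed| self-transition probability = 0.004
macrostate 0: p = 0.415 [0.410, 0.420], distance = 12.8 A -> intermediate_I
macrostate 1: p = 0.585 [0.580, 0.590], distance = 9.2 A -> inactive
planted ground truth: symmetric wells, 0.5 / 0.5 split
```

i.e. the implied timescale is flat across lags (the discretised dynamics
is Markovian), the CK test passes, and the two PCCA+ macrostates recover
the two wells — one classified inactive (9.2 Å, closed TM6 surrogate), one
intermediate I (12.8 Å, open TM6 surrogate with inactive-like NPxxYA
surrogate) — with stationary probabilities near the planted 50/50 split and
bootstrap quartiles quantifying the estimation spread.  Scripts 05–07 add
the transition-path decomposition and MFPT matrix, the transfer-entropy /
HITS role assignment (driver → transmitter, follower → receiver), and the
fingerprint matrix with exactly one bit per interaction archetype.

The same chain can be run in one call:

```python
from actiflow.pipeline import PipelineConfig, run_pipeline, generate_report
manifest = run_pipeline(PipelineConfig(seed=1), "runs/demo")
generate_report("runs/demo")
```

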