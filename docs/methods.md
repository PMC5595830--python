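# Methods

This note documents the models, estimators and numerical choices behind
`actiflow`, the assumptions they rest on, and what the synthetic test beds
do and do not establish about real trajectory data.

## Featurisation

Three descriptor families describe a receptor–ligand system per frame:
Cα–Cα distances over all unordered pairs of a thinned residue selection
(every third residue of the analysed span, giving 97 residues and 4,656
pairs for a 64–352 receptor span), binary sidechain–sidechain contacts
(minimum sidechain heavy-atom distance below 7 Å) for residue pairs that
touch in at least one reference structure, and binary residue–ligand
contacts (7 Å on heavy atoms, one descriptor per residue of the span).
Contact columns use a strict `<` comparison at the cutoff so boundary
behaviour is bit-exact and testable; glycine, which has no sidechain heavy
atoms, is represented by its Cα throughout.  Distances are in Ångström,
residue numbers are 1-based author numbering, frames 0-based.

Order parameters follow the standard activation coordinates of class-A
GPCRs: the TM3–TM6 Cα distance (residue pair 165/279 in µ-opioid-receptor
numbering) for the outward swing of TM6, and the Cα RMSD of the NPxxYA
segment (residues 332–337) from the inactive reference after rigid
superposition on a fit selection.  The fit defaults to all residues shared
with the reference — the segment RMSD then measures distortion within the
whole-receptor frame — and a local-fit mode is available by passing an
explicit fit selection.

The hydrogen-bond criterion is geometric: donor–acceptor heavy-atom
distance ≤ 3.5 Å, plus a D–H⋯A angle ≥ 120° whenever explicit hydrogens
are present (distance-only otherwise, as in crystal structures without
hydrogens).  Aromatic ring geometry uses the SVD plane of the ring atoms;
interplanar angles are folded to [0°, 90°], with ≤ 30° counted
face-to-face and ≥ 60° edge-to-face.  Aromatic-ring carbons are excluded
from the apolar atom class so the two fingerprint bits are controlled by
disjoint atom sets.

## tICA

Covariances are accumulated over all trajectories with a single global
mean; the time-lagged covariance never pairs frames across trajectory
boundaries and is symmetrised, which guarantees a real spectrum and
corresponds to a reversible estimate.  A ridge of 1e-8·trace(C)/d on the
diagonal of C keeps the generalized eigenproblem well-posed when binary
contact columns make C rank-deficient.  Eigenvectors are C-orthonormal
(training projections have unit variance) and sign-fixed so the
largest-magnitude loading is positive, making results deterministic.  Ten
components are retained by default, matching the dimensionality at which
projection marginals of receptor data stop looking multimodal; the tICA
lag defaults to the MSM lag so one time-resolution parameter governs both.
Descriptor importance per component is ranked by absolute Pearson
correlation between the raw descriptor trace and the projected coordinate
(top 75 by default); constant descriptors are reported with correlation 0
and a flag.

## Markov state model

Microstates are k-means clusters (k-means++ initialisation, fixed seed,
1000 clusters at production scale) in the retained tICA space.  Transition
counts use a sliding window at lag τ′ — maximal data use, the standard
choice for likelihood estimators — and are restricted to the largest
strongly connected component before estimation, since reversible maximum
likelihood requires an ergodic chain; trimming emits a warning.  The
reversible transition matrix is the fixed point of the standard
self-consistent iteration on the symmetric flux matrix, converged when the
largest relative change drops below 1e-10 (cap 10⁶ iterations, error with
diagnostics on failure).  Eigenvalues come from the symmetrised similarity
transform D^{1/2} T D^{-1/2}, which is numerically symmetric for a
reversible T.  Detailed balance and row-stochasticity are asserted on
every constructed model.

Implied timescales t_i = −τ′/ln|λ_i| are reported in physical units via
the frame interval; eigenvalue magnitudes within 1e-12 of 1 are flagged as
infinite rather than numerically amplified.  The default production lag is
10 ns expressed in frames, the resolution at which implied timescales of
the receptor systems converge.  The Chapman–Kolmogorov test compares the
set-restricted self-transition probability predicted by T(τ′)^m with the
same quantity from a model re-estimated at lag m·τ′, both optionally with
bootstrap quartiles.

PCCA+ memberships come from the top right eigenvectors via the
inner-simplex vertex construction (the first column pinned to the constant
stationary eigenvector); negative memberships are clipped and rows
renormalised, crisp states taken by maximal membership.  A degenerate
eigenvalue pair at the spectral cut raises an error suggesting a different
macrostate count.  Macrostate probabilities sum the stationary weights of
member microstates.  Macrostate order-parameter averages weight microstate
means by stationary probability; quartiles come from the
stationary-reweighted frame distribution (each frame carries π of its
microstate divided by the microstate's frame count).

Region classification: a macrostate is *inactive* when the TM3–TM6
distance is within 10 Å **and** the NPxxYA RMSD within 2.5 Å (boundaries
inclusive).  The remaining grid uses a configurable outer distance
threshold (default 13 Å): *intermediate I* for an open TM6 with
inactive-like NPxxYA, *active* for distance > 13 Å with distorted NPxxYA,
*intermediate II* for distorted NPxxYA at intermediate TM6 opening.  The
cell 10 Å < d ≤ 13 Å with inactive-like NPxxYA is assigned to
intermediate I — TM6 at least partially open while TM7 remains
inactive-like — since only the inactive rule has a published numerical
definition; both thresholds are parameters.

## Transition path theory

The forward committor solves the interior linear system exactly; the
gross reactive flux is π_i (1−q_i) T_ij q_j, netted by keeping the
positive part of f_ij − f_ji, and coarse-grained by summing over
macrostate pairs.  Pathways are extracted by repeatedly finding the widest
(maximum bottleneck capacity) source→target path on the net-flux graph and
subtracting its bottleneck flux — a deterministic decomposition whose
fractions are reported relative to the total A→B flux, keeping pathways
above 1% by default.  Macrostate MFPTs hit the full microstate set of the
target macrostate, averaged over source microstates with restricted
stationary weights; unreachable targets report infinity with a flag.

## Transfer entropy and link analysis

Each node's per-frame contact vector is treated as one discrete symbol, so
all entropies are exact plug-in estimates over the observed alphabet — no
binning is involved because contacts are binary.  The lag-1 (configurable)
transfer entropy is computed in bits via H(x⁺,x) − H(x) − H(x⁺,x,y) +
H(x,y); the equivalent direct summation over the empirical joint
distribution is implemented separately and the identity asserted in tests.
The finite-sample bias is removed by subtracting the same estimate after a
random permutation of the source's time indices, applied independently
within each trajectory (one permutation by default, configurable to
average several).  Production-scale runs subsample 30% of the trajectories
and average three independent repeats.  Negative corrected values are kept
in the matrix but clipped to zero when the directed graph is built, since
HITS requires non-negative weights.  HITS runs as a power iteration on the
weighted adjacency to 1e-12, scores max-normalised to [0, 1]; roles use a
default threshold of 0.5 on both scores (transmitter: hub only; receiver:
authority only; connector: both), a cutoff that is a reporting choice, not
a physical constant.

## Bootstrap protocol

Error bars are first/third quartiles over 500 re-estimates, each on a
random 95% subset of trajectories drawn without replacement with all
frames retained.  Estimator failures on a subsample are recorded, excluded
and counted.  Note what these bars are: the spread of the estimator under
small perturbations of the trajectory set — a measurement-stability band,
not a confidence interval.  Because a 95% subset differs from the full set
by only 5% of the data, the subset estimates scatter around the full-data
estimate with roughly √(1/0.95 − 1) ≈ 0.23 of the estimator's true
sampling standard error, so the Q1–Q3 band is several times narrower than
a genuine 50% confidence interval and cannot be expected to bracket the
true parameter value in most repeated experiments.  The package's coverage
experiment (50 independent synthetic chains) measures this directly and
reports the observed coverage honestly.

## Synthetic test beds

The generators provide ground truth per stage: an exact-transition-matrix
Markov chain (stationary distribution, eigenvalues and hence timescales,
committors and MFPTs all known analytically); overdamped Euler–Maruyama
diffusion in a sum-of-Gaussian-wells potential — analytic gradients,
controllable barriers, plus an optional harmonic confinement term because
a bare sum of Gaussians is flat at infinity and an unconfined walker would
eventually escape — embedded as a two-pseudo-atom distance equal to an
affine map of the latent coordinate, so the featurizer must recover it
exactly; Bernoulli driver/follower contact processes whose transfer
entropy is analytically 1 bit at zero noise and 0 in the reverse
direction; and toy receptor–ligand complexes that place one residue
archetype per spatial direction at exact interaction distances, verified
to 1e-6 Å at construction.

The crystal-fragment structures in `synthetic.crystal_fragment` are
generated stand-ins, not deposited coordinates: marker residues (R165,
T279, A240, H297, Y252, the NPxxYA segment) carry realistic names and
numbering, and the published marker distances (TM3–TM6 8 Å closed / 14 Å
open; binding-pocket A240–H297 minimum sidechain distance 4.4 Å inactive /
4.0 Å activated) hold by construction.  They validate the measurement
machinery — PDB round trips, atom typing, minimum-sidechain-distance
logic — not crystallographic geometry.

What passing tests show, and what they do not: the estimators recover
planted thermodynamics, kinetics, information flow and interaction
geometry on low-dimensional, exactly-Markovian or exactly-specified
inputs.  Real MD data add discretisation error from imperfect microstates,
non-Markovianity at short lags, force-field and sampling bias, and
symbol-alphabet explosion for highly connected residues — none of which
the synthetic beds emulate.  Conclusions about a specific receptor system
require the corresponding trajectory data.

## Problem sizes

Default analysis-scale sizes are 20 trajectories × 2000 frames for the
conformational chain (50 microstates, 2 macrostates), 10 × 20,000 frames
for the information-flow stage, 10⁵–10⁶ frames for the closed-form
recovery checks, and 200–500 bootstrap samples; these reproduce the
planted values to the tolerances asserted in the tests while keeping a
full run in minutes on one CPU core.  Production parameters (1000
microstates, 14 macrostates, 10 ns lag, 500 bootstrap samples, 30%/3-run
transfer entropy) are the configuration defaults where they do not depend
on problem size.

## Known limitations

PCCA+ uses the inner-simplex construction with clip-and-renormalise rather
than the full constrained optimisation of the objective; for
well-separated metastable spectra (the intended regime) the two coincide.
The transfer-entropy estimator is pairwise only — no conditional or
multivariate variants — and the plug-in entropy is biased upward for large
alphabets, which the shuffle correction compensates only to first order.
The pathway decomposition is deterministic but not unique; alternative
decompositions can split flux differently on graphs with strongly
overlapping channels.  Trajectory reading supports XTC/DCD coordinate
files against a PDB topology; multi-chain selections resolve by residue
number only.
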