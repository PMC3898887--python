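# Methods

## The model and its assumptions

`hmmbeam` treats an N-channel sensor recording `y_1 … y_T` as piecewise
stationary: a hidden Markov chain `s_t` with K states selects, at each
sample, a multivariate-Normal observation model `N(mu_k, Sigma_k)`. The
states are not given a physiological interpretation — they are whatever
covariance regimes the data contain (cardiac and ocular artefact phases,
transient network configurations, task periods). The only assumptions are
first-order Markov switching and Gaussian within-state statistics; state
means are estimated rather than fixed at zero, although on band-passed data
they fit near zero.

The reconstruction step is a scalar LCMV beamformer: unit gain along the
source orientation, minimum output variance given a covariance estimate.
The package's contribution is where that covariance comes from: either the
pooled data covariance (stationary mode), per-sample gathers of state
covariances `Sigma_{u_t}` from the decoded MAP path (adaptive mode), or
fixed consecutive blocks (the sliding-window comparator, which reuses the
adaptive code path with block labels).

## Variational inference

Inference is variational Bayes with conjugate priors: symmetric Dirichlet
(pseudo-count `prior_strength`, default 1) on the initial-state vector and
every transition row, and Normal–Wishart on each state's mean/precision
with `beta0 = prior_strength`, `nu0 = N + 2`, and Wishart scale set so the
prior expected state covariance equals the global data covariance. The
E-step runs scaled forward–backward on the usual surrogate parameters
`exp E[log pi]` and `exp E[log-likelihood]` (used unnormalised, so the
forward normaliser is the exact evidence term); the free energy recorded
per iteration is that normaliser minus the parameter KL terms, with the
sign convention that larger is better. Each full update cycle cannot
decrease it; the trace is checked to be monotone within `1e-6·|F|`.

Initialisation: the first restart runs k-means on log moving-variance
features (0.2 s window) — state structure here is variance structure — and
the remaining `n_restarts − 1` use random Dirichlet responsibilities; the
restart with the highest final free energy wins. Convergence at relative
free-energy change below `tol` (default 1e-6) or `max_iter` (default 200).

The reported `HMMPosterior.covariances` are responsibility-weighted
empirical covariances with unbiased denominator, not the Normal–Wishart
posterior means: this makes the single-state case reduce exactly to the
sample covariance and keeps the reported quantities on the same footing as
the state-pooled covariances used downstream. Viterbi decoding uses these
point estimates; exact likelihood ties resolve to the lowest state index,
the tie-break used everywhere in the package.

Model-order selection fits each candidate K and keeps the largest whose
least-occupied state (from the Viterbi path) still holds a minimum
occupancy in seconds — covariance quality, not model evidence, is the
binding constraint for beamforming, so the selected K is deliberately
below the evidence-optimal order.

## State statistics

Fractional occupancy, mean life-time, and occurrence counts are computed
from the label sequence with the conventions: occurrences are rising edges
of the state indicator, a run starting at the first sample counts, and runs
truncated by the end of the recording count. The dissimilarity of state
covariances is the symmetrised KL divergence between zero-mean Gaussians,
`0.25·[tr(Sb⁻¹Sa) + tr(Sa⁻¹Sb)] − N/2`, which is zero exactly at equality
(the constant matters only for absolute values; all uses here are relative
comparisons).

## Beamforming choices

**Subspace reduction.** Data and lead fields are projected onto the leading
principal axes of the sensor covariance before anything else; this is the
conditioning strategy (no diagonal loading by default, `reg` available).
Eigenvector signs are fixed (largest-magnitude component positive).

**Orientation.** The source orientation maximises the beamformer output
*SNR* (pseudo-Z): the largest generalized eigenvector of the pencil
`(H'C⁻¹H, H'C⁻²H)`, restricted to the numerically nonzero column space of
the lead field (rank 2 for spherical-conductor MEG, which is blind to
radial moments). Normalising by the white-noise gain is essential: the raw
output power is dominated by noise amplification along weak lead-field
directions whenever the source is far below sensor noise, and an
unnormalised max-power rule then picks an orientation nearly orthogonal to
the source. When the pseudo-Z is flat (covariance proportional to
identity) the tie breaks to the largest forward gain `‖H·eta‖`. In adaptive
mode the orientation is re-estimated per state from the state covariance
(default; a global mode uses the full covariance), since each state's
interference configuration differs.

**Weights.** Computed once per (voxel, state) by symmetric factorisation,
then gathered over the label sequence; the covariance condition number is
checked against a cap (default 1e12) and the error names the remedy rather
than silently switching to a pseudo-inverse. Unit gain `W·h = 1` holds to
machine precision by construction.

**Under-occupied states.** States whose Viterbi occupancy cannot support a
covariance estimate are absorbed into their temporal context
(forward-fill) and the labels renumbered; merges are logged. The
replication pipeline requires five samples per retained dimension.

## Envelope statistics

The band-pass is a zero-phase 4th-order Butterworth applied
forward–backward (family and order are a package choice; configurable).
Three envelope z variants are provided, following the defining expressions
literally: the stationary variant divides by the (constant) std *before*
the Hilbert envelope; the Monte-Carlo and proportional variants envelope
first and divide after. The two orders agree exactly only for
time-constant std — asserted by test. Monte-Carlo draws are independent
across samples (n_mc default 100); the per-sample std over sampled
envelopes is floored at 1e-8 times the median envelope of the mean (logged
when hit). The proportionality constant of the fast variant is 1: per-voxel
constants cancel in every downstream correlation and t-statistic. The first
and last `ceil(fs/lo_hz)` samples carry envelope edge artefacts; helpers
expose that count.

## Statistic maps

Leakage regression removes the seed's raw series from each test voxel by
OLS (with intercept) *within each state's samples*, so zero-lag covariance
is cancelled state by state even when mixing flips between states. GLM and
seed maps use plain OLS t-statistics with naive dof `T_out − P`; temporal
autocorrelation of envelope series is deliberately not corrected
(documented limitation — nominal and empirical null rates agree for white
input, not for smoothed envelopes). Fixed-effects combination across
states is the inverse-variance weighted average. Thresholding is
display-only: a rank-based map percentile (`floor(n·pct/100)` lowest
in-mask voxels nulled), idempotent because the in-brain mask never
changes; no multiple-testing correction is applied anywhere.

## The simulator

The generator reproduces the study conditions: 150 Hz sampling, a
unit-variance Gaussian signal dipole at MNI [41, −25, 49] mm, ten
mutually exclusive confound dipoles switched by a 10-state chain with
off-diagonal transition probability 2e-4 (mean dwell `1/(9·2e-4)/150 ≈
3.7 s` by the geometric law — the chain is specified by its transition
probability, not by a target dwell), within-state confound std 10 AU,
tangential dipole orientations with uniform random azimuth, and additive
white sensor noise at power SNRs {4.001e-3, 1.440e-3, 0.735e-3}. The SNR
is referenced to the projected *signal* power (mean square over sensors
and time) — referencing all sources would bury the 1-AU signal under the
100-fold stronger confounds at every stated level; `snr_reference="all"`
is available. The confound coordinates come in left/right homologue pairs
plus a frontal midline source; the tenth is the contralateral homologue
[−41, −25, 49] of the signal location (a confound exactly co-located with
the signal would make the stationary reference method fail at all noise
levels, which is not the behaviour the method is being compared against).

The forward model is the analytic current-dipole field in a spherically
symmetric conductor (Sarvas closed form), verified against an independent
scalar-potential-gradient computation. The array is a pseudo-CTF helmet:
275 radial axial gradiometers (5 cm baseline) on a Fibonacci spherical cap
down to 105° polar angle at 0.105 m radius (~15 mm standoff over the
0.09 m source sphere). MNI mm map to head metres by a fixed affine (sphere
centre at MNI [0, 0, 20] mm, scale 1e-3); geometric realism beyond that is
a non-goal. What the sphere does preserve: linear mixing, depth-dependent
sensitivity, the rank-2 structure of MEG lead fields, and realistic
inter-source leakage. What it does not: the sharper point spread of
synthetic higher-order gradiometer systems, realistic anatomy, cortical
constraints, or structured (non-white) sensor noise. Consequently, tests
passing on this generator validate the machinery and the qualitative
adaptive-versus-stationary pattern, not millimetre localisation accuracy
on real recordings — the stationary beamformer's low-noise correlation
profile, in particular, is a shallow lateral ramp here, and its peak
location is only accurate to about one 6 mm grid step.

## Problem sizes

The end-to-end comparison runs at 100 s per realisation (T = 15 000), 275
channels reduced to rank 48, K = 10, one k-means-seeded restart with at
most 40 VB iterations, five realisations per noise level, on a 6 mm line
of voxels through the source at fixed y = −25, z = 49. HMM-recovery checks
use two-state, two-channel generative data at T = 60 000. These sizes were
chosen so the full acceptance battery completes in minutes on one CPU;
rank 48 (rather than the 100 used with long recordings) is forced by the
state-pooled covariances, which need several samples per dimension within
every state at 100 s.

## Known limitations

- Hard state assignments: covariance pooling and weights use the Viterbi
  path, not the posterior probabilities; soft weighting would require
  per-sample weights.
- The free energy is comparable across K only under the same prior
  scaling, which the model-order search keeps fixed.
- Envelope statistics inherit beamformer depth bias; correlations are
  per-voxel scale-free but cross-voxel comparisons are not bias-free.
- The naive GLM dof overstates precision on smoothed envelope series.
- The Monte-Carlo envelope std assumes independent Gaussian errors per
  sample; temporally correlated reconstruction error is not modelled.
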