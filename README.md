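# hmmbeam

HMM-adaptive LCMV beamforming for MEG/EEG source reconstruction.

Beamformers reconstruct brain activity from sensor recordings with a spatial
filter whose weights depend on the sensor covariance matrix. The standard
LCMV beamformer pools all samples into one covariance estimate, assuming the
data are stationary — but M/EEG recordings switch between short-lived regimes
(artefact cycles, transient network states) on the scale of 100 ms to a few
seconds. `hmmbeam` segments the sensor data with a Gaussian-observation
hidden Markov model, pools samples *within* each inferred state to build
state-specific covariance matrices, and computes time-varying beamformer
weights that switch with the decoded state sequence. Downstream it provides
variance-corrected ("z-statistical") raw and Hilbert-envelope time courses,
seed-based correlation maps with per-state leakage regression, GLM t-maps
with fixed-effects combination across states, and a single-sphere MEG
simulator with full ground truth so the whole pipeline can be validated end
to end. It is aimed at electrophysiology methods researchers who want a
self-contained, testable reference implementation of temporally adaptive
beamforming.

## Model

Sensor vectors `y_t` (N channels) follow a K-state HMM: a Markov chain `s_t`
with row-stochastic transition matrix π, and state-conditional emissions

```
y_t | s_t = k  ~  N(mu_k, Sigma_k)
```

fitted by variational Bayes (Dirichlet priors on π, Normal–Wishart priors on
(mu_k, Sigma_k)); the free-energy (evidence lower bound) trace is monotone
and used for restarts and model-order comparison. The MAP state path `u_t`
comes from Viterbi decoding. For a source at `r` with oriented lead field
`h(r)`, the LCMV weights on covariance `C` are

```
W(r) = (h' C^-1 h)^-1 h' C^-1          (unit gain:  W h = 1)
m̂(r, t) = W(r) y_t                     std m̂ = (W C W')^(1/2)
```

In adaptive mode `C` is the state covariance `Sigma_{u_t}` — weights,
orientation and std all switch with `u_t`. The z-statistical time course
`m̂/std` corrects the spatially (and temporally) varying beamformer
sensitivity; envelope statistics divide the Hilbert envelope of `m̂` by an
envelope-std estimated either by Monte-Carlo sampling or proportionally
from the raw std.

## Worked example

Simulate 100 s of 275-channel MEG containing a unit-variance source in the
motor cortex plus ten strong HMM-switched confound dipoles, then compare the
stationary and the HMM-adaptive reconstruction against the known source:

```python
import numpy as np
from hmmbeam import (
    HMMConfig, SimConfig, bandpass, build_leadfields, envelope_z,
    estimate_covariances, evaluate_reconstruction, fit_hmm, line_grid_x,
    make_helmet_array, merge_rare_states, reconstruct, reduce_subspace,
    simulate_dataset, summarize_states, viterbi_decode,
)

cfg = SimConfig(duration_s=100.0, seed=0)          # 150 Hz, 10 confound states
array = make_helmet_array(275)                     # pseudo-CTF gradiometer helmet
data, truth = simulate_dataset(cfg, array, snr=cfg.snr_levels[0])

grid = line_grid_x()                               # x through the source, y=-25, z=49
leadfields = build_leadfields(array, grid)
beta = bandpass(data, 13.0, 30.0)
reduced, reduced_lf, _ = reduce_subspace(beta, leadfields, rank=48)

post = fit_hmm(reduced, HMMConfig(K=10, n_restarts=1, max_iter=40, tol=1e-5, seed=0))
states = merge_rare_states(viterbi_decode(post, reduced), min_samples=240)
summary = summarize_states(states)
print(f"free energy: {post.free_energy:.1f} after {len(post.free_energy_trace)} iterations")
print(f"decoded {states.K} states; mean lifetime "
      f"{np.mean(summary.mean_lifetime_s[summary.n_occurrences > 0]):.2f} s")

covs = estimate_covariances(reduced, states)
adaptive = reconstruct(reduced, reduced_lf, covs, states)
stationary = reconstruct(reduced, reduced_lf, estimate_covariances(reduced, None), None)

z_adapt = envelope_z(adaptive.mean, adaptive.std, method="prop")
z_stat = envelope_z(stationary.mean, stationary.std, method="stationary")
corr_a, _ = evaluate_reconstruction(np.atleast_2d(z_adapt.values), truth, fs=cfg.fs)
corr_s, _ = evaluate_reconstruction(np.atleast_2d(z_stat.values), truth, fs=cfg.fs)

i_true = int(np.argmin(np.abs(grid[:, 0] - 41.0)))
print(f"correlation with true envelope at x=41 mm: "
      f"adaptive {corr_a[i_true]:.3f}, stationary {corr_s[i_true]:.3f}")
print(f"adaptive profile peak at x = {grid[np.argmax(corr_a), 0]:.0f} mm (true: 41)")
```

Output:

```
free energy: 6438534.1 after 8 iterations
decoded 10 states; mean lifetime 0.63 s
correlation with true envelope at x=41 mm: adaptive 0.427, stationary 0.370
adaptive profile peak at x = 47 mm (true: 41)
```

The HMM found ten short-lived covariance states; the adaptive reconstruction
tracks the true source envelope better than the stationary one, and its
correlation profile along the left–right axis peaks one grid step from the
true source. The advantage grows as sensor noise increases (see
`scripts/acceptance.py` output).

## Command line

The same pipeline is scriptable through the `hmmbeam` console tool, which
stores everything in one HDF5 container:

```
hmmbeam simulate run.h5 --duration-s 100 --snr-index 0 --seed 1
hmmbeam fit-hmm  run.h5 --k 10 --rank 48 --seed 1
hmmbeam beamform run.h5 --mode hmm --rank 48
hmmbeam envelope run.h5 --method prop --smooth-s 0.1
hmmbeam seedcorr run.h5 --nifti seed_map.nii.gz
hmmbeam report   run.h5
```

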