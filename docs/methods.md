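# Methods

This note documents the models and procedures implemented in `tepnet`, the
assumptions behind them, the parameters that matter, and the design choices
made where more than one reasonable implementation existed.

## The analysis chain

The package analyses single-pulse TMS–EEG sessions delivered over the left
(O1) and right (O2) early visual cortex. The chain is:

1. **Phosphene threshold** (`psychometrics`) — a Method of Constant
   Stimuli session (7 intensities, 60–78 %MSO in steps of 3, 7 pulses per
   level) is fitted with a two-parameter cumulative logistic by maximum
   likelihood; the 50% point defines the phosphene threshold (PT).
2. **Signal conditioning** (`preprocessing`) — epoching ±1000 ms around
   the pulse, cubic interpolation of the −2..10 ms pulse window,
   anti-aliased downsampling 5000 → 500 Hz, zero-phase order-4 Butterworth
   filtering (0.1–100 Hz band-pass, 49–51 Hz notch, 40 Hz low-pass) and
   pre-stimulus demeaning.
3. **TEP estimation** (`tep`) — Bayesian sweep-by-sweep smoothing with
   inverse-error weighted averaging, against conventional averaging (CA);
   both summarized by the global mean field power (GMFP), the spatial
   standard deviation over channels at each sample.
4. **Effective connectivity** (`connectivity`) — a time-varying MVAR
   model fitted per sample across trials by the self-tuning optimized
   Kalman (STOK) filter; information partial directed coherence (iPDC)
   derived from the spectral transfer B(f, t) = I − Σₖ A_{k,t} e^{−j2πfk};
   |iPDC| averaged over 1–40 Hz and five analysis windows (12–24, 24–48,
   48–92, 92–124, 124–240 ms), minus the pre-stimulus baseline network.
5. **Graph metrics** (`graph`) — 50%-of-max thresholding, edge
   betweenness centrality (reciprocal-weight path lengths), in+out degree
   on the binarized graph, right-to-left electrode flipping of
   O2-condition networks, and pooling of degrees into four macro areas.
6. **Contrasts** (`stats`) — paired Wilcoxon signed-rank tests:
   per-sample GMFP comparison (Bonferroni-corrected, α = 0.05) and
   per-edge / per-area contrasts between stimulation sites (uncorrected,
   α = 0.001) with signed direction reporting.

## Bayesian single-sweep TEP smoothing

Each sweep is modelled as y = u + v. The background EEG v is an AR(q)
process fitted to the sweep's own pre-stimulus interval by least squares,
with the order chosen by the final prediction error (FPE) over 1..`max_ar_order`
(default 15; candidate fits share the same target rows so their residual
variances are comparable). The unknown evoked potential u carries an
m-fold integrated-white-noise prior (default m = 2, a smooth second-order
random walk). The posterior mean is

    u_hat = (AᵀA + γ FᵀF)⁻¹ AᵀA y,

with A the AR whitening operator, F the m-th difference operator and γ the
noise-to-prior variance ratio. All quantities are computed in the
generalized eigenbasis of (AᵀA, FᵀF), so scanning γ is cheap.

**Choice of γ.** The classical discrepancy criterion (whitened residual
energy = nσ²) proved fragile here: whenever a sweep is cleaner than σ²
suggests, the target lands on the plateau of the residual-energy curve and
γ diverges, collapsing the sweep to zero. The default is therefore
generalized cross-validation (GCV) on the whitened residuals, which needs
no noise-variance target; `reg="discrepancy"` and fixed numeric γ remain
available. Each sweep's reliability is its expected squared error
σ²·tr((AᵀA + γFᵀF)⁻¹); the TEP is the average of smoothed sweeps weighted
by the inverse of that quantity (weights normalized to 1). Each channel is
smoothed independently; no spatial prior is used.

The advantage over CA materializes exactly when sweep noise is
heterogeneous: under log-normal variance scaling across sweeps (σ of the
log factor 0.8) the weighted Bayesian estimate beats CA in ~85–90% of
seeded replicates; under strictly homogeneous noise CA is close to optimal
and the two are comparable.

## The STOK filter

The filter treats trials as repeated realizations and estimates A_{k,t} by
recursive least squares over the trial dimension with exponential
forgetting:

    R_t = λ_t R_{t−1} + (1−λ_t) ZᵀZ/N,   P_t analogous,   Θ_t = R_t⁺ P_t,

where Z stacks the p lagged trial vectors. The convex-combination update
makes the forgetting rate exactly (1−λ) regardless of accumulated history.
R_t⁺ is an eigendecomposition pseudo-inverse truncating eigenvalues below
1% of the largest (recursive regularization; it engages automatically when
trials are few relative to p·d).

**Self-tuning memory.** λ_t is driven by the ratio of each channel's
current innovation energy to its slow (τ ≈ 100 samples) running average:
the worst channel's ratio, lightly smoothed, is mapped linearly onto
[λ_min, λ_max] = [0.95, 0.999] above a dead-band of 0.03 with scale 0.05,
and a strong spike pins λ at λ_min for 12 samples (refractory hold) so the
memory stays short while a network change is being absorbed. These
constants were set against the filter's own recovery contracts: on
stationary VAR(1) ground truth (d = 3, 200 trials) the time-averaged
coefficient error stays below 0.02 max-entry; a 0 → 0.5 coupling step is
tracked to half height within 5–14 samples; uncoupled channels stay below
0.02. The innovation covariance Σε is the time-average of per-sample
trial residual covariances (warm-up excluded) with a 1e-8 relative
diagonal ridge before inversion.

## iPDC and window aggregation

With b_j the j-th column of B(f, t),

    iPDC_{i←j}(f, t) = σ_ii^{−1/2} b_ij / sqrt(b_jᴴ Σε⁻¹ b_j),

and the magnitude |iPDC| is analysed. With Σε = σ²I the squared
magnitudes sum to one over targets for every (source, f, t); this identity
is verified to 1e-10 over random stable models. The frequency grid is
1–40 Hz at 1 Hz spacing (the data are low-passed at 40 Hz); halving the
spacing changes window-aggregated adjacencies by under 1%. Time windows
are half-open [a, b) so the five canonical windows partition 12–240 ms.
Aggregated networks subtract the pre-stimulus baseline network
(entrywise), centring stationary nulls on zero; graph metrics then operate
on the positive part.

## Graph metrics

Edge weights convert to path lengths by reciprocal (the brain-connectivity
convention that stronger coupling = shorter path). Edge betweenness counts
all-pairs shortest paths through each directed edge with equal fractional
attribution among ties (networkx; validated exhaustively against a
brute-force path-enumeration oracle on all 4-node digraphs, 2000 random
5-node digraphs and 50 random weighted 6-node digraphs). Degree is in+out
on the thresholded, binarized graph. Only the ipsilateral-frontal
electrode list is fixed by the protocol (Fp1, AF7, AF3, F7, F5, F3, F1,
FT7, FC5, FC3, FC1); the other three macro areas are reconstructed by
left-right mirroring and by the anterior→posterior row mapping
Fp→O, AF→PO, F→P, FT→TP, FC→CP. This reconstruction is overridable by
configuration and may differ from the original assignment, which was never
printed.

## Statistics

Zero differences are discarded before ranking (classical Wilcoxon
treatment). The exact null distribution is used for n ≤ 25 pairs, the
normal approximation with continuity correction beyond. Edge and degree
contrasts are uncorrected at α = 0.001; the GMFP comparison alone is
Bonferroni-corrected over samples at α = 0.05. Degree contrasts pair
pooled values on (subject, electrode). Edges with fewer than five nonzero
paired differences are untestable and reported as not significant. On
fully null synthetic studies (18 subjects, 200 seeds) the significant-edge
fraction at α = 0.001 measures ≈ 0.001, within the 0.005 control bound.

## The synthetic-data generator

The generator emulates the study conditions: 18 subjects, two sessions
(O1/O2), 59-channel 10-10 montage (configurable; a 12-channel symmetric
subset is the quick-run default), 500 Hz epochs, 6 blocks × 60 trials,
randomized pre-interval 700–1000 ms, 2000 ms response window, 1300 ms ITI.
EEG is drawn from a stable time-varying VAR with diagonal self-coupling
0.5 (lag 1), prescribed directed couplings in prescribed ms windows,
internal burn-in of 10·p samples, and optional log-normal per-trial
innovation scaling (sweep nonstationarity). An evoked potential — a sum of
Gaussian-damped deflections peaking at 18, 36, 70, 108 and 180 ms with a
deterministic, mirror-symmetric spatial topography — is added
post-stimulus. Phosphene reports are Bernoulli draws from the logistic
psychometric function. Amplitudes and signal-to-noise ratios are free
parameters of the generator, not calibrated to any recording; passing
tests therefore demonstrate correctness of the machinery under the
generative model (linear dynamics, additive smooth EP, AR background),
not performance on real EEG with volume conduction, artifacts or
non-autoregressive noise.

## Problem sizes

Validation experiments run at deliberately compact sizes chosen as this
package's own defaults: STOK recovery at d = 3, 200 trials, 300 samples;
the Bayesian-vs-CA comparison at 1 channel, 30 sweeps of 120 post-stimulus
samples, 100 seeds; type-I control at d = 4, 24 trials, 18 subjects, 200
seeded studies; the planted-effect study at 12 channels, 60 trials, 18
subjects with an O1→F4 coupling of 0.35 confined to 48–92 ms. The full
battery completes in minutes on one CPU; all sizes scale up by
configuration.

## Known limitations

- No volume conduction, realistic TMS artifacts, ICA, re-referencing or
  trial rejection: the pipeline expects cleaned epochs.
- The Bayesian smoother assumes the evoked potential is smooth at the
  scale of its integrated-noise prior; deflections much narrower than
  ~5 samples are attenuated.
- STOK tracking latency is bounded below by λ_min: about ln 2 / (1−λ_min)
  ≈ 14 samples to half height at the default bound.
- The macro-area electrode lists (three of four) are reconstructions.
- Betweenness on weighted graphs uses reciprocal lengths; other monotone
  weight-to-length maps would change tie structure.
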