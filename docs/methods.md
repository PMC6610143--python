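# Methods

This note records the models implemented in `livespot`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical details a user re-deriving our numbers would
need.

## Synthetic data (`livespot.synth`)

**Motion models.** Tracks are simulated in µm. Brownian emitters take
per-axis Gaussian steps of variance `2·D·dt` with *reflecting* boundaries
(keeps the emitter density constant without birth/death bookkeeping);
bound emitters sit at a fixed anchor with i.i.d. Gaussian jitter
(`jitter_sd`, default 30 nm — the scale of residual chromatin motion plus
localization error); motored emitters alternate constant-velocity directed
runs and diffusive pauses according to an explicit segment schedule. An
optional `mobility_field(x, y)` scales D locally to emulate spatially
structured mobility such as reduced motion near the nuclear periphery.

**Camera model.** Each visible emitter is rendered as an isotropic 2-D
Gaussian of width `psf_sigma_px` (default 1.0 px ≈ 130 nm at the default
×100 pixel scale — a diffraction-limited spot is about one pixel wide
there) and amplitude `photons_per_spot` on a constant background; the
expected image is Poisson-sampled and Gaussian read noise added. This is
the simplest model that reproduces realistic localization error; we do not
model pixel-dependent sCMOS noise maps, 3-D PSFs, or illumination
geometry. Defaults give peak SNR ≈ 5–20 — chosen for solvable
localization, not to match any particular instrument.

**Photophysics.** Sparse-tracking movies use a pulsed-activation schedule:
emitters start dark (fraction configurable), an activation pulse every
`activation_pulse_period` (default 10 s) switches each dark emitter on
with fixed probability, and active emitters bleach irreversibly at
`bleach_rate` per second. States update per frame with the exact
exponential bleaching probability `1 − e^{−λ·dt}`.

**Kinetic traces.** FRAP traces follow
`I(t) = I_post0 + mobile_fraction·bleach_depth·(1 − e^{−k·t})` after an
instantaneous bleach, with an optional common acquisition-bleaching factor
`e^{−λt}` multiplying both the bleach-spot and whole-compartment series
(so double normalization can cancel it exactly). SPR sensorgrams follow
the pseudo-first-order one-to-one model:
association `R(t) = R_eq(1 − e^{−(k_on C + k_off)t})` with
`R_eq = R_max·C·k_on/(C·k_on + k_off)`, dissociation
`R(t_a)·e^{−k_off·Δt}`. Both generators agree with these closed forms
exactly at zero noise; tests rely on that.

**Run-off scenes** place spots uniformly per cell; each channel-0 spot
disappears at `drug_time + Exp(runoff_rate)` while channel-1 (mRNA
analogue) spots persist. **Embryo sequences** draw nuclei as bright disks
in a marker channel plus probe/target channels whose nuclear enrichment
follows a linear ramp (default 1 → 2.5); divisions are synchronous every
`division_period_frames`, daughters displaced along alternating axes with
the spacing scale halving and the radius dividing by √2 (area halves) per
generation. Real embryos have asynchronous divisions, chromatin texture
and z-structure; the generator trades those for exactly known per-frame
ground truth, so passing tests demonstrate correctness of the
measurement code, not robustness to every real-world artifact.

## Localization (`livespot.localize`)

Coordinates are 0-based, x = column, y = row, origin at the center of the
top-left pixel; public tables carry both px and µm. Detection: difference
of Gaussians (defaults σ = 1 and 3 px, a spot-sized passband), binarized
at mean + 3·SD of the bandpassed frame (Otsu available), connected
components of ≥ `min_area` (default 3 px²) reduced to intensity-weighted
centroids. Refinement: trust-region least squares of the elliptical
Gaussian over an 11×11 window (half-width 5), initialized at the window
minimum / peak excess / moment widths; widths are bounded below at
0.05 px and the moment initializer floored at 0.5 px to avoid collapse.
Optimizer failure or a flat window returns `converged=False` and the
detection centroid is kept. Adding a constant to the window shifts only
`I_BG` — verified to 1e−9.

Drift is estimated per frame against a reference by phase
cross-correlation with upsampled-DFT sub-pixel refinement (factor 50);
featureless frames report zero drift with `confident=False`. Channel
registration pairs bead localizations by mutual nearest neighbor within a
3 px gate (prevents many-to-one pairing) and fits translation /
similarity / affine by least squares, reporting the residual RMSE;
residuals can only decrease along that model ladder on fixed pairs.

## Linking and the bound filter (`livespot.linker`)

Frame-to-frame assignment is greedy by ascending candidate distance,
one-to-one, with exact ties broken toward the lower (deterministically
sorted) localization index — chosen over per-track independent claiming
so that conflicts resolve identically regardless of input row order.
`memory_frames` defaults to 0 (no gap closing): the bound filter requires
strictly consecutive frames, so gap-closed tracks would be discarded
anyway. The bound filter keeps tracks with ≥ 16 consecutive frames whose
jumps are all strictly below 220 nm — the standard criterion for
separating chromatin-bound from freely diffusing molecules at tens-of-ms
cadences. Default linking gates: 220 nm/frame for sparse bound-molecule
tracking, 1.5 µm/frame for translation-site movies at 0.5–1 Hz.

## Mobility (`livespot.mobility`)

MSD is time-averaged within each track over all ordered pairs of a given
lag, then averaged across tracks (unweighted), with across-track SEM as
the error bar. The diffusion coefficient comes from an OLS line through
the first five lags with a *free intercept* (absorbs static localization
error, which adds a constant 4σ² offset to every lag). The 95% CI on D
propagates the per-lag across-track SEMs through the OLS slope
coefficients and multiplies by the t quantile (3 degrees of freedom):
residual-based slope errors are meaningless here because the ensemble
curve is almost exactly straight while its sampling error is not. On
100-replicate simulations at the study scale (401 tracks × 30 frames,
dt = 2 s, 30 nm noise) this CI covers the true D in ≥ 90% of replicates
with a half-width of a few 10⁻³ µm²/s. A negative fitted slope is
reported as-is and flagged.

Directed-motion detection smooths the *velocity vector* with a centered
3-step moving average and thresholds its magnitude (default 1 µm/s,
≥ 3 consecutive samples). Vector averaging is the load-bearing choice:
Brownian steps largely cancel inside the window (false-positive rate
< 1% of tracks at D ≤ 0.1 µm²/s) while motor-driven runs keep their full
speed. Event boundaries are the positions spanned by the above-threshold
samples; reported path length sums the raw steps across the event.

## Kinetics (`livespot.kinetics`)

FRAP uses double normalization: background-subtract both series, divide
each by its own pre-bleach mean, and take the ratio — acquisition
photobleaching common to both channels cancels identically. (The
full-scale single-channel variant is available behind `mode="full_scale"`.)
Recovery is fit as a single exponential by default — the double
exponential is provided but the single model is the default because the
synthetic traces and most practical recoveries are adequately described
by one rate; `t_half` is read from the fitted model (ln2/k for the single
exponential; numeric half-rise for the double), not from a raw-curve
crossing, for noise robustness. `mobile_fraction = (plateau − I₀)/(1 − I₀)`;
an essentially flat recovery (A < 1e−4) reports t_half as missing.

SPR fitting is global across concentrations with shared `k_on`, `k_off`,
`R_max` (per-curve fitting available for diagnostics), parameterized in
log space with the analyte concentration rescaled to its maximum so the
optimizer sees O(1) quantities. `K_D = k_off/k_on` by construction.
Standard errors come from the Jacobian-based covariance at the optimum;
the K_D error uses the log-space delta method including the k_on–k_off
covariance. One concentration with association data only is rejected as
unidentifiable (only `k_obs = k_on·C + k_off` is constrained).

## Region quantification (`livespot.quantify`)

Ring masks use a disk (Euclidean) structuring element: ring =
dilate(nuclei, 4 px) \ dilate(nuclei, 1 px), clipped at frame edges, with
pixels contested by neighboring rings assigned to the nucleus with the
smaller Euclidean distance (via the exact distance transform) —
deterministic and verified against brute-force pixel enumeration. Ratios
are means of raw intensities (no background subtraction by default), so
they are invariant under positive scaling. The signal/background variant
takes an explicit caller-supplied background mask, since "background" is
experiment-specific. Ratio-of-means SEM uses the first-order delta
method. Run-off curves normalize each cell by its own pre-drug mean
count and average across cells with cell-to-cell SEM; cells without
pre-drug spots are excluded (logged); `spot_counts` materializes explicit
zeros so late frames are not biased toward surviving cells. Quantiles in
`summarize_distribution` interpolate linearly between order statistics
(box-whisker panels depend on the rule, so it is fixed and stated).

Nucleus lineage tracking assigns each nucleus at t+1 to the previous
lineage whose 6-px-dilated mask it overlaps most (ties to the lower
label); daughters thrown clear of the parent at division fall back to the
nearest previous centroid within 50 px. A parent with two or more
children is a division and every child starts a new branch recorded
against the parent. Segmentation is threshold (Otsu default) + connected
components + minimum area; touching nuclei are *not* watershed-separated
— the generator keeps nuclei separated, and real clumped fields would
need an upstream splitter.

## Problem sizes

Tests and the acceptance script use ensembles sized for exact, fast
ground-truth checks: 250-emitter bound/free populations, 401- and
285-track diffusion ensembles (100 seeded replicates for the CI-coverage
property), 49-spot rendered fields over 10–15 frames, 12 noisy FRAP
traces, two-concentration sensorgrams, 8-cell run-off scenes and
21-frame embryos. These choices are the package's own validation scale;
all generators accept larger sizes.

## Known limitations

No maximum-likelihood (Poisson) localization or astigmatic 3-D fitting;
no LAP/Kalman multi-hypothesis tracking; no anomalous-diffusion exponent
or HMM state segmentation; no reaction–diffusion FRAP or mass-transport
SPR models; max-projection 2-D segmentation only. The synthetic generator
is a validation instrument, not a microscope simulator: camera gain is
unity, PSFs are Gaussian, and nuclei are disks.
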