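# livespot

Quantification pipeline for live-cell single-molecule and translation-site
fluorescence imaging, with a built-in synthetic-data generator for
validation.

Modern epitope-tag imaging experiments — tracking single tagged histones,
watching nascent peptide chains on single mRNAs, measuring probe binding by
FRAP and SPR, or following tagged-protein expression through embryo
development — all reduce to a small set of custom computations that sit
between the microscope and the figures:

- **Spot localization** — bandpass → binarize → intensity-centroid
  detection, refined by nonlinear least-squares fitting of an elliptical
  2-D Gaussian
  `I(x,y) = I_BG + I·exp(−(x−x₀)²/2σx² − (y−y₀)²/2σy²)`,
  plus drift correction and dual-camera registration from bead fiducials.
- **Track linking** — greedy nearest-neighbor linking, with the
  bound-molecule filter (≥ 16 consecutive frames, every frame-to-frame
  jump < 220 nm) used to isolate chromatin-bound molecules.
- **Mobility analysis** — time-averaged/ensemble MSD with across-track SEM,
  diffusion from the first five lags via the 2-D Brownian slope relation
  `m = 4D`, per-track mobility maps, and directed-transport event detection
  above a 1 µm/s velocity threshold.
- **Kinetic fitting** — double-normalized FRAP recovery
  `I(t) = I₀ + A(1 − e^{−kt})` with `t_half = ln2/k`, and global one-to-one
  SPR binding fits with `K_D = k_off/k_on`.
- **Region quantification** — nuclear segmentation, perinuclear ring masks
  (dilate 4 px minus dilate 1 px), nuclear/cytoplasmic and
  signal/background ratios, ratio-of-means with delta-method SEM, drug
  run-off survival curves, colocalization, and nucleus lineage tracking
  through divisions.

Every stage can be exercised against the `livespot.synth` generator, which
produces movies and traces with exactly known ground truth: Brownian /
bound / motored emitters rendered as Gaussian spots on a Poisson + read-noise
camera, photoactivation–bleaching schedules, FRAP and SPR closed-form
traces, drug run-off scenes, and dividing-embryo nuclear sequences.

## Worked example

Fit one-to-one binding kinetics to two noisy synthetic sensorgrams:

```sh
$ python analysis/05_spr.py --seed 1
k_on = 9.96e+04 /M/s, k_off = 0.00147 /s, K_D = 14.7 nM (true 14.7 nM)
```

The script simulates association/dissociation curves at 100 and 30 nM
analyte with 2% noise, fits them globally with shared `k_on`, `k_off` and
`R_max`, and reports the dissociation constant — here recovered within a
fraction of a percent of the generator's truth.

The other numbered scripts under `analysis/` work the same way
(`--seed`, `--outdir`; tables land in `results/`):

```sh
$ python analysis/03_translation_site_diffusion.py --seed 1
species_a: n=401 tracks, true D=0.016, fitted D=0.0154 +/- 0.0010 um^2/s (95% CI)
species_b: n=285 tracks, true D=0.019, fitted D=0.0190 +/- 0.0014 um^2/s (95% CI)

$ python analysis/07_embryo.py --seed 1
counts: 4 -> 8 -> 16 nuclei
mean nuclear area: 453 -> 112 px^2
mean Nuc/Cyt ratio: 1.00 -> 2.50 (generated ramp 1.0 -> 2.5)
```

There is also a YAML-configured CLI for chaining stages
(`livespot run config.yaml`, stages `simulate → localize → track → msd`
etc.); see `livespot/pipeline.py` for the config schema.

## Layout

```
src/livespot/     library: synth, localize, linker, mobility, kinetics,
                  quantify, io, pipeline, cli
analysis/         numbered narrative drivers writing tables to results/
tests/            pytest suite (unit, property and end-to-end acceptance)
docs/methods.md   models, parameter choices, numerical details, limitations
```
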