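# Methods

## The compartmental bouton model

A bouton carries a fixed mass of pHluorin-tagged transporter, normalized to
1, distributed over compartments that differ only in the pH the reporter
sees:

- **q** — quenched vesicular pool at luminal pH 5.5;
- **s** — plasma-membrane surface pool at bath pH (7.4 in Tyrode's, 5.5
  during an acid-quench epoch);
- **b** — internalized but still-alkaline pool at pH 7.4, populated only when
  bafilomycin blocks the v-ATPase ("alkaline trapping");
- **a** — a transient internalized pool awaiting reacidification, used only
  when a nonzero reacidification time constant is configured (default 0:
  reacidification is treated as instantaneous, consistent with its being much
  faster than the frame interval).

Fluorescence is the brightness-weighted sum over compartments,
F(t) = T · Σᵢ mᵢ(t)·β(pHᵢ), with T the total-pool fluorescence. Brightness
follows the pHluorin titration curve β(pH) = f(pH)/f(7.4),
f(pH) = 1/(1 + 10^(pKa − pH)), pKa = 7.1 — normalized so that full
alkalinization (50 mM NH₄Cl, all compartments at pH 7.4) reads exactly T.
The quenched pool then retains β(5.5) ≈ 3.7% of its alkalinized brightness,
which is what makes the resting baseline F₀ nonzero even with no surface
pool.

### Kinetics

- **Endocytosis**: the surface excess above the resting membrane level m
  relaxes at first-order rate 1/τ_endo at all times (during and after
  stimulation). Under bafilomycin the retrieved mass enters **b** (bright);
  otherwise it returns to the quenched pool. Mass retrieved while the train
  is still running rejoins the reserve (non-releasable) part of the quenched
  pool — a bookkeeping choice that keeps the kinetics an exactly solvable
  triangular linear system and affects no measured quantity.
- **Exocytosis (exponential mode)**: the cumulative fraction of the
  recycling pool released after t seconds of stimulation is
  (1 − e^(−t/τ_exo)) / (1 − e^(−90/τ_exo)). The 90-s normalization encodes
  the defining property of the recycling-pool parameter — `rp_frac` *is* the
  fraction released by the standard 900-AP, 10 Hz, 90-s train — while the
  rising phase keeps the single-exponential shape with time constant τ_exo.
  Without the normalization a pure exponential with the wild-type τ_exo
  (~27 s) would leave ~4% of the pool unreleased at 90 s, contradicting the
  plateau the recycling-pool assay reads; with it, the plateau estimator
  (mean of the last three stimulation frames) recovers `rp_frac` to ~0.5%.
- **Exocytosis (linear mode)**: when `exo_rate_linear` is set, release is a
  constant ramp producing exactly that ΔF/F₀ per second, capped at the
  recycling pool. This mode exists so the linear-slope estimator can be
  validated against an exactly linear generative rise.
- **RRP burst rule**: trains at ≥ 30 Hz and hypertonic sucrose move the
  readily releasable pool to the surface as a linear ramp completing 1 s
  after stimulus onset (even when the train itself is shorter, e.g.
  100 Hz × 0.2 s). This matches the three burst-type RRP estimators without
  modelling per-action-potential release. A ≥ 30 Hz train longer than 1 s
  continues with exponential release of the remaining recycling pool.
- **FM4-64 destaining** is modelled separately as single-exponential
  unloading of the dye in the recycling pool (time constant `tau_fm`),
  monotone non-increasing; only monotonicity and ΔF/F₀ plumbing are
  validated against it.

### Integration

Within each frame interval the active rates are piecewise constant, so the
state is advanced by the exact closed-form solution of the linear system,
splitting at epoch/segment boundaries. With noise off the simulator is
deterministic and agrees with the analytic solution to machine precision;
transporter mass is conserved identically (asserted to 1e−9 in tests, which
also cross-check against an independent 1-ms forward-Euler integration).
Measurement noise is additive Gaussian per frame (photon shot noise is not
modelled); negative noisy values are clipped at zero. Frame exposure time is
ignored — fluorescence is sampled instantaneously at frame times.

### Assay-defined parameterization

The pool parameters are defined as what the assays read out, because those
are the only observable definitions:

- `surface_frac` is the value of (F₇.₄ − F₅.₅)/F_NH₄Cl. Internally the
  membrane mass is m = surface_frac/(1 − β(5.5)), slightly larger than the
  assay value because a membrane transporter still fluoresces β(5.5) at
  pH 5.5.
- `rp_frac` and `rrp_frac` are fractions of the *net* total pool
  (NH₄Cl minus baseline), i.e. of the internal vesicular pool — matching the
  denominators of the RP/RRP estimators. Note the two denominators the field
  uses are intentionally not harmonized: pool fractions divide by the net
  total, while the surface fraction divides by the raw NH₄Cl total; the
  package implements each formula as stated.

With this parameterization, noiseless simulate → quantify round trips
recover every generative constant within 1% (most exactly; the RP plateau
read carries the ~0.5% finite-train residual described above).

## Estimators: numerical choices

- **Endocytosis fit** y = A·e^(−(t−t₀)/τ) + C over frames with
  t ≥ stim_end + 3 s (at 3-s framing this drops exactly one frame), stopping
  before any later bath epoch. The fit runs on raw fluorescence: τ is
  invariant to the F₀ scaling, and under noise the noisy five-frame F₀ would
  shift a ΔF/F₀-based asymptote against the offset's lower bound and bias τ
  low. Initialization τ₀ = window/3, A₀ = first − last, C₀ = last; bounds
  A ≥ 0, τ ∈ (0, 10·window], C ∈ [0, first fitted value]; trust-region least
  squares with 1e−14 tolerances. A segment whose first fitted value does not
  exceed its last is flagged `non_decaying` (τ = NaN) rather than fit — the
  expected outcome for endocytosis-dead mutants. Fits with τ longer than the
  window are flagged `wide` (poorly constrained). Tests pin the fitter to a
  dense grid-search oracle over τ ∈ [1, 500] s.
- **Per-bouton vs ensemble-mean fitting**: per-bouton fitting followed by
  averaging is the default. When per-frame noise is comparable to the decay
  amplitude the per-bouton τ distribution becomes heavy-tailed and its mean
  unstable, so `ensemble_tau_decay(mode="ensemble_mean")` fits the
  frame-averaged trace instead; the noise-robustness checks use this mode.
- **Linear exocytosis rate**: OLS slope of ΔF/F₀ over
  stim_start ≤ t ≤ stim_start + 15 s, endpoint inclusive.
- **RP plateau**: mean of the last three stimulation frames (the plateau
  window is not otherwise pinned down by the assay definition).
- **Peak detection** for decay-from-peak: raw frames, no smoothing, earliest
  frame wins ties.
- **Surface fraction**: negative values within noise are clamped to 0 with a
  warning; values above 1 are rejected as physically impossible.
- **t-tests**: equal-variance Student's t by default (the historical default
  of the common graphing software), Welch behind a flag; no multiple-testing
  correction. Zero variance in both groups with equal means yields p = 1 by
  convention; with unequal means it is reported as a degenerate-input error.
- **Unit of analysis** is the coverslip: boutons are averaged within
  coverslips and SEM is computed over coverslip means, unweighted by bouton
  count.

## Synthetic images and detection

Puncta are isotropic Gaussians (default σ 1.8 px, matching ~1–2 µm boutons
at typical magnification) on a uniform background with additive Gaussian
noise; centers keep ≥ 4 px from borders and a minimum pairwise separation
(rejection sampling with a packing-limit error). Channel-2 spots appear
independently with probability `p_coloc`.

Detection thresholds at mean + k·sd (k = 3 default) — a documented stand-in
for proprietary auto-thresholding — keeps connected components of ≥ 4 px
(rejecting singleton noise pixels), reduces each to its intensity-weighted
center, merges centers closer than `min_separation`, and emits 4×4 boxes
(0-based, half-open). An ROI is colocalization-positive when its 4×4 mean in
the other channel exceeds that channel's mean + k·sd/√16 — the k-sigma rule
applied at the level of the statistic actually compared; a pixel-level k·sd
cut on a 16-pixel mean would be far off-scale. Seeded batches verify
precision and recall ≥ 0.95 at spot SNR 5 and colocalization bias within
2 points at 200 puncta.

## Presets and protocols

Genotype presets carry the kinetic constants of each condition
(`VGLUT2`: τ_endo 25.20 s, τ_exo 27.16 s, RP 51.73%, RRP 5.32%, surface
2.4%; `VGLUT1`: 14.18 s / 17.71 s / 53.38% / 7.24%; mutants, chimeras,
knockdowns, and thalamic variants analogously). Fields without a
condition-specific measurement inherit the wild-type hippocampal value —
presets are kinetic phenotypes, not mechanistic models of adaptor-protein
biology. Ensemble simulation supports mean-preserving lognormal jitter
(sd 10%) on τ_endo and the recycling-pool fraction, off by default so
deterministic tests see preset values exactly.

Protocol builders place five rest frames before the first stimulus (required
by the F₀ definition), use the acquisition interval conventional for each
stimulus class (3 s for 10/40 Hz trains, 6 s for the 5-min 5 Hz train, 1 s
for RRP bursts), and end with a five-frame NH₄Cl epoch except the FM4-64
protocol. Post-stimulus recovery lengths are builder arguments
(e.g. `get_protocol("10Hz60s", recovery_s=600)` for slow mutants).

## What the synthetic data do and do not show

The generator reproduces the statistical structure the estimators assume:
quenched baseline, stimulation-evoked rise, exponential recovery, alkaline
trapping, bath-exchange readouts, and additive frame noise. It does not
model per-AP release, calcium dynamics, photobleaching, focus drift, bulk
endosome intermediates, or shot noise — so passing recovery tests validates
the estimators and their implementation, not the biological fidelity of any
particular kinetic claim on real data. Quantities that emerge from the
model's balance of exo- and endocytosis during stimulation (decay-from-peak,
time-to-peak) are internally consistent but depend on the simplified release
model; they are exercised for arithmetic correctness, not matched to any
particular experimental ensemble.

## Problem sizes

Stochastic checks use 100-bouton ensembles (4 coverslips × 25 boutons) at
2% additive noise, 20-image detection batches, 50-seed colocalization
batches at 200 puncta, and 20-replicate power simulations at 10 coverslips —
sizes comparable to the experiments the package targets.
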