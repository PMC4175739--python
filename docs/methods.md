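# Methods

`pcmfrap` quantifies fluorescence-recovery-after-photobleaching (FRAP) movies
of centrosomes to distinguish two candidate mechanisms of pericentriolar
material (PCM) assembly:

- **Inside-out flux** — scaffold subunits are incorporated only in a narrow
  zone around the centriole and then move outward through the PCM, turning
  over at the periphery.  Recovery after a bleach starts as a narrow central
  peak that spreads outward over time.
- **Distributed binding-site exchange** — subunits exchange with the cytosol
  at binding sites spread throughout the PCM volume.  Recovery occurs at the
  same fractional rate everywhere, so the recovering profile is an
  amplitude-scaled copy of the pre-bleach profile at every time point.

The package contains a mechanistic simulator for both mechanisms, an
image-plane renderer with a simple camera model, a radial-profiling pipeline,
recovery-kinetics estimators, a rule-based mechanism classifier, and the
population statistics used for fixed-tissue comparisons.  Everything runs on
synthetic data; no real images ship with the package.

## 1. Ring-chain mechanistic model

The PCM around one centrosome is modelled as `n_rings` concentric annular
compartments of equal radial width `ring_width`, starting at `inner_radius`
(a non-zero inner radius makes the incorporation zone a toroid around the
centriole).  Ring `i` (0-based) holds an amount `C_i` of scaffold protein.
Two pools are integrated with identical dynamics: the **total** pool and the
**fluorescent** pool; photobleaching instantaneously reduces only the
fluorescent pool.

**Flux model** (influx `J`, ring-to-ring transfer rate `a`, peripheral loss
`k_loss`; loss acts on every ring, transfer out of the last ring is absent):

```
dC_0/dt = J          + a·C_{-1}(=0) − a·C_0 − k_loss·C_0
dC_i/dt =              a·C_{i−1}    − a·C_i − k_loss·C_i     (0 < i < n−1)
dC_{n−1}/dt =          a·C_{n−2}             − k_loss·C_{n−1}
```

The steady state is closed-form: `C_0 = J/(a + k_loss)`,
`C_i = C_{i−1}·a/(a + k_loss)` for interior rings,
`C_{n−1} = C_{n−2}·a/k_loss`, and total mass `Σ C_i = J/k_loss`.  The
outward advection speed is `v = a·ring_width`.

**Distributed model** (site density `ρ_i` per ring, exchange rate `k_ex`):

```
dC_i/dt = k_ex·(ρ_i − C_i)
```

After a uniform bleach of efficiency `e` at `t = 0` the fluorescent fraction
recovers as `f(t)/f(∞) = 1 − e·exp(−k_ex·t)` in **every** ring — the "even
recovery" signature.

**Integration.**  Both models are linear affine systems `x' = A x + b`.
They are integrated exactly (to machine precision) with the matrix
exponential of the augmented `(n+1)×(n+1)` system
`[[A, b], [0, 0]]`: `x(t+Δ) = E[:n,:n] x(t) + E[:n,n]` with
`E = expm(Δ·M)`.  Propagators are cached per distinct `Δ`, so irregular
frame-time grids cost one `expm` per unique spacing.  There is no
time-discretization error; accuracy is limited only by `scipy.linalg.expm`.

**Bleaching.**  A bleach event at time `t_b` multiplies the fluorescent pool
of each ring by `1 − e·ω_i`, where `ω_i` is the area fraction of ring `i`
inside the bleach disk (computed from exact circle–annulus overlap).  A frame
sampled exactly at `t_b` reports the **post**-bleach state.

### Default parameters

| parameter | flux | distributed |
|---|---|---|
| `n_rings` | 20 | 20 |
| `ring_width` (µm) | 0.14 | 0.14 |
| `inner_radius` (µm) | 0.15 | 0.15 |
| `J` (amount/s) | 1.0 | — |
| `transfer_rate` `a` (1/s) | 0.02 | — |
| `k_loss` (1/s) | `a/9 ≈ 0.00222` | — |
| `ρ` | — | flux steady state |
| `k_ex` (1/s) | — | 0.01 |

These were fixed at design time from physical considerations: the chain spans
0.15–2.95 µm (centriole-proximal toroid out past the PCM edge);
`k_loss = a/9` gives a per-ring retention ratio `a/(a+k_loss) = 0.9`, i.e. a
gently decaying steady-state profile with most mass in the inner micron; the
flux steady state is reused as the distributed site density `ρ` so both
models produce the *same* pre-bleach spot and differ only in recovery
dynamics; `k_ex = 0.01/s` gives a recovery half-time of ~69 s, comparable to
the flux model's refill timescale, so classification cannot key on overall
recovery speed.

## 2. Image formation

`render_movie` converts ring amounts into camera frames:

1. Each ring's amount is spread uniformly over its annulus area and the
   resulting radial density is convolved with an isotropic Gaussian
   point-spread function (PSF) of width `psf_sigma` (analytically, via the
   Gaussian-annulus radial convolution using `scipy.special.ive`).
2. The continuous image is integrated over camera pixels of size
   `camera_pixel`.
3. Expected counts are `gain · amount + background`; shot noise is Poisson
   on that expectation and read noise is additive Gaussian
   (`read_noise_sd`), both per pixel per frame.

Defaults: `psf_sigma = 0.11 µm` (super-resolution-like imaging is emulated
by halving a conventional 0.22-µm sigma), `camera_pixel = 0.14 µm`,
`gain = 200`, `background = 100`, `read_noise_sd = 2`.  The camera pixel is
chosen as exactly five profiler ring spacings (5 × 0.028 µm) so analysis
upsampling lands on the ring grid.

A `simulate_bead_image` helper renders a uniform disk (default diameter
170 nm) through the same optics for width-calibration studies; its oracle is
the disk⊗PSF convolution evaluated by direct quadrature.

## 3. Radial profiling

`profile_movie` reduces a movie to a `ProfileSet` — one averaged radial
profile per frame:

1. **Upsample** each spot crop by an integer factor (default 5; 0.14-µm
   camera pixels → 0.028-µm subpixels, block replication so the mean is
   preserved).
2. **Centre**: intensity-weighted centroid of above-threshold pixels of the
   brightest plane.
3. **Ring averages**: mean subpixel intensity in concentric rings of width
   0.028 µm (107 rings over a 3-µm span by default; rings extending past
   the field are NaN).  Ring membership is half-open: a subpixel at distance
   `d` belongs to ring `⌊d/spacing⌋`.
4. **Background**: median in a cytosolic annulus, subtracted once (double
   subtraction is an error).
5. **Average** across ≥10 centrosomes (`min_n` enforced; grids must match).
6. **Normalize and mirror** for width measurements: divide by the peak and
   reflect about r = 0, giving the symmetric profile on which
   `profile_fwhm` measures full width at half maximum by linear
   interpolation of the half-crossings (profiles that never fall below half
   maximum raise `UnboundedWidthError`).

## 4. Recovery kinetics

All recovery analyses operate on **residual-subtracted** profiles
(`recovery_profiles`): the first frame at or after each bleach is taken as
that bleach's residual baseline and subtracted from every later frame up to
the next bleach.  This isolates the signal *gained since the bleach* —
standard FRAP practice — so a 5 % unbleached residual with pre-bleach shape
cannot mask the shape of the newly added material.  Baseline frames are
excluded from the analysed series.

- **ROI curves** (`roi_curve`): mean intensity over the rings in a radial
  band.  Default bands: central 0.028–0.14 µm and peripheral 0.62–0.73 µm
  (five rings each at the default grid).  Band membership uses the ring
  mid-point with a half-spacing tolerance and a `1e-6·spacing` guard against
  float round-off at the half-open upper bound.
- **Initial rates** (`initial_rate`): least-squares slope over the first
  60 s after a bleach, with standard error.
- **Acceleration index** (`acceleration_index`): quadratic coefficient of a
  degree-2 fit to a recovery curve.  Peripheral recovery accelerates
  (positive index) under flux — material must transit the chain before
  arriving — and decelerates (negative, saturating exponential) under
  distributed exchange.
- **Double-bleach comparison** (`double_bleach_compare`): initial central
  and peripheral rates after the first and second bleach; under both
  mechanisms the rates reset, so the ratios are ≈1.
- **FWHM series** (`fwhm_series`): width of each residual-subtracted
  recovery profile after peak normalization and mirroring; unmeasurable
  frames (unbounded width, non-positive peak) are skipped.
- **Spread index** (`spread_index`): least-squares slope of FWHM versus
  time with a t-statistic.
- **Shape deviation** (`shape_deviation`): for each recovery profile, the
  pre-bleach profile is fitted by least-squares amplitude
  (`α = Σ rec·pre / Σ pre·pre` over finite rings), the residual
  `rec − α·pre` is boxcar-averaged over 5 rings (one camera-pixel width at
  5× upsampling — sub-pixel rings oversample the camera grid, so unaveraged
  ring noise is strongly correlated), and the maximum absolute averaged
  residual is reported as a fraction of the pre-bleach peak.  The
  least-squares amplitude avoids the 1/amplitude noise blow-up of
  peak-matching at early, dim time points.

### Mechanism call

`classify_mode` applies declared thresholds (`ModeThresholds`):

- **inside_out** iff the earliest measurable recovery FWHM is < 0.8 of the
  pre-bleach FWHM **and** the FWHM slope is positive with |t| > 2;
- **distributed** iff the maximum shape deviation is < 0.05 of the
  pre-bleach peak;
- otherwise **indeterminate**.

The thresholds were set midway between the two mechanisms' noise-free
signatures (deviation 0 versus ≈0.15–0.17 of peak; FWHM ratio ≈0.67 versus
≈1.0 at the defaults) before any test was run, and sit several noise
standard deviations from both.

## 5. Population statistics

For fixed-tissue-style group comparisons:

- `quantify_centrosome_box`: background-corrected integrated intensity in a
  box around a spot on a maximum-intensity z-projection.
- `brain_averages`: per-brain means (the brain, not the cell, is the
  statistical unit).
- `mann_whitney_u`: exact two-sided Mann–Whitney U when the pooled sample
  size is ≤ 12 and there are no ties, by full enumeration of all
  `C(n+m, n)` group assignments of the pooled ranks with
  `p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))`; otherwise the normal
  approximation with tie correction.
- `paired_rate_comparison`: paired t-test on per-pair differences plus a
  percent-reduction estimate `100·(1 − mean(treated)/mean(control))`; a
  zero-variance difference vector raises `DegenerateVarianceError` carrying
  the point estimate.
- `aster_percentage`: simple percentage summary with counts.

Simulated inputs come from `simulate_fixed_cell_table` (hierarchical
brain/cell Gaussian sampling) and `simulate_paired_rates` (paired control /
treated rates with multiplicative Gaussian noise).

## 6. Study protocols and reproducibility

`pcmfrap.protocols` composes simulator and analysis into the standard
in-silico experiments (classification batches, even-recovery,
profile-spreading, ROI kinetics, double-bleach, closed-form verification,
optical fidelity, test calibration, estimator recovery).  All randomness is
funnelled through `numpy.random.SeedSequence` fan-out from a single integer
seed; every pipeline output is byte-deterministic given (config, seed), and
`run_frap_pipeline` writes a manifest with the package version, the full
config, and a SHA-256 digest per output file.

Protocol constants: frame times −10…300 s (8 frames) for single-bleach
studies and 10-s sampling with a second bleach at 180 s for double-bleach
studies; 10 centrosomes averaged per condition; bleach efficiency 0.95 and
bleach radius 3 µm (whole-centrosome).  The double-bleach study uses
efficiency 1.0 and 16 centrosomes: with a partial second bleach the residual
is **not** in the centrally-concentrated near-steady shape — it has already
advected outward — which systematically inflates the post-second-bleach
peripheral rate (≈12 % at efficiency 0.95, noise-free); a complete bleach
removes that confound exactly, and the extra averaging tightens the noisy
peripheral ratio.

Closed-form verification integrates to `t = 40/k_loss` (the slowest mode
decays as `exp(−k_loss·t)`, so the transient is ~`e^{−40}` of steady state)
and checks mass conservation on a closed chain (`J = k_loss = 0`).

## 7. Generator realism limits and other limitations

- The simulator is a radially symmetric, deterministic mean-field model:
  no molecular stochasticity, no azimuthal structure (flares, satellites),
  no centriole pair, no mitotic growth of the PCM during the movie, and no
  z-dimension (movies are single-plane).
- Camera noise is the only stochastic element of a movie; spot-to-spot
  biological variability is not modelled, so averaging over `n_centrosomes`
  reduces noise faster than in real data.
- The PSF is an isotropic Gaussian without depth dependence, and
  photobleaching by acquisition itself (monitor bleaching) is not modelled.
- The distributed model's site density is static; recruitment of *new*
  binding sites during mitosis is outside scope.
- The classifier's thresholds are calibrated for the default optics and
  grid; markedly different SNR or sampling may require re-examining them
  (they are explicit in `ModeThresholds`).
- Exact Mann–Whitney enumeration is limited to pooled sizes ≤ 12 with no
  ties; beyond that the tie-corrected normal approximation is used.

No empirical claim in this note goes beyond quantities computed by the code
in this repository (tests, `scripts/acceptance.py`, or the worked examples
in the README).
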