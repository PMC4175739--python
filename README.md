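# pcmfrap

FRAP radial-profiling analysis of pericentriolar-material (PCM) assembly,
with a mechanistic ring-chain simulator.

## The scientific problem

Centrosomes organise the mitotic spindle by rapidly expanding their PCM — a
scaffold of proteins around the centriole.  Two mechanisms could explain how
new scaffold subunits are added:

- **Inside-out flux**: subunits are incorporated only in a narrow zone
  around the centriole and then move outward through the PCM, turning over
  at the periphery.
- **Distributed exchange**: subunits bind and unbind at sites spread
  throughout the PCM volume.

Fluorescence recovery after photobleaching (FRAP) distinguishes them.  After
bleaching a whole centrosome, inside-out flux predicts recovery that starts
as a *narrow central peak* and spreads outward, with peripheral signal
arriving late and accelerating; distributed exchange predicts recovery that
is an amplitude-scaled copy of the pre-bleach profile at every time point
("even recovery"), with decelerating kinetics everywhere.

`pcmfrap` implements the full quantification chain — radial profiling with
sub-pixel rings, residual-baseline subtraction, ROI recovery rates, profile
width (FWHM) series, a rule-based mechanism classifier — together with an
exact (matrix-exponential) two-pool ring-chain simulator and a camera model,
so every analysis can be exercised and validated end-to-end on synthetic
movies with known ground truth.  A small population-statistics module
(exact Mann–Whitney U, paired t, percent-reduction estimation) covers the
accompanying fixed-tissue-style group comparisons.

See [docs/methods.md](docs/methods.md) for models, parameters, numerical
choices, and limitations.

## Worked example (Python API)

Simulate an inside-out-flux FRAP study (10 centrosomes, whole-centrosome
bleach at t = 0, default camera noise), profile it, and quantify:

```python
from pcmfrap.protocols import simulate_frap_study, analyze_frap_movie
from pcmfrap.kinetics import RoiSpec, roi_curve, initial_rate, classify_mode

movie = simulate_frap_study("flux", seed=7)          # synthetic inside-out movie
pset = analyze_frap_movie(movie)                     # averaged radial profiles

roi = RoiSpec()                                      # central and peripheral bands
central = initial_rate(roi_curve(pset, roi.central))
peripheral = initial_rate(roi_curve(pset, roi.peripheral))
print(f"central initial rate:    {central.slope:.5f} per s")
print(f"peripheral initial rate: {peripheral.slope:.5f} per s")
print(f"central / peripheral:    {central.slope / peripheral.slope:.1f}")

call = classify_mode(pset)
print(f"mechanism call:          {call.call}")
print(f"early FWHM ratio:        {call.evidence['early_fwhm_ratio']:.3f}")
```

Output:

```text
central initial rate:    0.00940 per s
peripheral initial rate: 0.00047 per s
central / peripheral:    19.8
mechanism call:          inside_out
early FWHM ratio:        0.666
```

The central region recovers ~20× faster than the periphery, and the earliest
recovery profile is only 67 % as wide as the pre-bleach spot — the inside-out
signature.  Running the same code with `simulate_frap_study("distributed",
seed=7)` yields `mechanism call: distributed` with recovery profiles that
match the pre-bleach shape within a few percent of the peak.

## Worked example (CLI)

The same chain as three commands:

```console
$ pcmfrap simulate --model flux --seed 7 --out movie
wrote movie.tif and movie.json (8 frames, 10 centrosomes)
$ pcmfrap profile --movie movie --out profiles.json
wrote profiles.json and profiles.csv (8 time points, 10 centrosomes)
$ pcmfrap kinetics --profiles profiles.json --out kinetics.json
wrote kinetics.json; mode call: inside_out
```

`kinetics.json` then contains (abridged):

```json
{
  "central_rate_per_s": 0.009398378031406397,
  "peripheral_rate_per_s": 0.000474440935670681,
  "fwhm_spread_slope_um_per_s": 0.0012925946334091996,
  "fwhm_spread_t_stat": 10.497012346642824,
  "mode_call": {
    "call": "inside_out",
    "evidence": {
      "early_fwhm_ratio": 0.6658533987915828,
      "prebleach_fwhm_um": 1.0354918314528119,
      "shape_deviation_max": 0.1541908947012676
    }
  }
}
```

Other commands: `pcmfrap report` (simulate → profile → kinetics → manifest
in one step, fully config-driven via `--config run.yaml`), and
`pcmfrap fixed-stats` (hierarchical fixed-tissue group simulation and
Mann–Whitney comparisons).  All outputs are byte-deterministic given
(config, seed), and every `report` run writes a `manifest.json` with the
package version, the resolved config, and SHA-256 digests of each output.

## Package layout

| module | contents |
|---|---|
| `pcmfrap.simulate` | ring-chain ODE models (exact expm integration), closed forms, camera/PSF rendering, bead and statistics generators |
| `pcmfrap.images` | `ImageStack`, `FrapMovie`, `BleachEvent` containers |
| `pcmfrap.profiling` | upsampling, centring, ring averages, background, mirror/normalize, FWHM |
| `pcmfrap.kinetics` | residual-baseline recovery profiles, ROI rates, acceleration, double-bleach reset, FWHM spread, shape deviation, `classify_mode` |
| `pcmfrap.popstats` | box quantification, per-brain averages, exact Mann–Whitney U, paired t / percent reduction |
| `pcmfrap.protocols` | end-to-end in-silico studies used by the tests and the acceptance script |
| `pcmfrap.pipeline` / `pcmfrap.cli` | YAML-configured runs, manifests, `pcmfrap` command |

## Reproduction

Run the test suite (a few seconds; no network, no external data — all
fixtures are simulated at run time):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Run the acceptance battery, which executes every study protocol and writes
the headline quantities as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This records, among others: mechanism-classification accuracy over 40 movies
(20 per mechanism), the maximum distributed-model shape deviation, the flux
model's early-FWHM ratio and minimum FWHM increment, central/peripheral rate
ratio and peripheral accelerations, double-bleach rate-reset ratios,
ring-chain closed-form and mass-conservation errors, optical-model fidelity
(Gaussian-profile error, bead FWHM), Mann–Whitney type-I rate over 2000 null
replicates, and paired-reduction estimator recovery over 200 replicates.
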