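"""End-to-end study protocols on synthetic data.

Each function here composes the simulator and the analysis pipeline into one
of the standard in-silico experiments: mechanism-classification batches,
even-recovery and profile-spreading checks, central/peripheral kinetics,
double-bleach resets, estimator-recovery and test-calibration studies.  They
are what the test suite and ``scripts/acceptance.py`` run; all randomness is
funnelled through a single integer seed via ``numpy.random.SeedSequence``.

Problem sizes follow the source protocols where those state them (10
centrosomes averaged per condition, 60-s rate windows, a 180-s re-bleach);
movie frame counts and field layout are package choices documented in
``docs/methods.md``.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import ive

from .images import BleachEvent, FrapMovie, ImageStack
from .kinetics import (ModeCall, acceleration_index, classify_mode,
                       double_bleach_compare, fwhm_series, initial_rate,
                       roi_curve, shape_deviation, RoiSpec)
from .popstats import mann_whitney_u, paired_rate_comparison
from .profiling import (ProfileSet, RingGrid, normalize_and_mirror, profile_fwhm,
                        profile_movie, radial_profile, subtract_background)
from .simulate import (MechanisticParams, OpticsParams, default_distributed_params,
                       default_flux_params, render_movie, simulate_bead_image,
                       simulate_paired_rates, simulate_ring_chain)

__all__ = [
    "STUDY_GRID",
    "default_frame_times",
    "simulate_frap_study",
    "analyze_frap_movie",
    "classification_study",
    "even_recovery_study",
    "spreading_study",
    "roi_kinetics_study",
    "double_bleach_study",
    "ring_chain_verification",
    "gaussian_profile_fidelity",
    "bead_width_study",
    "mann_whitney_type1_study",
    "paired_reduction_study",
]

#: Analysis grid used by the simulation studies: the classic 0.028-um ring
#: spacing, restricted to a 1.54-um span that covers both ROI bands and every
#: width measurement while keeping per-frame cost low.
STUDY_GRID = RingGrid(spacing=0.028, span=1.54)

_BLEACH_EFFICIENCY = 0.95
_BLEACH_RADIUS = 3.0  # um: whole-centrosome bleach
_LAYOUT_ORIGIN = 3.8
_LAYOUT_SPACING = 6.0


def _as_seedseq(seed) -> np.random.SeedSequence:
    """Accept either raw entropy or an already-spawned SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def default_frame_times(double_bleach: bool = False) -> np.ndarray:
    """Acquisition times (s) relative to the first bleach at t = 0."""
    if double_bleach:
        return np.concatenate([[-15.0, -5.0], np.arange(0.0, 180.0, 10.0),
                               np.arange(180.0, 310.0, 10.0)])
    return np.array([-10.0, 0.0, 10.0, 30.0, 60.0, 120.0, 200.0, 300.0])


def _layout(n: int) -> list[tuple[float, float]]:
    cols = min(n, 5)
    return [(_LAYOUT_ORIGIN + (i % cols) * _LAYOUT_SPACING,
             _LAYOUT_ORIGIN + (i // cols) * _LAYOUT_SPACING) for i in range(n)]


def _study_params(model_kind: str) -> MechanisticParams:
    if model_kind == "flux":
        return default_flux_params()
    if model_kind == "distributed":
        return default_distributed_params()
    raise ValueError("model_kind must be 'flux' or 'distributed'")


def simulate_frap_study(model_kind: str,
                        seed,
                        n_centrosomes: int = 10,
                        frame_times: Sequence[float] | None = None,
                        double_bleach: bool = False,
                        optics: OpticsParams | None = None,
                        efficiency: float = _BLEACH_EFFICIENCY) -> FrapMovie:
    """Simulate one FRAP movie under the stated mechanism at the default SNR.

    ``n_centrosomes`` spots share one mechanistic trajectory but receive
    independent camera noise, mimicking the averaging over >=10 centrosomes of
    the standard protocol.  ``double_bleach=True`` adds a second bleach 180 s
    after the first.
    """
    params = _study_params(model_kind)
    optics = optics or OpticsParams()
    times = np.asarray(default_frame_times(double_bleach)
                       if frame_times is None else frame_times, dtype=float)
    layout = _layout(n_centrosomes)
    bleach_times = [0.0, 180.0] if double_bleach else [0.0]
    rng = np.random.default_rng(_as_seedseq(seed))
    events = []
    for tb in bleach_times:
        events.extend(BleachEvent(time=tb, center=c, radius=_BLEACH_RADIUS,
                                  efficiency=efficiency) for c in layout)
    # one mechanistic bleach series applies to the shared trajectory
    chain_events = [BleachEvent(time=tb, center=(0.0, 0.0), radius=_BLEACH_RADIUS,
                                efficiency=efficiency) for tb in bleach_times]
    state = simulate_ring_chain(params, times, chain_events)
    movie = render_movie(state, optics, layout, rng=rng, bleach_events=events)
    movie.metadata["model_kind"] = model_kind
    movie.metadata["mechanistic_params"] = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in dataclasses.asdict(params).items()}
    return movie


def analyze_frap_movie(movie: FrapMovie, grid: RingGrid = STUDY_GRID,
                       min_n: int = 10) -> ProfileSet:
    """Run the standard quantification on a movie (upsample, centre, profile,
    background-subtract, pre-bleach-normalize, average across centrosomes)."""
    return profile_movie(movie, grid, min_n=min_n)


def classification_study(seed, n_per_class: int = 20) -> dict:
    """Blind mechanism classification over a batch of simulated movies.

    Simulates ``n_per_class`` flux-model and ``n_per_class`` distributed-model
    movies at the default SNR, analyzes each, and calls the mechanism.
    Reports overall accuracy and the count of cross-mode errors (a flux movie
    called distributed or vice versa; ``indeterminate`` is a miss but not a
    cross error).
    """
    seeds = _as_seedseq(seed).spawn(2 * n_per_class)
    truths, calls = [], []
    for i in range(2 * n_per_class):
        truth = "flux" if i < n_per_class else "distributed"
        movie = simulate_frap_study(truth, seeds[i])
        pset = analyze_frap_movie(movie)
        calls.append(classify_mode(pset))
        truths.append(truth)
    expected = {"flux": "inside_out", "distributed": "distributed"}
    correct = sum(c.call == expected[t] for t, c in zip(truths, calls))
    cross = sum(c.call not in (expected[t], "indeterminate")
                for t, c in zip(truths, calls))
    return {"truths": truths, "calls": calls,
            "n_movies": 2 * n_per_class,
            "accuracy_pct": 100.0 * correct / (2 * n_per_class),
            "cross_mode_errors": cross}


def even_recovery_study(seed) -> dict:
    """Distributed-model movie: recovery-profile shape deviation.

    Under distributed exchange every amplitude-matched recovery profile
    should superimpose on the pre-bleach profile; the study reports the worst
    deviation (fraction of the pre-bleach peak) over all post-bleach times.
    """
    movie = simulate_frap_study("distributed", seed)
    pset = analyze_frap_movie(movie)
    times, devs = shape_deviation(pset)
    return {"times_s": times, "deviation": devs,
            "max_deviation": float(devs.max()), "pset": pset}


def spreading_study(seed) -> dict:
    """Flux-model movie: width of peak-matched recovery profiles over time."""
    movie = simulate_frap_study("flux", seed)
    pset = analyze_frap_movie(movie)
    ts, ws, pre = fwhm_series(pset)
    return {"times_s": ts, "fwhm_um": ws, "prebleach_fwhm_um": pre,
            "early_ratio": float(ws[0] / pre),
            "min_increment_um": float(np.diff(ws).min()) if ws.size > 1 else np.nan,
            "pset": pset}


def _kinetics_curves(pset: ProfileSet, roi: RoiSpec = RoiSpec()):
    central = roi_curve(pset, roi.central, "central")
    peripheral = roi_curve(pset, roi.peripheral, "peripheral")
    return central, peripheral


def roi_kinetics_study(seed) -> dict:
    """Central versus peripheral recovery kinetics under both mechanisms.

    Uses densely sampled early frames so the 60-s initial-rate and 120-s
    curvature windows are well populated.
    """
    times = np.array([-10.0, 0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 90.0, 120.0])
    seeds = _as_seedseq(seed).spawn(2)
    out = {}
    for model, s in zip(("flux", "distributed"), seeds):
        movie = simulate_frap_study(model, s, frame_times=times)
        pset = analyze_frap_movie(movie)
        central, peripheral = _kinetics_curves(pset)
        rc = initial_rate(central)
        rp = initial_rate(peripheral)
        out[model] = {
            "central_rate": rc, "peripheral_rate": rp,
            "rate_ratio": rc.slope / rp.slope if rp.slope != 0 else np.inf,
            "peripheral_acceleration": acceleration_index(peripheral),
        }
    return out


def double_bleach_study(seed) -> dict:
    """Flux-model double-bleach experiment (second bleach at 180 s).

    Compares the initial central and peripheral rates after the first and
    second bleach: the inside-out mechanism predicts both reset to their
    original values because recovery is driven by fresh incorporation at the
    centre, not by the history of the peripheral binding sites.

    The bleach is complete (efficiency 1) in this protocol: any unbleached
    residual left by the second bleach sits in a non-stationary, centrally
    recovered distribution and advects outward during the rate window, which
    would contaminate the second peripheral rate with residual transport
    rather than fresh incorporation.  Sixteen centrosomes are averaged (the
    upper end of the standard 10-16 protocol) because the peripheral rates
    are the smallest quantities the pipeline estimates.
    """
    movie = simulate_frap_study("flux", seed, n_centrosomes=16,
                                double_bleach=True, efficiency=1.0)
    pset = analyze_frap_movie(movie)
    central, peripheral = _kinetics_curves(pset)
    c1, c2, c_ratio = double_bleach_compare(central)
    p1, p2, p_ratio = double_bleach_compare(peripheral)
    return {"central_rate_1": c1, "central_rate_2": c2, "central_ratio": c_ratio,
            "peripheral_rate_1": p1, "peripheral_rate_2": p2,
            "peripheral_ratio": p_ratio,
            "peripheral_over_central_after_2": p2.slope / c2.slope}


def ring_chain_verification() -> dict:
    """Deterministic simulator checks: steady state and mass conservation.

    Long-time integration of the default flux chain is compared with the
    closed-form stationary solution, and a closed chain (J = k_loss = 0)
    started from an uneven load is integrated across a bleach to measure
    total-mass drift.
    """
    params = default_flux_params()
    from .simulate import steady_state_flux  # local to keep module surface tidy
    ss = steady_state_flux(params)
    # start far from equilibrium and integrate until the slowest mode
    # (rate k_loss) has decayed to well below the comparison tolerance
    t_long = 40.0 / params.k_loss
    state = simulate_ring_chain(params, [0.0, t_long], initial="zero")
    rel_err = float(np.max(np.abs(state.total[-1] - ss) / ss))

    closed = MechanisticParams(model_kind="flux", n_rings=params.n_rings,
                               ring_width=params.ring_width,
                               inner_radius=params.inner_radius,
                               J=0.0, transfer_rate=params.transfer_rate, k_loss=0.0)
    load = np.linspace(1.0, 5.0, params.n_rings)
    bleach = BleachEvent(time=500.0, center=(0.0, 0.0), radius=1.0, efficiency=0.8)
    closed_state = simulate_ring_chain(closed, np.linspace(0.0, 2000.0, 9),
                                       [bleach], initial=load)
    mass = closed_state.total.sum(axis=1)
    mass_err = float(np.max(np.abs(mass - mass[0])) / mass[0])
    return {"steady_state_rel_err": rel_err, "mass_conservation_rel_err": mass_err}


def gaussian_profile_fidelity(sigma: float = 0.2, grid: RingGrid | None = None) -> dict:
    """Noise-free Gaussian spot: profiler output versus polar quadrature.

    The image is synthesized directly at the profiler's subpixel resolution;
    the reference is the exact annulus mean of the analytic Gaussian computed
    by dense polar quadrature (no pixels involved), so any disagreement is the
    profiler's own discretization error.
    """
    grid = grid or RingGrid(spacing=0.028, span=1.4)
    px = 0.028
    half = grid.span + 0.2
    n = int(round(2 * half / px))
    c = n * px / 2.0
    coords = (np.arange(n) + 0.5) * px - c
    img = np.exp(-(coords[None, :] ** 2 + coords[:, None] ** 2) / (2 * sigma**2))
    stack = ImageStack(img, px)
    prof = radial_profile(stack, (c, c), grid)
    prof = subtract_background(prof, 0.0)

    # polar-quadrature reference: mean of exp(-r^2 / 2 sigma^2) over each annulus
    ref = np.empty(grid.n_rings)
    for i in range(grid.n_rings):
        r0, r1 = i * grid.spacing, (i + 1) * grid.spacing
        rs = np.linspace(r0, r1, 200)
        w = rs  # area element r dr
        ref[i] = np.trapezoid(np.exp(-rs**2 / (2 * sigma**2)) * w, rs) / np.trapezoid(w, rs)
    err = np.abs(prof.values - ref)
    return {"max_err_frac_of_peak": float(np.nanmax(err) / ref.max()),
            "profile": prof, "reference": ref}


def _disk_psf_profile_fwhm(radius: float, sigma: float) -> float:
    """FWHM of a uniform disk convolved with an isotropic Gaussian.

    Independent quadrature oracle: the radial profile is
    ``I(r) = int_0^R (s / sigma^2) exp(-(s - r)^2 / (2 sigma^2))
    ive(0, r s / sigma^2) ds`` (Rice form with the scaled Bessel function for
    stability); the half-maximum radius is found by bisection.
    """
    s = np.linspace(0.0, radius, 4001)

    def intensity(r: float) -> float:
        integrand = (s / sigma**2) * np.exp(-((s - r) ** 2) / (2 * sigma**2)) \
            * ive(0, r * s / sigma**2)
        return float(np.trapezoid(integrand, s))

    peak = intensity(0.0)
    lo, hi = 0.0, radius + 6 * sigma
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if intensity(mid) > peak / 2:
            lo = mid
        else:
            hi = mid
    return 2.0 * 0.5 * (lo + hi)


def bead_width_study(seed) -> dict:
    """Simulated sub-resolution bead versus the disk (x) PSF quadrature oracle.

    Renders a 170-nm bead through the camera model, measures its profile FWHM
    with the standard pipeline (5x upsampling, centre of mass, ring averages),
    and compares with the oracle width of the underlying disk-PSF convolution.
    """
    optics = OpticsParams()
    img = simulate_bead_image(optics, rng=np.random.default_rng(
        _as_seedseq(seed)))
    from .profiling import estimate_cytosol_background, find_center, upsample_image
    up = upsample_image(img, 5)
    center = find_center(up)
    grid = RingGrid(spacing=0.028, span=1.4)
    prof = radial_profile(up, center, grid)
    bg = estimate_cytosol_background(up, center, inner_r=1.0, outer_r=1.3)
    prof = subtract_background(prof, bg)
    fwhm = profile_fwhm(normalize_and_mirror(prof))
    oracle = _disk_psf_profile_fwhm(0.17 / 2.0, optics.psf_sigma)
    return {"bead_fwhm_um": float(fwhm), "oracle_fwhm_um": float(oracle),
            "abs_error_um": float(abs(fwhm - oracle)),
            "camera_pixel_um": optics.camera_pixel}


def mann_whitney_type1_study(seed, n_reps: int = 2000, n_per_group: int = 20,
                             alpha: float = 0.05) -> dict:
    """Type-I calibration: rejection rate on identically distributed groups."""
    rng = np.random.default_rng(_as_seedseq(seed))
    rejections = 0
    for _ in range(n_reps):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        if mann_whitney_u(a, b).p_value < alpha:
            rejections += 1
    return {"rejection_rate_pct": 100.0 * rejections / n_reps, "n_reps": n_reps}


def paired_reduction_study(seed, n_reps: int = 200, n_pairs: int = 10,
                           reduction: float = 0.75, noise_cv: float = 0.1) -> dict:
    """Estimator recovery of an implanted paired rate reduction.

    Repeatedly simulates paired control/experimental initial rates with the
    implanted fractional reduction and multiplicative measurement noise, runs
    the paired comparison, and reports how often the percent-reduction
    estimate lands within +/-10 points of the implanted value.
    """
    seeds = _as_seedseq(seed).spawn(n_reps)
    estimates = np.empty(n_reps)
    for i, s in enumerate(seeds):
        table = simulate_paired_rates(n_pairs, control_mean=1.0, reduction=reduction,
                                      noise_cv=noise_cv, rng=np.random.default_rng(s))
        result = paired_rate_comparison(table["control_rate"], table["experimental_rate"])
        estimates[i] = result.percent_reduction
    implanted = 100.0 * reduction
    within = np.abs(estimates - implanted) <= 10.0
    return {"estimates_pct": estimates, "mean_estimate_pct": float(estimates.mean()),
            "within_10_points_pct": 100.0 * float(within.mean()),
            "implanted_pct": implanted, "n_reps": n_reps}
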