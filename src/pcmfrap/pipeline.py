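"""Orchestration: configuration, seeding, manifests, end-to-end runs.

A run is driven by a strictly validated configuration (YAML or dict): unknown
keys are errors, every random stage consumes a seed derived from the single
run seed via ``numpy.random.SeedSequence`` spawning, and every output file is
checksummed into a run manifest so identical configs reproduce identical
artifacts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .exceptions import ConfigError, PcmFrapError
from .io import (profiles_to_frame, read_movie, sha256_file, write_json,
                 write_movie, write_profile_set)
from .kinetics import (ModeThresholds, RoiSpec, acceleration_index, classify_mode,
                       double_bleach_compare, initial_rate, roi_curve, spread_index)
from .popstats import brain_averages, mann_whitney_u
from .profiling import RingGrid, profile_movie
from .protocols import simulate_frap_study
from .simulate import simulate_fixed_cell_table

__all__ = ["RunConfig", "run_frap_pipeline", "run_fixed_pipeline", "load_config"]


def _from_dict(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {name: data[name] for name in names if name in data}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


@dataclass(frozen=True)
class SimulateConfig:
    """What to simulate; ``model`` empty means analyze an existing movie."""

    model: str = "flux"
    n_centrosomes: int = 10
    double_bleach: bool = False
    bleach_efficiency: float = 0.95

    def __post_init__(self) -> None:
        if self.model not in ("flux", "distributed"):
            raise ValueError("model must be 'flux' or 'distributed'")
        if self.n_centrosomes < 1:
            raise ValueError("n_centrosomes must be positive")


@dataclass(frozen=True)
class AnalysisConfig:
    ring_spacing: float = 0.028
    ring_span: float = 1.54
    upsample_factor: int = 5
    threshold_frac: float = 0.5
    bg_inner: float = 1.2
    bg_outer: float = 1.5
    min_centrosomes: int = 10

    def grid(self) -> RingGrid:
        return RingGrid(spacing=self.ring_spacing, span=self.ring_span)


@dataclass(frozen=True)
class KineticsConfig:
    central_band: tuple = (0.028, 0.14)
    peripheral_band: tuple = (0.62, 0.73)
    rate_window_s: float = 60.0
    acceleration_window_s: float = 120.0
    early_fwhm_ratio: float = 0.8
    shape_dev_max: float = 0.05
    spread_t_stat: float = 2.0

    def roi(self) -> RoiSpec:
        return RoiSpec(central=tuple(self.central_band),
                       peripheral=tuple(self.peripheral_band))

    def thresholds(self) -> ModeThresholds:
        return ModeThresholds(early_fwhm_ratio=self.early_fwhm_ratio,
                              shape_dev_max=self.shape_dev_max,
                              spread_t_stat=self.spread_t_stat)


@dataclass(frozen=True)
class FixedStatsConfig:
    """Fixed-brain study: group specs are (genotype, phase) -> [mean, sd]."""

    groups: dict = field(default_factory=lambda: {
        "wt/interphase": [40.0, 15.0], "wt/mitotic": [100.0, 25.0]})
    n_brains: int = 5
    cells_per_brain: int = 40
    input_csv: str | None = None


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    fixed_stats: FixedStatsConfig = field(default_factory=FixedStatsConfig)
    input_movie: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (("simulate", SimulateConfig), ("analysis", AnalysisConfig),
                         ("kinetics", KineticsConfig), ("fixed_stats", FixedStatsConfig)):
            if key in data:
                data[key] = _from_dict(sub, data[key], key)
        return _from_dict(cls, data, "config")


def load_config(path: str | Path) -> RunConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return RunConfig.from_dict(data or {})


def _manifest(outdir: Path, config: RunConfig, files: list[Path]) -> Path:
    payload = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "outputs": {f.name: sha256_file(f) for f in sorted(files)},
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    return write_json(payload, outdir / "manifest.json")


def _rate_record(rate) -> dict:
    return {"slope_per_s": rate.slope, "stderr": rate.stderr,
            "window_s": rate.window, "n_points": rate.n_points}


def run_frap_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """simulate (or load) -> profile -> kinetics -> report + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    if config.input_movie is not None:
        movie = read_movie(config.input_movie)
    else:
        sim_seed, _ = np.random.SeedSequence(config.seed).spawn(2)
        movie = simulate_frap_study(config.simulate.model, sim_seed,
                                    n_centrosomes=config.simulate.n_centrosomes,
                                    double_bleach=config.simulate.double_bleach,
                                    efficiency=config.simulate.bleach_efficiency)
        files.extend(write_movie(movie, outdir / "movie"))

    ana = config.analysis
    pset = profile_movie(movie, ana.grid(), upsample_factor=ana.upsample_factor,
                         threshold_frac=ana.threshold_frac, bg_inner=ana.bg_inner,
                         bg_outer=ana.bg_outer, min_n=ana.min_centrosomes)
    files.append(write_profile_set(pset, outdir / "profiles.json"))
    csv_path = outdir / "profiles.csv"
    profiles_to_frame(pset).to_csv(csv_path, index=False)
    files.append(csv_path)

    kin = config.kinetics
    roi = kin.roi()
    central = roi_curve(pset, roi.central, "central")
    peripheral = roi_curve(pset, roi.peripheral, "peripheral")
    report: dict = {
        "seed": config.seed,
        "n_centrosomes_averaged": pset.n_centrosomes,
        "central_rate": _rate_record(initial_rate(central, window=kin.rate_window_s)),
        "peripheral_rate": _rate_record(initial_rate(peripheral,
                                                     window=kin.rate_window_s)),
        "thresholds": dataclasses.asdict(kin.thresholds()),
        "roi_bands_um": {"central": list(roi.central), "peripheral": list(roi.peripheral)},
    }
    try:
        report["peripheral_acceleration"] = acceleration_index(
            peripheral, window=kin.acceleration_window_s)
    except PcmFrapError:
        report["peripheral_acceleration"] = None
    try:
        spread = spread_index(pset)
        report["fwhm_spread"] = {"slope_um_per_s": spread.slope,
                                 "stderr": spread.stderr, "t_stat": spread.t_stat,
                                 "n_points": spread.n_points}
    except PcmFrapError:
        report["fwhm_spread"] = None
    if pset.bleach_times.size == 2:
        r1, r2, ratio = double_bleach_compare(central, window=kin.rate_window_s)
        report["double_bleach"] = {"central_rate_1": _rate_record(r1),
                                   "central_rate_2": _rate_record(r2),
                                   "central_ratio": ratio}
    mode = classify_mode(pset, kin.thresholds())
    report["mode_call"] = {"call": mode.call, "evidence": mode.evidence}

    files.append(write_json(report, outdir / "kinetics_report.json"))
    _manifest(outdir, config, files)
    return report


def run_fixed_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Fixed-brain statistics: table -> per-brain averages -> group tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    fx = config.fixed_stats

    if fx.input_csv is not None:
        table = pd.read_csv(fx.input_csv)
        missing = {"brain_id", "genotype", "phase", "marker", "intensity"} - set(table.columns)
        if missing:
            raise ConfigError(f"input table lacks columns: {sorted(missing)}")
    else:
        specs = {}
        for key, (mean, sd) in fx.groups.items():
            try:
                genotype, phase = key.split("/")
            except ValueError as exc:
                raise ConfigError(
                    f"group key {key!r} must look like 'genotype/phase'") from exc
            specs[(genotype, phase)] = (float(mean), float(sd))
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        table = simulate_fixed_cell_table(specs, fx.n_brains, fx.cells_per_brain, rng)
        tpath = outdir / "cellquant.csv"
        table.to_csv(tpath, index=False)
        files.append(tpath)

    per_brain = brain_averages(table)
    bpath = outdir / "brain_averages.csv"
    per_brain.to_csv(bpath, index=False)
    files.append(bpath)

    comparisons = []
    for (genotype, marker), sub in per_brain.groupby(["genotype", "marker"]):
        inter = sub.loc[sub["phase"] == "interphase", "mean_intensity"]
        mito = sub.loc[sub["phase"] == "mitotic", "mean_intensity"]
        if len(inter) and len(mito):
            cmp_ = mann_whitney_u(inter.to_numpy(), mito.to_numpy())
            comparisons.append({"genotype": genotype, "marker": marker,
                                "statistic_U": cmp_.statistic, "p_value": cmp_.p_value,
                                "method": cmp_.method,
                                "n_brains": list(cmp_.n),
                                "interphase_mean": float(inter.mean()),
                                "mitotic_mean": float(mito.mean())})
    report = {"seed": config.seed, "comparisons": comparisons,
              "n_rows": int(len(table))}
    files.append(write_json(report, outdir / "fixed_stats_report.json"))
    _manifest(outdir, config, files)
    return report
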