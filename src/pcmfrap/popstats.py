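"""Fixed-cell and antibody-injection statistics.

Boxed-region centrosome quantification with local background correction,
per-brain averaging (one data point per brain, not per centrosome), a
Mann-Whitney U comparison of interphase versus mitotic intensity populations,
a paired control/experimental initial-rate comparison with the percent
reduction as effect size, and binary per-cell aster scoring.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateVarianceError, PcmFrapError
from .images import ImageStack

__all__ = [
    "GroupComparison",
    "PairedComparison",
    "quantify_centrosome_box",
    "brain_averages",
    "mann_whitney_u",
    "paired_rate_comparison",
    "aster_percentage",
]

CELLQUANT_COLUMNS = ["centrosome_id", "brain_id", "genotype", "phase", "marker", "intensity"]


@dataclass(frozen=True)
class GroupComparison:
    """A two-group test result."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class PairedComparison:
    """Percent reduction plus the paired t test behind it."""

    percent_reduction: float
    test: GroupComparison


def quantify_centrosome_box(img: ImageStack,
                            box: tuple[int, int, int, int],
                            bg_region: tuple[int, int, int, int]) -> float:
    """Total boxed fluorescence minus the local background expectation.

    ``box`` and ``bg_region`` are half-open pixel rectangles
    ``(row0, col0, row1, col1)``; the background region must be disjoint from
    the box.  Returns ``sum(box) - mean(bg_region) * box_area``.
    """
    plane = img.pixels if img.pixels.ndim == 2 else img.pixels.max(axis=0)
    ny, nx = plane.shape

    def check(r):
        r0, c0, r1, c1 = r
        if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
            raise PcmFrapError(f"region {r} out of image bounds {(ny, nx)}")
        return r

    b, g = check(box), check(bg_region)
    if not (b[2] <= g[0] or g[2] <= b[0] or b[3] <= g[1] or g[3] <= b[1]):
        raise PcmFrapError("box and background region overlap")
    box_px = plane[b[0]:b[2], b[1]:b[3]]
    bg_px = plane[g[0]:g[2], g[1]:g[3]]
    return float(box_px.sum() - bg_px.mean() * box_px.size)


def brain_averages(table: pd.DataFrame) -> pd.DataFrame:
    """One data point per (brain, genotype, phase, marker): the mean over its
    centrosomes, with the per-brain n."""
    required = {"brain_id", "genotype", "phase", "marker", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise PcmFrapError(f"table lacks required columns: {sorted(missing)}")
    if len(table) == 0:
        raise PcmFrapError("empty quantification table")
    out = (table.groupby(["brain_id", "genotype", "phase", "marker"], sort=True)
           ["intensity"].agg(mean_intensity="mean", n_centrosomes="size").reset_index())
    return out


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The p-value is exact (full enumeration of group assignments) when the
    pooled sample size is at most 12 and the data carry no ties; otherwise the
    normal approximation with tie correction and continuity correction is
    used.  The reported statistic is U for the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PcmFrapError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= 12) and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return GroupComparison(statistic=float(res.statistic), p_value=float(res.pvalue),
                           method="mann-whitney-exact" if exact else "mann-whitney-normal",
                           n=(int(a.size), int(b.size)))


def paired_rate_comparison(control: Sequence[float],
                           experimental: Sequence[float],
                           per_pair: bool = False) -> PairedComparison:
    """Percent rate reduction at experimental versus control centrosomes.

    The effect size is ``100 * (1 - mean(experimental) / mean(control))``
    (ratio of group means; ``per_pair=True`` averages per-pair ratios
    instead).  Significance comes from a two-sided paired Student t test on
    the differences.  Identical differences to machine precision raise
    :class:`DegenerateVarianceError`, which still carries the reduction.
    """
    c = np.asarray(control, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if c.shape != e.shape:
        raise PcmFrapError("control and experimental must pair one-to-one")
    if c.size < 2:
        raise PcmFrapError("need at least 2 pairs for the paired t test")
    mc = float(c.mean())
    if mc <= 0:
        raise PcmFrapError("mean control rate must be positive")
    if per_pair:
        reduction = 100.0 * float(np.mean(1.0 - e / c))
    else:
        reduction = 100.0 * (1.0 - float(e.mean()) / mc)
    d = c - e
    sd = float(np.std(d, ddof=1))
    scale = max(np.abs(d).max(), 1.0)
    if sd <= 1e-12 * scale:
        raise DegenerateVarianceError(
            "paired differences are identical to machine precision", reduction)
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
    test = GroupComparison(statistic=t, p_value=p, method="paired-t", n=(int(c.size),))
    return PairedComparison(percent_reduction=reduction, test=test)


def aster_percentage(table: pd.DataFrame,
                     group_col: str = "genotype",
                     score_col: str = "aster_positive") -> pd.DataFrame:
    """Percent of cells scored aster-positive per group, with n.

    A cell counts as positive when at least one of its centrosomes showed
    detectable astral microtubules (the scoring is done upstream; this is the
    per-genotype tabulation).
    """
    for col in (group_col, score_col):
        if col not in table.columns:
            raise PcmFrapError(f"table lacks column {col!r}")
    if len(table) == 0:
        raise PcmFrapError("empty scoring table")
    grouped = table.groupby(group_col, sort=True)[score_col]
    out = grouped.agg(n="size", positives="sum").reset_index()
    out["percent_positive"] = 100.0 * out["positives"] / out["n"]
    return out
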