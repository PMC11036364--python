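"""Facet growth rates from fitted template sequences.

Distances between paired parallel faces are converted to physical units,
the early linear stage of each distance-vs-time series is selected (late
stages flatten as the solute depletes), and the facet growth rate is half
the paired-distance slope: a facet's rate is its normal displacement from
the crystal centre, and the paired distance spans both opposite facets.
All exported rates are in m s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CrystalAngles, width_to_normal_distance

__all__ = [
    "DistanceSeries",
    "GrowthRateEstimate",
    "calibrate",
    "distance_series",
    "early_stage_window",
    "facet_growth_rate",
    "aggregate_repeats",
    "convert_axis_rates",
    "measurements_table",
]

#: default face-pair labels for the needle habit (direction 1 = prismatic)
DEFAULT_LABELS = ("(021)/(0-2-1)", "(101)/(-10-1)", "(10-1)/(-101)")

MIN_WINDOW = 5


@dataclass
class DistanceSeries:
    """Paired-face normal distances (um) against time (s)."""

    times: np.ndarray          # (n,) seconds, strictly increasing
    distances: np.ndarray      # (n, 3) um, one column per direction
    labels: tuple[str, str, str] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")


@dataclass
class GrowthRateEstimate:
    """Facet growth rate of one face pair (half-distance convention)."""

    face_pair: str
    rate: float        # m s^-1
    stderr: float      # m s^-1
    r2: float
    window: tuple[int, int]
    fallback_window: bool = False


def calibrate(scale_bar_px: float, scale_bar_physical: float) -> float:
    """Physical length per pixel from a scale bar."""
    if scale_bar_px <= 0 or scale_bar_physical <= 0:
        raise ValueError("scale bar inputs must be positive")
    return scale_bar_physical / scale_bar_px


def distance_series(
    fits: Sequence,
    times: Sequence[float],
    pixel_size: float,
    angles: CrystalAngles | None = None,
    correct_prismatic: bool = False,
    labels: tuple[str, str, str] = DEFAULT_LABELS,
) -> DistanceSeries:
    """Paired distances ``D_i = (d_i+ + d_i-) * pixel_size`` from FrameFits.

    With ``correct_prismatic`` the direction-1 (prismatic) projected widths
    are converted to normal distances with the 3D interfacial angle.
    """
    if len(fits) != len(times):
        raise ValueError("fits and times must have equal length")
    angles = angles or CrystalAngles()
    D = np.array([f.template.dists.sum(axis=1) for f in fits]) * pixel_size
    if correct_prismatic:
        D[:, 0] = width_to_normal_distance(D[:, 0], angles.prismatic_pair_3d)
    return DistanceSeries(times=np.asarray(times, float), distances=D,
                          labels=labels)


def early_stage_window(
    times: np.ndarray,
    dists: np.ndarray,
    r2_min: float = 0.99,
) -> tuple[int, int, bool]:
    """Longest linear prefix of one face pair's (t, D) series.

    Returns ``(first, last, fallback)`` inclusive indices of the longest
    prefix starting at 0, of length >= 5, whose OLS fit reaches
    ``r2_min``; if no prefix qualifies, the first five points are used and
    the fallback flag is set.
    """
    t = np.asarray(times, float)
    d = np.asarray(dists, float)
    n = t.size
    if n < MIN_WINDOW:
        raise ValueError(f"need at least {MIN_WINDOW} points")
    for last in range(n - 1, MIN_WINDOW - 2, -1):
        res = stats.linregress(t[: last + 1], d[: last + 1])
        if res.rvalue**2 >= r2_min:
            return 0, last, False
    return 0, MIN_WINDOW - 1, True


def facet_growth_rate(
    times: np.ndarray,
    dists_um: np.ndarray,
    window: tuple[int, int],
    face_pair: str = "",
    fallback: bool = False,
) -> GrowthRateEstimate:
    """OLS slope of D (um) vs t (s) over the window, halved, in m s^-1."""
    i0, i1 = window
    t = np.asarray(times, float)[i0 : i1 + 1]
    d = np.asarray(dists_um, float)[i0 : i1 + 1]
    if np.ptp(t) == 0:
        raise ValueError("degenerate window: constant time")
    res = stats.linregress(t, d)
    um_to_m = 1e-6
    return GrowthRateEstimate(
        face_pair=face_pair,
        rate=res.slope / 2.0 * um_to_m,
        stderr=res.stderr / 2.0 * um_to_m,
        r2=res.rvalue**2,
        window=(i0, i1),
        fallback_window=fallback,
    )


def sequence_growth_rates(
    series: DistanceSeries, r2_min: float = 0.99
) -> list[GrowthRateEstimate]:
    """Early-stage growth rate of each face pair of a distance series."""
    out = []
    for i, label in enumerate(series.labels):
        i0, i1, fb = early_stage_window(
            series.times, series.distances[:, i], r2_min
        )
        out.append(
            facet_growth_rate(
                series.times, series.distances[:, i], (i0, i1), label, fb
            )
        )
    return out


def aggregate_repeats(
    rates: Sequence[GrowthRateEstimate | float],
) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator; 0 when n = 1) and n of repeats."""
    vals = np.array(
        [r.rate if isinstance(r, GrowthRateEstimate) else float(r) for r in rates]
    )
    if vals.size == 0:
        raise ValueError("no repeats to aggregate")
    sd = 0.0 if vals.size == 1 else float(vals.std(ddof=1))
    return float(vals.mean()), sd, int(vals.size)


def convert_axis_rates(
    length_rate: float,
    width_rate: float,
    angles: CrystalAngles | None = None,
) -> tuple[float, float]:
    """Facet rates from whole-crystal length/width rates.

    The capping facet advances at half the length rate projected onto the
    capping normal (tilted from the long axis by half the 180-tip angle);
    the prismatic facet at half the width rate scaled by the out-of-plane
    ``sin(angle/2)`` correction.
    """
    if length_rate < 0 or width_rate < 0:
        raise ValueError("rates must be >= 0")
    angles = angles or CrystalAngles()
    tip_half = np.deg2rad((180.0 - angles.capping_capping) / 2.0)
    capping = (length_rate / 2.0) * np.cos(tip_half)
    prismatic = (width_rate / 2.0) * np.sin(
        np.deg2rad(angles.prismatic_pair_3d) / 2.0
    )
    return float(capping), float(prismatic)


def measurements_table(
    fits: Sequence, times: Sequence[float], pixel_size_um: float
) -> pd.DataFrame:
    """Per-frame measurement table (the open-format export).

    One row per frame: time, per-pair distances in px and um, fitted
    centre/orientation, loss terms and convergence flag.  Frames that
    failed to fit appear as all-NaN rows.
    """
    rows = []
    for i, (f, t) in enumerate(zip(fits, times)):
        row: dict = {"frame": i, "time_s": t}
        if f is None:
            rows.append(row)
            continue
        tm = f.template
        d = tm.dists
        for k in range(3):
            row[f"d{k+1}p_px"] = d[k, 0]
            row[f"d{k+1}m_px"] = d[k, 1]
            row[f"D{k+1}_um"] = d[k].sum() * pixel_size_um
        row.update(
            cx=tm.center[0], cy=tm.center[1], theta1_deg=tm.theta1,
            loss_total=f.loss_terms.get("total"),
            loss_mse=f.loss_terms.get("mse"),
            converged=f.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)
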