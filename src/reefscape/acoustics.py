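"""Splitbeam fish-target processing: target strength to length, size classes,
and equal-ensonified-area density bins along the survey track.

A calibrated splitbeam echosounder reports one averaged target strength (TS,
dB re 1 m^2) per tracked fish.  TS is converted to total length with the
generalized (species-independent) Love-form relation

    TS = m * log10(L_cm) - b_f * log10(f_kHz) - b0

with default constants m = 19.1, b_f = 0.9, b0 = 62.0.  Fish below a TS
threshold (default -50 dB, about a 5-6 cm fish at 120 kHz) are discarded as
probable plankton/small non-target echoes.  Retained fish fall into three
size classes: small (<= 11 cm), medium (12-28 cm), large (>= 29 cm), applied
to the length rounded to the nearest centimetre.

Densities are normalised for the depth-dependent beam footprint by binning
along the track into intervals of constant *ensonified area* (default
100 m^2): at seafloor depth d the swath width is w = 2 d tan(beam/2), so each
bin's along-track length is area / w and shortens over deeper water.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import BathymetryGrid

logger = logging.getLogger(__name__)

TS_SLOPE = 19.1
TS_FREQ_COEF = 0.9
TS_INTERCEPT = 62.0
DEFAULT_FREQUENCY_KHZ = 120.0
DEFAULT_TS_THRESHOLD_DB = -50.0
DEFAULT_BEAM_ANGLE_DEG = 7.0
DEFAULT_BIN_AREA_M2 = 100.0

SIZE_CLASSES = ("small", "medium", "large")
SMALL_MAX_CM = 11
MEDIUM_MAX_CM = 28


@dataclass
class FishTarget:
    """One tracked fish: position, depth, mean TS and derived size."""

    x: float
    y: float
    depth_m: float
    ts_db: float
    length_cm: float = float("nan")
    size_class: str = "none"


@dataclass
class DensityBin:
    """One constant-ensonified-area sample unit along the survey track."""

    x: float
    y: float
    area_m2: float
    track_len_m: float
    counts: dict = field(default_factory=lambda: {c: 0 for c in SIZE_CLASSES})

    def density(self, size_class: str) -> float:
        """Fish per 100 m^2 of ensonified area."""
        return self.counts[size_class] / self.area_m2 * 100.0


def length_to_ts(length_cm, frequency_khz: float = DEFAULT_FREQUENCY_KHZ,
                 slope: float = TS_SLOPE, freq_coef: float = TS_FREQ_COEF,
                 intercept: float = TS_INTERCEPT):
    """Forward Love-form equation: fish length (cm) to target strength (dB)."""
    if frequency_khz <= 0:
        raise ValueError("frequency_khz must be positive")
    L = np.asarray(length_cm, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    return slope * np.log10(L) - freq_coef * np.log10(frequency_khz) - intercept


def ts_to_length(ts_db, frequency_khz: float = DEFAULT_FREQUENCY_KHZ,
                 slope: float = TS_SLOPE, freq_coef: float = TS_FREQ_COEF,
                 intercept: float = TS_INTERCEPT):
    """Inverse Love-form equation: target strength (dB) to fish length (cm)."""
    if frequency_khz <= 0:
        raise ValueError("frequency_khz must be positive")
    ts = np.asarray(ts_db, dtype=float)
    return 10.0 ** ((ts + freq_coef * np.log10(frequency_khz) + intercept) / slope)


def classify_size(length_cm: float) -> str:
    """Size class from length, thresholds on the nearest-centimetre rounding."""
    if not np.isfinite(length_cm) or length_cm <= 0:
        raise ValueError("length must be positive and finite")
    rounded = int(np.rint(length_cm))
    if rounded <= SMALL_MAX_CM:
        return "small"
    if rounded <= MEDIUM_MAX_CM:
        return "medium"
    return "large"


def filter_targets(targets: list[FishTarget],
                   ts_threshold_db: float = DEFAULT_TS_THRESHOLD_DB) -> list[FishTarget]:
    """Targets at or above the TS threshold (boundary kept); order preserved."""
    return [t for t in targets if t.ts_db >= ts_threshold_db]


def derive_lengths(targets: list[FishTarget],
                   frequency_khz: float = DEFAULT_FREQUENCY_KHZ) -> list[FishTarget]:
    """New target list with length and size class filled in from TS."""
    out = []
    for t in targets:
        L = float(ts_to_length(t.ts_db, frequency_khz))
        out.append(replace(t, length_cm=L, size_class=classify_size(L)))
    return out


def _track_stations(track_xy: np.ndarray, step_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Densely resampled stations along a polyline and their chainage (m)."""
    xy = np.asarray(track_xy, dtype=float)
    seg = np.diff(xy, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("track has repeated consecutive vertices")
    chain = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = chain[-1]
    s = np.arange(0.0, total, step_m)
    s = np.append(s, total)
    px = np.interp(s, chain, xy[:, 0])
    py = np.interp(s, chain, xy[:, 1])
    return np.column_stack([px, py]), s


def bin_survey(targets: list[FishTarget], track_xy: np.ndarray, grid: BathymetryGrid,
               beam_angle_deg: float = DEFAULT_BEAM_ANGLE_DEG,
               bin_area_m2: float = DEFAULT_BIN_AREA_M2,
               fixed_bin_length_m: float | None = None,
               restrict_to_swath: bool = True) -> list[DensityBin]:
    """Bin classed targets into constant-ensonified-area intervals on the track.

    Walks the track in fine steps, accumulating ensonified area
    w(d) * ds with w(d) = 2 d tan(beam/2) at the local seafloor depth; a bin
    closes each time the accumulated area reaches ``bin_area_m2``, so every
    bin's ensonified area is exactly the target area while its along-track
    length varies inversely with swath width.  Targets are snapped to the
    nearest station and assigned by chainage interval (ties to the earlier
    bin).  ``fixed_bin_length_m`` switches to plain constant-length binning
    for comparison (bin areas then vary with depth).

    With ``restrict_to_swath`` (default) only targets inside the local beam
    footprint — within w(d)/2 of the track — are counted; a splitbeam sees
    nothing outside its swath.

    Empty bins are kept: zeros are data for occurrence models.
    """
    if not 0 < beam_angle_deg < 90:
        raise ValueError("beam_angle_deg must be in (0, 90)")
    if bin_area_m2 <= 0:
        raise ValueError("bin_area_m2 must be positive")
    xy = np.asarray(track_xy, dtype=float)
    if not np.all(grid.contains(xy[:, 0], xy[:, 1])):
        bad = int(np.flatnonzero(~grid.contains(xy[:, 0], xy[:, 1]))[0])
        raise ValueError(f"track vertex {bad} at {tuple(xy[bad])} lies outside the grid")
    step = grid.cell_size / 2.0
    stations, chain = _track_stations(xy, step)
    depths = grid.value_at(stations[:, 0], stations[:, 1])
    if np.any(~np.isfinite(depths)) or np.any(depths <= 0):
        bad = int(np.flatnonzero(~np.isfinite(depths) | (depths <= 0))[0])
        raise ValueError(
            f"zero/negative/nodata depth under the track near station {bad} at "
            f"{tuple(stations[bad])}")
    half = np.radians(beam_angle_deg) / 2.0
    width = 2.0 * depths * np.tan(half)

    # cumulative ensonified area along the chainage (trapezoid per step)
    darea = 0.5 * (width[1:] + width[:-1]) * np.diff(chain)
    cum_area = np.concatenate([[0.0], np.cumsum(darea)])

    if fixed_bin_length_m is not None:
        edges_s = np.arange(0.0, chain[-1], fixed_bin_length_m)
        edges_s = np.append(edges_s, chain[-1])
    else:
        n_bins = int(np.floor(cum_area[-1] / bin_area_m2))
        if n_bins == 0:
            logger.warning("track too short for a single %.0f m^2 bin", bin_area_m2)
            return []
        edges_a = np.arange(n_bins + 1) * bin_area_m2
        edges_s = np.interp(edges_a, cum_area, chain)

    # assign targets: snap to nearest station, then chainage -> bin interval
    bins: list[DensityBin] = []
    mids = 0.5 * (edges_s[:-1] + edges_s[1:])
    mx = np.interp(mids, chain, stations[:, 0])
    my = np.interp(mids, chain, stations[:, 1])
    for k in range(len(mids)):
        if fixed_bin_length_m is not None:
            area = float(np.interp(edges_s[k + 1], chain, cum_area)
                         - np.interp(edges_s[k], chain, cum_area))
        else:
            area = bin_area_m2
        bins.append(DensityBin(x=float(mx[k]), y=float(my[k]), area_m2=area,
                               track_len_m=float(edges_s[k + 1] - edges_s[k])))
    if targets:
        from scipy.spatial import cKDTree

        tx = np.array([t.x for t in targets])
        ty = np.array([t.y for t in targets])
        dist, nearest = cKDTree(stations).query(np.column_stack([tx, ty]))
        s_t = chain[nearest]
        in_swath = (dist <= width[nearest] / 2.0) if restrict_to_swath else np.ones(
            len(targets), dtype=bool)
        n_out = int((~in_swath).sum())
        if n_out:
            logger.debug("bin_survey: %d of %d targets outside the ensonified swath",
                         n_out, len(targets))
        # interval index; right edges tie toward the earlier bin
        idx = np.searchsorted(edges_s, s_t, side="left") - 1
        idx = np.clip(idx, 0, len(bins) - 1)
        for t, k, ok in zip(targets, idx, in_swath):
            if ok and t.size_class in bins[k].counts:
                bins[k].counts[t.size_class] += 1
    return bins


def bins_to_frame(bins: list[DensityBin]) -> pd.DataFrame:
    """Tabular view of density bins (the documented bin CSV schema)."""
    rows = []
    for b in bins:
        row = {"x": b.x, "y": b.y, "area_m2": b.area_m2, "track_len_m": b.track_len_m}
        for c in SIZE_CLASSES:
            row[f"count_{c}"] = b.counts[c]
        for c in SIZE_CLASSES:
            row[f"dens_{c}"] = b.density(c)
        rows.append(row)
    return pd.DataFrame(rows, columns=["x", "y", "area_m2", "track_len_m",
                                       *(f"count_{c}" for c in SIZE_CLASSES),
                                       *(f"dens_{c}" for c in SIZE_CLASSES)])


def targets_to_frame(targets: list[FishTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"x": t.x, "y": t.y, "depth_m": t.depth_m, "ts_db": t.ts_db,
          "length_cm": t.length_cm, "size_class": t.size_class} for t in targets],
        columns=["x", "y", "depth_m", "ts_db", "length_cm", "size_class"])


def targets_from_frame(df: pd.DataFrame) -> list[FishTarget]:
    required = {"x", "y", "depth_m", "ts_db"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target table missing column(s): {sorted(missing)}")
    out = []
    for rec in df.itertuples(index=False):
        out.append(FishTarget(x=float(rec.x), y=float(rec.y), depth_m=float(rec.depth_m),
                              ts_db=float(rec.ts_db),
                              length_cm=float(getattr(rec, "length_cm", float("nan"))),
                              size_class=str(getattr(rec, "size_class", "none"))))
    return out
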