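"""Occupancy-normalized rate maps, place-field detection and map statistics.

A trial's rate map is built from the trajectory and an activity train (spike
times with unit weights, or deconvolved calcium event weights):

1. samples slower than 2 cm/s are discarded from both the activity count and
   the occupancy (the animal must be moving for place coding to be read out);
2. activity and occupancy are binned on the 1 cm native grid (or on the
   anisotropic 1 cm x 1.5 cm grid for square-compressed maps);
3. both maps are smoothed with a Gaussian kernel (sigma = 3 cm, truncated at
   4 sigma and renormalized inside the chamber so no mass bleeds across
   walls), and rate = smoothed activity / smoothed occupancy;
4. pixels whose smoothed occupancy is below 0.05 s are masked as unsampled
   and never enter any downstream statistic.

Smoothing numerator and denominator with the same kernel before dividing
avoids the instability of ratios of nearly-empty bins; ``smooth_mode`` can
switch to dividing first and smoothing the ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy import ndimage

from . import geometry as geom
from .errors import DomainError, GeometryError

SPEED_THRESHOLD_CM_S = 2.0
OCCUPANCY_MIN_S = 0.05
SMOOTH_SIGMA_CM = 3.0
FIELD_PERCENTILE = 95.0


@dataclass
class Trajectory:
    """Timestamped path through the chamber, in canonical cm coordinates."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise DomainError("t, x, y must have equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise DomainError("timestamps must be strictly increasing")

    @property
    def speed(self) -> np.ndarray:
        """Instantaneous speed (cm/s), forward difference, last value repeated."""
        if len(self.t) < 2:
            return np.zeros(len(self.t))
        dt = np.diff(self.t)
        v = np.hypot(np.diff(self.x), np.diff(self.y)) / dt
        return np.append(v, v[-1])

    @property
    def frame_dt(self) -> np.ndarray:
        """Time credited to each sample (forward dt, last value repeated)."""
        if len(self.t) < 2:
            return np.ones(len(self.t))
        dt = np.diff(self.t)
        return np.append(dt, dt[-1])


@dataclass
class ActivityTrain:
    """Event times and nonnegative weights for one cell in one trial."""

    cell_id: int
    times: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.times)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise DomainError("event weights must be nonnegative")
        if len(self.weights) != len(self.times):
            raise DomainError("times and weights must have equal length")


@dataclass
class _FilteredSamples:
    """Speed-filtered raw samples retained so square maps can be re-binned
    from the data rather than resampled from the smoothed native map."""

    occ_x: np.ndarray
    occ_y: np.ndarray
    occ_dt: np.ndarray
    ev_x: np.ndarray
    ev_y: np.ndarray
    ev_w: np.ndarray


@dataclass
class OccupancyGrid:
    """Speed-filtered, smoothed occupancy for one trial on one binning.

    Occupancy depends only on the trajectory, so it is computed once per
    trial and shared across that trial's cells.
    """

    nx: int
    ny: int
    bin_x_cm: float
    bin_y_cm: float
    sigma_cm: float
    occupancy_min_s: float
    keep: np.ndarray            # per-frame speed filter
    occ_s: np.ndarray           # smoothed occupancy (s)
    mask: np.ndarray            # occ_s >= occupancy_min_s
    occ_x: np.ndarray
    occ_y: np.ndarray
    occ_dt: np.ndarray


def compute_occupancy(traj: Trajectory,
                      square: bool = False,
                      sigma_cm: float = SMOOTH_SIGMA_CM,
                      speed_threshold: float = SPEED_THRESHOLD_CM_S,
                      occupancy_min_s: float = OCCUPANCY_MIN_S) -> OccupancyGrid:
    """Bin and smooth the speed-filtered occupancy of one trial."""
    nx, ny = (geom.SQUARE_N, geom.SQUARE_N) if square else (geom.NX, geom.NY)
    bin_y = geom.SQUARE_BIN_Y_CM if square else geom.BIN_CM
    keep = traj.speed > speed_threshold
    ox, oy, odt = traj.x[keep], traj.y[keep], traj.frame_dt[keep]
    x_edges = np.arange(nx + 1) * geom.BIN_CM
    y_edges = np.arange(ny + 1) * bin_y
    occ, _, _ = np.histogram2d(oy, ox, bins=(y_edges, x_edges), weights=odt)
    occ_s = smooth_grid(occ, (sigma_cm / bin_y, sigma_cm / geom.BIN_CM))
    return OccupancyGrid(nx=nx, ny=ny, bin_x_cm=geom.BIN_CM, bin_y_cm=bin_y,
                         sigma_cm=sigma_cm, occupancy_min_s=occupancy_min_s,
                         keep=keep, occ_s=occ_s, mask=occ_s >= occupancy_min_s,
                         occ_x=ox, occ_y=oy, occ_dt=odt)


@dataclass
class RateMap:
    """Smoothed occupancy-normalized rate grid with a sampled-pixel mask.

    ``rate`` is NaN on unsampled pixels.  ``shape`` is (rows, cols) =
    (y bins, x bins); native maps are 30 x 20, square maps 20 x 20.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    sampled_mask: np.ndarray
    bin_x_cm: float
    bin_y_cm: float
    sigma_cm: float
    empty: bool = False
    raw: _FilteredSamples | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rate.shape

    @property
    def is_square(self) -> bool:
        return self.shape == (geom.SQUARE_N, geom.SQUARE_N)

    @property
    def center_cm(self) -> tuple[float, float]:
        return geom.CHAMBER_CENTER

    def sampled_rates(self) -> np.ndarray:
        return self.rate[self.sampled_mask]


@dataclass
class PlaceField:
    """A contiguous set of supra-threshold pixels of one rate map."""

    pixels: np.ndarray          # (k, 2) array of (row, col)
    rates: np.ndarray           # rate at each pixel
    area: int
    weighted_centroid_cm: tuple[float, float]
    peak_rate: float


def smooth_grid(grid: np.ndarray, sigma_bins: tuple[float, float]) -> np.ndarray:
    """Gaussian-smooth a grid, renormalizing the truncated kernel inside the
    chamber so edge pixels are not deflated by out-of-chamber zeros."""
    sy, sx = sigma_bins
    if sy == 0 and sx == 0:
        return grid.astype(float)
    sm = ndimage.gaussian_filter(grid.astype(float), sigma=(sy, sx), mode="constant", truncate=4.0)
    norm = _edge_norm(grid.shape, (sy, sx))
    return sm / norm


@lru_cache(maxsize=8)
def _edge_norm(shape: tuple[int, int], sigma_bins: tuple[float, float]) -> np.ndarray:
    ones = np.ones(shape)
    return ndimage.gaussian_filter(ones, sigma=sigma_bins, mode="constant", truncate=4.0)


def _filter_events(traj: Trajectory, act: ActivityTrain,
                   keep: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.searchsorted(traj.t, act.times, side="right") - 1
    idx = np.clip(idx, 0, len(traj.t) - 1)
    ev_keep = keep[idx]
    kept = idx[ev_keep]
    return traj.x[kept], traj.y[kept], act.weights[ev_keep]


def _build_map(occ: OccupancyGrid, ev_x: np.ndarray, ev_y: np.ndarray,
               ev_w: np.ndarray,
               smooth_mode: Literal["smooth_then_divide", "divide_then_smooth"],
               ) -> RateMap:
    x_edges = np.arange(occ.nx + 1) * occ.bin_x_cm
    y_edges = np.arange(occ.ny + 1) * occ.bin_y_cm
    actv, _, _ = np.histogram2d(ev_y, ev_x, bins=(y_edges, x_edges), weights=ev_w)
    sigma_bins = (occ.sigma_cm / occ.bin_y_cm, occ.sigma_cm / occ.bin_x_cm)
    mask = occ.mask
    empty = not mask.any()
    rate = np.full(actv.shape, np.nan)
    if not empty:
        if smooth_mode == "smooth_then_divide":
            act_s = smooth_grid(actv, sigma_bins)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = act_s / occ.occ_s
        else:
            occ_raw, _, _ = np.histogram2d(occ.occ_y, occ.occ_x,
                                           bins=(y_edges, x_edges),
                                           weights=occ.occ_dt)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(occ_raw > 0,
                                 actv / np.where(occ_raw > 0, occ_raw, 1.0), 0.0)
            r = smooth_grid(ratio, sigma_bins)
        rate[mask] = r[mask]
    raw = _FilteredSamples(occ_x=occ.occ_x, occ_y=occ.occ_y, occ_dt=occ.occ_dt,
                           ev_x=ev_x, ev_y=ev_y, ev_w=ev_w)
    return RateMap(rate=rate, occupancy=occ.occ_s, sampled_mask=mask.copy(),
                   bin_x_cm=occ.bin_x_cm, bin_y_cm=occ.bin_y_cm,
                   sigma_cm=occ.sigma_cm, empty=empty, raw=raw)


def compute_rate_map(
    traj: Trajectory,
    act: ActivityTrain,
    sigma_cm: float = SMOOTH_SIGMA_CM,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
    occupancy_min_s: float = OCCUPANCY_MIN_S,
    smooth_mode: Literal["smooth_then_divide", "divide_then_smooth"] = "smooth_then_divide",
    occupancy: OccupancyGrid | None = None,
) -> RateMap:
    """Native 1 cm rate map for one cell on one trial.

    A precomputed :class:`OccupancyGrid` for the same trial can be passed to
    avoid re-binning the trajectory per cell.  Zero total filtered occupancy
    yields a map flagged ``empty`` (all pixels unsampled) rather than NaN
    propagation downstream.
    """
    if occupancy is None:
        occupancy = compute_occupancy(traj, square=False, sigma_cm=sigma_cm,
                                      speed_threshold=speed_threshold,
                                      occupancy_min_s=occupancy_min_s)
    ev_x, ev_y, ev_w = _filter_events(traj, act, occupancy.keep)
    return _build_map(occupancy, ev_x, ev_y, ev_w, smooth_mode)


def compress_to_square(rate_map: RateMap,
                       occupancy: OccupancyGrid | None = None) -> RateMap:
    """Anisotropically re-bin the trial's raw filtered samples into the
    20 x 20 square grid (1 cm x-bins, 1.5 cm y-bins) and re-smooth.

    The compression reuses the raw data retained on the native map — it is
    not a resampling of the smoothed grid — so total event weight is
    conserved before normalization.
    """
    if rate_map.raw is None:
        raise GeometryError("rate map does not carry raw samples; cannot re-bin")
    if rate_map.is_square:
        raise GeometryError("map is already square-compressed")
    raw = rate_map.raw
    if occupancy is None:
        x_edges = np.arange(geom.SQUARE_N + 1) * geom.BIN_CM
        y_edges = np.arange(geom.SQUARE_N + 1) * geom.SQUARE_BIN_Y_CM
        occ, _, _ = np.histogram2d(raw.occ_y, raw.occ_x,
                                   bins=(y_edges, x_edges), weights=raw.occ_dt)
        occ_s = smooth_grid(occ, (rate_map.sigma_cm / geom.SQUARE_BIN_Y_CM,
                                  rate_map.sigma_cm / geom.BIN_CM))
        occupancy = OccupancyGrid(
            nx=geom.SQUARE_N, ny=geom.SQUARE_N, bin_x_cm=geom.BIN_CM,
            bin_y_cm=geom.SQUARE_BIN_Y_CM, sigma_cm=rate_map.sigma_cm,
            occupancy_min_s=OCCUPANCY_MIN_S, keep=np.array([]),
            occ_s=occ_s, mask=occ_s >= OCCUPANCY_MIN_S,
            occ_x=raw.occ_x, occ_y=raw.occ_y, occ_dt=raw.occ_dt)
    return _build_map(occupancy, raw.ev_x, raw.ev_y, raw.ev_w,
                      "smooth_then_divide")


def align_positions(
    raw_xy: np.ndarray,
    chamber_corners: np.ndarray,
    trial_orientation_deg: float = 0.0,
) -> np.ndarray:
    """Map video-frame positions into the canonical chamber frame.

    A planar projective transform (homography) is estimated from the four
    marked chamber corners to the canonical 20 x 30 cm rectangle; the corner
    correspondence is rolled by the known chamber orientation (multiples of
    90 deg) so the short wall adjacent to the rewarded corner lands on the
    same canonical side on every trial.
    """
    from skimage.transform import ProjectiveTransform

    corners = np.asarray(chamber_corners, dtype=float)
    if corners.shape != (4, 2):
        raise GeometryError("need exactly four chamber corners")
    if abs(np.linalg.matrix_rank(np.c_[corners, np.ones(4)]) ) < 3:
        raise GeometryError("chamber corners are collinear")
    k = int(round(trial_orientation_deg / 90.0)) % 4
    dst = np.roll(geom.CANONICAL_CORNERS, -k, axis=0)
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(corners, dst)
        ok = bool(tf)
    else:  # older scikit-image
        tf = ProjectiveTransform()
        ok = tf.estimate(corners, dst)
    if not ok or not np.all(np.isfinite(tf.params)):
        raise GeometryError("degenerate corner configuration")
    return tf(np.asarray(raw_xy, dtype=float))


def detect_place_fields(rate_map: RateMap,
                        percentile: float = FIELD_PERCENTILE) -> list[PlaceField]:
    """Contiguous pixel sets above the map's 95th-percentile rate.

    The percentile is taken over sampled pixels only (linear interpolation);
    components use 4-connectivity; fields are sorted by area descending (then
    by peak rate), so callers wanting "the" field take ``fields[0]``.
    An all-zero or empty map yields no fields.
    """
    if rate_map.empty or not rate_map.sampled_mask.any():
        return []
    vals = rate_map.sampled_rates()
    if np.nanmax(vals) <= 0:
        return []
    thr = np.percentile(vals, percentile)
    above = np.zeros(rate_map.shape, dtype=bool)
    above[rate_map.sampled_mask] = vals > thr
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(above, structure=structure)
    fields = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        rates = rate_map.rate[rows, cols]
        w = rates.sum()
        cx = float(np.sum((cols + 0.5) * rate_map.bin_x_cm * rates) / w)
        cy = float(np.sum((rows + 0.5) * rate_map.bin_y_cm * rates) / w)
        fields.append(PlaceField(
            pixels=np.column_stack([rows, cols]),
            rates=rates,
            area=len(rows),
            weighted_centroid_cm=(cx, cy),
            peak_rate=float(rates.max()),
        ))
    fields.sort(key=lambda f: (-f.area, -f.peak_rate, f.pixels[0, 0], f.pixels[0, 1]))
    return fields


def center_out_angle(place_field: PlaceField,
                     map_center_cm: tuple[float, float] = geom.CHAMBER_CENTER,
                     ) -> float | None:
    """Angle (deg, [0, 360)) from the map center to the field's rate-weighted
    centroid; None if the centroid coincides with the center."""
    cx, cy = place_field.weighted_centroid_cm
    dx, dy = cx - map_center_cm[0], cy - map_center_cm[1]
    if np.hypot(dx, dy) < 1e-9:
        return None
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def trial_rate_stats(
    act: ActivityTrain,
    traj: Trajectory,
    mode: Literal["mean", "peak"] = "mean",
    rate_map: RateMap | None = None,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
) -> float | None:
    """Per-trial firing-rate summary.

    ``mean`` = total speed-filtered event weight / total filtered time (an
    empty train gives 0).  ``peak`` = maximum sampled smoothed rate of the
    trial's map (built on demand unless supplied).  Returns None when the
    filtered time is zero.
    """
    keep = traj.speed > speed_threshold
    total_t = float(traj.frame_dt[keep].sum())
    if total_t <= 0:
        return None
    if mode == "mean":
        _, _, ev_w = _filter_events(traj, act, keep)
        return float(ev_w.sum()) / total_t
    if mode == "peak":
        rm = rate_map if rate_map is not None else compute_rate_map(traj, act)
        if rm.empty:
            return None
        return float(np.nanmax(rm.sampled_rates()))
    raise DomainError(f"unknown mode {mode!r}")


def spatial_information(rate_map: RateMap) -> float | None:
    """Skaggs spatial information content, bits per event:
    sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda), over sampled
    pixels, with p_i the occupancy probability.  None when the overall mean
    rate is zero."""
    if rate_map.empty:
        return None
    occ = rate_map.occupancy[rate_map.sampled_mask]
    lam = rate_map.sampled_rates()
    p = occ / occ.sum()
    mean_rate = float(np.sum(p * lam))
    if mean_rate <= 0:
        return None
    ratio = lam / mean_rate
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def masked_pearson(a: np.ndarray, b: np.ndarray,
                   mask_a: np.ndarray, mask_b: np.ndarray,
                   min_overlap: int = 1) -> tuple[float, int]:
    """Pearson correlation over pixels sampled in both maps.

    Returns (r, n_overlap); r is NaN when the overlap is below
    ``min_overlap`` or either masked vector has zero variance.
    """
    m = mask_a & mask_b
    n = int(m.sum())
    if n < max(min_overlap, 2):
        return float("nan"), n
    av, bv = a[m], b[m]
    if np.std(av) == 0 or np.std(bv) == 0:
        return float("nan"), n
    return float(np.corrcoef(av, bv)[0, 1]), n
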