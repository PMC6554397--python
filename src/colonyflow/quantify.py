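"""Image quantification: segmentation, coverage, colony areas, mixing,
attachment-event detection and the attachment-probability estimator.

The pipeline mirrors a standard two-channel epifluorescence analysis of
early biofilms:

1. each channel is segmented with a local-mean adaptive threshold whose
   sensitivity (and an optional background-percentile floor) is chosen
   from the image's median intensity, then objects smaller than 15 px
   (the area of a single upright cell) are discarded;
2. the two channel masks are OR-merged; surface coverage is the covered
   pixel fraction; images above 80% coverage are excluded from colony
   statistics because individual clusters can no longer be resolved;
3. colony areas: objects under 200 px (~5 cells) are removed, the mask is
   morphologically closed with a disk of radius 5 px to bridge sub-cell
   gaps, and connected-component areas are reported in um^2 (median per
   image);
4. clonal mixing: each channel is closed separately, and for every colony
   centroid the Euclidean distance to the nearest centroid of the other
   color is pooled over both directions (mean/SD in um);
5. attachment events in a timelapse are new objects persisting at the same
   location (within a pixel tolerance) for at least three consecutive
   frames; the attachment rate is the OLS slope of the cumulative event
   count, and Eq.-style normalisation by the cell flux gives
   ``p_att = r / (Q * C)``.

The sensitivity-vs-median and background-vs-median calibrations such
pipelines use in practice are instrument-specific; both are exposed here
as configurable piecewise-linear mappings with documented defaults.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .errors import InvalidParameterError
from .geometry import ChannelGeometry

#: Minimum object area (px): the observed area of a single upright cell.
MIN_OBJECT_AREA_PX = 15
#: Minimum colony area (px): ~ a group of five cells.
MIN_COLONY_AREA_PX = 200
#: Empirical mean cell footprint (um^2) and its pixel-area equivalent.
CELL_AREA_UM2 = 1.29
CELL_AREA_PX = 40.2
#: Coverage above which colony/mixing statistics are not computed.
COVERAGE_GATE = 0.8
CLOSING_RADIUS_PX = 5


@dataclass(frozen=True)
class SegParams:
    """Adaptive-threshold segmentation parameters.

    The local threshold interpolates between the local background mean
    (a ``block_size`` moving average) and a robust foreground plateau
    level ``F`` (the 75th percentile of clearly-bright pixels)::

        T(x) = mean_local(x) + (1 - s) * (F - mean_local(x))

    where the sensitivity ``s`` is read off a piecewise-linear mapping of
    the normalised median intensity (higher sensitivity -> lower
    threshold -> more foreground; ``s = 0.5`` thresholds at the half-max
    contour, which best recovers the pre-blur object outline).  A second
    mapping gives the percentage of dimmest pixels excluded outright
    (background removal).  Breakpoints are (median, value) pairs.
    """

    block_size: int = 251
    sensitivity_breakpoints: tuple = ((0.0, 0.50), (0.2, 0.65))
    background_breakpoints: tuple = ((0.0, 0.0), (0.2, 10.0))
    min_area: int = MIN_OBJECT_AREA_PX
    foreground_zscore: float = 5.0
    foreground_percentile: float = 75.0

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise InvalidParameterError("min_area must be >= 1")
        for _, s in self.sensitivity_breakpoints:
            if not (0.0 < s <= 1.0):
                raise InvalidParameterError("sensitivity values must lie in (0, 1]")


@dataclass
class SegmentationResult:
    """Binary mask plus labelled objects (areas in px, centroids in px)."""

    mask: np.ndarray
    labels: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray  # (n, 2) array of (row, col)
    channel: str = ""

    @property
    def n_objects(self) -> int:
        return self.areas.size


@dataclass
class ColonyStats:
    """Coverage, post-filter colony areas (um^2) and their median.

    ``excluded`` is True when coverage exceeds the 80% gate, in which case
    no colony areas are reported.
    """

    coverage: float
    excluded: bool
    areas_um2: np.ndarray
    median_um2: float


@dataclass
class MixingStats:
    """Pooled cross-lineage nearest-neighbour distances (um).

    ``defined`` is False when either channel has no colonies: mixing is
    then undefined, which is distinct from zero distance.
    """

    defined: bool
    distances_um: np.ndarray
    mean_um: float
    std_um: float

    @property
    def n(self) -> int:
        return self.distances_um.size


@dataclass
class AttachmentRate:
    """OLS attachment rate (slope of cumulative events vs time)."""

    rate: float  # cells / s
    stderr: float
    n_events: int


@dataclass
class AttachmentEstimate:
    """Attachment probability p_att = r / (Q*C), with flux J = Q*C/A."""

    p_att: float
    rate: float
    flow_rate: float
    concentration: float
    flux: float | None = None


# ---------------------------------------------------------------------------
# segmentation and mask statistics
# ---------------------------------------------------------------------------

def _normalized_median(raster: np.ndarray) -> float:
    med = float(np.median(raster))
    if np.issubdtype(raster.dtype, np.integer):
        return med / np.iinfo(raster.dtype).max
    return med / max(float(raster.max()), 1e-12)


def _empty_result(shape, channel) -> SegmentationResult:
    return SegmentationResult(
        mask=np.zeros(shape, dtype=bool),
        labels=np.zeros(shape, dtype=np.int32),
        areas=np.empty(0, dtype=int),
        centroids=np.empty((0, 2)),
        channel=channel,
    )


def segment_channel(
    raster: np.ndarray, params: SegParams | None = None, channel: str = ""
) -> SegmentationResult:
    """Adaptive-threshold segmentation of one fluorescence channel.

    A constant-intensity raster (no information) yields an empty result
    with a warning, mirroring the exclusion of aberrant segmentations.
    Objects are 8-connected; those below ``params.min_area`` px are
    removed.
    """
    params = params or SegParams()
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise InvalidParameterError("raster must be 2-d")
    if raster.min() < 0:
        raise InvalidParameterError("raster intensities must be nonnegative")
    img = raster.astype(float)
    if np.ptp(img) == 0:
        warnings.warn("constant-intensity raster: aberrant segmentation, returning empty",
                      stacklevel=2)
        return _empty_result(raster.shape, channel)

    med = _normalized_median(raster)
    sx, sy = zip(*params.sensitivity_breakpoints)
    sensitivity = float(np.interp(med, sx, sy))
    bx, by = zip(*params.background_breakpoints)
    bg_pct = float(np.interp(med, bx, by))

    local_mean = ndimage.uniform_filter(img, size=params.block_size, mode="reflect")
    # robust foreground plateau: bright pixels well above the background
    sigma_bg = 1.4826 * float(np.median(np.abs(img - np.median(img))))
    bright = img > local_mean + params.foreground_zscore * max(sigma_bg, 1e-12)
    if bright.sum() < params.min_area:
        # no resolvable foreground (blank or pure-noise field)
        return _empty_result(raster.shape, channel)
    plateau = float(np.percentile(img[bright], params.foreground_percentile))
    threshold = local_mean + (1.0 - sensitivity) * (plateau - local_mean)
    mask = img > threshold
    if bg_pct > 0:
        mask &= img > np.percentile(img, bg_pct)

    mask = _remove_small(mask, params.min_area)
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props], dtype=int)
    centroids = (
        np.array([p.centroid for p in props]) if props else np.empty((0, 2))
    )
    return SegmentationResult(mask=mask, labels=labels.astype(np.int32),
                              areas=areas, centroids=centroids, channel=channel)


def surface_coverage(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Fraction of pixels covered by the OR-merge of the two channel masks."""
    if mask_a.shape != mask_b.shape:
        raise InvalidParameterError("masks must have the same shape")
    return float(np.logical_or(mask_a, mask_b).mean())


def _disk_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing with a disk, padded so border objects are unaffected."""
    footprint = morphology.disk(radius)
    padded = np.pad(mask.astype(bool), radius, mode="constant")
    closed = morphology.closing(padded, footprint)
    return closed[radius:-radius, radius:-radius].astype(bool)


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected objects with area < min_size pixels."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def colony_areas(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    pixel_um: float,
    min_colony_px: int = MIN_COLONY_AREA_PX,
    closing_radius: int = CLOSING_RADIUS_PX,
    coverage_gate: float = COVERAGE_GATE,
    filter_before_close: bool = True,
) -> ColonyStats:
    """Colony area statistics on the OR-merged mask.

    Images above the coverage gate are flagged excluded with no areas.
    Default order is filter-then-close; the alternative order is available
    for sensitivity analysis via ``filter_before_close=False``.
    """
    if pixel_um <= 0:
        raise InvalidParameterError("pixel_um must be > 0")
    coverage = surface_coverage(mask_a, mask_b)
    if coverage > coverage_gate:
        return ColonyStats(coverage=coverage, excluded=True,
                           areas_um2=np.empty(0), median_um2=math.nan)
    merged = np.logical_or(mask_a, mask_b)
    if filter_before_close:
        merged = _remove_small(merged, min_colony_px)
        closed = _disk_closing(merged, closing_radius)
    else:
        closed = _disk_closing(merged, closing_radius)
        closed = _remove_small(closed, min_colony_px)
    labels = measure.label(closed, connectivity=2)
    areas_px = np.bincount(labels.ravel())[1:]
    areas_px = areas_px[areas_px > 0]
    areas_um2 = areas_px * pixel_um**2
    median = float(np.median(areas_um2)) if areas_um2.size else math.nan
    return ColonyStats(coverage=coverage, excluded=False,
                       areas_um2=areas_um2, median_um2=median)


# ---------------------------------------------------------------------------
# cross-lineage mixing
# ---------------------------------------------------------------------------

def nearest_cross_distances(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Pooled nearest-neighbour distances A->B and B->A (same units as input)."""
    points_a = np.atleast_2d(points_a)
    points_b = np.atleast_2d(points_b)
    d_ab, _ = cKDTree(points_b).query(points_a)
    d_ba, _ = cKDTree(points_a).query(points_b)
    return np.concatenate([np.atleast_1d(d_ab), np.atleast_1d(d_ba)])


def _colony_centroids(mask: np.ndarray, closing_radius: int, min_colony_px: int | None):
    closed = _disk_closing(mask.astype(bool), closing_radius)
    if min_colony_px:
        closed = _remove_small(closed, min_colony_px)
    labels = measure.label(closed, connectivity=2)
    props = measure.regionprops(labels)
    return np.array([p.centroid for p in props]) if props else np.empty((0, 2))


def cross_lineage_mixing(
    result_a: SegmentationResult,
    result_b: SegmentationResult,
    pixel_um: float,
    closing_radius: int = CLOSING_RADIUS_PX,
    min_colony_px: int | None = None,
) -> MixingStats:
    """Cross-lineage colony distances between the two channels.

    Each channel mask is closed separately before centroid extraction; for
    every colony the distance to the nearest opposite-color centroid is
    pooled over both directions.  By default no minimum-colony filter is
    applied for mixing (only the closing); pass ``min_colony_px`` to apply
    one.  If either channel has no colonies the statistic is undefined.
    """
    if result_a.mask.shape != result_b.mask.shape:
        raise InvalidParameterError("channel masks must have the same shape")
    if pixel_um <= 0:
        raise InvalidParameterError("pixel_um must be > 0")
    cent_a = _colony_centroids(result_a.mask, closing_radius, min_colony_px)
    cent_b = _colony_centroids(result_b.mask, closing_radius, min_colony_px)
    if cent_a.size == 0 or cent_b.size == 0:
        return MixingStats(defined=False, distances_um=np.empty(0),
                           mean_um=math.nan, std_um=math.nan)
    d = nearest_cross_distances(cent_a, cent_b) * pixel_um
    return MixingStats(defined=True, distances_um=d,
                       mean_um=float(d.mean()),
                       std_um=float(d.std(ddof=1)) if d.size > 1 else 0.0)


def mixing_from_tables(
    centroids_a_um: np.ndarray, centroids_b_um: np.ndarray
) -> MixingStats:
    """Mixing statistic computed directly from ground-truth colony tables."""
    a = np.atleast_2d(np.asarray(centroids_a_um, dtype=float))
    b = np.atleast_2d(np.asarray(centroids_b_um, dtype=float))
    if a.size == 0 or b.size == 0:
        return MixingStats(defined=False, distances_um=np.empty(0),
                           mean_um=math.nan, std_um=math.nan)
    d = nearest_cross_distances(a, b)
    return MixingStats(defined=True, distances_um=d,
                       mean_um=float(d.mean()),
                       std_um=float(d.std(ddof=1)) if d.size > 1 else 0.0)


# ---------------------------------------------------------------------------
# attachment kinetics (timelapse)
# ---------------------------------------------------------------------------

def detect_attachment_events(
    frames,
    frame_times,
    epsilon_px: float = 3.0,
    min_consecutive: int = 3,
) -> np.ndarray:
    """Detect attachment events in a timelapse of per-frame detections.

    ``frames`` is a sequence of (k_i, 2) centroid arrays (px), one per
    frame, at uniformly spaced ``frame_times`` (s).  An attachment event
    is recorded at the first frame of each maximal run of >=
    ``min_consecutive`` detections whose centroid stays within
    ``epsilon_px`` from frame to frame ("same location").  Returns sorted
    event times.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frames) != frame_times.size:
        raise InvalidParameterError("frames and frame_times must have equal length")
    if frame_times.size < min_consecutive:
        raise InvalidParameterError(f"need at least {min_consecutive} frames")
    dts = np.diff(frame_times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise InvalidParameterError("frame times must be uniformly spaced")

    events: list[float] = []
    tracks: list[dict] = []  # {pos, start_time, length, counted}
    for t, dets in zip(frame_times, frames):
        dets = np.atleast_2d(np.asarray(dets, dtype=float)) if len(dets) else np.empty((0, 2))
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if tracks and dets.shape[0]:
            pos = np.array([tr["pos"] for tr in tracks])
            dist = np.linalg.norm(pos[:, None, :] - dets[None, :, :], axis=2)
            pairs = np.argwhere(dist <= epsilon_px)
            order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
            for ti, di in pairs[order]:
                if ti in matched_tracks or di in matched_dets:
                    continue
                matched_tracks.add(int(ti))
                matched_dets.add(int(di))
                tr = tracks[ti]
                tr["pos"] = dets[di]
                tr["length"] += 1
                if tr["length"] == min_consecutive and not tr["counted"]:
                    tr["counted"] = True
                    events.append(tr["start"])
        tracks = [tr for i, tr in enumerate(tracks) if i in matched_tracks]
        for di in range(dets.shape[0]):
            if di not in matched_dets:
                tracks.append({"pos": dets[di], "start": t, "length": 1, "counted": False})
    return np.sort(np.asarray(events))


def attachment_rate(event_times, frame_times) -> AttachmentRate:
    """Attachment rate = OLS slope of cumulative event count vs time.

    With zero events the rate is 0 with infinite standard error (flagged
    via ``stderr = inf``).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    event_times = np.sort(np.asarray(event_times, dtype=float))
    if frame_times.size < 2 or np.ptp(frame_times) <= 0:
        raise InvalidParameterError("observation span must be positive")
    if event_times.size == 0:
        return AttachmentRate(rate=0.0, stderr=math.inf, n_events=0)
    cumulative = np.searchsorted(event_times, frame_times, side="right")
    res = stats.linregress(frame_times, cumulative)
    return AttachmentRate(rate=float(res.slope), stderr=float(res.stderr),
                          n_events=event_times.size)


def attachment_probability(
    rate: float,
    flow_rate: float,
    concentration: float,
    geometry: ChannelGeometry | None = None,
) -> AttachmentEstimate:
    """Attachment probability p_att = r / (Q*C).

    ``rate`` in cells/s, ``flow_rate`` Q in m^3/s, ``concentration`` C in
    cells/m^3.  Q*C is the number of cells traversing the channel per
    second; normalising by it yields a probability.  When a geometry is
    supplied the areal flux J = Q*C/A is also reported.  A result above 1
    (more attachments than through-flux) indicates inconsistent inputs and
    raises.
    """
    if flow_rate <= 0 or concentration <= 0:
        raise InvalidParameterError("flow_rate and concentration must be > 0")
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    p = rate / (flow_rate * concentration)
    if p > 1.0:
        raise InvalidParameterError(
            f"p_att = {p:.3g} > 1: attachment rate exceeds the cell through-flux"
        )
    flux = flow_rate * concentration / geometry.area if geometry is not None else None
    return AttachmentEstimate(p_att=p, rate=rate, flow_rate=flow_rate,
                              concentration=concentration, flux=flux)


def colony_filter_cell_equivalent(
    min_colony_px: int = MIN_COLONY_AREA_PX, cell_area_px: float = CELL_AREA_PX
) -> int:
    """Number of average cells corresponding to the minimum colony area."""
    return round(min_colony_px / cell_area_px)
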