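"""Frame Difference Method (FDM) analysis of time-lapse biosensor movies.

FDM turns a raw intensity movie into a percent-change movie: each pixel's
temporally averaged intensity is compared with the average one differencing
interval later, and the difference is expressed as a percentage of the
earlier value (+100 = a doubling).  Thresholding the percent-change movie
then separates three classes of dynamic events:

* boundary protrusions — strong (>=100% over 6 min) increases in a band
  around the cell outline, tracked over time with duration and size
  filters;
* interior flashes — weaker (>=10%) transients away from the boundary,
  detected after eroding the cell mask;
* perimeter kymographs — percent change sampled along the cell outline,
  binned by arclength, position vs time.

All operations are deterministic: fixed inputs give bitwise-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import InvalidInputError, SegmentationFailureError


@dataclass
class ImageStack:
    """A single-channel T × H × W time-lapse with acquisition calibration."""

    data: np.ndarray
    frame_interval: float  # minutes per frame
    pixel_size: float | None = None  # length per pixel, if known
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise InvalidInputError("ImageStack needs a T x H x W array with T >= 2")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise InvalidInputError("intensities must be finite and non-negative")
        if self.frame_interval <= 0:
            raise InvalidInputError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class FdmStack:
    """Percent-change movie produced by :func:`frame_difference_pct`.

    ``pct[i]`` compares the ``avg_window``-frame average starting at raw
    frame ``i`` (earlier) with the one starting at ``i + interval_frames``
    (later).  Pixels whose earlier average fell below ``floor_used`` are
    NaN in ``pct`` and flagged in ``invalid``; they are never silently
    zero.  FDM frame ``i`` is aligned to the later window start, the time
    by which the change has happened.
    """

    pct: np.ndarray  # T' x H x W, NaN at masked pixels
    invalid: np.ndarray  # boolean, True where the denominator was floored
    interval_minutes: float
    interval_frames: int
    avg_window: int
    floor_used: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.pct.shape[0]

    def later_frame_index(self, i: int) -> int:
        """Raw-stack frame index of FDM frame ``i`` (later-window start)."""
        return i + self.interval_frames

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Percent-change array with masked pixels replaced by ``fill``."""
        out = self.pct.copy()
        out[self.invalid] = fill
        return out


@dataclass
class CellMask:
    """Per-frame segmentation: boolean mask, boundary polyline, centroid."""

    masks: np.ndarray  # T x H x W boolean
    boundaries: list[np.ndarray]  # per frame, (N, 2) array of (row, col)
    centroids: np.ndarray  # T x 2, (row, col)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass
class ProtrusionEvent:
    """A tracked spatiotemporal event in the percent-change movie."""

    id: int
    first_frame: int  # FDM frame indices
    last_frame: int
    duration: float  # minutes, (last - first + 1) * frame_interval
    area_per_frame: list[int]  # pixels per frame within the span
    peak_area: int
    centroid_trace: np.ndarray  # (n_frames_in_span, 2) of (row, col)
    angular_position: float  # radians on the perimeter, from cell centroid
    magnitude: float  # integrated percent-change over the event's pixels

    @property
    def onset_frame(self) -> int:
        return self.first_frame


def angle_of(row: float, col: float, centroid: np.ndarray) -> float:
    """Angle of an image point about a centroid, in [0, 2π).

    Convention used package-wide: 0 along the +x (column) axis,
    increasing counter-clockwise with the y axis pointing up (image rows
    decreasing).  Pixel coordinates are 0-based, row-major, origin
    top-left.
    """
    return float(np.arctan2(centroid[0] - row, col - centroid[1]) % (2 * np.pi))


def point_at(centroid, radius: float, theta: float) -> tuple[float, float]:
    """Inverse of :func:`angle_of`: (row, col) at ``radius`` and ``theta``."""
    return (
        float(centroid[0] - radius * np.sin(theta)),
        float(centroid[1] + radius * np.cos(theta)),
    )


def temporal_average(stack: ImageStack, window: int = 3) -> ImageStack:
    """Sliding-window temporal mean; filters rapid boundary undulations.

    Output has ``T - window + 1`` frames; frame ``i`` averages raw frames
    ``[i, i + window)`` and keeps the window-start timestamp.
    """
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    if window > stack.n_frames:
        raise InvalidInputError(f"window {window} exceeds stack length {stack.n_frames}")
    if window == 1:
        data = stack.data.copy()
    else:
        csum = np.cumsum(stack.data, axis=0, dtype=float)
        csum = np.concatenate([np.zeros((1,) + stack.data.shape[1:]), csum], axis=0)
        data = (csum[window:] - csum[:-window]) / window
    return ImageStack(
        data=data,
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
        channel=stack.channel,
    )


def frame_difference_pct(
    stack: ImageStack,
    interval_minutes: float = 6.0,
    avg_window: int = 3,
    intensity_floor: float | None = None,
) -> FdmStack:
    """Pixelwise percent change across ``interval_minutes``.

    Both the earlier and the later values are ``avg_window``-frame
    temporal averages (averaging precedes differencing); the denominator
    is the earlier average, so +100 means a twofold increase.  The floor
    defaults to 1% of the stack maximum and masks near-zero denominators.
    """
    ratio = interval_minutes / stack.frame_interval
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise InvalidInputError(
            f"interval {interval_minutes} min is not a whole number of frames "
            f"at {stack.frame_interval} min/frame"
        )
    if k < avg_window:
        raise InvalidInputError(
            f"interval ({k} frames) overlaps the {avg_window}-frame averaging window"
        )
    avg = temporal_average(stack, avg_window).data
    if avg.shape[0] <= k:
        raise InvalidInputError("stack too short for the requested interval")
    earlier = avg[:-k]
    later = avg[k:]
    floor = (
        float(intensity_floor)
        if intensity_floor is not None
        else 0.01 * float(stack.data.max())
    )
    invalid = earlier < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (later - earlier) / earlier
    pct[invalid] = np.nan
    return FdmStack(
        pct=pct,
        invalid=invalid,
        interval_minutes=interval_minutes,
        interval_frames=k,
        avg_window=avg_window,
        floor_used=floor,
        frame_interval=stack.frame_interval,
    )


def _segment_frame(frame: np.ndarray) -> np.ndarray:
    if frame.max() <= 0:
        raise SegmentationFailureError("frame is empty (all-zero)")
    thr = threshold_otsu(frame)
    fg = frame > thr
    if not fg.any():
        raise SegmentationFailureError("empty foreground after thresholding")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fg = labels == int(np.argmax(counts))
    return ndimage.binary_fill_holes(fg)


def segment_cell(stack: ImageStack) -> CellMask:
    """Histogram-threshold segmentation of the single dominant cell.

    Per frame: Otsu threshold, largest 8-connected component, hole fill;
    the boundary is the longest iso-contour of the mask, returned as an
    ordered closed polyline.  Deterministic by construction.
    """
    masks = np.empty(stack.shape, dtype=bool)
    boundaries: list[np.ndarray] = []
    centroids = np.empty((stack.n_frames, 2))
    for i, frame in enumerate(stack.data):
        try:
            m = _segment_frame(frame)
        except SegmentationFailureError as e:
            raise SegmentationFailureError(f"frame {i}: {e}") from None
        masks[i] = m
        contours = measure.find_contours(m.astype(float), 0.5)
        if not contours:
            raise SegmentationFailureError(f"frame {i}: no boundary contour")
        boundaries.append(max(contours, key=len))
        centroids[i] = ndimage.center_of_mass(m)
    return CellMask(masks=masks, boundaries=boundaries, centroids=centroids)


def _boundary_band(mask: np.ndarray, width: int = 3) -> np.ndarray:
    """Pixels within ``width`` px of the mask outline, inside or outside."""
    selem = morphology.disk(width)
    return ndimage.binary_dilation(mask, structure=selem) & ~ndimage.binary_erosion(
        mask, structure=selem
    )


def _track_regions(binary: np.ndarray, pct_filled: np.ndarray) -> list[dict]:
    """Group thresholded pixels into spatiotemporal tracks.

    Within a frame: 8-connected components.  Across frames: components in
    consecutive frames belong to the same track when they overlap by at
    least one pixel (no gap closing); tracks that merge count as one
    event.
    """
    n_frames = binary.shape[0]
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    labeled = np.empty_like(binary, dtype=np.int32)
    for t in range(n_frames):
        lab = measure.label(binary[t], connectivity=2)
        labeled[t] = lab
        for r in range(1, lab.max() + 1):
            parent[(t, r)] = (t, r)
        if t > 0:
            overlap = binary[t] & binary[t - 1]
            for rr, cc in zip(*np.nonzero(overlap)):
                union((t, labeled[t, rr, cc]), (t - 1, labeled[t - 1, rr, cc]))

    tracks: dict[tuple[int, int], dict] = {}
    for t in range(n_frames):
        lab = labeled[t]
        for r in range(1, lab.max() + 1):
            root = find((t, r))
            region = lab == r
            rows, cols = np.nonzero(region)
            tr = tracks.setdefault(root, {"frames": {}, "magnitude": 0.0})
            fr = tr["frames"].setdefault(t, {"area": 0, "rsum": 0.0, "csum": 0.0})
            fr["area"] += int(region.sum())
            fr["rsum"] += float(rows.sum())
            fr["csum"] += float(cols.sum())
            tr["magnitude"] += float(pct_filled[t][region].sum())
    return list(tracks.values())


def _tracks_to_events(
    tracks: list[dict],
    frame_interval: float,
    centroids: np.ndarray,
    fdm: FdmStack,
    min_duration: float,
    min_area: int,
) -> list[ProtrusionEvent]:
    events = []
    for tr in tracks:
        frames = sorted(tr["frames"])
        first, last = frames[0], frames[-1]
        duration = (last - first + 1) * frame_interval
        areas = [
            tr["frames"][t]["area"] if t in tr["frames"] else 0
            for t in range(first, last + 1)
        ]
        peak_area = max(areas)
        if duration < min_duration or peak_area < min_area:
            continue
        ctrace = np.array(
            [
                (
                    tr["frames"][t]["rsum"] / tr["frames"][t]["area"],
                    tr["frames"][t]["csum"] / tr["frames"][t]["area"],
                )
                for t in frames
            ]
        )
        w = np.array([tr["frames"][t]["area"] for t in frames], dtype=float)
        rbar = float(np.average(ctrace[:, 0], weights=w))
        cbar = float(np.average(ctrace[:, 1], weights=w))
        cell_centroid = centroids[min(fdm.later_frame_index(first), len(centroids) - 1)]
        events.append(
            ProtrusionEvent(
                id=-1,
                first_frame=first,
                last_frame=last,
                duration=duration,
                area_per_frame=areas,
                peak_area=peak_area,
                centroid_trace=ctrace,
                angular_position=angle_of(rbar, cbar, cell_centroid),
                magnitude=tr["magnitude"],
            )
        )
    events.sort(key=lambda e: (e.first_frame, e.angular_position))
    for k, e in enumerate(events):
        e.id = k
    return events


def _aligned_mask_frame(mask: CellMask, fdm: FdmStack, i: int) -> int:
    j = fdm.later_frame_index(i)
    return min(j, mask.n_frames - 1)


def detect_protrusions(
    fdm: FdmStack,
    mask: CellMask,
    threshold_pct: float = 100.0,
    min_duration: float = 5.0,
    min_area: int = 25,
    band_width: int = 3,
) -> list[ProtrusionEvent]:
    """Detect and track boundary protrusions in the percent-change movie.

    Pixels with pct >= ``threshold_pct`` inside a band of ``band_width``
    px around the cell outline are grouped by 8-connectivity per frame
    and linked across frames by pixel overlap; tracks shorter than
    ``min_duration`` minutes or never reaching ``min_area`` px are
    discarded.  Events are reported sorted by onset.
    """
    if mask.n_frames < fdm.later_frame_index(fdm.n_frames - 1) + 1:
        raise InvalidInputError(
            f"mask has {mask.n_frames} frames; FDM needs raw-frame coverage up to "
            f"{fdm.later_frame_index(fdm.n_frames - 1)}"
        )
    pct_thresh = fdm.filled(fill=-np.inf)
    binary = np.empty(fdm.pct.shape, dtype=bool)
    for i in range(fdm.n_frames):
        j = _aligned_mask_frame(mask, fdm, i)
        band = _boundary_band(mask.masks[j], band_width)
        binary[i] = (pct_thresh[i] >= threshold_pct) & band
    tracks = _track_regions(binary, fdm.filled(0.0))
    return _tracks_to_events(
        tracks, fdm.frame_interval, mask.centroids, fdm, min_duration, min_area
    )


def interior_flashes(
    fdm: FdmStack,
    mask: CellMask,
    threshold_pct: float = 10.0,
    boundary_margin: int = 5,
    min_duration: float = 0.0,
    min_area: int = 9,
) -> list[ProtrusionEvent]:
    """Detect interior activity flashes after removing boundary pixels.

    The cell mask is eroded by ``boundary_margin`` px and pct >=
    ``threshold_pct`` is tracked inside the eroded region, with no
    minimum-duration filter by default.
    """
    if boundary_margin < 1:
        raise InvalidInputError("boundary_margin must be >= 1")
    selem = morphology.disk(boundary_margin)
    pct_thresh = fdm.filled(fill=-np.inf)
    binary = np.empty(fdm.pct.shape, dtype=bool)
    for i in range(fdm.n_frames):
        j = _aligned_mask_frame(mask, fdm, i)
        interior = ndimage.binary_erosion(mask.masks[j], structure=selem)
        if not interior.any():
            raise InvalidInputError(
                f"erosion by {boundary_margin} px emptied the mask at frame {j}"
            )
        binary[i] = (pct_thresh[i] >= threshold_pct) & interior
    tracks = _track_regions(binary, fdm.filled(0.0))
    return _tracks_to_events(
        tracks, fdm.frame_interval, mask.centroids, fdm, min_duration, min_area
    )


def protrusion_frequency(events: list[ProtrusionEvent], total_time: float) -> float:
    """Events per hour over ``total_time`` minutes of imaging."""
    if total_time <= 0:
        raise InvalidInputError("total_time must be positive")
    return len(events) * 60.0 / total_time


def boundary_kymograph(
    fdm: FdmStack,
    mask: CellMask,
    n_bins: int = 300,
    band_width: int = 2,
) -> np.ndarray:
    """Percent change around the perimeter vs time (``n_bins`` × T').

    For each FDM frame the percent-change image (masked pixels treated as
    0, the no-change value) is max-pooled over a ``band_width``-px disc
    and sampled along the boundary polyline, resampled by arclength into
    ``n_bins`` starting from the boundary point at angle 0 (the +x axis
    from the centroid) and proceeding counter-clockwise.
    """
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    kymo = np.empty((n_bins, fdm.n_frames))
    selem = morphology.disk(band_width)
    pct0 = fdm.filled(0.0)
    for i in range(fdm.n_frames):
        j = _aligned_mask_frame(mask, fdm, i)
        contour = mask.boundaries[j]
        if len(contour) < 8:
            raise InvalidInputError(f"degenerate boundary (<8 points) at frame {j}")
        pooled = ndimage.grey_dilation(pct0[i], footprint=selem)
        centroid = mask.centroids[j]
        angles = np.array([angle_of(r, c, centroid) for r, c in contour])
        # orient counter-clockwise in the package convention and start the
        # polyline at the point nearest angle 0
        if np.diff(np.unwrap(angles)).sum() < 0:
            contour = contour[::-1]
            angles = angles[::-1]
        start = int(np.argmin(angles))
        contour = np.roll(contour, -start, axis=0)
        seglen = np.linalg.norm(
            np.diff(contour, axis=0, append=contour[:1]), axis=1
        )
        arclen = np.concatenate([[0.0], np.cumsum(seglen[:-1])])
        total = arclen[-1] + seglen[-1]
        targets = total * np.arange(n_bins) / n_bins
        rows = np.interp(targets, arclen, contour[:, 0])
        cols = np.interp(targets, arclen, contour[:, 1])
        kymo[:, i] = ndimage.map_coordinates(
            pooled, np.vstack([rows, cols]), order=1, mode="nearest"
        )
    return kymo


def protrusion_area_trace(
    fdm: FdmStack,
    mask: CellMask,
    threshold_pct: float = 100.0,
    band_width: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """(times_minutes, area_px) of thresholded boundary-band pixels per frame.

    The per-frame protrusion area is the summary used against reporter
    traces in lag analyses; times are aligned to the later FDM window.
    """
    pct = fdm.filled(fill=-np.inf)
    areas = np.empty(fdm.n_frames)
    for i in range(fdm.n_frames):
        j = _aligned_mask_frame(mask, fdm, i)
        band = _boundary_band(mask.masks[j], band_width)
        areas[i] = int(((pct[i] >= threshold_pct) & band).sum())
    times = fdm.frame_interval * (
        np.arange(fdm.n_frames) + fdm.interval_frames
    )
    return times, areas


def kymograph_bin_of_angle(theta: float, n_bins: int) -> int:
    """Kymograph row index corresponding to perimeter angle ``theta``."""
    return int(np.floor((theta % (2 * np.pi)) / (2 * np.pi) * n_bins)) % n_bins
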