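"""Per-cell fluorescence quantification on multichannel cytospin images.

Turns a five-channel stack (DAPI, keratins, vimentin, PD-L1, and a binary
CD45 positivity mask) into a table of per-cell measurements.  The central
quantity is the corrected total cell fluorescence

    CTCF = integrated density − cell area × mean background,

i.e. the sum of pixel intensities over the cell region minus the expected
contribution of the slide background over the same area.  CTCF can be
negative for cells dimmer than the background; negative values are kept
as measured and interpreted downstream (a nonpositive keratin CTCF means
keratin-negative).

Processing steps: nuclei are segmented from the DAPI plane (Otsu
threshold, watershed split of touching nuclei), each nucleus is grown
into a whole-cell region by bounded nearest-nucleus expansion, the
background is the mean of pixels outside all cell regions plus a guard
band, and per-channel integrated densities over each cell region give the
CTCF values.  CD45 status is called from the coverage of the cell region
by the CD45 mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import expand_labels, watershed

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "MARKER_CHANNELS",
    "ChannelStack",
    "BackgroundEstimate",
    "QuantifyConfig",
    "QuantifyResult",
    "segment_nuclei",
    "expand_to_cell_regions",
    "estimate_background",
    "compute_ctcf",
    "quantify_sample",
]

#: Fluorescence channels in stack order (the CD45 mask is carried separately).
CHANNELS = ("dapi", "ker", "vim", "pdl1")
#: Channels for which CTCF is reported.
MARKER_CHANNELS = ("ker", "vim", "pdl1")


@dataclass
class ChannelStack:
    """Named 2-D intensity planes of one cytospin field.

    All planes share dimensions; intensities are nonnegative arbitrary
    fluorescence units; ``cd45mask`` is binary (1 inside CD45+ cells).
    Pixel indexing is 0-based, row-major, with ``x`` = column and
    ``y`` = row.
    """

    dapi: np.ndarray
    ker: np.ndarray
    vim: np.ndarray
    pdl1: np.ndarray
    cd45mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {name: getattr(self, name).shape for name in (*CHANNELS, "cd45mask")}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel planes differ in shape: {shapes}")
        if self.dapi.ndim != 2 or self.dapi.size == 0:
            raise ValueError("channel planes must be nonempty 2-D arrays")
        mask = np.asarray(self.cd45mask)
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("cd45mask must be binary (0/1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in (*CHANNELS, "cd45mask"):
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-channel mean background fluorescence outside all cell regions."""

    means: dict  # channel name -> mean background (arbitrary units)
    method: str
    n_pixels: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.means.values()):
            raise ValueError("mean background must be nonnegative")


@dataclass(frozen=True)
class QuantifyConfig:
    """Parameters of the quantification pipeline.

    ``dilation_px`` should cover the cytoplasmic annulus (cell radius
    minus nucleus radius, plus a pixel or two of segmentation slack).
    """

    min_area_px: int = 20
    max_area_px: int = 10_000
    smoothing_sigma: float = 1.0
    min_peak_distance: int = 5
    dilation_px: float = 6.0
    guard_px: int = 2
    min_background_px: int = 100
    cd45_coverage_threshold: float = 0.5
    sample_id: str = "sample"


@dataclass
class QuantifyResult:
    """Output of :func:`quantify_sample`.

    ``cells`` has one row per detected cell with columns: cell_id,
    sample_id, x, y, area_px, intden_<c>, mean_bg_<c>, ctcf_<c> for
    c in (ker, vim, pdl1), dapi_positive, cd45_positive.
    """

    cells: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    background: BackgroundEstimate


def segment_nuclei(
    stack: ChannelStack,
    min_area_px: int = 20,
    max_area_px: int = 10_000,
    *,
    smoothing_sigma: float = 1.0,
    min_peak_distance: int = 5,
) -> np.ndarray:
    """Segment nuclei from the DAPI plane.

    Otsu threshold on the (optionally smoothed) DAPI image, then a
    distance-transform watershed to split touching nuclei, then an area
    filter.  Returns a label image with consecutive positive integer
    labels; a blank DAPI plane yields zero labels with a logged warning.
    """
    dapi = np.asarray(stack.dapi, dtype=float)
    if dapi.max() <= 0 or np.ptp(dapi) == 0:
        logger.warning("blank DAPI plane: no nuclei segmented")
        return np.zeros(dapi.shape, dtype=np.int32)

    smoothed = gaussian(dapi, sigma=smoothing_sigma, preserve_range=True) if smoothing_sigma > 0 else dapi
    mask = smoothed > threshold_otsu(smoothed)
    if not mask.any():
        logger.warning("no foreground after Otsu threshold")
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=max(1, int(min_peak_distance)), labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        # degenerate: fall back to plain connected components
        markers, _ = ndi.label(mask)
    labels = watershed(-distance, markers, mask=mask)

    return _filter_and_relabel(labels, min_area_px, max_area_px)


def _filter_and_relabel(labels: np.ndarray, min_area: int, max_area: int) -> np.ndarray:
    """Drop regions outside [min_area, max_area]; relabel consecutively."""
    out = np.zeros(labels.shape, dtype=np.int32)
    next_id = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        region = labels == lab
        area = int(region.sum())
        if min_area <= area <= max_area:
            out[region] = next_id
            next_id += 1
    return out


def expand_to_cell_regions(nucleus_labels: np.ndarray, dilation_px: float) -> np.ndarray:
    """Grow each nucleus into a whole-cell region.

    Each nucleus is expanded by up to ``dilation_px`` pixels; contested
    pixels go to the nearest nucleus (ties resolved deterministically by
    the underlying distance transform).  Every region is a superset of its
    nucleus and regions never overlap.
    """
    if dilation_px < 0:
        raise ValueError(f"dilation_px must be nonnegative, got {dilation_px}")
    return expand_labels(nucleus_labels, distance=dilation_px)


def estimate_background(
    stack: ChannelStack,
    cell_labels: np.ndarray,
    *,
    guard_px: int = 2,
    min_background_px: int = 100,
) -> BackgroundEstimate:
    """Mean background per channel over pixels outside all cell regions.

    A guard band of ``guard_px`` pixels around every cell region is
    excluded so blurred cell edges do not inflate the estimate.

    Raises
    ------
    ValueError
        If fewer than ``min_background_px`` background pixels remain.
    """
    occupied = cell_labels > 0
    if guard_px > 0:
        occupied = ndi.binary_dilation(occupied, structure=disk(guard_px))
    bg_mask = ~occupied
    n_bg = int(bg_mask.sum())
    if n_bg < min_background_px:
        raise ValueError(
            f"only {n_bg} background pixels available (need >= {min_background_px}) "
            f"for channels {CHANNELS}"
        )
    means = {c: float(stack.channel(c)[bg_mask].mean()) for c in CHANNELS}
    return BackgroundEstimate(
        means=means, method=f"mean outside regions + {guard_px}px guard", n_pixels=n_bg
    )


def compute_ctcf(integrated_density, area_px, mean_background):
    """Corrected total cell fluorescence.

    ``CTCF = integrated_density − area_px × mean_background``.  Accepts
    scalars or arrays; the result may be negative (dim cells on a bright
    background) and is deliberately not clipped.

    Raises
    ------
    ValueError
        If any area is nonpositive.
    """
    area = np.asarray(area_px)
    if np.any(area <= 0):
        raise ValueError("area_px must be positive")
    return np.asarray(integrated_density) - area * np.asarray(mean_background)


def quantify_sample(stack: ChannelStack, config: QuantifyConfig | None = None) -> QuantifyResult:
    """Full per-cell quantification of one channel stack.

    Segments nuclei, grows cell regions, estimates the background, and
    emits one :class:`CellRecord`-shaped row per cell.  ``dapi_positive``
    is always true for segmented cells (segmentation is DAPI-driven);
    ``cd45_positive`` is true when more than
    ``config.cd45_coverage_threshold`` of the cell region lies inside the
    CD45 mask.
    """
    cfg = config or QuantifyConfig()
    nucleus_labels = segment_nuclei(
        stack,
        cfg.min_area_px,
        cfg.max_area_px,
        smoothing_sigma=cfg.smoothing_sigma,
        min_peak_distance=cfg.min_peak_distance,
    )
    cell_labels = expand_to_cell_regions(nucleus_labels, cfg.dilation_px)

    n_cells = int(cell_labels.max())
    columns = [
        "cell_id", "sample_id", "x", "y", "area_px",
        *(f"intden_{c}" for c in MARKER_CHANNELS),
        *(f"mean_bg_{c}" for c in MARKER_CHANNELS),
        *(f"ctcf_{c}" for c in MARKER_CHANNELS),
        "dapi_positive", "cd45_positive",
    ]
    if n_cells == 0:
        empty = pd.DataFrame(columns=columns)
        bg = BackgroundEstimate(
            means={c: float(stack.channel(c).mean()) for c in CHANNELS},
            method="whole image (no cells)",
            n_pixels=int(stack.dapi.size),
        )
        return QuantifyResult(empty, nucleus_labels, cell_labels, bg)

    background = estimate_background(
        stack, cell_labels, guard_px=cfg.guard_px, min_background_px=cfg.min_background_px
    )

    ids = np.arange(1, n_cells + 1)
    areas = ndi.sum_labels(np.ones(cell_labels.shape), cell_labels, ids).astype(int)
    cy, cx = zip(*ndi.center_of_mass(np.ones(cell_labels.shape), cell_labels, ids))
    cd45_frac = ndi.mean(stack.cd45mask.astype(float), cell_labels, ids)

    rows: dict = {
        "cell_id": ids,
        "sample_id": cfg.sample_id,
        "x": np.asarray(cx, dtype=float),
        "y": np.asarray(cy, dtype=float),
        "area_px": areas,
    }
    for c in MARKER_CHANNELS:
        intden = ndi.sum_labels(stack.channel(c).astype(float), cell_labels, ids)
        rows[f"intden_{c}"] = intden
        rows[f"mean_bg_{c}"] = background.means[c]
        rows[f"ctcf_{c}"] = compute_ctcf(intden, areas, background.means[c])
    rows["dapi_positive"] = True
    rows["cd45_positive"] = np.asarray(cd45_frac) > cfg.cd45_coverage_threshold

    cells = pd.DataFrame(rows, columns=columns)
    return QuantifyResult(cells, nucleus_labels, cell_labels, background)
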