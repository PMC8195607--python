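"""Puncta density, molecular-layer thickness and climbing-fiber extension.

Works on single-plane grayscale images of the cerebellar cortex.  The
image y-axis (array axis 0) points apically: the Purkinje-cell soma edge
is the horizontal line ``soma_line_um`` and the molecular layer (ML)
extends toward larger y.  Pixel centers sit at ``(i + 0.5) * um_per_px``.

VGluT2-labeled climbing-fiber puncta are segmented as connected
components; the CF height is the distance from the soma line to the most
apical punctum centroid near each measurement line, and the CF extension
is ``100 * mean(CF height) / mean(ML height)`` per image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .exceptions import ParameterError, UndefinedStatisticError


@dataclass
class PunctaImage:
    """Grayscale plane with physical scale and soma-line position."""

    pixels: np.ndarray  # (ny, nx), axis 0 = apical direction
    um_per_px: float
    soma_line_um: float  # y-coordinate of the PC soma edge

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be 2-D")
        if self.um_per_px <= 0:
            raise ParameterError("um_per_px must be > 0")
        if not 0 <= self.soma_line_um <= self.pixels.shape[0] * self.um_per_px:
            raise ParameterError("soma_line_um must lie within the image")

    @property
    def height_um(self) -> float:
        return self.pixels.shape[0] * self.um_per_px

    @property
    def width_um(self) -> float:
        return self.pixels.shape[1] * self.um_per_px


@dataclass
class ROI:
    """Axis-aligned rectangle in µm; membership is half-open on both axes."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ParameterError("ROI must satisfy x1 > x0 and y1 > y0")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        return (
            (x_um >= self.x0) & (x_um < self.x1) & (y_um >= self.y0) & (y_um < self.y1)
        )


@dataclass
class LayerMeasure:
    ml_height: float  # µm
    cf_height: float  # µm
    cf_extension: float  # %
    n_measurements: int


def detect_puncta(
    image: PunctaImage, intensity_threshold: float, min_size_px: int = 3
) -> pd.DataFrame:
    """Segment puncta as 8-connected supra-threshold components.

    Returns one row per punctum with centroid coordinates in µm
    (``x_um``, ``y_um``), pixel area and µm² area.  A fully saturated
    image yields a single component plus a warning.
    """
    bw = image.pixels > intensity_threshold
    if bw.all() and bw.size:
        warnings.warn("image fully saturated above threshold: single component",
                      UserWarning, stacklevel=2)
    lab = measure.label(bw, connectivity=2)
    rows = []
    for rp in measure.regionprops(lab):
        if rp.area < min_size_px:
            continue
        cy, cx = rp.centroid
        rows.append(
            {
                "x_um": (cx + 0.5) * image.um_per_px,
                "y_um": (cy + 0.5) * image.um_per_px,
                "area_px": int(rp.area),
                "area_um2": rp.area * image.um_per_px**2,
            }
        )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "area_px", "area_um2"])


def puncta_density(puncta: pd.DataFrame, roi: ROI) -> float:
    """Puncta per µm²: centroids inside the ROI divided by the ROI area."""
    if roi.area <= 0:
        raise ParameterError("ROI area must be > 0")
    if len(puncta) == 0:
        return 0.0
    inside = roi.contains(puncta["x_um"].to_numpy(), puncta["y_um"].to_numpy())
    return float(inside.sum()) / roi.area


@dataclass
class MLThickness:
    mean_um: float
    per_x_um: list
    n_measurements: int


def ml_thickness(
    image: PunctaImage, measurement_xs: Sequence[float], threshold: float = 0.15
) -> MLThickness:
    """Molecular-layer height: soma line to the apical edge of the layer.

    At each measurement x (µm), the apical edge is the top edge of the
    outermost supra-threshold pixel in that column; positions with no
    supra-threshold pixel are skipped and the skip count is reported via
    ``n_measurements``.
    """
    ny, nx = image.pixels.shape
    heights = []
    for x in measurement_xs:
        col = int(x / image.um_per_px)
        if not 0 <= col < nx:
            raise ParameterError(f"measurement x={x} µm outside image")
        rows = np.flatnonzero(image.pixels[:, col] > threshold)
        if rows.size == 0:
            continue
        apical_edge = (rows.max() + 1) * image.um_per_px
        heights.append(apical_edge - image.soma_line_um)
    if not heights:
        raise UndefinedStatisticError("no-layer", "no supra-threshold pixel at any measurement x")
    return MLThickness(float(np.mean(heights)), heights, len(heights))


def cf_extension_percent(cf_height_um: float, ml_height_um: float) -> float:
    """CF extension = 100 · CF height / ML height (%)."""
    if ml_height_um <= 0:
        raise ParameterError("ml_height must be > 0")
    return 100.0 * cf_height_um / ml_height_um


def cf_extension(
    image: PunctaImage,
    measurement_xs: Sequence[float],
    puncta: Optional[pd.DataFrame] = None,
    ml_threshold: float = 0.15,
    puncta_threshold: float = 0.6,
    min_size_px: int = 3,
    x_window_um: float = 10.0,
) -> LayerMeasure:
    """Climbing-fiber extension per ML thickness for one image.

    CF height at each measurement line is the distance from the soma line
    to the most apical punctum centroid within ``±x_window_um`` of that
    line; the extension is the ratio of mean CF height to mean ML height,
    in percent.
    """
    ml = ml_thickness(image, measurement_xs, threshold=ml_threshold)
    if puncta is None:
        puncta = detect_puncta(image, puncta_threshold, min_size_px=min_size_px)
    if len(puncta) == 0:
        raise UndefinedStatisticError("no-puncta", "no puncta detected")
    xs = puncta["x_um"].to_numpy()
    ys = puncta["y_um"].to_numpy()
    cf_heights = []
    for x in measurement_xs:
        sel = np.abs(xs - x) <= x_window_um
        if not sel.any():
            continue
        cf_heights.append(float(ys[sel].max() - image.soma_line_um))
    if not cf_heights:
        raise UndefinedStatisticError("no-puncta", "no puncta near any measurement x")
    cf_mean = float(np.mean(cf_heights))
    return LayerMeasure(
        ml_height=ml.mean_um,
        cf_height=cf_mean,
        cf_extension=cf_extension_percent(cf_mean, ml.mean_um),
        n_measurements=min(ml.n_measurements, len(cf_heights)),
    )
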