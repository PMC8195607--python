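"""Synthetic climbing-fiber puncta fields inside a molecular layer.

Renders a single-plane grayscale image: a dim molecular-layer band from
the soma line up to ``ml_thickness`` (calbindin-like background,
intensity 0.35) and bright puncta disks (VGluT2-like, intensity 1.0)
whose centers are uniform in the band from the soma line up to
``cf_height``.  The ground-truth punctum table is returned alongside so
segmentation and layer measures can be scored exactly.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd

from ..exceptions import ParameterError
from ..histo import PunctaImage

ML_INTENSITY = 0.35
PUNCTA_INTENSITY = 1.0


def generate_puncta_image(
    ml_thickness: float,
    cf_height: float,
    density: float,
    size: Tuple[int, int] = (256, 256),
    um_per_px: float = 0.5,
    soma_line_um: float = 10.0,
    punctum_radius_um: float = 1.2,
    seed: int = 0,
) -> Tuple[PunctaImage, pd.DataFrame]:
    """Build a puncta image with known ground truth.

    ``density`` is puncta per µm² of the CF band (soma line to
    ``cf_height``); the punctum count is Poisson with that mean.  Warns
    when the expected disk-overlap fraction exceeds 50%.
    """
    if cf_height > ml_thickness:
        raise ParameterError("cf_height must be <= ml_thickness")
    if cf_height < 0 or density < 0:
        raise ParameterError("cf_height and density must be >= 0")
    ny, nx = size
    height_um = ny * um_per_px
    width_um = nx * um_per_px
    if soma_line_um + ml_thickness > height_um:
        raise ParameterError("molecular layer extends beyond the image")

    rng = np.random.default_rng(seed)
    img = np.zeros((ny, nx))

    # molecular-layer band (calbindin-like fill)
    y_centers = (np.arange(ny) + 0.5) * um_per_px
    in_ml = (y_centers >= soma_line_um) & (y_centers < soma_line_um + ml_thickness)
    img[in_ml, :] = ML_INTENSITY

    disk_area = np.pi * punctum_radius_um**2
    if density * disk_area > 0.5:
        warnings.warn("puncta density high enough to force >50% overlap",
                      UserWarning, stacklevel=2)

    if cf_height > 0 and density > 0:
        n = rng.poisson(density * width_um * cf_height)
    else:
        n = 0
    px = rng.uniform(0.0, width_um, size=n)
    py = rng.uniform(soma_line_um, soma_line_um + cf_height, size=n) if n else np.empty(0)

    if n:
        xc = (np.arange(nx) + 0.5) * um_per_px
        yc = y_centers
        for x, y in zip(px, py):
            j0 = max(0, int((x - punctum_radius_um) / um_per_px) - 1)
            j1 = min(nx, int((x + punctum_radius_um) / um_per_px) + 2)
            i0 = max(0, int((y - punctum_radius_um) / um_per_px) - 1)
            i1 = min(ny, int((y + punctum_radius_um) / um_per_px) + 2)
            sub_x, sub_y = np.meshgrid(xc[j0:j1], yc[i0:i1])
            disk = (sub_x - x) ** 2 + (sub_y - y) ** 2 <= punctum_radius_um**2
            img[i0:i1, j0:j1][disk] = PUNCTA_INTENSITY

    truth = pd.DataFrame({"x_um": px, "y_um": py})
    return PunctaImage(img, um_per_px, soma_line_um), truth
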