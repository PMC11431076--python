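"""Segmentation scene container: tissue-class and compartment label rasters.

Coordinate convention (documented in every sidecar): origin at the raster
top-left, x rightward along columns, y downward along rows, all distances
in µm.  A pixel (row, col) has its center at ((col+0.5)*upp, (row+0.5)*upp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TISSUE_CODES = {"background": 0, "epithelium": 1, "stroma": 2}
COMPARTMENT_CODES = {"excluded": 0, "tumor": 1, "liver": 2}

MAX_UM_PER_PIXEL = 4.0


@dataclass
class SegmentationScene:
    """Label rasters defining tissue classes and compartments over a slide.

    Attributes
    ----------
    tissue
        uint8 raster, codes per ``TISSUE_CODES`` (background/epithelium/stroma).
    compartment
        uint8 raster of identical shape, codes per ``COMPARTMENT_CODES``
        (excluded/tumor/liver).
    um_per_pixel
        Isotropic pixel pitch in µm.
    """

    tissue: np.ndarray
    compartment: np.ndarray
    um_per_pixel: float

    def __post_init__(self):
        self.tissue = np.asarray(self.tissue, dtype=np.uint8)
        self.compartment = np.asarray(self.compartment, dtype=np.uint8)
        if self.tissue.shape != self.compartment.shape:
            raise ValueError(
                f"tissue raster {self.tissue.shape} and compartment raster "
                f"{self.compartment.shape} differ in shape"
            )
        if not (0 < self.um_per_pixel):
            raise ValueError("um_per_pixel must be positive")
        bad_t = set(np.unique(self.tissue)) - set(TISSUE_CODES.values())
        bad_c = set(np.unique(self.compartment)) - set(COMPARTMENT_CODES.values())
        if bad_t or bad_c:
            raise ValueError(
                f"unknown label codes: tissue={sorted(bad_t)} compartment={sorted(bad_c)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue.shape

    @property
    def width_um(self) -> float:
        return self.tissue.shape[1] * self.um_per_pixel

    @property
    def height_um(self) -> float:
        return self.tissue.shape[0] * self.um_per_pixel

    @property
    def bbox_um(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.width_um, self.height_um)

    def tissue_mask(self) -> np.ndarray:
        """Boolean raster of non-background pixels."""
        return self.tissue != TISSUE_CODES["background"]
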