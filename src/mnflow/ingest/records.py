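"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from mnflow.taxonomy import PhenotypeClass

#: Standardised image geometry: 64 x 64 pixels, 2 channels.
IMAGE_SIZE = 64
N_CHANNELS = 2
#: Channel order is fixed as (nuclear fluorescence, brightfield) regardless
#: of the source cytometer's channel numbering.
CH_FLUOR = 0
CH_BRIGHTFIELD = 1


@dataclass(frozen=True)
class GatingFeatures:
    """Per-cell features used for single-cell / in-focus gating.

    Attributes
    ----------
    brightfield_area : float
        Object area in square microns (> 0).
    aspect_ratio : float
        Minor/major axis ratio of the object mask's second-moment ellipse,
        in (0, 1].
    gradient_rms : float
        Focus score: calibrated RMS of the brightfield gradient magnitude
        over the object mask.
    """

    brightfield_area: float
    aspect_ratio: float
    gradient_rms: float

    def __post_init__(self):
        if not self.brightfield_area > 0:
            raise ValueError(f"brightfield_area must be > 0, got {self.brightfield_area}")
        if not 0 < self.aspect_ratio <= 1.0 + 1e-9:
            raise ValueError(f"aspect_ratio must be in (0, 1], got {self.aspect_ratio}")


@dataclass(frozen=True)
class CellMeta:
    """Provenance of one cell record."""

    lab: str = ""
    compound: str = ""
    concentration: float = 0.0  # ug/mL
    replicate: int = 0
    source: str = ""


@dataclass
class CellRecord:
    """One cell's two-channel 64x64 16-bit image plus features and provenance."""

    image: np.ndarray  # (64, 64, 2) uint16, channels (fluor, brightfield)
    features: Optional[GatingFeatures] = None
    meta: CellMeta = field(default_factory=CellMeta)
    label: Optional[PhenotypeClass] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        img = np.asarray(self.image)
        if img.shape != (IMAGE_SIZE, IMAGE_SIZE, N_CHANNELS):
            raise ValueError(
                f"image must have shape ({IMAGE_SIZE}, {IMAGE_SIZE}, {N_CHANNELS}), "
                f"got {img.shape}"
            )
        if img.dtype != np.uint16:
            raise ValueError(f"image must be uint16, got {img.dtype}")

    @property
    def fluorescence(self) -> np.ndarray:
        return self.image[:, :, CH_FLUOR]

    @property
    def brightfield(self) -> np.ndarray:
        return self.image[:, :, CH_BRIGHTFIELD]
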