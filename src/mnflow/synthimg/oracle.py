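"""Independent blob-count oracle for synthetic fluorescence images.

Thresholds the fluorescence channel at mid-intensity, labels connected
components with 8-connectivity and classifies them as parent nuclei or
micronuclei by equivalent diameter. Used to verify round-trip label fidelity
of the renderer and label invariance of augmentation; deliberately simple
and independent of the rendering path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from mnflow.synthimg.specs import MN_RATIO_MAX, MN_RATIO_MIN
from mnflow.taxonomy import PhenotypeClass

#: 8-connectivity structuring element
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BlobCounts:
    n_nuclei: int
    n_micronuclei: int
    nucleus_diameters: tuple[float, ...]
    mn_diameters: tuple[float, ...]
    mn_diameter_ratios: tuple[float, ...]


def count_blobs(fluorescence: np.ndarray, min_area_px: int = 3) -> BlobCounts:
    """Count large (nucleus) and small (micronucleus) blobs.

    Components are split at half the largest equivalent diameter: blobs
    larger than that are nuclei; smaller blobs whose diameter ratio against
    the mean nucleus diameter falls in [1/16, 1/3] (with a small measurement
    margin) are micronuclei.
    """
    img = np.asarray(fluorescence, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return BlobCounts(0, 0, (), (), ())
    mask = img > (lo + hi) / 2.0
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return BlobCounts(0, 0, (), (), ())
    areas = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64),
                               labels, index=np.arange(1, n + 1))
    areas = areas[areas >= min_area_px]
    if areas.size == 0:
        return BlobCounts(0, 0, (), (), ())
    diameters = 2.0 * np.sqrt(areas / np.pi)
    dmax = diameters.max()
    is_nucleus = diameters > dmax / 2.0
    nuc_d = np.sort(diameters[is_nucleus])[::-1]
    small_d = np.sort(diameters[~is_nucleus])[::-1]
    mean_nuc = float(nuc_d.mean()) if nuc_d.size else 0.0
    ratios = tuple(float(d / mean_nuc) for d in small_d) if mean_nuc > 0 else ()
    return BlobCounts(
        n_nuclei=int(nuc_d.size),
        n_micronuclei=int(small_d.size),
        nucleus_diameters=tuple(float(d) for d in nuc_d),
        mn_diameters=tuple(float(d) for d in small_d),
        mn_diameter_ratios=ratios,
    )


def classify_blobs(fluorescence: np.ndarray) -> PhenotypeClass:
    """Map blob counts onto the nine-class taxonomy.

    Anything with no nuclei or more than four nuclei is other/unscorable.
    """
    blobs = count_blobs(fluorescence)
    if blobs.n_nuclei < 1 or blobs.n_nuclei > 4:
        return PhenotypeClass.OTHER_UNSCORABLE
    return PhenotypeClass.from_counts(blobs.n_nuclei, blobs.n_micronuclei > 0)


def mn_ratios_admissible(fluorescence: np.ndarray, tolerance: float = 0.0) -> bool:
    """True if every detected micronucleus diameter ratio lies in
    [1/16 - tolerance, 1/3 + tolerance]."""
    blobs = count_blobs(fluorescence)
    return all(
        MN_RATIO_MIN - tolerance <= r <= MN_RATIO_MAX + tolerance
        for r in blobs.mn_diameter_ratios
    )
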