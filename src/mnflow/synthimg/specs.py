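"""Validated specifications for synthetic cells, populations and experiments."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from mnflow.synthimg.profiles import LabProfile, DEFAULT_LAB
from mnflow.taxonomy import N_CLASSES, PhenotypeClass

#: Admissible micronucleus diameter as a fraction of the mean parent-nucleus
#: diameter: 1/16th to 1/3rd.
MN_RATIO_MIN = 1.0 / 16.0
MN_RATIO_MAX = 1.0 / 3.0

UNSCORABLE_KINDS = ("debris", "doublet", "out_of_focus", "mitotic", "dead")


@dataclass(frozen=True)
class CellSpec:
    """Geometry of one synthetic cell.

    Micronucleus diameter ratios are relative to the mean parent-nucleus
    diameter and must lie within [1/16, 1/3].
    """

    n_nuclei: int
    n_micronuclei: int = 0
    mn_diameter_ratios: tuple[float, ...] = ()
    nucleus_diameters_px: tuple[float, ...] = ()
    cell_diameter_px: float = 52.0
    phenotype: PhenotypeClass | None = None
    unscorable_kind: Optional[str] = None
    aspect: float = 1.0  # x-axis squash of the cell disc, in (0, 1]

    def __post_init__(self):
        if self.unscorable_kind is not None:
            if self.unscorable_kind not in UNSCORABLE_KINDS:
                raise ValueError(
                    f"unscorable_kind must be one of {UNSCORABLE_KINDS}, "
                    f"got {self.unscorable_kind!r}"
                )
            if self.phenotype not in (None, PhenotypeClass.OTHER_UNSCORABLE):
                raise ValueError("unscorable_kind requires phenotype other_unscorable")
            object.__setattr__(self, "phenotype", PhenotypeClass.OTHER_UNSCORABLE)
            return
        if not 1 <= self.n_nuclei <= 4:
            raise ValueError(f"n_nuclei must be 1-4, got {self.n_nuclei}")
        if self.n_micronuclei < 0:
            raise ValueError("n_micronuclei must be >= 0")
        if len(self.mn_diameter_ratios) != self.n_micronuclei:
            raise ValueError(
                f"expected {self.n_micronuclei} mn_diameter_ratios, "
                f"got {len(self.mn_diameter_ratios)}"
            )
        for r in self.mn_diameter_ratios:
            if not MN_RATIO_MIN <= r <= MN_RATIO_MAX:
                raise ValueError(
                    f"micronucleus diameter ratio {r:.4f} outside the admissible "
                    f"range [1/16, 1/3] = [{MN_RATIO_MIN:.4f}, {MN_RATIO_MAX:.4f}]"
                )
        if len(self.nucleus_diameters_px) != self.n_nuclei:
            raise ValueError(
                f"expected {self.n_nuclei} nucleus_diameters_px, "
                f"got {len(self.nucleus_diameters_px)}"
            )
        if self.cell_diameter_px <= 0:
            raise ValueError("cell_diameter_px must be > 0")
        if not 0 < self.aspect <= 1.0:
            raise ValueError("aspect must be in (0, 1]")
        expected = PhenotypeClass.from_counts(self.n_nuclei, self.n_micronuclei > 0)
        if self.phenotype is None:
            object.__setattr__(self, "phenotype", expected)
        elif self.phenotype != expected:
            raise ValueError(
                f"phenotype {self.phenotype.name} inconsistent with "
                f"n_nuclei={self.n_nuclei}, n_micronuclei={self.n_micronuclei}"
            )

    @property
    def mean_nucleus_diameter(self) -> float:
        if not self.nucleus_diameters_px:
            return 0.0
        return float(np.mean(self.nucleus_diameters_px))


@dataclass(frozen=True)
class MorphologyConfig:
    """Free morphology parameters of the cell-geometry sampler.

    No quantitative morphology distributions are prescribed upstream; these
    defaults are calibrated so rendered phenotypes are recoverable by the
    blob oracle and most single cells fall inside the default gates.
    """

    cell_diameter_range: tuple[float, float] = (49.0, 58.0)
    #: mean nucleus diameter as a fraction of cell diameter, keyed by n_nuclei
    nucleus_fraction: tuple[float, float, float, float] = (0.48, 0.38, 0.32, 0.285)
    nucleus_jitter: float = 0.07
    mn_ratio_range: tuple[float, float] = (0.18, 0.30)
    #: probability of 1, 2 micronuclei given an MN-positive phenotype
    mn_count_probs: tuple[float, ...] = (0.8, 0.2)
    min_mn_diameter_px: float = 3.2
    cell_aspect_range: tuple[float, float] = (0.88, 1.0)


DEFAULT_CLASS_FREQUENCIES = (0.30, 0.05, 0.34, 0.05, 0.06, 0.01, 0.05, 0.01, 0.13)


@dataclass(frozen=True)
class PopulationSpec:
    """A labelled population of synthetic cells from one laboratory."""

    n_cells: int
    class_frequencies: tuple[float, ...] = DEFAULT_CLASS_FREQUENCIES
    lab: LabProfile = DEFAULT_LAB
    seed: int = 0
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be > 0, got {self.n_cells}")
        freqs = np.asarray(self.class_frequencies, dtype=float)
        if freqs.shape != (N_CLASSES,):
            raise ValueError(f"class_frequencies must have length {N_CLASSES}")
        if (freqs < 0).any():
            raise ValueError("class_frequencies must be non-negative")
        if not math.isclose(freqs.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"class_frequencies must sum to 1, got {freqs.sum()}")


@dataclass(frozen=True)
class DoseResponseSpec:
    """Design of a simulated concentration-response experiment.

    The mean induction curve is Hill-shaped:
    f(x) = f0 * (1 + (F - 1) * x^d / (b^d + x^d)), with f0 the background
    binucleated-cell MN frequency, F the maximum fold induction, b the
    potency parameter and d the log-steepness. Replicate noise is
    multiplicative lognormal with the given scale (natural-log sd).
    """

    concentrations: tuple[float, ...]
    replicates: int = 3
    n_scored_per_sample: int = 2000
    background_mn_freq: float = 0.01
    potency_param: float = 1.0
    max_fold_induction: float = 6.0
    hill_steepness: float = 2.0
    noise_model: float = 0.1
    binucleate_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self):
        concs = tuple(float(c) for c in self.concentrations)
        if len(concs) < 2 or 0.0 not in concs:
            raise ValueError("concentrations must include 0 (vehicle control)")
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "concentrations", concs)
        if not 0 < self.background_mn_freq < 1:
            raise ValueError("background_mn_freq must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_scored_per_sample < 1:
            raise ValueError("n_scored_per_sample must be >= 1")
        if self.potency_param <= 0:
            raise ValueError("potency_param must be > 0 (may be inf for no induction)")
        if self.max_fold_induction < 1:
            raise ValueError("max_fold_induction must be >= 1")
        if self.hill_steepness <= 0:
            raise ValueError("hill_steepness must be > 0")
        if self.noise_model < 0:
            raise ValueError("noise_model (lognormal scale) must be >= 0")
        if not 0 < self.binucleate_fraction < 1:
            raise ValueError("binucleate_fraction must be in (0, 1)")
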