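"""Sampling labelled populations of synthetic cells."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mnflow.ingest.features import compute_gating_features
from mnflow.ingest.records import CellMeta, CellRecord
from mnflow.synthimg.render import render_cell
from mnflow.synthimg.specs import (
    CellSpec,
    MorphologyConfig,
    PopulationSpec,
    UNSCORABLE_KINDS,
)
from mnflow.taxonomy import PhenotypeClass


def sample_cell_spec(
    label: PhenotypeClass,
    rng: np.random.Generator,
    morphology: MorphologyConfig | None = None,
) -> CellSpec:
    """Draw a random cell geometry consistent with the given phenotype."""
    m = morphology or MorphologyConfig()
    cell_d = rng.uniform(*m.cell_diameter_range)
    aspect = rng.uniform(*m.cell_aspect_range)

    if label is PhenotypeClass.OTHER_UNSCORABLE:
        kind = UNSCORABLE_KINDS[rng.integers(len(UNSCORABLE_KINDS))]
        return CellSpec(
            n_nuclei=1, cell_diameter_px=cell_d, aspect=aspect,
            nucleus_diameters_px=(m.nucleus_fraction[0] * cell_d,),
            unscorable_kind=kind,
        )

    n_nuclei = label.n_nuclei
    base = m.nucleus_fraction[n_nuclei - 1] * cell_d
    diam = tuple(
        base * rng.uniform(1 - m.nucleus_jitter, 1 + m.nucleus_jitter)
        for _ in range(n_nuclei)
    )
    mean_d = float(np.mean(diam))

    n_mn = 0
    ratios: tuple[float, ...] = ()
    if label.has_mn:
        probs = np.asarray(m.mn_count_probs, dtype=float)
        n_mn = int(rng.choice(np.arange(1, probs.size + 1), p=probs / probs.sum()))
        lo = max(m.mn_ratio_range[0], m.min_mn_diameter_px / mean_d)
        hi = max(m.mn_ratio_range[1], lo)
        ratios = tuple(float(rng.uniform(lo, hi)) for _ in range(n_mn))

    return CellSpec(
        n_nuclei=n_nuclei,
        n_micronuclei=n_mn,
        mn_diameter_ratios=ratios,
        nucleus_diameters_px=diam,
        cell_diameter_px=cell_d,
        aspect=aspect,
    )


def sample_labels(pop: PopulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the population's class labels i.i.d. from class_frequencies."""
    rng = rng if rng is not None else np.random.default_rng(pop.seed)
    freqs = np.asarray(pop.class_frequencies, dtype=float)
    return rng.choice(9, size=pop.n_cells, p=freqs)


def sample_population(
    pop: PopulationSpec,
    compute_features: bool = True,
    meta: CellMeta | None = None,
) -> list[CellRecord]:
    """Render a labelled population of cells.

    Labels are drawn i.i.d. from ``pop.class_frequencies``; geometry is drawn
    per cell from the morphology config; records carry gating features when
    ``compute_features`` is set. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(pop.seed)
    labels = sample_labels(pop, rng)
    records: list[CellRecord] = []
    base_meta = meta or CellMeta(lab=pop.lab.name)
    for i, lab_idx in enumerate(labels):
        label = PhenotypeClass(int(lab_idx))
        spec = sample_cell_spec(label, rng, pop.morphology)
        cell_seed = int(rng.integers(0, 2**63 - 1))
        image = render_cell(spec, pop.lab, cell_seed)
        features = None
        if compute_features:
            try:
                features = compute_gating_features(image)
            except ValueError:
                features = None  # e.g. featureless debris frame
        records.append(
            CellRecord(image=image, features=features, meta=base_meta, label=label)
        )
    return records


def sample_feature_table(n: int, seed: int = 0) -> pd.DataFrame:
    """Fast feature-only simulator for gate testing (no images rendered).

    Draws (area_um2, aspect_ratio, gradient_rms) from wide distributions that
    straddle every gate boundary, including exact boundary values, so both
    sides of each inclusive gate are exercised.
    """
    rng = np.random.default_rng(seed)
    area = rng.uniform(50.0, 1000.0, size=n)
    aspect = rng.uniform(0.4, 1.0, size=n)
    grms = rng.uniform(20.0, 120.0, size=n)
    # pin a handful of records exactly on the gate boundaries
    boundaries = [(200.0, 0.75, 55.0), (500.0, 1.0, 80.0), (200.0, 1.0, 55.0)]
    for i, (a, r, g) in enumerate(boundaries):
        if i < n:
            area[i], aspect[i], grms[i] = a, r, g
    return pd.DataFrame(
        {"area_um2": area, "aspect_ratio": aspect, "gradient_rms": grms}
    )
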