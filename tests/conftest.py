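import numpy as np
import pytest

from mnflow.ingest.records import CellMeta, CellRecord, GatingFeatures
from mnflow.synthimg import (
    DEFAULT_LAB,
    PopulationSpec,
    sample_cell_spec,
    sample_population,
)
from mnflow.taxonomy import PhenotypeClass


@pytest.fixture(scope="session")
def lab():
    return DEFAULT_LAB


@pytest.fixture(scope="session")
def small_population():
    """120 labelled rendered cells with features (shared across tests)."""
    pop = PopulationSpec(n_cells=120, seed=2024)
    return sample_population(pop)


@pytest.fixture(scope="session")
def two_class_records():
    """Separable mono-vs-binucleate set, 500 cells per class, low noise."""
    rng = np.random.default_rng(7)
    records = []
    for cls in (PhenotypeClass.MONONUCLEATE, PhenotypeClass.BINUCLEATE):
        for _ in range(500):
            spec = sample_cell_spec(cls, rng)
            from mnflow.synthimg import render_cell

            img = render_cell(spec, DEFAULT_LAB, int(rng.integers(1 << 60)))
            records.append(CellRecord(image=img, label=cls, meta=CellMeta(lab="default")))
    return records


def make_record(area=300.0, aspect=0.9, grms=60.0, label=PhenotypeClass.BINUCLEATE):
    """Feature-only record around a shared blank image (gating tests)."""
    img = np.zeros((64, 64, 2), dtype=np.uint16)
    return CellRecord(
        image=img,
        features=GatingFeatures(area, aspect, grms),
        label=label,
    )
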