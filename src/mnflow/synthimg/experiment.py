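"""Simulated concentration-response experiments with known ground truth."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from mnflow.bmd.data import DoseResponseDataset
from mnflow.ingest.records import CellMeta, CellRecord
from mnflow.synthimg.profiles import DEFAULT_LAB, LabProfile
from mnflow.synthimg.population import sample_population
from mnflow.synthimg.specs import DEFAULT_CLASS_FREQUENCIES, DoseResponseSpec, PopulationSpec
from mnflow.taxonomy import PhenotypeClass


def hill_mean_frequency(x: float, spec: DoseResponseSpec) -> float:
    """Expected binucleated-cell MN frequency at concentration x.

    f(x) = f0 * (1 + (F - 1) * x^d / (b^d + x^d)); an infinite potency
    parameter gives the flat no-induction limit f(x) = f0.
    """
    f0 = spec.background_mn_freq
    F = spec.max_fold_induction
    b = spec.potency_param
    d = spec.hill_steepness
    if math.isinf(b) or F == 1.0:
        return f0
    if x == 0:
        return f0
    xd = x**d
    return f0 * (1.0 + (F - 1.0) * xd / (b**d + xd))


def hill_true_bmd(spec: DoseResponseSpec, ces: float = 0.5) -> float:
    """Closed-form BMD of the generating curve: f(BMD) = f0 * (1 + ces).

    Raises ValueError when the benchmark is unreachable
    (max fold induction <= 1 + ces) or potency is infinite.
    """
    F = spec.max_fold_induction
    if math.isinf(spec.potency_param) or F <= 1.0 + ces:
        raise ValueError(
            f"benchmark response unreachable: max fold induction {F} <= 1 + ces"
        )
    t = ces / (F - 1.0)
    return spec.potency_param * (t / (1.0 - t)) ** (1.0 / spec.hill_steepness)


@dataclass
class SimulatedSample:
    concentration: float
    replicate: int
    true_frequency: float  # after replicate noise, before binomial sampling
    n_scored: int
    n_binucleate: int
    n_binucleate_mn: int
    records: Optional[list[CellRecord]] = None

    @property
    def empirical_frequency(self) -> float:
        total_bn = self.n_binucleate + self.n_binucleate_mn
        return self.n_binucleate_mn / total_bn if total_bn else float("nan")


@dataclass
class SimulatedExperiment:
    spec: DoseResponseSpec
    samples: list[SimulatedSample]
    dataset: DoseResponseDataset
    true_bmd: Optional[float]


def _sample_class_frequencies(bn_fraction: float, mn_freq: float) -> np.ndarray:
    """Population class frequencies with the requested binucleate MN rate."""
    base = np.asarray(DEFAULT_CLASS_FREQUENCIES, dtype=float)
    freqs = base.copy()
    bn_total = bn_fraction
    freqs[PhenotypeClass.BINUCLEATE] = bn_total * (1.0 - mn_freq)
    freqs[PhenotypeClass.BINUCLEATE_MN] = bn_total * mn_freq
    others = [i for i in range(9) if i not in
              (PhenotypeClass.BINUCLEATE, PhenotypeClass.BINUCLEATE_MN)]
    rest = base[others]
    freqs[others] = rest / rest.sum() * (1.0 - bn_total)
    return freqs


def simulate_experiment(
    drspec: DoseResponseSpec,
    render_images: bool = False,
    lab: LabProfile = DEFAULT_LAB,
    covariate_level: str = "simulated",
    ces: float = 0.5,
) -> SimulatedExperiment:
    """Simulate a full concentration-response experiment.

    For each concentration x replicate, the true binucleated-cell MN
    frequency follows the Hill induction curve with multiplicative lognormal
    replicate noise; scored counts are binomial draws at that frequency.
    When ``render_images`` is set, a full labelled image population is
    rendered per sample (slow; counts-only mode is the default).

    Returns the per-replicate dataset together with the ground-truth BMD of
    the generating curve at the given CES (None when unreachable).
    """
    rng = np.random.default_rng(drspec.seed)
    samples: list[SimulatedSample] = []
    rows = []
    for conc in drspec.concentrations:
        f_mean = hill_mean_frequency(conc, drspec)
        for rep in range(1, drspec.replicates + 1):
            f_rep = f_mean
            if drspec.noise_model > 0:
                f_rep = f_mean * float(np.exp(rng.normal(0.0, drspec.noise_model)))
            f_rep = min(f_rep, 0.95)
            n_bn_total = int(rng.binomial(drspec.n_scored_per_sample, drspec.binucleate_fraction))
            n_bn_mn = int(rng.binomial(n_bn_total, f_rep))
            n_bn = n_bn_total - n_bn_mn
            records = None
            if render_images:
                freqs = _sample_class_frequencies(drspec.binucleate_fraction, f_rep)
                pop = PopulationSpec(
                    n_cells=drspec.n_scored_per_sample,
                    class_frequencies=tuple(freqs),
                    lab=lab,
                    seed=int(rng.integers(0, 2**63 - 1)),
                )
                records = sample_population(
                    pop,
                    meta=CellMeta(lab=lab.name, concentration=conc, replicate=rep),
                )
            sample = SimulatedSample(
                concentration=conc,
                replicate=rep,
                true_frequency=f_rep,
                n_scored=drspec.n_scored_per_sample,
                n_binucleate=n_bn,
                n_binucleate_mn=n_bn_mn,
                records=records,
            )
            samples.append(sample)
            rows.append((conc, sample.empirical_frequency, covariate_level, rep))

    dataset = DoseResponseDataset.from_records(rows)
    try:
        true_bmd = hill_true_bmd(drspec, ces)
    except ValueError:
        true_bmd = None
    return SimulatedExperiment(spec=drspec, samples=samples, dataset=dataset, true_bmd=true_bmd)
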