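"""Per-sample class counts and the binucleated-cell MN frequency."""

from __future__ import annotations

from dataclasses import dataclass

from mnflow.taxonomy import PhenotypeClass


@dataclass(frozen=True)
class SampleCounts:
    """Scored phenotype counts for one sample (concentration x replicate).

    counts: mapping PhenotypeClass -> integer count; n_scored must equal the
    sum of counts. scoring_method distinguishes human and network scores.
    """

    counts: dict
    n_scored: int
    concentration: float = 0.0
    replicate: int = 0
    scoring_method: str = "network"

    def __post_init__(self):
        counts = {PhenotypeClass(int(k)): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("counts must be non-negative")
        total = sum(counts.values())
        if total != self.n_scored:
            raise ValueError(
                f"counts sum to {total} but n_scored = {self.n_scored}"
            )
        object.__setattr__(self, "counts", counts)

    def count(self, cls: PhenotypeClass) -> int:
        return self.counts.get(cls, 0)


def mn_frequency(sample: SampleCounts) -> float | None:
    """Micronucleated-binucleate frequency: N(BN+MN) / (N(BN) + N(BN+MN)).

    The denominator is the total binucleated population (MN-positive
    binucleates included). Returns None (undefined) when no binucleated
    cells were scored.
    """
    n_bn = sample.count(PhenotypeClass.BINUCLEATE)
    n_bn_mn = sample.count(PhenotypeClass.BINUCLEATE_MN)
    denom = n_bn + n_bn_mn
    if denom == 0:
        return None
    return n_bn_mn / denom
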