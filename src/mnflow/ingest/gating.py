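"""Single-cell / in-focus gating on the extracted feature table."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from mnflow.ingest.records import CellRecord


@dataclass(frozen=True)
class GatingConfig:
    """Feature gates selecting in-focus single cells.

    All bounds are inclusive. Defaults: brightfield area 200-500 um^2,
    aspect ratio 0.75-1.0, gradient RMS 55-80; the wider acquisition area
    range (100-900 um^2) emulates the debris pre-filter applied at capture.
    """

    area_range: tuple[float, float] = (200.0, 500.0)
    aspect_ratio_range: tuple[float, float] = (0.75, 1.0)
    gradient_rms_range: tuple[float, float] = (55.0, 80.0)
    acquisition_area_range: tuple[float, float] = (100.0, 900.0)

    def __post_init__(self):
        for name in ("area_range", "aspect_ratio_range", "gradient_rms_range",
                     "acquisition_area_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper {hi}")

    def passes(self, features) -> bool:
        """Inclusive-boundary test of the three scoring gates."""
        a_lo, a_hi = self.area_range
        r_lo, r_hi = self.aspect_ratio_range
        g_lo, g_hi = self.gradient_rms_range
        f = features
        return (
            a_lo <= f.brightfield_area <= a_hi
            and r_lo <= f.aspect_ratio <= r_hi
            and g_lo <= f.gradient_rms <= g_hi
        )


def gate_single_cells(
    records: Sequence[CellRecord], cfg: GatingConfig | None = None
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Partition records into (kept, rejected) by the feature gates.

    kept and rejected are disjoint, preserve input order, and together
    contain every input record. Records without populated features raise.
    """
    cfg = cfg or GatingConfig()
    kept: list[CellRecord] = []
    rejected: list[CellRecord] = []
    for rec in records:
        if rec.features is None:
            raise ValueError("record has no gating features; run feature extraction first")
        (kept if cfg.passes(rec.features) else rejected).append(rec)
    return kept, rejected
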