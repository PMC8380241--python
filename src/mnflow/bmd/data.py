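"""Dose-response dataset container shared by the simulator and the BMD fitter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ("concentration", "response", "covariate_level", "replicate")


@dataclass
class DoseResponseDataset:
    """Per-replicate responses by concentration and covariate level.

    Wraps a DataFrame with columns (concentration, response, covariate_level,
    replicate). Each covariate level must include at least one
    zero-concentration (vehicle control) record.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(COLUMNS)))

    def __post_init__(self):
        missing = set(COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
        if len(self.table):
            if (self.table["concentration"] < 0).any():
                raise ValueError("concentrations must be >= 0")
            for level, grp in self.table.groupby("covariate_level"):
                if not (grp["concentration"] == 0).any():
                    raise ValueError(
                        f"covariate level {level!r} has no zero-concentration control"
                    )

    @classmethod
    def from_records(cls, records) -> "DoseResponseDataset":
        return cls(pd.DataFrame.from_records(records, columns=list(COLUMNS)))

    @property
    def levels(self) -> list:
        return sorted(self.table["covariate_level"].unique().tolist())

    def for_level(self, level) -> tuple[np.ndarray, np.ndarray]:
        grp = self.table[self.table["covariate_level"] == level]
        return grp["concentration"].to_numpy(float), grp["response"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)
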