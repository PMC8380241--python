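"""Nine-way cell phenotype taxonomy and the reduced 'polynucleated' variant.

The integer encoding (0-8) is stable and is the label encoding used by the
classifier, the confusion matrix and the CSV manifests.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Iterable, Sequence


class PhenotypeClass(IntEnum):
    """Cell phenotype classes scored in the CBMN assay."""

    MONONUCLEATE = 0
    MONONUCLEATE_MN = 1
    BINUCLEATE = 2
    BINUCLEATE_MN = 3
    TRINUCLEATE = 4
    TRINUCLEATE_MN = 5
    TETRANUCLEATE = 6
    TETRANUCLEATE_MN = 7
    OTHER_UNSCORABLE = 8

    @property
    def n_nuclei(self) -> int | None:
        """Number of main nuclei, or None for other/unscorable."""
        if self is PhenotypeClass.OTHER_UNSCORABLE:
            return None
        return self.value // 2 + 1

    @property
    def has_mn(self) -> bool:
        """Whether the class carries at least one micronucleus."""
        if self is PhenotypeClass.OTHER_UNSCORABLE:
            return False
        return self.value % 2 == 1

    @classmethod
    def from_counts(cls, n_nuclei: int, has_mn: bool) -> "PhenotypeClass":
        if not 1 <= n_nuclei <= 4:
            raise ValueError(f"n_nuclei must be 1-4, got {n_nuclei}")
        return cls((n_nuclei - 1) * 2 + int(has_mn))


#: Canonical short names, index-aligned with the integer encoding.
CLASS_NAMES: tuple[str, ...] = (
    "mononucleate",
    "mononucleate_mn",
    "binucleate",
    "binucleate_mn",
    "trinucleate",
    "trinucleate_mn",
    "tetranucleate",
    "tetranucleate_mn",
    "other_unscorable",
)

N_CLASSES = 9

_NAME_TO_CLASS = {n: PhenotypeClass(i) for i, n in enumerate(CLASS_NAMES)}

#: Reduced six-class taxonomy obtained by pooling tri/tetra(+MN).
MERGED_CLASS_NAMES: tuple[str, ...] = (
    "mononucleate",
    "mononucleate_mn",
    "binucleate",
    "binucleate_mn",
    "polynucleated",
    "other_unscorable",
)

_POLY = {
    PhenotypeClass.TRINUCLEATE,
    PhenotypeClass.TRINUCLEATE_MN,
    PhenotypeClass.TETRANUCLEATE,
    PhenotypeClass.TETRANUCLEATE_MN,
}

_MERGE_MAP = {
    "mononucleate": "mononucleate",
    "mononucleate_mn": "mononucleate_mn",
    "binucleate": "binucleate",
    "binucleate_mn": "binucleate_mn",
    "trinucleate": "polynucleated",
    "trinucleate_mn": "polynucleated",
    "tetranucleate": "polynucleated",
    "tetranucleate_mn": "polynucleated",
    "other_unscorable": "other_unscorable",
    # idempotence: the merged name maps to itself
    "polynucleated": "polynucleated",
}


def class_name(label: PhenotypeClass | int) -> str:
    return CLASS_NAMES[int(label)]


def parse_class(name: str) -> PhenotypeClass:
    """Parse a manifest label string into a PhenotypeClass.

    Raises ValueError for labels outside the taxonomy.
    """
    key = name.strip().lower()
    if key not in _NAME_TO_CLASS:
        raise ValueError(
            f"unknown phenotype label {name!r}; expected one of {CLASS_NAMES}"
        )
    return _NAME_TO_CLASS[key]


def merge_polynucleated(labels: Iterable[PhenotypeClass | int | str]) -> list[str]:
    """Map nine-class labels onto the reduced six-class taxonomy.

    Tri- and tetranucleated classes (with and without MN) pool into a single
    'polynucleated' class; all other classes are unchanged. Idempotent:
    already-merged labels map to themselves.
    """
    out = []
    for lab in labels:
        if isinstance(lab, str):
            name = lab.strip().lower()
            if name not in _MERGE_MAP:
                raise ValueError(f"unknown label {lab!r}")
            out.append(_MERGE_MAP[name])
        else:
            out.append(_MERGE_MAP[CLASS_NAMES[int(lab)]])
    return out


def encode_merged(names: Sequence[str]) -> list[int]:
    """Integer-encode merged labels in MERGED_CLASS_NAMES order."""
    idx = {n: i for i, n in enumerate(MERGED_CLASS_NAMES)}
    return [idx[n] for n in names]
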