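"""1536-well plate geometry: row labels, well roles, control layout.

A 1536-well plate has 32 rows (labelled ``A``–``Z`` then ``AA``–``AF``) and 48
columns (1-based).  The screening layout dedicates the first three columns to
controls and the rest to test compounds:

* column 1 — positive-inhibitor dose series (16 doses, 1:2 dilution from
  285 µM, two wells per dose),
* column 2 — no-enzyme negative control (background),
* column 3 — saturating positive control (uninhibited signal),
* columns 4–48 — test compounds.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

from .exceptions import InvalidParameterError

#: Well roles used throughout plate tables.
ROLE_POS_DOSE = "pos_dose"
ROLE_NEG = "neg"
ROLE_POS = "pos"
ROLE_TEST = "test"

ROLES = (ROLE_POS_DOSE, ROLE_NEG, ROLE_POS, ROLE_TEST)


def row_label(index: int) -> str:
    """0-based row index -> plate-reader row label (``A`` … ``Z``, ``AA`` … )."""
    if index < 0:
        raise InvalidParameterError(f"row index must be >= 0, got {index}")
    letters = string.ascii_uppercase
    if index < 26:
        return letters[index]
    return "A" + letters[index - 26]


def row_index(label: str) -> int:
    """Inverse of :func:`row_label`."""
    letters = string.ascii_uppercase
    label = label.strip().upper()
    if len(label) == 1 and label in letters:
        return letters.index(label)
    if len(label) == 2 and label[0] == "A" and label[1] in letters:
        return 26 + letters.index(label[1])
    raise InvalidParameterError(f"unrecognised row label {label!r}")


@dataclass(frozen=True)
class PlateLayout:
    """Control geometry of a screening plate.

    Parameters
    ----------
    n_rows, n_cols : int
        Plate dimensions; defaults describe 1536-well format.
    control_top_um : float
        Top concentration of the column-1 inhibitor dose series (µM).
    control_n_doses : int
        Number of doses in the column-1 series (1:2 dilutions).
    control_dilution : float
        Fold-dilution between consecutive doses of the series.
    """

    n_rows: int = 32
    n_cols: int = 48
    control_top_um: float = 285.0
    control_n_doses: int = 16
    control_dilution: float = 2.0
    control_map: dict = field(
        default_factory=lambda: {1: ROLE_POS_DOSE, 2: ROLE_NEG, 3: ROLE_POS}
    )

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise InvalidParameterError("plate dimensions must be positive")
        if self.control_top_um <= 0 or self.control_n_doses <= 0:
            raise InvalidParameterError("control series must have positive top and count")
        if self.control_dilution <= 1:
            raise InvalidParameterError("control dilution factor must exceed 1")
        if self.n_rows % self.control_n_doses:
            raise InvalidParameterError(
                "control_n_doses must divide n_rows so the series tiles column 1"
            )

    def role_of(self, col: int) -> str:
        """Role of every well in 1-based column ``col``."""
        return self.control_map.get(col, ROLE_TEST)

    @property
    def test_columns(self) -> list[int]:
        return [c for c in range(1, self.n_cols + 1) if self.role_of(c) == ROLE_TEST]

    @property
    def n_test_wells(self) -> int:
        return len(self.test_columns) * self.n_rows

    def control_doses_um(self) -> list[float]:
        """Column-1 dose series, highest first (geometric 1:`control_dilution`)."""
        return [
            self.control_top_um / self.control_dilution**k
            for k in range(self.control_n_doses)
        ]
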