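"""Herb ingredient tables and the oral-bioavailability / drug-likeness screen.

Herbal-medicine databases such as TCMSP annotate each compound of a herb with
precomputed ADME descriptors.  Two of them drive the standard activity screen
used in network pharmacology:

* ``OB`` — oral bioavailability, the percentage of an orally administered dose
  reaching systemic circulation (stored on the percent scale, e.g. ``59.29``);
* ``DL`` — drug-likeness, a dimensionless 0-1 index of structural similarity
  to known drugs.

A compound is called *active* when both descriptors clear their thresholds
(conventionally OB >= 30 % and DL >= 0.18).  This module loads ingredient
tables from TSV and applies that conjunctive screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IngredientRecord",
    "ScreenCriteria",
    "IngredientFormatError",
    "load_ingredients",
    "screen_ingredients",
    "write_ingredients",
]

#: Required header of an ingredient TSV, in canonical order.
INGREDIENT_COLUMNS = ("molecule_id", "name", "mol_weight", "ob", "dl")


class IngredientFormatError(ValueError):
    """Raised when an ingredient table violates the expected TSV layout."""


@dataclass(frozen=True)
class IngredientRecord:
    """One herb compound with its ADME descriptors.

    Parameters
    ----------
    molecule_id
        Opaque stable identifier (e.g. ``"MOL004328"``).
    name
        Display name of the compound.
    mol_weight
        Molecular mass in g/mol; must be positive.
    ob
        Oral bioavailability in percent; non-negative.
    dl
        Drug-likeness index in [0, 1].
    """

    molecule_id: str
    name: str
    mol_weight: float
    ob: float
    dl: float

    def __post_init__(self) -> None:
        if not self.molecule_id:
            raise ValueError("molecule_id must be non-empty")
        if not (self.mol_weight > 0):
            raise ValueError(
                f"{self.molecule_id}: mol_weight must be > 0, got {self.mol_weight}"
            )
        if not (self.ob >= 0):
            raise ValueError(f"{self.molecule_id}: ob must be >= 0, got {self.ob}")
        if not (0 <= self.dl <= 1):
            raise ValueError(f"{self.molecule_id}: dl must be in [0, 1], got {self.dl}")


@dataclass(frozen=True)
class ScreenCriteria:
    """Activity-screen thresholds.

    ``inclusive=True`` (default) keeps compounds with ``ob >= ob_min`` and
    ``dl >= dl_min``; ``inclusive=False`` switches both comparisons to strict
    ``>`` for sensitivity analysis.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValueError(f"ob_min must be >= 0, got {self.ob_min}")
        if self.dl_min < 0:
            raise ValueError(f"dl_min must be >= 0, got {self.dl_min}")

    def passes(self, record: IngredientRecord) -> bool:
        if self.inclusive:
            return record.ob >= self.ob_min and record.dl >= self.dl_min
        return record.ob > self.ob_min and record.dl > self.dl_min


def load_ingredients(path: str | Path) -> list[IngredientRecord]:
    """Read an ingredient TSV into records, in file order.

    The file must be UTF-8 with a header row naming all five canonical
    columns (any order; extra columns are ignored).  Missing or unparseable
    numeric cells and duplicated molecule ids are hard errors: silent loss of
    rows at screen time is worse than failing loudly at load time.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INGREDIENT_COLUMNS if c not in frame.columns]
    if missing:
        raise IngredientFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    records: list[IngredientRecord] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is line 1
        numeric = {}
        for col in ("mol_weight", "ob", "dl"):
            raw = row[col].strip()
            try:
                value = float(raw)
            except ValueError:
                raise IngredientFormatError(
                    f"{path}, line {line_no}: cannot parse {col}={raw!r} as a number"
                ) from None
            if raw == "" or math.isnan(value):
                raise IngredientFormatError(
                    f"{path}, line {line_no}: missing value for {col}"
                )
            numeric[col] = value
        molecule_id = row["molecule_id"].strip()
        if molecule_id in seen:
            raise IngredientFormatError(
                f"{path}, line {line_no}: duplicated molecule_id {molecule_id!r}"
            )
        seen.add(molecule_id)
        records.append(
            IngredientRecord(
                molecule_id=molecule_id,
                name=row["name"].strip(),
                mol_weight=numeric["mol_weight"],
                ob=numeric["ob"],
                dl=numeric["dl"],
            )
        )
    return records


def screen_ingredients(
    records: Iterable[IngredientRecord],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> list[IngredientRecord]:
    """Return the records passing the OB/DL conjunction, input order preserved.

    The input is never modified; screening the output again with the same
    criteria is a no-op (the filter is idempotent), and raising either
    threshold can only shrink the survivor list.
    """
    return [r for r in records if criteria.passes(r)]


def write_ingredients(records: Sequence[IngredientRecord], path: str | Path) -> None:
    """Write records to a TSV in the same dialect accepted by the loader."""
    frame = pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "name": r.name,
                "mol_weight": r.mol_weight,
                "ob": r.ob,
                "dl": r.dl,
            }
            for r in records
        ],
        columns=list(INGREDIENT_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
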