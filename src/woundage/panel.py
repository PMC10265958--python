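"""Reference panel of differential metabolites and molecular-formula mass arithmetic.

The package ships a 43-metabolite reference panel identified in contused rat
skeletal muscle (name, molecular formula, measured neutral monoisotopic mass,
mass error in ppm, retention time, mzCloud and HMDB identifiers).  The tabulated
``mz`` column is the neutral monoisotopic mass — it agrees with the formula mass
to within the printed ppm errors (e.g. valine C5H11NO2 at 117.0789 Da) — not a
protonated-ion m/z.

Formulas use plain Hill-style notation (``C11H12N2O2``): one- or two-letter
element symbols, each followed by an optional positive integer count.  No
parentheses, isotope labels or charges are supported; none occur in the panel.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "MetaboliteRecord",
    "parse_formula",
    "monoisotopic_mass",
    "ppm_error",
    "load_panel",
    "default_panel_path",
]

#: IUPAC 2021 monoisotopic atomic masses (Da) for the most abundant isotope.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
    "F": 18.99840316,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a molecular formula cannot be parsed or contains unknown symbols."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``C11H12N2O2``-style notation into an element → count map.

    Repeated element symbols accumulate (``CH3CH3`` → ``{"C": 2, "H": 6}``).
    """
    if not formula or not formula.strip():
        raise FormulaError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    text = formula.strip()
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        symbol, digits = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in formula {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = match.end()
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of a molecular formula.

    Sum over elements of count × monoisotopic atomic mass.  Accepts either a
    formula string or an element → count map.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    mass = 0.0
    for symbol, count in counts.items():
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r}")
        if not isinstance(count, int) or count <= 0:
            raise FormulaError(f"count for {symbol!r} must be a positive integer")
        mass += count * MONOISOTOPIC_MASS[symbol]
    return mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million: 1e6 × (observed − theoretical) / theoretical."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class MetaboliteRecord:
    """One panel entry: identity, formula, measured mass and database identifiers."""

    index: int
    name: str
    formula: dict[str, int]
    mz: float
    mass_error_ppm: float
    rt_min: float
    mzcloud_id: str | None = None
    hmdb_id: str | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"record index must be ≥ 1, got {self.index}")
        if self.mz <= 0:
            raise ValueError(f"{self.name}: mz must be positive, got {self.mz}")
        if self.rt_min < 0:
            raise ValueError(f"{self.name}: retention time must be ≥ 0, got {self.rt_min}")
        if abs(self.mass_error_ppm) >= 10:
            raise ValueError(
                f"{self.name}: |mass error| must be < 10 ppm, got {self.mass_error_ppm}"
            )

    @property
    def theoretical_mass(self) -> float:
        return monoisotopic_mass(self.formula)


_COLUMNS = ["index", "name", "formula", "mz", "mass_error_ppm", "rt_min", "mzcloud_id", "hmdb_id"]


def default_panel_path() -> Path:
    """Path of the packaged 43-metabolite panel fixture."""
    return Path(str(resources.files("woundage").joinpath("data/metabolite_panel.csv")))


def load_panel(path: str | Path | None = None) -> list[MetaboliteRecord]:
    """Load a metabolite panel CSV into a list of :class:`MetaboliteRecord`.

    With no argument, loads the packaged 43-metabolite panel.  Empty ID cells
    become ``None``.  Raises on malformed formulas (naming the row) and on
    duplicate record indices.
    """
    path = default_panel_path() if path is None else Path(path)
    records: list[MetaboliteRecord] = []
    seen: set[int] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or list(reader.fieldnames) != _COLUMNS:
            raise ValueError(
                f"unexpected panel header {reader.fieldnames!r}; expected {_COLUMNS!r}"
            )
        for row_no, row in enumerate(reader, start=2):
            try:
                formula = parse_formula(row["formula"])
            except FormulaError as exc:
                raise FormulaError(f"row {row_no} ({row.get('name', '?')}): {exc}") from exc
            idx = int(row["index"])
            if idx in seen:
                raise ValueError(f"duplicate record index {idx} at row {row_no}")
            seen.add(idx)
            records.append(
                MetaboliteRecord(
                    index=idx,
                    name=row["name"],
                    formula=formula,
                    mz=float(row["mz"]),
                    mass_error_ppm=float(row["mass_error_ppm"]),
                    rt_min=float(row["rt_min"]),
                    mzcloud_id=row["mzcloud_id"] or None,
                    hmdb_id=row["hmdb_id"] or None,
                )
            )
    return records
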