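"""Dataset model, unit conversion, extraction-efficiency correction and I/O.

Study datasets are exchanged as comma-separated text with one measurement
per row and the NONMEM-inspired header::

    ID,GROUP,ROUTE,DOSE_UG,TIME,CMT,DV,EFF

``CMT`` is ``plasma`` (dependent value in µmol/L) or ``urine`` (cumulative
amount over the collection interval, µmol); only these two compartments are
observed — tissue measurements are out of scope.  ``DV`` holds the raw
measured value; dividing by the extraction efficiency ``EFF`` recovers the
corrected value used by all downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LISINOPRIL_MOLAR_MASS_G_PER_MOL",
    "ObservationRecord",
    "DesignCell",
    "StudyDesign",
    "DatasetError",
    "COLUMNS",
    "dose_to_umol",
    "umol_to_dose_ug",
    "correct_extraction",
    "correct_records",
    "read_dataset",
    "write_dataset",
    "build_design",
]

#: Molar mass of lisinopril used to convert administered µg to µmol.
LISINOPRIL_MOLAR_MASS_G_PER_MOL = 405.5

COLUMNS = ("ID", "GROUP", "ROUTE", "DOSE_UG", "TIME", "CMT", "DV", "EFF")

_GROUPS = ("control", "irradiated")
_ROUTES = ("gavage", "iv")
_COMPARTMENTS = ("plasma", "urine")


class DatasetError(ValueError):
    """Raised on malformed dataset files, carrying row-numbered diagnostics."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        shown = "\n".join(self.diagnostics[:10])
        extra = len(self.diagnostics) - 10
        if extra > 0:
            shown += f"\n... and {extra} more"
        super().__init__(f"invalid dataset:\n{shown}")


@dataclass(frozen=True)
class ObservationRecord:
    """One measured value from one animal.

    ``value`` is the raw measurement (µmol/L for plasma, µmol for urine);
    dividing by ``efficiency`` gives the extraction-corrected value.  After
    correction, negative values are permitted (additive error model);
    pre-correction raw values may likewise be negative.
    """

    animal_id: str
    group: str
    route: str
    dose_ug: float
    time_h: float
    compartment: str
    value: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.route not in _ROUTES:
            raise ValueError(f"route must be one of {_ROUTES}, got {self.route!r}")
        if self.compartment not in _COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {_COMPARTMENTS}, got {self.compartment!r}"
            )
        if self.dose_ug < 0:
            raise ValueError("dose_ug must be >= 0")
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")
        if not 0 < self.efficiency <= 1:
            raise ValueError(f"efficiency must be in (0, 1], got {self.efficiency}")

    @property
    def corrected_value(self) -> float:
        return self.value / self.efficiency


@dataclass(frozen=True)
class DesignCell:
    """One study-design cell: identically treated and sampled animals."""

    group: str
    route: str
    dose_ug: float
    n_plasma_draws: int
    urine_collected: bool
    n_animals: int

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0 <= self.n_plasma_draws <= 4:
            raise ValueError("n_plasma_draws must be in 0..4")


@dataclass(frozen=True)
class StudyDesign:
    cells: tuple[DesignCell, ...]

    @property
    def n_animals(self) -> int:
        return sum(c.n_animals for c in self.cells)


def dose_to_umol(dose_ug: float) -> float:
    """Convert an administered dose in µg to µmol (molar mass 405.5 g/mol)."""
    if dose_ug < 0:
        raise ValueError("dose must be >= 0")
    return dose_ug / LISINOPRIL_MOLAR_MASS_G_PER_MOL


def umol_to_dose_ug(amount_umol: float) -> float:
    """Inverse of :func:`dose_to_umol`."""
    return amount_umol * LISINOPRIL_MOLAR_MASS_G_PER_MOL


def correct_extraction(value: float, efficiency: float) -> float:
    """Correct a raw measured value for incomplete extraction.

    Spike-in experiments estimate the fraction of analyte recovered by the
    extraction protocol; the measured value divided by that fraction is the
    estimate of the true concentration/amount.
    """
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    return value / efficiency


def correct_records(records: Iterable[ObservationRecord]) -> list[ObservationRecord]:
    """Apply the extraction correction to every record (efficiency set to 1)."""
    return [
        replace(r, value=correct_extraction(r.value, r.efficiency), efficiency=1.0)
        for r in records
    ]


def _resolve_columns(overrides: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {c: c for c in COLUMNS}
    if overrides:
        unknown = set(overrides) - set(COLUMNS)
        if unknown:
            raise ValueError(f"unknown column keys in override: {sorted(unknown)}")
        mapping.update(overrides)
    return mapping


def read_dataset(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[ObservationRecord]:
    """Read a study dataset from CSV, validating every row.

    Parameters
    ----------
    columns : mapping, optional
        Maps canonical column names (``ID`` ... ``EFF``) to the names used
        in the file.

    Raises
    ------
    DatasetError
        Listing every malformed row with its row number and column.
    """
    colmap = _resolve_columns(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise DatasetError([f"missing required column(s): {', '.join(missing)}"])

    records: list[ObservationRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        row_d = dict(zip(df.columns, row))

        def bad(col: str, msg: str) -> None:
            problems.append(f"row {i}, column {colmap[col]}: {msg}")

        fields: dict[str, object] = {"animal_id": row_d[colmap["ID"]].strip()}
        group = row_d[colmap["GROUP"]].strip().lower()
        if group not in _GROUPS:
            bad("GROUP", f"expected one of {_GROUPS}, got {group!r}")
        route = row_d[colmap["ROUTE"]].strip().lower()
        if route not in _ROUTES:
            bad("ROUTE", f"expected one of {_ROUTES}, got {route!r}")
        cmt = row_d[colmap["CMT"]].strip().lower()
        if cmt not in _COMPARTMENTS:
            bad("CMT", f"expected one of {_COMPARTMENTS}, got {cmt!r}")

        numeric: dict[str, float] = {}
        for col in ("DOSE_UG", "TIME", "DV", "EFF"):
            raw = row_d[colmap[col]].strip()
            try:
                numeric[col] = float(raw)
            except ValueError:
                bad(col, f"not a number: {raw!r}")
        if len(numeric) == 4:
            if numeric["DOSE_UG"] < 0:
                bad("DOSE_UG", "dose must be >= 0")
            if numeric["TIME"] < 0:
                bad("TIME", "time must be >= 0")
            if not 0 < numeric["EFF"] <= 1:
                bad("EFF", "efficiency must be in (0, 1]")
        if problems and problems[-1].startswith(f"row {i},"):
            continue
        records.append(
            ObservationRecord(
                animal_id=str(fields["animal_id"]),
                group=group,
                route=route,
                dose_ug=numeric["DOSE_UG"],
                time_h=numeric["TIME"],
                compartment=cmt,
                value=numeric["DV"],
                efficiency=numeric["EFF"],
            )
        )
    if problems:
        raise DatasetError(problems)
    return records


def write_dataset(
    records: Iterable[ObservationRecord],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write records as CSV; ``read_dataset(write_dataset(x)) == x``."""
    colmap = _resolve_columns(columns)
    recs = list(records)
    df = pd.DataFrame(
        {
            colmap["ID"]: [r.animal_id for r in recs],
            colmap["GROUP"]: [r.group for r in recs],
            colmap["ROUTE"]: [r.route for r in recs],
            colmap["DOSE_UG"]: [r.dose_ug for r in recs],
            colmap["TIME"]: [r.time_h for r in recs],
            colmap["CMT"]: [r.compartment for r in recs],
            colmap["DV"]: [r.value for r in recs],
            colmap["EFF"]: [r.efficiency for r in recs],
        },
        columns=[colmap[c] for c in COLUMNS],
    )
    df.to_csv(path, index=False, float_format="%.12g")


def build_design() -> StudyDesign:
    """The sampling design of the rat study, one cell per design row.

    219 animals across radiation group x route x dose cells; each cell
    states how many plasma draws an animal contributes (0-4) and whether a
    24-h cumulative urine collection was made.  Doses are µg per animal
    (0.3/0.6 mg gavage, 0.06 mg IV).
    """
    rows = [
        # group, route, dose_ug, plasma draws, urine, n
        ("control", "gavage", 0, 1, False, 4),
        ("control", "gavage", 300, 0, True, 4),
        ("control", "gavage", 300, 1, False, 55),
        ("control", "gavage", 300, 2, False, 2),
        ("control", "gavage", 600, 0, True, 6),
        ("control", "gavage", 600, 1, True, 3),
        ("control", "gavage", 600, 2, False, 9),
        ("control", "gavage", 600, 4, False, 9),
        ("control", "iv", 60, 0, True, 6),
        ("control", "iv", 60, 1, False, 11),
        ("control", "iv", 60, 1, True, 3),
        ("control", "iv", 60, 2, False, 3),
        ("irradiated", "gavage", 300, 0, True, 5),
        ("irradiated", "gavage", 300, 1, False, 58),
        ("irradiated", "gavage", 300, 2, False, 2),
        ("irradiated", "gavage", 600, 0, True, 6),
        ("irradiated", "gavage", 600, 2, False, 8),
        ("irradiated", "gavage", 600, 4, False, 8),
        ("irradiated", "iv", 60, 0, True, 6),
        ("irradiated", "iv", 60, 1, False, 11),
    ]
    return StudyDesign(
        cells=tuple(
            DesignCell(
                group=g,
                route=rt,
                dose_ug=float(d),
                n_plasma_draws=npd,
                urine_collected=ur,
                n_animals=n,
            )
            for g, rt, d, npd, ur, n in rows
        )
    )
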