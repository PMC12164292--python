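"""Amniote digit phenotype table and staging conventions.

The packaged table records, for an inferred ancestral amniote and 13 study
species, the per-digit phalanx count (stored as a ``[min, max]`` range so
that digits with naturally variable counts can be represented), claw
presence and digit presence, for both limbs.  Developmental time is
expressed on the chicken Hamburger-Hamilton stage axis throughout the
package, quantized to half stages.
"""

from __future__ import annotations

import csv
import enum
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "STAGE_STEP",
    "Limb",
    "DigitID",
    "ClockWindow",
    "PhenotypeRecord",
    "PhenotypeTableError",
    "UnknownPhenotypeError",
    "VariableCountWarning",
    "as_stage",
    "as_limb",
    "roman",
    "index_from_roman",
    "load_phenotypes",
    "write_phenotypes",
    "records_for",
    "get_record",
    "phalanx_formula",
    "total_phalanges",
]

#: Resolution of the stage grid (half stages).
STAGE_STEP = 0.5

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}
_ROMAN_INV = {v: k for k, v in _ROMAN.items()}


class PhenotypeTableError(ValueError):
    """Raised when the packaged phenotype table is malformed."""


class UnknownPhenotypeError(KeyError):
    """Raised when a (species, limb) lookup finds no records."""


class VariableCountWarning(UserWarning):
    """Emitted when a phalanx total includes digits with variable counts."""


class Limb(str, enum.Enum):
    """Limb type; digits are numbered I-V anterior to posterior within it."""

    FORELIMB = "forelimb"
    HINDLIMB = "hindlimb"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def as_limb(value: "Limb | str") -> Limb:
    """Coerce a string or :class:`Limb` to a :class:`Limb`."""
    if isinstance(value, Limb):
        return value
    try:
        return Limb(str(value).strip().lower())
    except ValueError as exc:
        raise ValueError(f"not a limb: {value!r}") from exc


def as_stage(value: float) -> float:
    """Validate and snap a stage value to the half-stage grid.

    Stages must be finite, positive multiples of :data:`STAGE_STEP`
    (to within floating tolerance).
    """
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"stage must be a finite positive number, got {value!r}")
    steps = v / STAGE_STEP
    if abs(steps - round(steps)) > 1e-6:
        raise ValueError(f"stage must be a multiple of {STAGE_STEP}, got {value!r}")
    return round(steps) * STAGE_STEP


def roman(index: int) -> str:
    """Roman-numeral label of a digit index (1 -> 'I' ... 5 -> 'V')."""
    try:
        return _ROMAN[int(index)]
    except KeyError as exc:
        raise ValueError(f"digit index must be 1-5, got {index!r}") from exc


def index_from_roman(label: str) -> int:
    """Inverse of :func:`roman`."""
    try:
        return _ROMAN_INV[str(label).strip().upper()]
    except KeyError as exc:
        raise ValueError(f"not a digit label: {label!r}") from exc


@dataclass(frozen=True, order=True)
class DigitID:
    """A digit identified by limb and anterior-to-posterior index (1-5)."""

    limb: Limb
    index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "limb", as_limb(self.limb))
        idx = int(self.index)
        if not 1 <= idx <= 5:
            raise ValueError(f"digit index must be in [1, 5], got {self.index!r}")
        object.__setattr__(self, "index", idx)

    @property
    def roman(self) -> str:
        return roman(self.index)

    def __str__(self) -> str:
        return f"{self.limb.value} digit {self.roman}"


@dataclass(frozen=True)
class ClockWindow:
    """The conserved stage window in which phalanges are laid down.

    Defaults to onset at stage 29 and offset at stage 36.
    """

    s_on: float = 29.0
    s_off: float = 36.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_on", as_stage(self.s_on))
        object.__setattr__(self, "s_off", as_stage(self.s_off))
        if not self.s_on < self.s_off:
            raise ValueError(f"window requires s_on < s_off, got {self.s_on} >= {self.s_off}")

    @property
    def span(self) -> float:
        return self.s_off - self.s_on


@dataclass(frozen=True)
class PhenotypeRecord:
    """Phalanx count range, claw and presence status for one digit.

    ``provisional`` marks records whose encoding required editorial judgment
    (e.g. truncated source descriptions); their values are best-effort.
    """

    species: str
    digit: DigitID
    phalanx_min: int
    phalanx_max: int
    claw: bool
    present: bool
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.phalanx_min < 0 or self.phalanx_max < self.phalanx_min:
            raise ValueError(
                f"need 0 <= phalanx_min <= phalanx_max, got "
                f"[{self.phalanx_min}, {self.phalanx_max}]"
            )
        if not self.present and (self.phalanx_min, self.phalanx_max, self.claw) != (0, 0, False):
            raise ValueError("absent digits must have zero phalanges and no claw")

    @property
    def variable(self) -> bool:
        """True when the digit's phalanx count is a nontrivial range."""
        return self.phalanx_min != self.phalanx_max


_COLUMNS = ["species", "limb", "digit", "phalanx_min", "phalanx_max", "claw", "present", "provisional"]


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in {"1", "true", "yes"}:
        return True
    if t in {"0", "false", "no"}:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _default_table_path() -> Path:
    return Path(str(resources.files("digitclock").joinpath("data/phenotypes.csv")))


def load_phenotypes(path: "str | Path | None" = None) -> list[PhenotypeRecord]:
    """Load the packaged phenotype table (or a compatible CSV at *path*).

    Raises :class:`PhenotypeTableError` naming the offending row on any
    malformed entry.
    """
    src = Path(path) if path is not None else _default_table_path()
    records: list[PhenotypeRecord] = []
    with open(src, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _COLUMNS if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise PhenotypeTableError(f"phenotype table {src} lacks columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    PhenotypeRecord(
                        species=row["species"].strip(),
                        digit=DigitID(as_limb(row["limb"]), int(row["digit"])),
                        phalanx_min=int(row["phalanx_min"]),
                        phalanx_max=int(row["phalanx_max"]),
                        claw=_parse_bool(row["claw"]),
                        present=_parse_bool(row["present"]),
                        provisional=_parse_bool(row.get("provisional", "0")),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise PhenotypeTableError(
                    f"malformed phenotype row {lineno} "
                    f"({row.get('species')!r}, {row.get('limb')!r}, digit {row.get('digit')!r}): {exc}"
                ) from exc
    return records


def write_phenotypes(path: "str | Path", records: Iterable[PhenotypeRecord]) -> None:
    """Serialize records to CSV in the packaged-table column layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.species,
                    rec.digit.limb.value,
                    rec.digit.index,
                    rec.phalanx_min,
                    rec.phalanx_max,
                    int(rec.claw),
                    int(rec.present),
                    int(rec.provisional),
                ]
            )


def records_for(
    species: str,
    limb: "Limb | str",
    records: "Sequence[PhenotypeRecord] | None" = None,
) -> list[PhenotypeRecord]:
    """All records of one (species, limb), sorted by digit index."""
    limb = as_limb(limb)
    if records is None:
        records = load_phenotypes()
    out = sorted(
        (r for r in records if r.species == species and r.digit.limb is limb),
        key=lambda r: r.digit.index,
    )
    if not out:
        raise UnknownPhenotypeError(f"no phenotype records for ({species!r}, {limb.value})")
    return out


def get_record(
    species: str,
    limb: "Limb | str",
    index: int,
    records: "Sequence[PhenotypeRecord] | None" = None,
) -> PhenotypeRecord:
    """The record of one digit."""
    for rec in records_for(species, limb, records):
        if rec.digit.index == int(index):
            return rec
    raise UnknownPhenotypeError(f"no record for ({species!r}, {limb!s}, digit {index})")


def phalanx_formula(
    species: str,
    limb: "Limb | str",
    records: "Sequence[PhenotypeRecord] | None" = None,
) -> list[int]:
    """Per-digit phalanx counts I-V (``phalanx_max``; absent digits -> 0)."""
    recs = {r.digit.index: r for r in records_for(species, limb, records)}
    return [recs[i].phalanx_max if i in recs else 0 for i in range(1, 6)]


def total_phalanges(
    species: str,
    limb: "Limb | str",
    records: "Sequence[PhenotypeRecord] | None" = None,
) -> int:
    """Sum of ``phalanx_max`` over the present digits of one limb.

    Digits with a variable count contribute their maximum; a
    :class:`VariableCountWarning` is emitted whenever any such digit is
    included so callers know the total is an upper figure.
    """
    recs = records_for(species, limb, records)
    present = [r for r in recs if r.present]
    if any(r.variable for r in present):
        warnings.warn(
            f"({species}, {as_limb(limb).value}) total includes variable-count digits; "
            "reporting the maximum",
            VariableCountWarning,
            stacklevel=2,
        )
    return sum(r.phalanx_max for r in present)
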