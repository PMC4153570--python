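"""Reading, writing and editing 96-well plate absorbance data.

Two text inputs are supported:

* the *raw grid* dialect — eight lines of at least twelve whitespace-separated
  optical-density values, one line per plate row A–H, optionally prefixed by
  the row letter; and
* *delimited* exports from spreadsheet programs (semicolon-separated by
  default), where the caller states which line holds plate row A, which token
  on each line is well 1, and whether decimals use a period or a comma.

Both produce a :class:`Plate`: 96 :class:`WellValue` records carrying the
absorbance, an audit trail of manual overrides/discards, and provenance.
Discarded wells never contribute to any downstream statistic or fit.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Iterator

ROWS = "ABCDEFGH"
N_COLS = 12

ROLES = ("cell_control", "medium_control", "treated", "unused")


class PlateError(ValueError):
    """Base class for plate-level input errors."""


class MalformedGridError(PlateError):
    """Raised when a grid file does not contain 8 usable data lines."""


class PlateParseError(PlateError):
    """Raised when a token that should be numeric cannot be parsed."""


class EditError(ValueError):
    """Raised for invalid manual edits (e.g. negative absorbance)."""


@dataclass
class WellValue:
    """One well: its address, absorbance and audit state.

    ``original_absorbance`` is set exactly when the value was manually
    overridden; ``discarded`` wells are excluded from every mean, SD, fit
    and bootstrap downstream.
    """

    row: str
    column: int
    absorbance: float
    original_absorbance: float | None = None
    discarded: bool = False
    role: str = "unused"

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValueError(f"invalid row {self.row!r}; expected one of {ROWS}")
        if not 1 <= self.column <= N_COLS:
            raise ValueError(f"invalid column {self.column}; expected 1..{N_COLS}")
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r}")

    def to_dict(self) -> dict:
        return {
            "row": self.row,
            "column": self.column,
            "absorbance": self.absorbance,
            "original_absorbance": self.original_absorbance,
            "discarded": self.discarded,
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WellValue":
        return cls(**d)


@dataclass
class Plate:
    """An 8x12 plate: one :class:`WellValue` per (row, column) plus provenance.

    ``edits`` is the append-only audit log of manual interventions, kept so a
    report can print both the original and the modified value of every well.
    """

    wells: dict[tuple[str, int], WellValue]
    source_path: str = ""
    source_timestamp: str = ""
    label: str = ""
    edits: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = {(r, c) for r in ROWS for c in range(1, N_COLS + 1)}
        if set(self.wells) != expected:
            missing = sorted(expected - set(self.wells))
            extra = sorted(set(self.wells) - expected)
            raise ValueError(
                f"plate must hold exactly one well per A1..H12; "
                f"missing={missing[:3]} extra={extra[:3]}"
            )

    def well(self, row: str, column: int) -> WellValue:
        try:
            return self.wells[(row, column)]
        except KeyError:
            raise KeyError(f"no such well {row}{column}") from None

    def iter_row(self, row: str) -> Iterator[WellValue]:
        for c in range(1, N_COLS + 1):
            yield self.wells[(row, c)]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "source_path": self.source_path,
            "source_timestamp": self.source_timestamp,
            "wells": [self.wells[(r, c)].to_dict() for r in ROWS for c in range(1, N_COLS + 1)],
            "edits": copy.deepcopy(self.edits),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Plate":
        wells = {(w["row"], w["column"]): WellValue.from_dict(w) for w in d["wells"]}
        return cls(
            wells=wells,
            source_path=d.get("source_path", ""),
            source_timestamp=d.get("source_timestamp", ""),
            label=d.get("label", ""),
            edits=copy.deepcopy(d.get("edits", [])),
        )

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "Plate":
        return cls.from_dict(json.loads(text))


@dataclass
class ConverterConfig:
    """How to slice a delimited spreadsheet export into the 8x12 grid.

    ``first_value_index`` and ``first_data_line`` are 1-based.  With
    ``decimal_separator="auto"`` a token with exactly one comma and no period
    is read as comma-decimal, one period and no comma as period-decimal, and
    a token containing both is rejected (thousands separators unsupported).
    """

    delimiter: str = ";"
    first_value_index: int = 1
    first_data_line: int = 1
    decimal_separator: str = "auto"

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")
        if self.first_value_index < 1 or self.first_data_line < 1:
            raise ValueError("first_value_index and first_data_line are 1-based positives")
        if self.decimal_separator not in (".", ",", "auto"):
            raise ValueError('decimal_separator must be ".", "," or "auto"')


def _parse_token(token: str, decimal_separator: str, where: str) -> float:
    token = token.strip()
    if decimal_separator == ",":
        token = token.replace(",", ".")
    elif decimal_separator == "auto":
        has_comma = "," in token
        has_period = "." in token
        if has_comma and has_period:
            raise PlateParseError(
                f"ambiguous decimal separator in token {token!r} at {where}: "
                "contains both ',' and '.'"
            )
        if has_comma:
            token = token.replace(",", ".")
    try:
        value = float(token)
    except ValueError:
        raise PlateParseError(f"non-numeric token {token!r} at {where}") from None
    return value


def _blank_wells() -> dict[tuple[str, int], WellValue]:
    return {
        (r, c): WellValue(row=r, column=c, absorbance=0.0)
        for r in ROWS
        for c in range(1, N_COLS + 1)
    }


def read_plate_grid(text_content: str, label: str = "",
                    source_path: str = "", source_timestamp: str = "") -> Plate:
    """Parse the raw grid dialect into a :class:`Plate`.

    The first 8 non-blank lines become rows A–H.  A leading single-letter
    token A–H on a line is treated as a row label and skipped.  Each line
    must then provide at least 12 numeric tokens; values are assigned
    row-major (A1..A12, ..., H1..H12) and all roles start as ``unused``.
    """
    data_lines: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(text_content.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens[0]) == 1 and tokens[0].upper() in ROWS:
            tokens = tokens[1:]
        if tokens:
            data_lines.append((lineno, tokens))
        if len(data_lines) == 8:
            break

    if len(data_lines) < 8:
        raise MalformedGridError(
            f"malformed grid: found {len(data_lines)} data line(s), need 8"
        )

    wells = _blank_wells()
    for row, (lineno, tokens) in zip(ROWS, data_lines):
        if len(tokens) < N_COLS:
            raise MalformedGridError(
                f"line {lineno}: found {len(tokens)} value(s), need {N_COLS}"
            )
        for col, token in enumerate(tokens[:N_COLS], start=1):
            value = _parse_token(token, ".", f"line {lineno}, token {col}")
            wells[(row, col)].absorbance = value
    return Plate(wells=wells, label=label, source_path=source_path,
                 source_timestamp=source_timestamp)


def write_plate_grid(plate: Plate) -> str:
    """Render the plate's current absorbances in the raw grid dialect.

    Uses shortest-round-trip float formatting, so
    ``read_plate_grid(write_plate_grid(p))`` reproduces all 96 values exactly.
    """
    lines = []
    for r in ROWS:
        values = " ".join(repr(w.absorbance) for w in plate.iter_row(r))
        lines.append(f"{r} {values}")
    return "\n".join(lines) + "\n"


def convert_delimited(text_content: str, config: ConverterConfig,
                      label: str = "", source_path: str = "",
                      source_timestamp: str = "") -> Plate:
    """Convert a delimited spreadsheet export into a :class:`Plate`.

    Lines ``first_data_line .. first_data_line+7`` (1-based) become rows A–H;
    on each, tokens ``first_value_index .. first_value_index+11`` (1-based,
    split on the configured delimiter) become wells 1–12.  Everything before,
    after and around the 8x12 window is discarded.  Decimal commas are
    normalized to periods before numeric parsing.
    """
    lines = text_content.splitlines()
    first = config.first_data_line
    if len(lines) < first + 7:
        raise MalformedGridError(
            f"delimited input has {len(lines)} line(s); "
            f"need lines {first}..{first + 7}"
        )

    wells = _blank_wells()
    for offset, row in enumerate(ROWS):
        lineno = first + offset
        tokens = lines[lineno - 1].split(config.delimiter)
        start = config.first_value_index - 1
        if len(tokens) < start + N_COLS:
            available = max(0, len(tokens) - start)
            raise MalformedGridError(
                f"line {lineno}: only {available} value token(s) available "
                f"from position {config.first_value_index}, need {N_COLS} "
                f"(line holds {len(tokens)} token(s))"
            )
        for col in range(1, N_COLS + 1):
            token = tokens[start + col - 1]
            value = _parse_token(
                token, config.decimal_separator, f"line {lineno}, token {start + col}"
            )
            wells[(row, col)].absorbance = value
    return Plate(wells=wells, label=label, source_path=source_path,
                 source_timestamp=source_timestamp)


def apply_edit(plate: Plate, row: str, column: int, action: str,
               new_value: float | None = None) -> Plate:
    """Apply a manual edit and return a new plate; the input is untouched.

    Actions: ``"override"`` (requires ``new_value`` >= 0; the first override
    preserves the original absorbance), ``"discard"`` and ``"restore"``
    (reverts both override and discard).  Every action is appended to the
    plate's audit log so the report can print the full edit history.
    """
    edited = Plate.from_dict(plate.to_dict())
    well = edited.well(row, column)

    if action == "override":
        if new_value is None:
            raise EditError("override requires a new value")
        if new_value < 0:
            raise EditError(f"absorbance must be >= 0, got {new_value}")
        event = {"row": row, "column": column, "action": "override",
                 "old_value": well.absorbance, "new_value": new_value}
        if well.original_absorbance is None:
            well.original_absorbance = well.absorbance
        well.absorbance = new_value
    elif action == "discard":
        event = {"row": row, "column": column, "action": "discard"}
        well.discarded = True
    elif action == "restore":
        event = {"row": row, "column": column, "action": "restore"}
        if well.original_absorbance is not None:
            well.absorbance = well.original_absorbance
            well.original_absorbance = None
        well.discarded = False
    else:
        raise EditError(f"unknown edit action {action!r}")

    edited.edits.append(event)
    return edited
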