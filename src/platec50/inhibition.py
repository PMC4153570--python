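"""Control statistics, percent inhibition and triplicate summaries.

The plate layout contract: one control row whose first 9 wells hold untreated
cells (cell control, CC) and whose last 3 wells hold medium without cells
(medium control, CM); every compound row holds 4 concentrations x 3 wells,
concentrations descending left to right.

Percent inhibition of proliferation for a treated well with absorbance A_p is

    IP = 100 * (1 - (A_p - A_cm) / (A_cc - A_cm))

where A_cc and A_cm are the mean cell-control and medium-control absorbances.
IP is deliberately *not* clamped: values below 0 (growth stimulation) or above
100 propagate to the estimators, which filter or flag them; clamping would
bias the regression fits.

Outlier screening per triplicate flags values farther than k sample standard
deviations from the triplicate mean.  With n=3 the largest possible deviation
is (n-1)/sqrt(n) = 2/sqrt(3) ~ 1.1547 SDs, so any k at or above that bound can
never flag anything.  Flags are always recorded; flagged wells are excluded
from computation only when the discard-outliers option is on (off by default,
since discarding real variation is rarely justified).  Detection runs on
absorbances, but IP is an affine function of absorbance so the flags would be
identical either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plate_io import N_COLS, ROWS, Plate

N_CELL_CONTROL = 9   # control-row wells 1..9: untreated cells
N_MEDIUM_CONTROL = 3 # control-row wells 10..12: medium background

DEFAULT_OUTLIER_K = 1.0


class AnalysisError(ValueError):
    """Base class for analysis-stage errors."""


class InsufficientControlsError(AnalysisError):
    """Too few non-discarded control wells to form control statistics."""


class DegenerateControlsError(AnalysisError):
    """Cell-control mean does not exceed medium-control mean."""


class EmptyRowError(AnalysisError):
    """Every well of a compound row was discarded."""


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size >= 2 else 0.0


@dataclass(frozen=True)
class ControlStats:
    """Means and sample SDs of the non-discarded control wells."""

    a_cc: float
    a_cm: float
    sd_cc: float
    sd_cm: float
    n_cc: int
    n_cm: int

    @property
    def window(self) -> float:
        """Dynamic range of the assay, A_cc - A_cm."""
        return self.a_cc - self.a_cm

    def to_dict(self) -> dict:
        return {"a_cc": self.a_cc, "a_cm": self.a_cm, "sd_cc": self.sd_cc,
                "sd_cm": self.sd_cm, "n_cc": self.n_cc, "n_cm": self.n_cm}


@dataclass(frozen=True)
class RowSpec:
    """A compound row: name plus its 4 doses, greatest to smallest."""

    row: str
    compound_name: str
    doses: tuple[float, float, float, float]
    units: str = "ug/ml"

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValueError(f"invalid row {self.row!r}")
        doses = tuple(float(d) for d in self.doses)
        if len(doses) != 4:
            raise ValueError("exactly 4 doses per row")
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be positive")
        if any(a <= b for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly decreasing left to right")
        object.__setattr__(self, "doses", doses)

    def dose_for_column(self, column: int) -> float:
        # wells 1-3 -> doses[0], 4-6 -> doses[1], 7-9 -> doses[2], 10-12 -> doses[3]
        return self.doses[(column - 1) // 3]

    def to_dict(self) -> dict:
        return {"row": self.row, "compound_name": self.compound_name,
                "doses": list(self.doses), "units": self.units}

    @classmethod
    def from_dict(cls, d: dict) -> "RowSpec":
        return cls(row=d["row"], compound_name=d["compound_name"],
                   doses=tuple(d["doses"]), units=d.get("units", "ug/ml"))


@dataclass
class InhibitionPoint:
    """One well's percent inhibition at its dose, with its exclusion flags."""

    dose: float
    ip: float
    well: tuple[str, int] | None = None
    discarded: bool = False
    outlier: bool = False

    def to_dict(self) -> dict:
        return {"dose": self.dose, "ip": self.ip,
                "well": list(self.well) if self.well else None,
                "discarded": self.discarded, "outlier": self.outlier}


@dataclass
class TriplicateSummary:
    """Per-dose summary over the wells that survive discards (and, when the
    discard-outliers option is on, outlier flags)."""

    dose: float
    mean_od: float | None
    sd_od: float | None
    mean_ip: float | None
    n_used: int
    flag_0_or_100: bool = False

    def to_dict(self) -> dict:
        return {"dose": self.dose, "mean_od": self.mean_od, "sd_od": self.sd_od,
                "mean_ip": self.mean_ip, "n_used": self.n_used,
                "flag_0_or_100": self.flag_0_or_100}


@dataclass
class DoseResponseTable:
    """Per-compound dose-response data: individual well points + triplicate
    summaries.  ``outliers_discarded`` records whether flagged wells were
    excluded, so estimators apply the same filter."""

    compound_name: str
    points: list[InhibitionPoint]
    triplicates: list[TriplicateSummary]
    row: str = ""
    units: str = "ug/ml"
    outliers_discarded: bool = False

    def usable_points(self) -> list[InhibitionPoint]:
        """Points eligible for fitting: not discarded, not excluded outliers."""
        return [p for p in self.points
                if not p.discarded
                and not (self.outliers_discarded and p.outlier)]

    def dose_means(self) -> list[tuple[float, float]]:
        """(dose, mean IP) per non-empty triplicate, dose ascending."""
        pairs = [(t.dose, t.mean_ip) for t in self.triplicates if t.n_used > 0]
        return sorted(pairs)

    def to_dict(self) -> dict:
        return {"compound_name": self.compound_name, "row": self.row,
                "units": self.units,
                "outliers_discarded": self.outliers_discarded,
                "points": [p.to_dict() for p in self.points],
                "triplicates": [t.to_dict() for t in self.triplicates]}

    @classmethod
    def from_points(cls, compound_name: str, points: list[InhibitionPoint],
                    units: str = "ug/ml") -> "DoseResponseTable":
        """Build a table (with triplicate-style summaries) directly from
        (dose, IP) points — used by simulations and tests that have no plate."""
        by_dose: dict[float, list[InhibitionPoint]] = {}
        for p in points:
            by_dose.setdefault(p.dose, []).append(p)
        triplicates = []
        for dose in sorted(by_dose, reverse=True):
            used = [p.ip for p in by_dose[dose] if not p.discarded]
            mean_ip = float(np.mean(used)) if used else None
            triplicates.append(TriplicateSummary(
                dose=dose, mean_od=None, sd_od=None, mean_ip=mean_ip,
                n_used=len(used),
                flag_0_or_100=mean_ip is not None and (mean_ip <= 0 or mean_ip >= 100),
            ))
        return cls(compound_name=compound_name, points=list(points),
                   triplicates=triplicates, units=units)


def control_stats(plate: Plate, control_row: str) -> ControlStats:
    """Compute control means/SDs over the non-discarded control wells.

    Requires at least 2 usable cell-control wells and 1 usable medium well,
    and a positive assay window (A_cc > A_cm); otherwise the analysis cannot
    proceed at all.
    """
    cells = [w.absorbance for w in plate.iter_row(control_row)
             if w.column <= N_CELL_CONTROL and not w.discarded]
    medium = [w.absorbance for w in plate.iter_row(control_row)
              if w.column > N_CELL_CONTROL and not w.discarded]
    if len(cells) < 2 or len(medium) < 1:
        raise InsufficientControlsError(
            f"control row {control_row}: {len(cells)} cell-control and "
            f"{len(medium)} medium well(s) usable; need >=2 and >=1"
        )
    cells = np.asarray(cells, dtype=float)
    medium = np.asarray(medium, dtype=float)
    stats = ControlStats(
        a_cc=float(cells.mean()), a_cm=float(medium.mean()),
        sd_cc=_sample_sd(cells), sd_cm=_sample_sd(medium),
        n_cc=len(cells), n_cm=len(medium),
    )
    if stats.a_cc <= stats.a_cm:
        raise DegenerateControlsError(
            f"degenerate controls: A_cc={stats.a_cc:.6g} <= A_cm={stats.a_cm:.6g}; "
            "untreated cells must absorb more than medium background"
        )
    return stats


def percent_inhibition(a_p: float, controls: ControlStats) -> float:
    """Percent inhibition of a well with absorbance ``a_p`` (unclamped)."""
    return 100.0 * (1.0 - (a_p - controls.a_cm) / (controls.a_cc - controls.a_cm))


def detect_outliers(triplicate_values, k: float = DEFAULT_OUTLIER_K) -> list[bool]:
    """Flag triplicate values farther than k sample SDs from the mean.

    With zero SD nothing is flagged.  Note the hard n=3 bound: no value can
    deviate by more than 2/sqrt(3) SDs, so k >= 1.1548 flags nothing, ever.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    values = np.asarray(list(triplicate_values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for outlier detection")
    mean = values.mean()
    sd = _sample_sd(values)
    if sd == 0.0 or not math.isfinite(sd):
        return [False] * values.size
    return [bool(abs(v - mean) > k * sd) for v in values]


def build_dose_response(plate: Plate, spec: RowSpec, controls: ControlStats,
                        discard_outliers: bool = False,
                        outlier_k: float = DEFAULT_OUTLIER_K) -> DoseResponseTable:
    """Turn one compound row into a :class:`DoseResponseTable`.

    Per-well IPs come from :func:`percent_inhibition`; outlier flags are
    computed per triplicate on absorbances (and excluded from summaries only
    when ``discard_outliers``); each dose's summary averages the surviving
    wells.  A dose whose three wells are all discarded yields an empty
    triplicate (``n_used=0``) for the estimators to cope with.
    """
    row_wells = list(plate.iter_row(spec.row))
    if all(w.discarded for w in row_wells):
        raise EmptyRowError(f"row {spec.row}: all 12 wells discarded")

    points: list[InhibitionPoint] = []
    triplicates: list[TriplicateSummary] = []
    for idx, dose in enumerate(spec.doses):
        trio = row_wells[idx * 3:(idx + 1) * 3]
        alive = [w for w in trio if not w.discarded]

        flags = {w.column: False for w in trio}
        if len(alive) >= 2:
            for w, flagged in zip(alive, detect_outliers(
                    [w.absorbance for w in alive], k=outlier_k)):
                flags[w.column] = flagged

        used_od, used_ip = [], []
        for w in trio:
            ip = percent_inhibition(w.absorbance, controls)
            points.append(InhibitionPoint(
                dose=dose, ip=ip, well=(w.row, w.column),
                discarded=w.discarded, outlier=flags[w.column]))
            if not w.discarded and not (discard_outliers and flags[w.column]):
                used_od.append(w.absorbance)
                used_ip.append(ip)

        if used_od:
            od = np.asarray(used_od, dtype=float)
            mean_ip = float(np.mean(used_ip))
            triplicates.append(TriplicateSummary(
                dose=dose, mean_od=float(od.mean()), sd_od=_sample_sd(od),
                mean_ip=mean_ip, n_used=len(used_od),
                flag_0_or_100=mean_ip <= 0 or mean_ip >= 100))
        else:
            triplicates.append(TriplicateSummary(
                dose=dose, mean_od=None, sd_od=None, mean_ip=None, n_used=0))

    return DoseResponseTable(
        compound_name=spec.compound_name, points=points, triplicates=triplicates,
        row=spec.row, units=spec.units, outliers_discarded=discard_outliers)
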