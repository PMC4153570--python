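"""Synthetic plate generation with known Hill-curve ground truth.

The simulator inverts the percent-inhibition normalization: for a well at
dose C on a compound row with true Hill parameters (i_max, h, k), the true
inhibition IP(C) is mapped back to an absorbance

    A = a_cm + (1 - IP/100) * (a_cc - a_cm)

and Gaussian noise is added (additive on absorbance by default, matching
photometer noise near mid-range OD; proportional noise is available).  The
control row is filled per the standard layout: 9 untreated-cell wells at
a_cc and 3 medium wells at a_cm, noisy.  With probability ``outlier_rate``
a compound well is replaced by a gross error uniform on [0, 2*a_cc], which
exercises the k-SD triplicate flagging rule.  Everything is deterministic
under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .estimators import HillParams, hill_absolute_ic50
from .inhibition import RowSpec
from .plate_io import N_COLS, Plate, WellValue

DEFAULT_A_CC = 1.0
DEFAULT_A_CM = 0.1
# Ten-fold serial dilution reaching a decade above the default compound's
# half-maximal concentration, so the upper plateau (and hence I_max and the
# relative IC50) is actually delineated by the design.
DEFAULT_DOSES = (1000.0, 100.0, 10.0, 1.0)


@dataclass(frozen=True)
class SimRow:
    """One simulated compound row: its spec plus the true Hill parameters."""

    spec: RowSpec
    params: HillParams


@dataclass(frozen=True)
class SimulationTruth:
    """Full ground truth for one plate."""

    rows: tuple[SimRow, ...]
    control_row: str = "H"
    a_cc_true: float = DEFAULT_A_CC
    a_cm_true: float = DEFAULT_A_CM
    noise_sd: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0
    noise_model: str = "additive"

    def __post_init__(self) -> None:
        if self.a_cc_true <= self.a_cm_true:
            raise ValueError("a_cc_true must exceed a_cm_true")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.noise_model not in ("additive", "proportional"):
            raise ValueError("noise_model must be 'additive' or 'proportional'")
        if any(r.spec.row == self.control_row for r in self.rows):
            raise ValueError("control row cannot also carry a compound")
        rows_used = [r.spec.row for r in self.rows]
        if len(set(rows_used)) != len(rows_used):
            raise ValueError("duplicate compound rows")

    @property
    def window(self) -> float:
        return self.a_cc_true - self.a_cm_true


def single_row_truth(params: HillParams,
                     doses: tuple[float, float, float, float] = DEFAULT_DOSES,
                     noise_sd: float = 0.0, outlier_rate: float = 0.0,
                     seed: int = 0, compound_name: str = "compound-A",
                     **kwargs) -> SimulationTruth:
    """Convenience: one compound on row A, controls on row H."""
    spec = RowSpec(row="A", compound_name=compound_name, doses=doses)
    return SimulationTruth(rows=(SimRow(spec=spec, params=params),),
                           noise_sd=noise_sd, outlier_rate=outlier_rate,
                           seed=seed, **kwargs)


def simulate_plate(truth: SimulationTruth) -> tuple[Plate, dict]:
    """Generate one plate and its truth record.

    Wells are visited in a fixed row-major order so the same seed always
    yields a byte-identical plate.  The truth record carries every generating
    parameter plus the closed-form relative and absolute IC50 per row.
    """
    rng = np.random.default_rng(truth.seed)
    by_row = {r.spec.row: r for r in truth.rows}

    def noisy(mean: float) -> float:
        if truth.noise_sd == 0.0:
            return mean
        sd = truth.noise_sd if truth.noise_model == "additive" \
            else truth.noise_sd * abs(mean)
        return float(mean + rng.normal(0.0, sd))

    wells: dict[tuple[str, int], WellValue] = {}
    for row in "ABCDEFGH":
        for col in range(1, N_COLS + 1):
            if row == truth.control_row:
                mean = truth.a_cc_true if col <= 9 else truth.a_cm_true
                role = "cell_control" if col <= 9 else "medium_control"
                value = noisy(mean)
            elif row in by_row:
                sim = by_row[row]
                ip_true = sim.params.predict(sim.spec.dose_for_column(col))
                mean = truth.a_cm_true + (1.0 - ip_true / 100.0) * truth.window
                value = noisy(mean)
                if truth.outlier_rate > 0 and rng.random() < truth.outlier_rate:
                    value = float(rng.uniform(0.0, 2.0 * truth.a_cc_true))
                role = "treated"
            else:
                value, role = 0.0, "unused"
            wells[(row, col)] = WellValue(row=row, column=col,
                                          absorbance=max(0.0, value), role=role)

    plate = Plate(wells=wells, label=f"simulated(seed={truth.seed})",
                  source_path="<simulated>")

    record = {
        "seed": truth.seed,
        "control_row": truth.control_row,
        "a_cc_true": truth.a_cc_true,
        "a_cm_true": truth.a_cm_true,
        "noise_sd": truth.noise_sd,
        "noise_model": truth.noise_model,
        "outlier_rate": truth.outlier_rate,
        "rows": [
            {
                "spec": r.spec.to_dict(),
                "params": r.params.to_dict(),
                "relative_ic50": r.params.k,
                "absolute_ic50": hill_absolute_ic50(r.params),
            }
            for r in truth.rows
        ],
    }
    return plate, record


def truth_from_dict(d: dict) -> SimulationTruth:
    """Rebuild a :class:`SimulationTruth` from a YAML/JSON mapping."""
    rows = tuple(
        SimRow(spec=RowSpec.from_dict(r["spec"]),
               params=HillParams(**r["params"]))
        for r in d["rows"]
    )
    return SimulationTruth(
        rows=rows,
        control_row=d.get("control_row", "H"),
        a_cc_true=d.get("a_cc_true", DEFAULT_A_CC),
        a_cm_true=d.get("a_cm_true", DEFAULT_A_CM),
        noise_sd=d.get("noise_sd", 0.0),
        outlier_rate=d.get("outlier_rate", 0.0),
        seed=d.get("seed", 0),
        noise_model=d.get("noise_model", "additive"),
    )


def truth_record_json(record: dict) -> str:
    return json.dumps(record, indent=2, sort_keys=True)
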