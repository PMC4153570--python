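"""Full-plate analysis orchestration and report rendering.

:func:`analyze_plate` runs the whole pipeline — control statistics, per-row
dose-response tables, the selected IC50 estimator, and bootstrap CIs for the
regression methods — and assembles an :class:`AnalysisReport`.  A refusal on
one compound never aborts the others; only degenerate controls (or an invalid
configuration) abort the analysis.

The canonical report format is JSON: it embeds the full plate block (current
values, originals of overridden wells, discards, the edit log) and the echoed
configuration, so the analysis can be re-run exactly from the report alone.
A plain-text rendering mirrors the printed-report inventory — metadata, IC50s
with type/CI/goodness of fit, per-dose means and SDs, inhibition percentages,
control values, the raw plate with edit marks, and the absorbance-ratio table
(each well divided by the cell-control mean, the quick visual-assessment
quantity).  Dose-response plots show individual points, the fitted curve,
and the IC50 marker with its inhibition-level line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import estimators, inhibition, plate_io, uncertainty
from .estimators import (HillParams, Ic50Estimate, TransformSpec, linear_ic50,
                         nonlinear_ic50, transform, two_point_ic50)
from .inhibition import (ControlStats, DoseResponseTable, RowSpec,
                         build_dose_response, control_stats)
from .plate_io import N_COLS, ROWS, Plate
from .uncertainty import BootstrapConfig, BootstrapResult, bootstrap_ci


class ConfigError(ValueError):
    """Invalid analysis configuration; message lists every violation."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to analyze one plate.

    ``ic50_type`` has no default on purpose: whether the regression methods
    report absolute or relative IC50 is a scientific choice the user must
    state explicitly.  The two-point method is inherently absolute.
    """

    control_row: str
    row_specs: tuple[RowSpec, ...]
    ic50_type: str
    method: str = "nonlinear"
    transforms: TransformSpec = field(default_factory=TransformSpec)
    band: tuple[float, float] = estimators.DEFAULT_BAND
    discard_outliers: bool = False
    outlier_k: float = inhibition.DEFAULT_OUTLIER_K
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    display_digits: int = 2
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if self.control_row not in ROWS:
            problems.append(f"control_row {self.control_row!r} is not A-H")
        rows = [s.row for s in self.row_specs]
        if self.control_row in rows:
            problems.append(f"control_row {self.control_row} also listed in row_specs")
        if len(set(rows)) != len(rows):
            problems.append("duplicate rows in row_specs")
        if not self.row_specs:
            problems.append("row_specs is empty")
        if self.method not in estimators.METHODS:
            problems.append(f"unknown method {self.method!r}")
        if self.ic50_type not in estimators.IC50_TYPES:
            problems.append(f"unknown ic50_type {self.ic50_type!r}")
        if self.method == "two_point" and self.ic50_type != "absolute":
            problems.append("two_point method can only estimate absolute IC50")
        lo, hi = self.band
        if not 0 <= lo < 50 < hi <= 100:
            problems.append(f"band {self.band} must satisfy 0 <= low < 50 < high <= 100")
        if self.outlier_k <= 0:
            problems.append("outlier_k must be positive")
        if self.display_digits < 0:
            problems.append("display_digits must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        return {
            "control_row": self.control_row,
            "row_specs": [s.to_dict() for s in self.row_specs],
            "ic50_type": self.ic50_type,
            "method": self.method,
            "transforms": self.transforms.to_dict(),
            "band": list(self.band),
            "discard_outliers": self.discard_outliers,
            "outlier_k": self.outlier_k,
            "bootstrap": self.bootstrap.to_dict(),
            "display_digits": self.display_digits,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        if "ic50_type" not in d:
            raise ConfigError("ic50_type must be stated explicitly (absolute or relative)")
        if "control_row" not in d or "row_specs" not in d:
            raise ConfigError("config requires control_row and row_specs")
        tf = d.get("transforms", {})
        bs = d.get("bootstrap", {})
        return cls(
            control_row=d["control_row"],
            row_specs=tuple(RowSpec.from_dict(s) for s in d["row_specs"]),
            ic50_type=d["ic50_type"],
            method=d.get("method", "nonlinear"),
            transforms=TransformSpec(x=tf.get("x", "log10"), y=tf.get("y", "linear")),
            band=tuple(d.get("band", list(estimators.DEFAULT_BAND))),
            discard_outliers=d.get("discard_outliers", False),
            outlier_k=d.get("outlier_k", inhibition.DEFAULT_OUTLIER_K),
            bootstrap=BootstrapConfig(
                n_replicates=bs.get("n_replicates", uncertainty.DEFAULT_B),
                seed=bs.get("seed", 0),
                percentiles=tuple(bs.get("percentiles", (2.5, 97.5))),
                failure_tolerance=bs.get("failure_tolerance",
                                         uncertainty.DEFAULT_FAILURE_TOLERANCE),
            ),
            display_digits=d.get("display_digits", 2),
            metadata=dict(d.get("metadata", {})),
        )


@dataclass
class CompoundResult:
    """One compound's dose-response table, estimate and CI bookkeeping."""

    spec: RowSpec
    table: DoseResponseTable
    estimate: Ic50Estimate
    bootstrap: BootstrapResult | None = None

    def to_dict(self) -> dict:
        return {"spec": self.spec.to_dict(), "table": self.table.to_dict(),
                "estimate": self.estimate.to_dict(),
                "bootstrap": self.bootstrap.to_dict() if self.bootstrap else None}


@dataclass
class AnalysisReport:
    """Everything the analysis produced, sufficient to re-run it exactly."""

    plate: Plate
    config: AnalysisConfig
    controls: ControlStats
    compounds: list[CompoundResult]

    def to_dict(self) -> dict:
        ratio = {}
        for r in ROWS:
            ratio[r] = [round(w.absorbance / self.controls.a_cc, 4)
                        for w in self.plate.iter_row(r)]
        return {
            "provenance": {"source_path": self.plate.source_path,
                           "source_timestamp": self.plate.source_timestamp,
                           "label": self.plate.label},
            "config": self.config.to_dict(),
            "controls": self.controls.to_dict(),
            "compounds": [c.to_dict() for c in self.compounds],
            "absorbance_ratio": ratio,
            "plate": self.plate.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _fit_and_extract_factory(config: AnalysisConfig):
    """Build the (points -> (ic50, fitted)) callable the bootstrap refits.

    For the linear method both the residuals and the pseudo-responses live in
    transformed-y space (the scale on which the line is actually fit), so
    resampled responses always stay in the model's domain; points arriving
    here are therefore (transformed dose, transformed IP).  For the nonlinear
    method residuals live on the raw percent-inhibition scale.
    """
    tf = config.transforms

    if config.method == "linear":
        def fit(points):
            tx = np.array([x for x, _ in points])
            ty = np.array([y for _, y in points])
            slope, intercept = np.polyfit(tx, ty, 1)
            if slope <= 0:
                return None, ty
            fitted = intercept + slope * tx
            if config.ic50_type == "absolute":
                target = transform(50.0, tf.y)
            else:
                # i_max is frozen at the base table's value by the caller
                target = fit.target_ty
            value = estimators.inverse_transform((target - intercept) / slope, tf.x)
            if not np.isfinite(value) or value <= 0:
                return None, fitted
            return float(value), fitted
        return fit

    # Replicate refits warm-start from the base fit and use a lighter
    # stopping rule; the base fit (first call) runs at full accuracy.
    fast = {"restarts": 0, "xatol": 1e-4, "fatol": 1e-4, "maxiter": 2000}

    def fit(points, _cache={}):
        table = DoseResponseTable.from_points(
            "bootstrap", [inhibition.InhibitionPoint(dose=d, ip=ip)
                          for d, ip in points])
        init = _cache.get("init")
        est = nonlinear_ic50(table, ic50_type=config.ic50_type, init=init,
                             fit_options=fast if init is not None else None)
        if est.refused:
            return None, np.zeros(len(points))
        params = HillParams(**est.extra["params"])
        _cache.setdefault("init", params)  # warm-start subsequent refits
        doses = np.array([d for d, _ in points])
        return est.value, params.predict(doses)
    return fit


def _estimate_row(table: DoseResponseTable, config: AnalysisConfig
                  ) -> tuple[Ic50Estimate, BootstrapResult | None]:
    if config.method == "two_point":
        return two_point_ic50(table, config.transforms, config.band), None

    if config.method == "linear":
        est = linear_ic50(table, config.transforms, config.ic50_type)
    else:
        est = nonlinear_ic50(table, ic50_type=config.ic50_type)
    if est.refused:
        return est, None

    fit = _fit_and_extract_factory(config)
    if config.method == "linear":
        pts = [(transform(d, config.transforms.x), transform(ip, config.transforms.y))
               for d, ip in estimators._linear_filter(table)]
        if config.ic50_type == "relative":
            fit.target_ty = transform(est.i_max / 2.0, config.transforms.y)
        X = np.column_stack([np.ones(len(pts)), [x for x, _ in pts]])
        q, _ = np.linalg.qr(X)
        leverages = (q ** 2).sum(axis=1)
    else:
        pts = [(p.dose, p.ip) for p in table.usable_points()]
        leverages = estimators.hill_leverages(
            [d for d, _ in pts], HillParams(**est.extra["params"]))

    result = bootstrap_ci(pts, fit, config.bootstrap, leverages=leverages)
    if result is not None:
        est = replace(est, ci_95=(result.low, result.high))
    return est, result


def analyze_plate(plate: Plate, config: AnalysisConfig) -> AnalysisReport:
    """Run the full analysis.

    Raises :class:`ConfigError` on an invalid configuration and
    :class:`~platec50.inhibition.DegenerateControlsError` (or
    ``InsufficientControlsError``) when the control row cannot anchor the
    0/100% scale; any per-compound problem becomes a refusal in that
    compound's estimate instead of an exception.
    """
    config.validate()

    plate = Plate.from_dict(plate.to_dict())
    for col in range(1, N_COLS + 1):
        w = plate.well(config.control_row, col)
        w.role = "cell_control" if col <= inhibition.N_CELL_CONTROL else "medium_control"
    for spec in config.row_specs:
        for w in plate.iter_row(spec.row):
            w.role = "treated"

    controls = control_stats(plate, config.control_row)

    compounds = []
    for spec in config.row_specs:
        try:
            table = build_dose_response(
                plate, spec, controls,
                discard_outliers=config.discard_outliers,
                outlier_k=config.outlier_k)
            estimate, boot = _estimate_row(table, config)
        except inhibition.AnalysisError as err:
            table = DoseResponseTable(compound_name=spec.compound_name,
                                      points=[], triplicates=[], row=spec.row,
                                      units=spec.units)
            estimate = Ic50Estimate(
                method=config.method,
                ic50_type="absolute" if config.method == "two_point" else config.ic50_type,
                refusal_reason=str(err))
            boot = None
        compounds.append(CompoundResult(spec=spec, table=table,
                                        estimate=estimate, bootstrap=boot))

    return AnalysisReport(plate=plate, config=config, controls=controls,
                          compounds=compounds)


def restore_from_report(report_dict: dict) -> tuple[Plate, AnalysisConfig]:
    """Rebuild the plate and configuration embedded in a JSON report.

    Together with :func:`analyze_plate` this realizes the restore guarantee:
    the report alone suffices to repeat the analysis exactly.
    """
    return (Plate.from_dict(report_dict["plate"]),
            AnalysisConfig.from_dict(report_dict["config"]))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt(value, digits: int) -> str:
    if value is None:
        return "-"
    return f"{value:.{digits}f}"


def render_text(report: AnalysisReport) -> str:
    """Plain-text report mirroring the printed-report inventory."""
    cfg = report.config
    d = cfg.display_digits
    lines: list[str] = []
    push = lines.append

    push("=" * 72)
    push("PLATE IC50 ANALYSIS REPORT")
    push("=" * 72)
    for key, val in cfg.metadata.items():
        push(f"{key}: {val}")
    push(f"source file: {report.plate.source_path or '-'}")
    push(f"file date/time: {report.plate.source_timestamp or '-'}")
    push(f"method: {cfg.method}   IC50 type: {cfg.ic50_type}   "
         f"x: {cfg.transforms.x}   y: {cfg.transforms.y}")
    push(f"outlier discard: {'on' if cfg.discard_outliers else 'off'} "
         f"(k = {cfg.outlier_k:g} SD)   two-point band: "
         f"{cfg.band[0]:g}-{cfg.band[1]:g}%")
    c = report.controls
    push("")
    push(f"controls (row {cfg.control_row}): "
         f"A_cc = {c.a_cc:.4f} +/- {c.sd_cc:.4f} (n={c.n_cc}), "
         f"A_cm = {c.a_cm:.4f} +/- {c.sd_cm:.4f} (n={c.n_cm})")

    for comp in report.compounds:
        est = comp.estimate
        push("")
        push("-" * 72)
        push(f"compound: {comp.spec.compound_name} (row {comp.spec.row}, "
             f"doses in {comp.spec.units})")
        push(f"{'dose':>12} {'mean OD':>10} {'SD OD':>10} {'mean IP%':>10} "
             f"{'n':>3} {'flag':>6}")
        for t in comp.table.triplicates:
            flag = "0/100" if t.flag_0_or_100 else ""
            push(f"{t.dose:>12g} {_fmt(t.mean_od, 4):>10} {_fmt(t.sd_od, 4):>10} "
                 f"{_fmt(t.mean_ip, d):>10} {t.n_used:>3} {flag:>6}")
        pts = "  ".join(
            f"{p.well[0]}{p.well[1]}={p.ip:.{d}f}%"
            + ("[discarded]" if p.discarded else "")
            + ("[outlier]" if p.outlier else "")
            for p in comp.table.points if p.well)
        if pts:
            push(f"individual IP: {pts}")
        if est.refused:
            push(f"IC50 ({est.ic50_type}, {est.method}): "
                 f"NOT CALCULATED - {est.refusal_reason}")
        else:
            line = (f"IC50 ({est.ic50_type}, {est.method}): "
                    f"{est.value:.{d}f} {comp.spec.units}")
            if est.ci_95 is not None:
                line += f"   95% CI [{est.ci_95[0]:.{d}f}, {est.ci_95[1]:.{d}f}]"
            if est.gof is not None:
                name = "R^2" if est.method == "nonlinear" else "r^2"
                line += f"   {name} = {est.gof:.4f}"
            if est.i_max is not None:
                line += f"   I_max = {est.i_max:.{d}f}%"
            push(line)
            if comp.bootstrap is not None:
                push(f"bootstrap: {comp.bootstrap.n_success} ok, "
                     f"{comp.bootstrap.n_failed} failed refits")

    push("")
    push("-" * 72)
    push("absorbance / A_cc ratio table:")
    for r in ROWS:
        vals = " ".join(f"{w.absorbance / c.a_cc:6.3f}"
                        for w in report.plate.iter_row(r))
        push(f"  {r} {vals}")

    push("")
    push("raw plate data (current values; edits listed below):")
    for line in plate_io.write_plate_grid(report.plate).rstrip("\n").splitlines():
        push(f"  {line}")
    edited = [w for w in report.plate.wells.values()
              if w.original_absorbance is not None or w.discarded]
    for w in sorted(edited, key=lambda w: (w.row, w.column)):
        marks = []
        if w.original_absorbance is not None:
            marks.append(f"changed from {w.original_absorbance!r} to {w.absorbance!r}")
        if w.discarded:
            marks.append("discarded")
        push(f"  {w.row}{w.column}: " + "; ".join(marks))
    if report.plate.edits:
        push("edit log:")
        for e in report.plate.edits:
            detail = f" {e.get('old_value')!r} -> {e.get('new_value')!r}" \
                if e["action"] == "override" else ""
            push(f"  {e['row']}{e['column']}: {e['action']}{detail}")
    push("=" * 72)
    return "\n".join(lines) + "\n"


def render_plots(report: AnalysisReport, out_dir) -> list[str]:
    """One dose-response figure per compound; returns the file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for comp in report.compounds:
        est = comp.estimate
        fig, ax = plt.subplots(figsize=(5.5, 4))
        used = [p for p in comp.table.points if not p.discarded]
        if used:
            ax.scatter([p.dose for p in used], [p.ip for p in used],
                       color="black", s=18, zorder=3, label="wells")
        dropped = [p for p in comp.table.points if p.discarded]
        if dropped:
            ax.scatter([p.dose for p in dropped], [p.ip for p in dropped],
                       color="grey", marker="x", s=24, label="discarded")

        doses = [p.dose for p in comp.table.points] or [1.0]
        grid = np.geomspace(min(doses) / 3, max(doses) * 3, 200)
        if not est.refused and est.method == "nonlinear":
            params = HillParams(**est.extra["params"])
            ax.plot(grid, params.predict(grid), color="tab:blue", label="Hill fit")
        elif not est.refused and est.method == "linear":
            tf = report.config.transforms
            tgrid = transform(grid, tf.x)
            ty = est.extra["intercept"] + est.extra["slope"] * tgrid
            with np.errstate(over="ignore"):
                ax.plot(grid, estimators.inverse_transform(ty, tf.y),
                        color="tab:red", label="linear fit")
        if not est.refused:
            level = 50.0 if est.ic50_type == "absolute" else (est.i_max or 100) / 2
            ax.axhline(level, color="magenta", ls="--", lw=1)
            ax.plot([est.value], [level], "o", color="green", ms=8,
                    label=f"IC50 = {est.value:.3g}")
            title = (f"{comp.spec.compound_name}: {est.ic50_type} IC50 "
                     f"{est.value:.3g} {comp.spec.units} ({est.method})")
            if est.ci_95:
                title += f"\n95% CI [{est.ci_95[0]:.3g}, {est.ci_95[1]:.3g}]"
            if est.gof is not None:
                title += f", GoF {est.gof:.3f}"
        else:
            title = f"{comp.spec.compound_name}: {est.refusal_reason}"
        ax.set_xscale("log")
        ax.set_xlabel(f"dose ({comp.spec.units})")
        ax.set_ylabel("inhibition of proliferation (%)")
        ax.set_title(title, fontsize=9)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"{comp.spec.row}_{comp.spec.compound_name}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(str(path))
    return paths


def render_report(report: AnalysisReport, format: str = "json",
                  out_dir=None):
    """Render the report as ``"json"``, ``"text"`` or ``"plots"``."""
    if format == "json":
        return report.to_json()
    if format == "text":
        return render_text(report)
    if format == "plots":
        if out_dir is None:
            raise ValueError("plots rendering requires out_dir")
        return render_plots(report, out_dir)
    raise ValueError(f"unknown format {format!r}")
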