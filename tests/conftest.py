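import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from platec50 import (AnalysisConfig, BootstrapConfig, ControlStats,
                      HillParams, RowSpec, read_plate_grid, simulate_plate,
                      single_row_truth)

GRID_DOSES = (1000.0, 100.0, 10.0, 1.0)


def make_grid_text(values_by_row):
    """Build raw-grid text from {row_letter: [12 floats]}; missing rows 0.0."""
    lines = []
    for r in "ABCDEFGH":
        vals = values_by_row.get(r, [0.0] * 12)
        lines.append(f"{r} " + " ".join(repr(float(v)) for v in vals))
    return "\n".join(lines) + "\n"


@pytest.fixture
def controls():
    return ControlStats(a_cc=1.0, a_cm=0.1, sd_cc=0.0, sd_cm=0.0, n_cc=9, n_cm=3)


@pytest.fixture
def simple_plate():
    """Control row H (cells 1.0, medium 0.1); row A all at IP = 50%."""
    rows = {"H": [1.0] * 9 + [0.1] * 3, "A": [0.55] * 12}
    return read_plate_grid(make_grid_text(rows), label="simple")


@pytest.fixture
def row_a_spec():
    return RowSpec(row="A", compound_name="cmpd", doses=GRID_DOSES)


def noiseless_plate(i_max=80.0, h=1.0, k=10.0, doses=GRID_DOSES, seed=0):
    truth = single_row_truth(HillParams(i_max, h, k), doses=doses,
                             noise_sd=0.0, seed=seed)
    plate, record = simulate_plate(truth)
    return plate, truth, record


def quick_config(method="nonlinear", ic50_type="relative", n_boot=0, **kw):
    """Analysis config for the single-compound simulated plate; n_boot=0
    means a tiny bootstrap (still >=1 replicate) to keep unit tests fast."""
    return AnalysisConfig(
        control_row="H",
        row_specs=(RowSpec(row="A", compound_name="cmpd", doses=GRID_DOSES),),
        ic50_type=ic50_type, method=method,
        bootstrap=BootstrapConfig(n_replicates=max(1, n_boot), seed=42),
        **kw)
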