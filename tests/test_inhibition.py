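"""Control statistics, percent inhibition and triplicate handling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from platec50 import (ControlStats, DegenerateControlsError,
                      InsufficientControlsError, RowSpec, apply_edit,
                      build_dose_response, control_stats, detect_outliers,
                      percent_inhibition, read_plate_grid)

from conftest import make_grid_text

OUTLIER_BOUND = 2.0 / math.sqrt(3.0)  # max |z| reachable in a triplicate


class TestControlStats:
    def test_clean_controls(self, simple_plate):
        c = control_stats(simple_plate, "H")
        assert c.a_cc == pytest.approx(1.0)
        assert c.a_cm == pytest.approx(0.1)
        assert c.sd_cc == pytest.approx(0.0, abs=1e-15)
        assert c.sd_cm == pytest.approx(0.0, abs=1e-15)
        assert (c.n_cc, c.n_cm) == (9, 3)

    def test_discarded_control_excluded(self):
        rows = {"H": [1.0] * 8 + [0.2] + [0.1] * 3}
        plate = read_plate_grid(make_grid_text(rows))
        plate = apply_edit(plate, "H", 9, "discard")
        c = control_stats(plate, "H")
        assert c.a_cc == 1.0 and c.n_cc == 8

    def test_degenerate_controls_rejected(self):
        plate = read_plate_grid(make_grid_text({"H": [0.1] * 12}))
        with pytest.raises(DegenerateControlsError):
            control_stats(plate, "H")

    def test_too_few_controls_rejected(self, simple_plate):
        p = simple_plate
        for col in range(1, 9):
            p = apply_edit(p, "H", col, "discard")
        with pytest.raises(InsufficientControlsError):
            control_stats(p, "H")

    def test_sample_sd_denominator(self):
        # cells {0.9, 1.0, 1.1, 1.0 x6}: sample SD, not population SD
        rows = {"H": [0.9, 1.0, 1.1] + [1.0] * 6 + [0.1] * 3}
        c = control_stats(read_plate_grid(make_grid_text(rows)), "H")
        assert c.sd_cc == pytest.approx(np.std([0.9, 1.0, 1.1] + [1.0] * 6, ddof=1))


class TestPercentInhibition:
    def test_anchors(self, controls):
        assert percent_inhibition(controls.a_cc, controls) == 0.0
        assert percent_inhibition(controls.a_cm, controls) == 100.0

    def test_hand_computed_midpoint(self, controls):
        assert percent_inhibition(0.55, controls) == pytest.approx(50.0)

    def test_not_clamped(self, controls):
        assert percent_inhibition(1.3, controls) < 0.0
        assert percent_inhibition(0.01, controls) > 100.0

    @given(a_cc=st.floats(0.5, 3.0), a_cm=st.floats(0.01, 0.4),
           a_p=st.floats(0.0, 4.0),
           alpha=st.floats(0.1, 10.0), beta=st.floats(-0.05, 1.0))
    def test_affine_invariance(self, a_cc, a_cm, a_p, alpha, beta):
        """Rescaling every absorbance a -> alpha*a + beta leaves IP unchanged."""
        c1 = ControlStats(a_cc, a_cm, 0, 0, 9, 3)
        c2 = ControlStats(alpha * a_cc + beta, alpha * a_cm + beta, 0, 0, 9, 3)
        ip1 = percent_inhibition(a_p, c1)
        ip2 = percent_inhibition(alpha * a_p + beta, c2)
        assert ip2 == pytest.approx(ip1, abs=1e-9 * max(1, abs(ip1)))

    @given(st.floats(0.5, 3.0), st.floats(0.01, 0.4),
           st.floats(0.0, 4.0), st.floats(1e-6, 0.5))
    def test_strictly_decreasing_in_absorbance(self, a_cc, a_cm, a_p, step):
        c = ControlStats(a_cc, a_cm, 0, 0, 9, 3)
        assert percent_inhibition(a_p + step, c) < percent_inhibition(a_p, c)


class TestDetectOutliers:
    def test_zero_sd_flags_nothing(self):
        assert detect_outliers([0.5, 0.5, 0.5], k=1.0) == [False] * 3

    def test_gross_error_flagged_at_k1(self):
        # mean 2, SD sqrt(3): |4-2| = 2 > 1.732
        assert detect_outliers([1.0, 1.0, 4.0], k=1.0) == [False, False, True]

    def test_bound_makes_flagging_impossible(self):
        # max |z| in a triplicate is 2/sqrt(3) ~ 1.1547
        assert detect_outliers([1.0, 1.0, 4.0], k=1.2) == [False] * 3

    @given(st.lists(st.floats(0, 4, allow_nan=False), min_size=3, max_size=3),
           st.floats(OUTLIER_BOUND + 1e-9, 10.0))
    def test_no_triplicate_value_flagged_above_bound(self, values, k):
        assert not any(detect_outliers(values, k=k))


class TestBuildDoseResponse:
    def test_uniform_half_inhibition(self, simple_plate, row_a_spec, controls):
        table = build_dose_response(simple_plate, row_a_spec, controls)
        assert [p.ip for p in table.points] == pytest.approx([50.0] * 12)
        assert [t.mean_ip for t in table.triplicates] == pytest.approx([50.0] * 4)
        assert all(t.n_used == 3 for t in table.triplicates)

    def test_override_to_background_gives_full_inhibition(
            self, simple_plate, row_a_spec, controls):
        p = apply_edit(simple_plate, "A", 1, "override", controls.a_cm)
        table = build_dose_response(p, row_a_spec, controls)
        assert table.points[0].ip == pytest.approx(100.0)
        assert table.triplicates[0].mean_ip == pytest.approx((100 + 50 + 50) / 3)

    def test_zero_mean_ip_flagged(self, row_a_spec, controls):
        plate = read_plate_grid(make_grid_text(
            {"H": [1.0] * 9 + [0.1] * 3, "A": [1.0] * 12}))
        table = build_dose_response(plate, row_a_spec, controls)
        assert all(t.flag_0_or_100 for t in table.triplicates)

    def test_discarded_triplicate_is_empty_not_fatal(
            self, simple_plate, row_a_spec, controls):
        p = simple_plate
        for col in (1, 2, 3):
            p = apply_edit(p, "A", col, "discard")
        table = build_dose_response(p, row_a_spec, controls)
        assert table.triplicates[0].n_used == 0
        assert table.triplicates[0].mean_ip is None
        assert len(table.dose_means()) == 3

    def test_outlier_exclusion_only_when_enabled(self, row_a_spec, controls):
        rows = {"H": [1.0] * 9 + [0.1] * 3,
                "A": [0.55, 0.55, 0.95] + [0.55] * 9}
        plate = read_plate_grid(make_grid_text(rows))
        kept = build_dose_response(plate, row_a_spec, controls,
                                   discard_outliers=False, outlier_k=1.0)
        assert kept.points[2].outlier
        assert kept.triplicates[0].n_used == 3
        dropped = build_dose_response(plate, row_a_spec, controls,
                                      discard_outliers=True, outlier_k=1.0)
        assert dropped.triplicates[0].n_used == 2
        assert dropped.triplicates[0].mean_ip == pytest.approx(50.0)
        assert len(dropped.usable_points()) == 11


class TestRowSpec:
    @pytest.mark.parametrize("doses", [
        (1.0, 10.0, 100.0, 1000.0),   # ascending
        (100.0, 10.0, 10.0, 1.0),     # tie
        (100.0, 10.0, 1.0, -0.1),     # nonpositive
        (100.0, 10.0, 1.0),           # wrong count
    ])
    def test_invalid_dose_series_rejected(self, doses):
        with pytest.raises(ValueError):
            RowSpec(row="A", compound_name="x", doses=doses)

    def test_column_to_dose_mapping(self, row_a_spec):
        assert [row_a_spec.dose_for_column(c) for c in (1, 3, 4, 7, 10, 12)] == \
            [1000.0, 1000.0, 100.0, 10.0, 1.0, 1.0]
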