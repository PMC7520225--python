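"""Control-corrected proportional uptake from raw tracer signals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydroniche import isotope
from hydroniche.isotope import (
    ControlSummary,
    deuterium_excess,
    nitrogen_uptake_profile,
    proportional_uptake,
    summarize_controls,
)


def make_samples(rows, campaign="c1", channel="water"):
    """Rows of (species, growth_form, plot, depth, signal)."""
    recs = []
    for i, (sp, gf, plot, depth, val) in enumerate(rows):
        rec = {
            "sample_id": f"s{i}",
            "campaign": campaign,
            "plot_id": plot,
            "species": sp,
            "growth_form": gf,
            "injection_depth_cm": depth,
            "d2H_permil": np.nan,
            "d18O_permil": np.nan,
            "d15N_permil": np.nan,
        }
        if channel == "water":
            # choose d18O = 0 so that d_e = d2H - 10
            rec["d2H_permil"] = val + 10.0
            rec["d18O_permil"] = 0.0
        else:
            rec["d15N_permil"] = val
        recs.append(rec)
    return pd.DataFrame(recs)


class TestDeuteriumExcess:
    @pytest.mark.parametrize(
        "d2h,d18o,expected",
        [(0.0, 0.0, -10.0), (10.0, 0.0, 0.0), (-65.0, -8.0, -11.0)],
    )
    def test_formula(self, d2h, d18o, expected):
        assert deuterium_excess(d2h, d18o) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            deuterium_excess(np.nan, 0.0)
        with pytest.raises(ValueError):
            deuterium_excess(0.0, np.inf)

    def test_vectorized(self):
        out = deuterium_excess(np.array([0.0, 10.0]), np.array([0.0, 0.0]))
        np.testing.assert_allclose(out, [-10.0, 0.0])


class TestControlSummary:
    def test_printed_control_summary_threshold(self):
        # a -65 +/- 30 permil control population exceeds at -5
        s = ControlSummary(mean_permil=-65.0, sd_permil=30.0, n=100)
        assert s.exceedance_threshold_permil == pytest.approx(-5.0)

    def test_identical_controls(self):
        s = ControlSummary.from_values([-60.0, -60.0, -60.0])
        assert s.mean_permil == -60.0
        assert s.sd_permil == 0.0
        assert s.exceedance_threshold_permil == -60.0

    def test_two_point_sample_sd(self):
        s = ControlSummary.from_values([-90.0, -40.0])
        assert s.mean_permil == pytest.approx(-65.0)
        assert s.sd_permil == pytest.approx(35.3553, abs=1e-3)
        assert s.exceedance_threshold_permil == pytest.approx(5.7107, abs=1e-3)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ControlSummary.from_values([-60.0])

    def test_water_channel_reports_excess_and_raw(self):
        df = make_samples(
            [("a", "tree", "p1", "control", -60.0), ("a", "tree", "p2", "control", -70.0)]
        )
        excess, raw = summarize_controls(df, "water")
        assert excess.mean_permil == pytest.approx(-65.0)
        assert raw.mean_permil == pytest.approx(-55.0)  # d2H = d_e + 10 here


class TestProportionalUptake:
    def test_hand_worked_two_depth_profile(self):
        # plot means d_e {10 cm: 40, 50 cm: -40}, C = -60 -> 100/120, 20/120
        rows = [
            ("a", "tree", "p1", 10.0, 40.0),
            ("a", "tree", "p2", 50.0, -40.0),
        ]
        controls = ControlSummary(-60.0, 10.0, 10)
        res = proportional_uptake(make_samples(rows), controls)
        prof = res["species"]["a"]
        np.testing.assert_allclose(prof.proportions, [100 / 120, 20 / 120])

    def test_equal_enrichment_gives_uniform(self):
        rows = [("a", "tree", f"p{d}", d, 30.0) for d in (5.0, 10.0, 20.0)]
        res = proportional_uptake(make_samples(rows), ControlSummary(-60.0, 5.0, 5))
        np.testing.assert_allclose(res["species"]["a"].proportions, 1 / 3)

    def test_below_control_clamped_and_renormalized(self):
        rows = [
            ("a", "grass", "p1", 10.0, 40.0),
            ("a", "grass", "p2", 50.0, -80.0),  # below C = -60
        ]
        res = proportional_uptake(make_samples(rows), ControlSummary(-60.0, 5.0, 5))
        prof = res["species"]["a"]
        np.testing.assert_allclose(prof.proportions, [1.0, 0.0])
        assert prof.clamped_mass > 0

    def test_no_uptake_raises(self):
        rows = [("a", "tree", "p1", 10.0, -80.0), ("a", "tree", "p2", 50.0, -90.0)]
        with pytest.raises(ValueError, match="no detectable tracer uptake"):
            proportional_uptake(make_samples(rows), ControlSummary(-60.0, 5.0, 5))

    def test_missing_depth_named_in_error(self):
        rows = [("a", "tree", "p1", 10.0, 40.0), ("a", "tree", "p2", 50.0, 20.0)]
        with pytest.raises(ValueError, match="100"):
            proportional_uptake(
                make_samples(rows), ControlSummary(-60.0, 5.0, 5),
                depth_set=[10.0, 50.0, 100.0],
            )

    def test_subreplicates_averaged_within_plot(self):
        rows = [
            ("a", "tree", "p1", 10.0, 30.0),
            ("a", "tree", "p1", 10.0, 50.0),  # plot mean 40
            ("a", "tree", "p2", 50.0, -40.0),
        ]
        res = proportional_uptake(make_samples(rows), ControlSummary(-60.0, 5.0, 5))
        np.testing.assert_allclose(res["species"]["a"].proportions, [100 / 120, 20 / 120])

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_and_scale_invariance(self, shift, scale):
        """Adding a constant to all signals and the control, or scaling all
        signal-minus-control differences, leaves proportions unchanged."""
        base = [
            ("a", "tree", "p1", 10.0, 40.0),
            ("a", "tree", "p2", 20.0, 10.0),
            ("a", "tree", "p3", 50.0, -30.0),
        ]
        c0 = -60.0
        ref = proportional_uptake(
            make_samples(base), ControlSummary(c0, 5.0, 5)
        )["species"]["a"].proportions
        shifted = [(s, g, p, d, v + shift) for s, g, p, d, v in base]
        out1 = proportional_uptake(
            make_samples(shifted), ControlSummary(c0 + shift, 5.0, 5)
        )["species"]["a"].proportions
        scaled = [(s, g, p, d, c0 + scale * (v - c0)) for s, g, p, d, v in base]
        out2 = proportional_uptake(
            make_samples(scaled), ControlSummary(c0, 5.0, 5)
        )["species"]["a"].proportions
        np.testing.assert_allclose(out1, ref, atol=1e-9)
        np.testing.assert_allclose(out2, ref, atol=1e-9)

    def test_profiles_sum_to_one_and_bounded(self, campaign_replicates):
        for _, group in campaign_replicates.groupby(["growth_form", "depth_cm"]):
            assert ((group["proportion"] >= 0) & (group["proportion"] <= 1)).all()


class TestNitrogenChannel:
    def test_printed_control_values_hand_worked(self):
        # d15N plot means {10: 103.4, 20: 53.4}, control mean 3.4
        rows = [
            ("a", "grass", "p1", 10.0, 103.4),
            ("a", "grass", "p2", 20.0, 53.4),
        ]
        res = nitrogen_uptake_profile(
            make_samples(rows, channel="nitrogen"), ControlSummary(3.4, 2.1, 4)
        )
        np.testing.assert_allclose(
            res["species"]["a"].proportions, [100 / 150, 50 / 150], atol=1e-12
        )

    def test_single_depth_is_unity(self):
        rows = [("a", "grass", "p1", 10.0, 50.0)]
        res = nitrogen_uptake_profile(
            make_samples(rows, channel="nitrogen"), ControlSummary(3.4, 2.1, 4)
        )
        np.testing.assert_allclose(res["species"]["a"].proportions, [1.0])
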