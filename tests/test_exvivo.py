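"""Ussing-chamber conductivity chain: velocity fit, Darcy reduction, correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import ols_oracle
from tumorperf.exvivo import (
    MU_IF,
    LeakSuspectWarning,
    TemperatureRangeWarning,
    UssingMeasurement,
    conductivity_from_track,
    estimate_bubble_velocity,
    nominal_conductivity,
    pbs_viscosity,
    process_tracks,
    viscosity_correct,
)
from tumorperf.synthetic import generate_bubble_track


def chamber(**kw):
    base = dict(
        sample_id="t", times=[0.0, 600.0, 1200.0], positions=[0.0, 6e-5, 1.2e-4]
    )
    base.update(kw)
    return UssingMeasurement(**base)


class TestBubbleVelocity:
    def test_exact_line_recovers_slope(self):
        v, se = estimate_bubble_velocity([0, 600, 1200], [0, 6e-5, 1.2e-4])
        assert v == pytest.approx(1.0e-7)
        assert se == pytest.approx(0.0, abs=1e-18)

    def test_stationary_bubble_gives_zero(self):
        v, _ = estimate_bubble_velocity([0, 600, 1200], [0.0, 0.0, 0.0])
        assert v == 0.0

    def test_matches_closed_form_least_squares(self):
        t = [0.0, 600.0, 1200.0, 1800.0]
        x = [0.0, 5.5e-5, 1.25e-4, 1.79e-4]
        slope, _, _, se_slope = ols_oracle(t, x)
        v, se = estimate_bubble_velocity(t, x)
        assert v == pytest.approx(slope, rel=1e-12)
        assert se == pytest.approx(se_slope, rel=1e-9)

    @pytest.mark.parametrize(
        "times,positions",
        [([0, 600], [0, 1e-5]), ([0, 600, 600], [0, 1e-5, 2e-5])],
    )
    def test_rejects_short_or_nonmonotone_tracks(self, times, positions):
        with pytest.raises(ValueError):
            estimate_bubble_velocity(times, positions)


class TestNominalConductivity:
    def test_table_defaults_magnitude(self):
        # independent arithmetic: (b/d)^2 * w * v / (rho g h)
        m = chamber()
        expected = (1e-3 / 5.05e-3) ** 2 * 1e-3 * 1e-7 / (998.0 * 9.81 * 0.16)
        assert expected == pytest.approx(2.50e-15, rel=2e-3)
        assert nominal_conductivity(m, 1e-7) == pytest.approx(expected, rel=1e-12)

    def test_zero_velocity_gives_zero(self):
        assert nominal_conductivity(chamber(), 0.0) == 0.0

    def test_tube_and_tissue_diameter_scaling(self):
        base = nominal_conductivity(chamber(), 1e-7)
        assert nominal_conductivity(chamber(b=2e-3), 1e-7) == pytest.approx(4 * base)
        assert nominal_conductivity(chamber(d=2 * 5.05e-3), 1e-7) == pytest.approx(
            base / 4
        )

    @given(factor=st.floats(0.25, 4.0))
    def test_joint_bore_scaling_invariance(self, factor):
        m = chamber(b=1e-3 * factor, d=5.05e-3 * factor)
        assert nominal_conductivity(m, 1e-7) == pytest.approx(
            nominal_conductivity(chamber(), 1e-7), rel=1e-9
        )

    @given(v=st.floats(1e-9, 1e-6), w=st.floats(5e-4, 2e-3))
    def test_linear_in_velocity_and_thickness(self, v, w):
        m = chamber(w=w)
        k1 = nominal_conductivity(m, v)
        assert nominal_conductivity(m, 2 * v) == pytest.approx(2 * k1, rel=1e-9)
        m2 = chamber(w=2 * w)
        assert nominal_conductivity(m2, v) == pytest.approx(2 * k1, rel=1e-9)

    def test_negative_velocity_flags_leak(self):
        with pytest.warns(LeakSuspectWarning):
            k = nominal_conductivity(chamber(), -1e-7)
        assert k < 0


class TestViscosity:
    @pytest.mark.parametrize(
        "temp,expected", [(18.0, 1.1e-3), (25.0, 8.9e-4), (21.5, 9.95e-4)]
    )
    def test_anchors_and_midpoint(self, temp, expected):
        assert pbs_viscosity(temp) == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_warns_and_extrapolates(self):
        with pytest.warns(TemperatureRangeWarning):
            mu = pbs_viscosity(30.0)
        assert mu < 8.9e-4

    def test_correction_formula(self):
        assert viscosity_correct(1e-14, 8.9e-4, 3.5e-3) == pytest.approx(
            1e-14 * 8.9e-4 / 3.5e-3, rel=1e-12
        )
        assert viscosity_correct(1e-14, 8.9e-4, 3.5e-3) == pytest.approx(
            2.543e-15, rel=1e-3
        )
        assert viscosity_correct(1e-14, 1e-3, 1e-3) == 1e-14
        assert viscosity_correct(0.0, 1e-3, 3.5e-3) == 0.0

    def test_zero_viscosity_rejected(self):
        with pytest.raises(ValueError):
            viscosity_correct(1e-14, 8.9e-4, 0.0)


class TestFullChain:
    def test_noiseless_roundtrip_is_exact(self):
        K_true = 7.3e-15
        m = generate_bubble_track(K_true, noise_sd_position=0.0, seed=42)
        res = conductivity_from_track(m)
        assert res.K_corrected == pytest.approx(K_true, rel=1e-12)
        assert not res.leak_suspect

    def test_sane_envelope_for_measured_velocities(self):
        # velocities spanning the instrument range land inside a plausible
        # conductivity envelope around the measured 1e-15..1e-14 decade
        # (the chain maps 1e-7 m/s to ~2.5e-15, scaling linearly)
        Ks = []
        for v in (1e-9, 1e-8, 1e-7, 1e-6):
            m = chamber()
            K = viscosity_correct(
                nominal_conductivity(m, v), pbs_viscosity(m.temperature_C), MU_IF
            )
            assert 1e-18 <= K <= 1e-12
            Ks.append(K)
        assert Ks == sorted(Ks)
        assert Ks[2] == pytest.approx(2.5e-15 * 9.95e-4 / 3.5e-3, rel=2e-3)

    def test_invariant_correction_ratio(self):
        m = generate_bubble_track(5e-15, noise_sd_position=1e-6, seed=0)
        res = conductivity_from_track(m)
        assert res.K_corrected == pytest.approx(
            res.K_nominal * res.mu_pbs / res.mu_if, rel=1e-14
        )

    def test_process_tracks_batches_by_sample(self):
        rows = []
        for sid, K in (("A", 3e-15), ("B", 1e-14)):
            m = generate_bubble_track(K, noise_sd_position=0.0, seed=1, sample_id=sid)
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "time_s": m.times,
                        "position_m": m.positions,
                        "temperature_C": m.temperature_C,
                    }
                )
            )
        out = process_tracks(pd.concat(rows, ignore_index=True))
        assert list(out["sample_id"]) == ["A", "B"]
        assert out["K_corrected"].to_numpy() == pytest.approx([3e-15, 1e-14], rel=1e-10)

    def test_measurement_validation(self):
        with pytest.raises(ValueError):
            chamber(times=[0.0, 600.0], positions=[0.0, 1e-5])
        with pytest.raises(ValueError):
            chamber(h=0.0)
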