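"""Polymerase-chain ODE simulator: closed forms, backends, and profiles."""

import numpy as np
import pytest

from polkin.simulate import (
    PolymeraseField,
    SimParams,
    front_window,
    integrate,
    lfc_profile,
    simulate_experiment,
    steady_state,
)


class TestIntegrate:
    def test_equilibrium_is_uniform_without_processivity_loss(self):
        params = SimParams(p=2, e=3, d=0.0, L=80)
        st = integrate(params, PolymeraseField.zeros(80), "no4sU", 1000)
        assert np.allclose(st.o, 1.0 / (2 * 3), rtol=1e-8)

    def test_equilibrium_matches_geometric_closed_form(self):
        params = SimParams(p=2, e=3, d=0.02, L=80)
        st = integrate(params, PolymeraseField.zeros(80), "no4sU", 1000)
        cf = steady_state(params)
        assert np.max(np.abs(st.o - cf) / cf) < 1e-6
        # successive-window ratio 1/(1+d)
        assert np.allclose(st.o[1:] / st.o[:-1], 1 / 1.02, rtol=1e-6)

    def test_flux_conservation_at_equilibrium(self):
        params = SimParams(p=2, e=3, d=0.0, L=40)
        st = integrate(params, PolymeraseField.zeros(40), "no4sU", 1000)
        assert np.isclose(params.e * st.o[-1], 1.0 / params.p, rtol=1e-8)

    def test_zero_duration_is_identity(self):
        params = SimParams(p=2, e=3, d=0.0, L=10)
        st0 = PolymeraseField(np.arange(10.0), np.ones(10), t=5.0)
        st = integrate(params, st0, "4sU", 0)
        assert np.array_equal(st.o, st0.o) and np.array_equal(st.b, st0.b)

    @pytest.mark.parametrize("bad", [-1.0, -0.001])
    def test_negative_duration_rejected(self, bad):
        params = SimParams(p=2, e=3, d=0.0, L=10)
        with pytest.raises(ValueError):
            integrate(params, PolymeraseField.zeros(10), "no4sU", bad)

    def test_nonfinite_state_rejected(self):
        params = SimParams(p=2, e=3, d=0.0, L=10)
        st = PolymeraseField.zeros(10)
        st.o[3] = np.nan
        with pytest.raises(ValueError):
            integrate(params, st, "no4sU", 1.0)

    @pytest.mark.parametrize("mode", ["no4sU", "4sU"])
    def test_analytic_and_expm_backends_agree(self, mode):
        params = SimParams(p=2, e=3, d=0.02, L=25)
        start = integrate(params, PolymeraseField.zeros(25), "no4sU", 40)
        a = integrate(params, start, mode, 7.0, backend="analytic")
        b = integrate(params, start, mode, 7.0, backend="expm")
        assert np.allclose(a.o, b.o, rtol=1e-8, atol=1e-12)
        assert np.allclose(a.b, b.b, rtol=1e-8, atol=1e-12)

    def test_total_occupancy_continuous_across_mode_switch(self):
        params = SimParams(p=2, e=3, d=0.01, L=30)
        st = integrate(params, PolymeraseField.zeros(30), "no4sU", 500)
        before = st.total.copy()
        st2 = integrate(params, st, "4sU", 1e-6)
        assert np.allclose(st2.total, before, rtol=1e-6)


class TestSimulateExperiment:
    def test_pulse_foursu_profile_non_increasing(self):
        prof = simulate_experiment(SimParams(p=2, e=3, d=0.0, L=80), "pulse", 15)
        assert np.all(np.diff(prof.foursu) <= 1e-12)
        # first element is the total labeled mass
        assert np.isclose(prof.foursu[0], prof.foursu[0])

    def test_drb_front_tracks_advection_distance(self):
        for e, t in [(3.0, 20.0), (1.5, 20.0), (3.0, 10.0)]:
            prof = simulate_experiment(SimParams(p=2, e=e, d=0.0, L=80), "drb", t)
            assert abs(front_window(prof.chip) - e * t) <= 1.0

    def test_drb_rejects_nonpositive_label_time(self):
        with pytest.raises(ValueError):
            simulate_experiment(SimParams(p=2, e=3, d=0.0, L=80), "drb", 0)

    def test_equilibrium_chip_ratio_constant_in_log2(self):
        prof_d = simulate_experiment(SimParams(p=2, e=3, d=0.02, L=80), "pulse", 15)
        prof_0 = simulate_experiment(SimParams(p=2, e=3, d=0.0, L=80), "pulse", 15)
        ratio = np.log2(prof_d.chip / prof_0.chip)
        slopes = np.diff(ratio)
        assert np.allclose(slopes, -np.log2(1.02), atol=1e-6)

    def test_fine_discretization_bins_back_to_coarse_totals(self):
        fine = simulate_experiment(SimParams(p=2, e=3, d=0.0, L=80, w=0.25), "drb", 20)
        binned = fine.binned(1.0)
        assert len(binned.chip) == 80
        # mean aggregation conserves total polymerase mass
        assert np.isclose(binned.chip.sum() * 4, fine.chip.sum())

    def test_mode_history_records_protocol(self):
        prof = simulate_experiment(SimParams(p=2, e=3, d=0.0, L=80), "pulse", 15)
        assert prof.mode_history == [("no4sU", 1000.0), ("4sU", 15.0)]


class TestLfcProfile:
    def test_identical_profiles_give_zeros(self):
        x = np.linspace(1, 5, 20)
        assert np.allclose(lfc_profile(x, x), 0.0)

    def test_unprocessive_vs_unperturbed_chip_is_linear(self):
        chip_d = simulate_experiment(SimParams(p=2, e=3, d=0.02, L=80), "pulse").chip
        chip_0 = simulate_experiment(SimParams(p=2, e=3, d=0.0, L=80), "pulse").chip
        lfc = lfc_profile(chip_d, chip_0)
        assert np.allclose(np.diff(lfc), -np.log2(1.02), atol=1e-6)

    def test_slow_pulse_lfc_is_flat_occupancy_scaling(self):
        """Once the label saturates the gene, halving e doubles occupancy
        uniformly, so the pulse suffix-sum LFC is constant log2(2).

        The slow-elongation signature instead shows in the DRB channel
        (front at e*t)."""
        f_slow = simulate_experiment(SimParams(p=2, e=1.5, d=0.0, L=80), "pulse").foursu
        f_ref = simulate_experiment(SimParams(p=2, e=3.0, d=0.0, L=80), "pulse").foursu
        lfc = lfc_profile(f_slow, f_ref)
        assert np.allclose(lfc, 1.0, atol=1e-6)
        drb_slow = simulate_experiment(SimParams(p=2, e=1.5, d=0.0, L=80), "drb", 20)
        drb_ref = simulate_experiment(SimParams(p=2, e=3.0, d=0.0, L=80), "drb", 20)
        assert front_window(drb_slow.chip) < front_window(drb_ref.chip)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lfc_profile(np.ones(5), np.ones(6))
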