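import numpy as np
import pytest

from astrofilter.gchi import rhs
from astrofilter.network import AstrocyteNetwork
from astrofilter.simulate import (find_rest_state, flux_decomposition, simulate,
                                  star_network)
from astrofilter.synapse import make_fixed_duration_protocol
from astrofilter.sweeps import single_frequency_run


def two_disconnected(stim_first=True):
    return AstrocyteNetwork((0, 1), np.array([[0.0, 0.0], [100.0, 0.0]]),
                            np.empty((0, 2), int),
                            np.array([stim_first, False]))


class TestRestState:
    def test_rest_is_a_fixed_point(self, gchi, rest):
        dy = rhs(rest.as_array(), np.zeros(1), np.empty((0, 2), int), gchi, None)
        assert np.max(np.abs(dy)) < 1e-9

    def test_rest_h_in_interior(self, rest):
        assert 0.0 < rest.h < 1.0

    def test_rest_independent_of_start(self, gchi):
        a = find_rest_state(gchi, y0=(0.05, 0.9, 0.05))
        b = find_rest_state(gchi, y0=(0.3, 0.4, 0.4))
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-6)


class TestSimulate:
    def test_empty_protocol_stays_at_rest(self, gchi, gjc, tm, rest):
        prot = make_fixed_duration_protocol([], train_duration=30.0)
        tr = simulate(star_network(0), prot, gchi, gjc, tm, pre_time=20.0,
                      post_time=0.0, rest=rest)
        assert np.max(np.abs(tr.C[0] - rest.C)) < 1e-6
        assert np.all(tr.G == 0)

    def test_disconnected_unstimulated_cell_remains_at_rest(self, gchi, gjc, tm, rest):
        tr = single_frequency_run(two_disconnected(), 10.0, gchi, gjc, tm,
                                  train_s=20.0, pre_s=5.0, rest=rest)
        assert np.max(np.abs(tr.C[1] - rest.C)) < 1e-6
        assert tr.C[0].max() > 10 * rest.C   # the stimulated one responds

    def test_subthreshold_drive_reaches_steady_plateau(self, gchi, gjc, tm, rest):
        """Below the onset frequency, IP3 and Ca2+ rise to elevated steady
        levels without oscillating."""
        tr = single_frequency_run(star_network(0), 1.0, gchi, gjc, tm,
                                  train_s=30.0, pre_s=10.0, rest=rest)
        win = tr.time >= 25.0
        C, I = tr.C[0][win], tr.I[0][win]
        assert np.ptp(C) < 0.05                 # no Ca spike
        assert I[-1] > 2 * rest.I               # but IP3 clearly elevated
        assert C[-1] > rest.C

    def test_state_bounds_along_trajectory(self, gchi, gjc, tm, rest):
        tr = single_frequency_run(star_network(2), 20.0, gchi, gjc, tm,
                                  train_s=30.0, pre_s=5.0, rest=rest)
        assert tr.C.min() >= 0 and tr.I.min() >= 0
        assert tr.h.min() >= 0 and tr.h.max() <= 1

    def test_time_shift_equivariance(self, gchi, gjc, tm, rest):
        """Delaying the protocol delays the response by the same amount."""
        a = single_frequency_run(star_network(0), 5.0, gchi, gjc, tm,
                                 train_s=20.0, pre_s=10.0, rest=rest)
        b = single_frequency_run(star_network(0), 5.0, gchi, gjc, tm,
                                 train_s=20.0, pre_s=20.0, rest=rest)
        ca = a.C[0][(a.time >= 10.0) & (a.time <= 30.0)]
        cb = b.C[0][(b.time >= 20.0) & (b.time <= 40.0)]
        n = min(ca.size, cb.size)
        np.testing.assert_allclose(ca[:n], cb[:n], atol=5e-3)

    def test_solver_tolerance_convergence(self, gchi, gjc, tm, rest):
        """Tightening tolerances changes the Ca trace by well under 1%."""
        net = star_network(0)
        prot = make_fixed_duration_protocol([5.0], train_duration=20.0)
        coarse = simulate(net, prot, gchi, gjc, tm, pre_time=5.0, rest=rest,
                          rtol=1e-6, atol=1e-9)
        fine = simulate(net, prot, gchi, gjc, tm, pre_time=5.0, rest=rest,
                        rtol=1e-8, atol=1e-11)
        scale = np.abs(fine.C[0]).max()
        assert np.abs(coarse.C[0] - fine.C[0]).max() / scale < 0.01


class TestFluxDecomposition:
    def test_rest_production_balances_degradation(self, gchi, gjc, tm, rest):
        prot = make_fixed_duration_protocol([], train_duration=10.0)
        tr = simulate(star_network(0), prot, gchi, gjc, tm, pre_time=10.0,
                      post_time=0.0, rest=rest)
        fl = flux_decomposition(tr, gchi)
        prod = fl["J_delta"].iloc[-1]           # J_beta = 0 at rest (G = 0)
        deg = fl["J_3K"].iloc[-1] + fl["J_5P"].iloc[-1]
        assert prod == pytest.approx(deg, abs=1e-6)

    def test_plcdelta_peaks_before_calcium_maximum(self, gchi, gjc, tm, rest):
        """During a Ca2+ rise the PLCdelta surge precedes the Ca2+ peak:
        rising Ca activates PLCdelta production, which then collapses as
        IP3R inactivation and SERCA terminate the spike."""
        tr = single_frequency_run(star_network(0), 5.0, gchi, gjc, tm,
                                  train_s=30.0, pre_s=5.0, rest=rest)
        fl = flux_decomposition(tr, gchi)
        win = (tr.time >= 5.0) & (tr.time <= 20.0)
        t = tr.time[win]
        c_peak_t = t[np.argmax(tr.C[0][win])]
        delta_peak_t = t[np.argmax(fl["J_delta"].to_numpy()[win])]
        assert delta_peak_t < c_peak_t

    def test_calcium_fluxes_close_over_a_period(self, gchi, gjc, tm, rest):
        """dC/dt integrates to ~0 over one full oscillation cycle."""
        tr = single_frequency_run(star_network(0), 20.0, gchi, gjc, tm,
                                  train_s=60.0, pre_s=5.0, rest=rest)
        C = tr.C[0]
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(C, prominence=0.2)
        assert peaks.size >= 3
        a, b = peaks[-3], peaks[-1]
        fl = flux_decomposition(tr, gchi)
        dC = (fl["J_C"] + fl["J_L"] - fl["J_P"]).to_numpy()
        integral = np.trapezoid(dC[a:b + 1], tr.time[a:b + 1])
        assert abs(integral) < 0.05 * np.abs(C).max()

    def test_unstimulated_neighbour_stays_subthreshold_near_onset(
            self, gchi, gjc, tm, rest):
        """With PLCdelta production lowered, an oscillating astrocyte's
        unstimulated neighbour shows only sub-threshold IP3/Ca elevations
        at default coupling (no regenerative wave)."""
        tr = single_frequency_run(star_network(1), 3.0, gchi, gjc, tm,
                                  train_s=30.0, pre_s=10.0, rest=rest)
        assert tr.C[0].max() > 0.3          # the hub spikes
        assert tr.C[1].max() < 0.15         # the neighbour does not
        assert tr.I[1].max() > 2 * rest.I   # but its IP3 is clearly elevated
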