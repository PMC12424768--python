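"""Cell-model tests: resting behavior, firing, resonance, population jitter,
and agreement with an independent fixed-step RK4 integrator."""

import dataclasses

import numpy as np
import pytest

from mecgamma import (FSParams, StellateParams, PopulationSpec, make_fs_cell,
                      make_stellate_cell, jitter_population, impedance_profile,
                      f_i_curve, ZapSpec)
from mecgamma.cells import ZapSpikingError, params_to_yaml, params_from_yaml


def rk4_trace(cell, duration_ms, dt, i_inj=0.0, g_drive=0.0, e_drive=0.0,
              v0=None):
    """Naive fixed-step RK4 on the cell's own right-hand side (oracle)."""
    v = cell.params.e_l if v0 is None else v0
    gates = cell.steady_gates(v)
    n = int(round(duration_ms / dt))
    out = np.empty(n + 1)
    out[0] = v

    def f(y):
        dv, dg = cell.derivatives(y[0], y[1:], i_inj, g_drive, e_drive)
        return np.concatenate([[dv], dg])

    y = np.concatenate([[v], gates])
    for k in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = y[0]
    return out


class TestFastSpiking:
    def test_rest_is_fixed_point(self):
        cell = make_fs_cell()
        t, v, spikes = cell.simulate(500.0, v0=cell.params.e_l)
        assert len(spikes) == 0
        assert abs(v[-1] - v[-2000]) < 0.01  # settled

    def test_fires_under_theta_peak_drive(self):
        # 7 nS excitatory conductance = the peak optogenetic drive to I cells
        cell = make_fs_cell()
        _, _, spikes = cell.simulate(1000.0, g_drive=7.0, e_drive=0.0)
        assert len(spikes) > 50

    def test_tonic_firing_no_adaptation_over_5s(self):
        cell = make_fs_cell()
        _, _, spikes = cell.simulate(5000.0, g_drive=7.0, e_drive=0.0)
        # firing persists through the last half second
        assert spikes[-1] > 4500.0
        rate_first = np.sum((spikes > 500) & (spikes < 1500))
        rate_last = np.sum(spikes > 4000)
        assert rate_last > 0.8 * rate_first

    def test_f_i_curve_matches_rk4_oracle(self):
        cell = make_fs_cell()
        for i0 in (150.0, 300.0):
            v = rk4_trace(cell, 1500.0, 0.005, i_inj=i0)
            t_axis = np.arange(len(v)) * 0.005
            spikes_oracle = t_axis[1:][(v[1:] >= 0) & (v[:-1] < 0)]
            rate_oracle = np.sum(spikes_oracle >= 500.0) / 1.0
            rate = f_i_curve(cell, [i0], duration_ms=1500.0,
                             discard_ms=500.0)[0]
            assert rate == pytest.approx(rate_oracle, abs=1.0)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            FSParams(g_na=-1.0)
        with pytest.raises(ValueError):
            FSParams(e_na=-100.0)  # violates E_Na > E_L


class TestStellate:
    def test_subthreshold_matches_rk4_oracle(self):
        # 1 s subthreshold trace: engine (exp-Euler, dt 0.025) vs RK4 oracle
        cell = make_stellate_cell()
        rest = cell.resting_potential()
        _, v, spikes = cell.simulate(1000.0, dt=0.025, i_inj=10.0, v0=rest)
        assert len(spikes) == 0
        v_oracle = rk4_trace(cell, 1000.0, 0.005, i_inj=10.0, v0=rest)
        assert np.max(np.abs(v[::40][:1000] - v_oracle[::200][:1000])) < 0.1

    def test_theta_band_resonance(self):
        cell = make_stellate_cell()
        res = impedance_profile(cell, ZapSpec(amp_pa=4.0, f1_hz=30.0,
                                              duration_s=20.0))
        assert 4.0 <= res.resonance_hz <= 12.0

    def test_no_resonance_without_nap_and_h(self):
        p = dataclasses.replace(StellateParams(), g_nap=0.0, g_h=0.0)
        res = impedance_profile(make_stellate_cell(p),
                                ZapSpec(amp_pa=4.0, f1_hz=30.0,
                                        duration_s=20.0))
        # low-pass: peak at the lowest tested frequency
        assert res.resonance_hz == pytest.approx(res.freqs_hz[0])

    def test_zap_spiking_invalidates(self):
        cell = make_stellate_cell()
        with pytest.raises(ZapSpikingError):
            impedance_profile(cell, ZapSpec(amp_pa=500.0, duration_s=5.0))


class TestPassiveImpedance:
    def test_dc_impedance_is_inverse_leak(self):
        p = dataclasses.replace(FSParams(), g_na=0.0, g_k=0.0)
        res = impedance_profile(make_fs_cell(p),
                                ZapSpec(f0_hz=0.2, f1_hz=20.0,
                                        duration_s=20.0))
        # |Z| in GOhm; DC limit = 1/g_L (nS)
        assert res.impedance_gohm[0] == pytest.approx(1.0 / p.g_l, rel=0.05)
        # monotone low-pass
        coarse = res.impedance_gohm[::200]
        assert np.all(np.diff(coarse) <= 1e-4)


class TestJitterPopulation:
    def test_zero_cv_gives_identical_copies(self):
        base = FSParams()
        pop = jitter_population(PopulationSpec(10, base, jitter_cv=0.0, seed=1))
        assert all(p == base for p in pop)

    def test_population_size_and_truncation(self):
        pop = jitter_population(PopulationSpec(400, StellateParams(),
                                               jitter_cv=0.5, seed=2))
        assert len(pop) == 400
        assert all(p.g_nap >= 0 for p in pop)

    def test_sample_mean_within_3se_at_n400(self):
        base = StellateParams()
        cv = 0.1
        pop = jitter_population(PopulationSpec(400, base, jitter_cv=cv, seed=3))
        for name in ("g_na", "g_k", "g_l", "g_nap", "g_h"):
            vals = np.array([getattr(p, name) for p in pop])
            se = cv * getattr(base, name) / np.sqrt(400)
            assert abs(vals.mean() - getattr(base, name)) < 3 * se

    def test_deterministic_given_seed(self):
        spec = PopulationSpec(50, FSParams(), 0.2, seed=7)
        a = jitter_population(spec)
        b = jitter_population(spec)
        assert a == b


def test_refinement_stability_dt_halving():
    """Halving dt changes the subthreshold trajectory by < 0.5 mV and spike
    times by < 0.5 ms over 1 s for the default cells."""
    fs = make_fs_cell()
    # theta-driven firing (the operating condition): the drive re-locks the
    # phase each cycle, so discretization error does not accumulate
    for dt in (0.025, 0.0125):
        tg = np.arange(int(round(1000.0 / dt))) * dt
        g = 3.5 * (1.0 - np.cos(2e-3 * np.pi * 8.0 * tg))
        if dt == 0.025:
            _, v1, s1 = fs.simulate(1000.0, dt=dt, g_drive=g, e_drive=0.0)
        else:
            _, v2, s2 = fs.simulate(1000.0, dt=dt, g_drive=g, e_drive=0.0)
    assert len(s1) == len(s2)
    assert np.max(np.abs(s1 - s2)) < 0.5
    st = make_stellate_cell()
    rest = st.resting_potential()
    _, w1, _ = st.simulate(1000.0, dt=0.025, i_inj=10.0, v0=rest)
    _, w2, _ = st.simulate(1000.0, dt=0.0125, i_inj=10.0, v0=rest)
    assert np.max(np.abs(w1[::40] - w2[::80])) < 0.5


def test_yaml_roundtrip():
    for params in (FSParams(), StellateParams(g_h=33.0)):
        assert params_from_yaml(params_to_yaml(params)) == params
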