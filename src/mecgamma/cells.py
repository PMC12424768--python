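"""Single-compartment conductance-based neuron models.

Two cell classes are provided:

* **Fast-spiking PV+ interneuron** -- the Wang-Buzsaki formalism (Na, K-DR and
  leak currents, instantaneous Na activation, temperature factor ``phi``),
  the standard realization of a non-adapting interneuron capable of sustained
  firing well into the fast-gamma range.
* **Stellate cell** -- the classic Hodgkin-Huxley equations augmented with a
  persistent sodium current and an HCN (h) current, the pair of conductances
  that confer the theta-band subthreshold resonance characteristic of medial
  entorhinal cortex layer II stellate cells.

All conductances are absolute (nS), capacitance in pF, potentials in mV and
time in ms, so that synaptic and optogenetic drive specified in nS plugs in
directly.  Every parameter is exposed so calibrated values can be dropped in
from configuration files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import yaml
from numba import njit

from . import rates

__all__ = [
    "FSParams",
    "StellateParams",
    "PopulationSpec",
    "ZapSpec",
    "ImpedanceResult",
    "CellModel",
    "ZapSpikingError",
    "make_fs_cell",
    "make_stellate_cell",
    "jitter_population",
    "impedance_profile",
    "f_i_curve",
    "params_to_yaml",
    "params_from_yaml",
    "default_params",
]

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 2.0


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"conductance {name} must be >= 0, got {value}")


@dataclass
class FSParams:
    """Wang-Buzsaki fast-spiking interneuron parameters (absolute units)."""

    c_m: float = 100.0      # pF
    g_na: float = 3500.0    # nS
    g_k: float = 900.0      # nS
    g_l: float = 20.0       # nS
    e_na: float = 55.0      # mV
    e_k: float = -90.0      # mV
    e_l: float = -65.0      # mV
    phi: float = 5.0        # gating temperature factor
    v_shift: float = 0.0    # mV, optional depolarizing shift of the gates

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_l"):
            _check_nonneg(name, getattr(self, name))
        if not (self.e_na > self.e_l > self.e_k):
            raise ValueError("reversal potentials must satisfy E_Na > E_L > E_K")

    conductance_fields = ("g_na", "g_k", "g_l")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StellateParams:
    """Classic HH + persistent-Na + h-current stellate cell parameters."""

    c_m: float = 50.0       # pF
    g_na: float = 6000.0    # nS
    g_k: float = 1800.0     # nS
    g_l: float = 15.0       # nS
    e_na: float = 50.0      # mV
    e_k: float = -90.0      # mV
    e_l: float = -75.0      # mV
    phi: float = 1.0
    g_nap: float = 8.5      # nS, persistent sodium
    g_h: float = 15.0       # nS, HCN
    e_h: float = -20.0      # mV
    v_shift: float = 8.0    # mV depolarizing shift of the Na spike gates
    v_shift_k: float = 25.0  # mV depolarizing shift of the K-DR gate

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_l", "g_nap", "g_h"):
            _check_nonneg(name, getattr(self, name))
        if not (self.e_na > self.e_l > self.e_k):
            raise ValueError("reversal potentials must satisfy E_Na > E_L > E_K")

    conductance_fields = ("g_na", "g_k", "g_l", "g_nap", "g_h")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


CellParams = Union[FSParams, StellateParams]


@dataclass
class PopulationSpec:
    """A heterogeneous population derived from a base parameter set.

    Each maximal conductance of ``base`` is jittered independently per cell
    as Normal(g, jitter_cv * g), truncated at zero.
    """

    n: int
    base: CellParams
    jitter_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("population size n must be > 0")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")


# ----------------------------------------------------------------------------
# numba-compiled kinetics and single-cell integrators
# ----------------------------------------------------------------------------

# aliases used by the compiled integrators (rates are njit-compiled)
_wb_m_inf = rates.wb_m_inf
_wb_h_alpha = rates.wb_h_alpha
_wb_h_beta = rates.wb_h_beta
_wb_n_alpha = rates.wb_n_alpha
_wb_n_beta = rates.wb_n_beta
_hh_m_alpha = rates.hh_m_alpha
_hh_m_beta = rates.hh_m_beta
_hh_h_alpha = rates.hh_h_alpha
_hh_h_beta = rates.hh_h_beta
_hh_n_alpha = rates.hh_n_alpha
_hh_n_beta = rates.hh_n_beta
_nap_m_inf = rates.nap_m_inf
_h_r_inf = rates.h_r_inf
_h_r_tau = rates.h_r_tau


@njit(cache=True)
def _integrate_fs(v0, h0, n0, cm, gna, gk, gl, ena, ek, el, phi, vshift,
                  dt, i_inj, g_drive, e_drive):
    """Exponential-Euler integration of a single Wang-Buzsaki cell.

    ``i_inj`` (pA) and ``g_drive`` (nS) are per-step arrays of equal length.
    Returns the voltage trace (including the initial condition) and spike
    times (upward crossings of 0 mV, 2 ms refractory).
    """
    n_steps = i_inj.shape[0]
    v = np.empty(n_steps + 1)
    v[0] = v0
    h = h0
    nn = n0
    spikes = np.empty(n_steps, np.float64)
    n_sp = 0
    last_sp = -1e9
    for k in range(n_steps):
        vk = v[k]
        vg = vk - vshift
        # gates (exponential Euler at old voltage)
        ah = _wb_h_alpha(vg) * phi
        bh = _wb_h_beta(vg) * phi
        an = _wb_n_alpha(vg) * phi
        bn = _wb_n_beta(vg) * phi
        h = h + (ah / (ah + bh) - h) * -np.expm1(-dt * (ah + bh))
        nn = nn + (an / (an + bn) - nn) * -np.expm1(-dt * (an + bn))
        m = _wb_m_inf(vg)
        g_na_eff = gna * m * m * m * h
        g_k_eff = gk * nn ** 4
        g_tot = g_na_eff + g_k_eff + gl + g_drive[k]
        num = (g_na_eff * ena + g_k_eff * ek + gl * el
               + g_drive[k] * e_drive + i_inj[k])
        v_inf = num / g_tot
        v_new = v_inf + (vk - v_inf) * np.exp(-dt * g_tot / cm)
        t = (k + 1) * dt
        if v_new >= SPIKE_THRESHOLD_MV and vk < SPIKE_THRESHOLD_MV \
                and t - last_sp >= SPIKE_REFRACTORY_MS:
            spikes[n_sp] = t
            n_sp += 1
            last_sp = t
        v[k + 1] = v_new
    return v, spikes[:n_sp]


@njit(cache=True)
def _integrate_stellate(v0, m0, h0, n0, r0, cm, gna, gk, gl, ena, ek, el, phi,
                        gnap, gh, eh, vshift, vshiftk, dt, i_inj, g_drive, e_drive):
    """Exponential-Euler integration of a single HH+NaP+H stellate cell."""
    n_steps = i_inj.shape[0]
    v = np.empty(n_steps + 1)
    v[0] = v0
    m = m0
    h = h0
    nn = n0
    r = r0
    spikes = np.empty(n_steps, np.float64)
    n_sp = 0
    last_sp = -1e9
    for k in range(n_steps):
        vk = v[k]
        vg = vk - vshift
        am = _hh_m_alpha(vg) * phi
        bm = _hh_m_beta(vg) * phi
        ah = _hh_h_alpha(vg) * phi
        bh = _hh_h_beta(vg) * phi
        vn = vk - vshiftk
        an = _hh_n_alpha(vn) * phi
        bn = _hh_n_beta(vn) * phi
        m = m + (am / (am + bm) - m) * -np.expm1(-dt * (am + bm))
        h = h + (ah / (ah + bh) - h) * -np.expm1(-dt * (ah + bh))
        nn = nn + (an / (an + bn) - nn) * -np.expm1(-dt * (an + bn))
        tr = _h_r_tau(vk)
        r = r + (_h_r_inf(vk) - r) * -np.expm1(-dt / tr)
        g_na_eff = gna * m * m * m * h
        g_k_eff = gk * nn ** 4
        g_nap_eff = gnap * _nap_m_inf(vk)
        g_h_eff = gh * r
        g_tot = g_na_eff + g_k_eff + gl + g_nap_eff + g_h_eff + g_drive[k]
        num = (g_na_eff * ena + g_k_eff * ek + gl * el + g_nap_eff * ena
               + g_h_eff * eh + g_drive[k] * e_drive + i_inj[k])
        v_inf = num / g_tot
        v_new = v_inf + (vk - v_inf) * np.exp(-dt * g_tot / cm)
        t = (k + 1) * dt
        if v_new >= SPIKE_THRESHOLD_MV and vk < SPIKE_THRESHOLD_MV \
                and t - last_sp >= SPIKE_REFRACTORY_MS:
            spikes[n_sp] = t
            n_sp += 1
            last_sp = t
        v[k + 1] = v_new
    return v, spikes[:n_sp]


# ----------------------------------------------------------------------------
# CellModel
# ----------------------------------------------------------------------------

def _as_step_array(x, n_steps: int, name: str) -> np.ndarray:
    if x is None:
        return np.zeros(n_steps)
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(n_steps, float(arr))
    if len(arr) != n_steps:
        raise ValueError(f"{name} must have length duration/dt = {n_steps}")
    return np.ascontiguousarray(arr)


class ZapSpikingError(RuntimeError):
    """The ZAP drive elicited spikes; the impedance estimate is invalid."""


class CellModel:
    """A parameterized single-compartment neuron.

    Provides the membrane right-hand side (:meth:`derivatives`), steady
    states and a fast fixed-step simulator.  ``kind`` is ``"fs"`` or
    ``"stellate"``.
    """

    def __init__(self, kind: str, params: CellParams):
        if kind not in ("fs", "stellate"):
            raise ValueError(f"unknown cell kind {kind!r}")
        self.kind = kind
        self.params = params

    # -- state layout: fs -> (h, n); stellate -> (m, h, n, r) ---------------

    def steady_gates(self, v: float) -> np.ndarray:
        if self.kind == "fs":
            vg = v - self.params.v_shift
            h = rates.wb_h_alpha(vg) / (rates.wb_h_alpha(vg) + rates.wb_h_beta(vg))
            n = rates.wb_n_alpha(vg) / (rates.wb_n_alpha(vg) + rates.wb_n_beta(vg))
            return np.array([h, n])
        vg = v - self.params.v_shift
        vn = v - self.params.v_shift_k
        m = rates.hh_m_alpha(vg) / (rates.hh_m_alpha(vg) + rates.hh_m_beta(vg))
        h = rates.hh_h_alpha(vg) / (rates.hh_h_alpha(vg) + rates.hh_h_beta(vg))
        n = rates.hh_n_alpha(vn) / (rates.hh_n_alpha(vn) + rates.hh_n_beta(vn))
        r = rates.h_r_inf(v)
        return np.array([m, h, n, r])

    def resting_potential(self, v_guess: float = -65.0) -> float:
        """Resting membrane potential found by relaxing the full system."""
        t, v, _ = self.simulate(1000.0, dt=0.05, v0=v_guess)
        return float(v[-1])

    def membrane_currents(self, v: float, gates: np.ndarray) -> tuple:
        """Total conductance (nS) and conductance-weighted reversal sum (nS*mV)."""
        p = self.params
        if self.kind == "fs":
            h, n = gates
            m = rates.wb_m_inf(v - self.params.v_shift)
            g_na = p.g_na * m ** 3 * h
            g_k = p.g_k * n ** 4
            g_tot = g_na + g_k + p.g_l
            num = g_na * p.e_na + g_k * p.e_k + p.g_l * p.e_l
        else:
            m, h, n, r = gates
            g_na = p.g_na * m ** 3 * h
            g_k = p.g_k * n ** 4
            g_nap = p.g_nap * rates.nap_m_inf(v)
            g_h = p.g_h * r
            g_tot = g_na + g_k + p.g_l + g_nap + g_h
            num = (g_na * p.e_na + g_k * p.e_k + p.g_l * p.e_l
                   + g_nap * p.e_na + g_h * p.e_h)
        return g_tot, num

    def derivatives(self, v: float, gates: np.ndarray,
                    i_inj: float = 0.0, g_drive: float = 0.0,
                    e_drive: float = 0.0) -> tuple:
        """dV/dt (mV/ms) and gate derivatives, for external integrators."""
        p = self.params
        g_tot, num = self.membrane_currents(v, gates)
        g_tot = g_tot + g_drive
        num = num + g_drive * e_drive + i_inj
        dv = (num - g_tot * v) / p.c_m
        if self.kind == "fs":
            h, n = gates
            vg = v - p.v_shift
            dh = p.phi * (rates.wb_h_alpha(vg) * (1 - h) - rates.wb_h_beta(vg) * h)
            dn = p.phi * (rates.wb_n_alpha(vg) * (1 - n) - rates.wb_n_beta(vg) * n)
            return dv, np.array([dh, dn])
        m, h, n, r = gates
        vg = v - p.v_shift
        vn = v - p.v_shift_k
        dm = p.phi * (rates.hh_m_alpha(vg) * (1 - m) - rates.hh_m_beta(vg) * m)
        dh = p.phi * (rates.hh_h_alpha(vg) * (1 - h) - rates.hh_h_beta(vg) * h)
        dn = p.phi * (rates.hh_n_alpha(vn) * (1 - n) - rates.hh_n_beta(vn) * n)
        dr = (rates.h_r_inf(v) - r) / rates.h_r_tau(v)
        return dv, np.array([dm, dh, dn, dr])

    def simulate(self, duration_ms: float, dt: float = 0.025,
                 i_inj=None, g_drive=None, e_drive: float = 0.0,
                 v0: Optional[float] = None):
        """Fixed-step exponential-Euler simulation.

        ``i_inj`` (pA) and ``g_drive`` (nS) may be scalars or per-step arrays.
        Returns ``(t, v, spike_times)`` with ``t``/``v`` of length
        ``n_steps + 1``.
        """
        n_steps = int(round(duration_ms / dt))
        i_arr = _as_step_array(i_inj, n_steps, "i_inj")
        g_arr = _as_step_array(g_drive, n_steps, "g_drive")
        p = self.params
        if v0 is None:
            v0 = p.e_l
        gates = self.steady_gates(v0)
        if self.kind == "fs":
            v, spikes = _integrate_fs(
                v0, gates[0], gates[1], p.c_m, p.g_na, p.g_k, p.g_l,
                p.e_na, p.e_k, p.e_l, p.phi, p.v_shift, dt, i_arr, g_arr,
                e_drive)
        else:
            v, spikes = _integrate_stellate(
                v0, gates[0], gates[1], gates[2], gates[3], p.c_m, p.g_na,
                p.g_k, p.g_l, p.e_na, p.e_k, p.e_l, p.phi, p.g_nap, p.g_h,
                p.e_h, p.v_shift, p.v_shift_k, dt, i_arr, g_arr, e_drive)
        t = np.arange(n_steps + 1) * dt
        return t, v, spikes


def make_fs_cell(params: Optional[FSParams] = None) -> CellModel:
    """Fast-spiking PV+ interneuron model (Wang-Buzsaki formalism)."""
    return CellModel("fs", params if params is not None else FSParams())


def make_stellate_cell(params: Optional[StellateParams] = None) -> CellModel:
    """Stellate cell model (classic HH + persistent Na + h-current)."""
    return CellModel("stellate", params if params is not None else StellateParams())


# ----------------------------------------------------------------------------
# Population heterogeneity
# ----------------------------------------------------------------------------

def jitter_population(spec: PopulationSpec) -> list:
    """Draw ``spec.n`` parameter sets with Gaussian-jittered conductances.

    Each maximal conductance g is drawn Normal(g, jitter_cv * g) and
    truncated at 0.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    fields = type(spec.base).conductance_fields
    for _ in range(spec.n):
        kw = {}
        for name in fields:
            base = getattr(spec.base, name)
            g = rng.normal(base, spec.jitter_cv * base) if spec.jitter_cv > 0 else base
            kw[name] = max(g, 0.0)
        out.append(dataclasses.replace(spec.base, **kw))
    return out


# ----------------------------------------------------------------------------
# Impedance / f-I characterization
# ----------------------------------------------------------------------------

@dataclass
class ZapSpec:
    """Subthreshold chirp (ZAP) current drive for impedance profiling."""

    f0_hz: float = 0.5
    f1_hz: float = 20.0
    duration_s: float = 20.0
    amp_pa: float = 10.0
    i_bias_pa: float = 0.0
    dt_ms: float = 0.05
    settle_s: float = 2.0   # discarded from the start of the response


@dataclass
class ImpedanceResult:
    freqs_hz: np.ndarray
    impedance_gohm: np.ndarray   # |Z| in GOhm (= mV/pA = 1/nS)
    resonance_hz: float


def impedance_profile(cell: CellModel, zap: ZapSpec = ZapSpec()) -> ImpedanceResult:
    """Subthreshold impedance magnitude |FFT(V)| / |FFT(I)| over the chirp band.

    Raises :class:`ZapSpikingError` if the drive elicits spikes (the
    estimate would then be dominated by action-potential harmonics).
    """
    dt = zap.dt_ms
    n_settle = int(round(zap.settle_s * 1000.0 / dt))
    n_steps = int(round(zap.duration_s * 1000.0 / dt)) + n_settle
    t_s = np.arange(n_steps) * dt / 1000.0
    t_chirp = np.clip(t_s - zap.settle_s, 0.0, None)
    T = zap.duration_s
    phase = 2 * np.pi * (zap.f0_hz * t_chirp
                         + (zap.f1_hz - zap.f0_hz) * t_chirp ** 2 / (2 * T))
    i_inj = zap.i_bias_pa + zap.amp_pa * np.sin(phase) * (t_s >= zap.settle_s)
    _, v, spikes = cell.simulate(n_steps * dt, dt=dt, i_inj=i_inj)
    spikes = spikes[spikes >= zap.settle_s * 1000.0]   # ignore onset transient
    if len(spikes):
        raise ZapSpikingError(
            f"ZAP drive elicited {len(spikes)} spikes; reduce amp_pa")
    v_seg = v[n_settle:-1]
    i_seg = i_inj[n_settle:] - zap.i_bias_pa
    fs = 1000.0 / dt
    freqs = np.fft.rfftfreq(len(v_seg), 1.0 / fs)
    vf = np.fft.rfft(v_seg - v_seg.mean())
    if_ = np.fft.rfft(i_seg)
    band = (freqs >= zap.f0_hz) & (freqs <= zap.f1_hz)
    z = np.abs(vf[band]) / np.maximum(np.abs(if_[band]), 1e-12)
    f_band = freqs[band]
    return ImpedanceResult(f_band, z, float(f_band[np.argmax(z)]))


def f_i_curve(cell: CellModel, currents_pa, duration_ms: float = 2000.0,
              dt: float = 0.025, discard_ms: float = 500.0) -> np.ndarray:
    """Steady firing rate (Hz) for each injected current step."""
    out = []
    for i0 in np.atleast_1d(currents_pa):
        _, _, spikes = cell.simulate(duration_ms, dt=dt, i_inj=float(i0))
        spikes = spikes[spikes >= discard_ms]
        out.append(len(spikes) / ((duration_ms - discard_ms) / 1000.0))
    return np.asarray(out)


# ----------------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------------

_PROFILE_KINDS = {"fs": FSParams, "stellate": StellateParams}


def params_to_yaml(params: CellParams) -> str:
    kind = "fs" if isinstance(params, FSParams) else "stellate"
    return yaml.safe_dump({"kind": kind, "params": params.to_dict()},
                          sort_keys=False)


def params_from_yaml(text: str) -> CellParams:
    block = yaml.safe_load(text)
    cls = _PROFILE_KINDS[block["kind"]]
    return cls(**block["params"])


def default_params(kind: str) -> CellParams:
    """Named default parameter profile per cell type."""
    return _PROFILE_KINDS[kind]()
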