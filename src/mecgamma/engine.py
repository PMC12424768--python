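"""Network simulation driver: integrate the ODEs, record spikes, voltages and
readout clamp currents on a fixed time grid."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .network import Network, theta_conductance, ThetaDriveSpec, set_class_conductance  # noqa: F401
from .cells import CellModel

__all__ = ["SimConfig", "SimResult", "run", "clamp_current"]


@dataclass
class SimConfig:
    """Simulation settings.

    ``n_theta_cycles`` defaults to 41: the first cycle is discarded by the
    analysis and the following 40 are analyzed, matching the recording
    protocol.  ``seed`` controls the drive-noise realization and the initial
    conditions (connectivity randomness lives on the Network).
    """

    dt: float = 0.025               # ms
    n_theta_cycles: int = 41
    seed: int = 0
    record_dt: float = 0.1          # ms, sampling interval of recorded traces
    record_v: Tuple[int, ...] = ()  # global cell ids to record voltage from
    duration_ms: Optional[float] = None   # override; default cycles/f_theta

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_theta_cycles < 2:
            raise ValueError("need at least 2 theta cycles (1 discarded)")

    def resolved_duration(self, f_theta: float) -> float:
        if self.duration_ms is not None:
            if self.duration_ms < self.n_theta_cycles * 1000.0 / f_theta:
                raise ValueError("duration shorter than n_theta_cycles periods")
            return self.duration_ms
        return self.n_theta_cycles * 1000.0 / f_theta


@dataclass
class SimResult:
    """Spike times, readout clamp currents and optional voltage traces."""

    t_ms: np.ndarray                 # recording time grid
    spike_times: np.ndarray          # ms, sorted by time within each step
    spike_gids: np.ndarray           # global ids (I: 0..n_i-1, E: n_i..)
    clamp_i_pa: np.ndarray           # (n_readouts, n_t) I-population readouts
    clamp_e_pa: np.ndarray           # (n_readouts, n_t) E-population readouts
    voltages: Dict[int, np.ndarray]  # gid -> mV trace
    network: Network
    config: SimConfig

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.config.record_dt

    @property
    def n_i(self) -> int:
        return self.network.n_i

    def spikes_of(self, gid: int) -> np.ndarray:
        return np.sort(self.spike_times[self.spike_gids == gid])

    def population_spikes(self, pop: str) -> Tuple[np.ndarray, np.ndarray]:
        """(times, gids) of one population ('I' or 'E')."""
        n_i = self.network.n_i
        mask = (self.spike_gids < n_i) if pop == "I" else (self.spike_gids >= n_i)
        return self.spike_times[mask], self.spike_gids[mask]

    def spikes_dataframe(self) -> pd.DataFrame:
        pop = np.where(self.spike_gids < self.network.n_i, "I", "E")
        return pd.DataFrame({"cell_id": self.spike_gids,
                             "population": pop,
                             "t_ms": self.spike_times})

    def spikes_to_csv(self, path) -> None:
        self.spikes_dataframe().to_csv(path, index=False)

    def traces_to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.t_ms)
            f.create_dataset("clamp_I_pA", data=self.clamp_i_pa)
            f.create_dataset("clamp_E_pA", data=self.clamp_e_pa)
            g = f.create_group("voltage_mV")
            for gid, v in self.voltages.items():
                g.create_dataset(str(gid), data=v)

    def metadata(self) -> dict:
        return {
            "network_seed": self.network.seed,
            "sim_seed": self.config.seed,
            "dt_ms": self.config.dt,
            "n_theta_cycles": self.config.n_theta_cycles,
            "n_spikes": int(len(self.spike_times)),
            "g_ei_nS": self.network.config.g_ei,
            "g_ii_nS": self.network.config.g_ii,
            "e_gaba_ii": (self.network.config.e_gaba_ii
                          if isinstance(self.network.config.e_gaba_ii, (int, float))
                          else str(self.network.config.e_gaba_ii)),
        }

    def metadata_to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.metadata(), f, indent=1)


def clamp_current(g_syn_ns, v_hold: float, e_rev: float) -> np.ndarray:
    """Voltage-clamp current I = g (V_hold - E_rev), in pA for g in nS."""
    return np.asarray(g_syn_ns) * (v_hold - e_rev)


def _csr(pre: np.ndarray, n_pre: int) -> np.ndarray:
    counts = np.bincount(pre, minlength=n_pre)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr


def run(network: Network, config: Optional[SimConfig] = None) -> SimResult:
    """Integrate the network; deterministic given (network, config).

    Raises ``RuntimeError`` on numerical blow-up (|V| > 200 mV) or spike
    buffer overflow, with a diagnostic message.
    """
    config = config if config is not None else SimConfig()
    net_cfg = network.config
    duration = config.resolved_duration(net_cfg.f_theta)
    dt = config.dt
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(config.record_dt / dt)))
    n_rec = (n_steps + rec_stride - 1) // rec_stride

    n_i, n_e, n_ro = net_cfg.n_i, net_cfg.n_e, net_cfg.n_readouts
    pi = net_cfg.fs_params
    pe = net_cfg.stellate_params

    def _garr(params, name):
        return np.array([getattr(p, name) for p in params], dtype=np.float64)

    gna_i, gk_i, gl_i = (_garr(network.params_i, n) for n in ("g_na", "g_k", "g_l"))
    gna_e, gk_e, gl_e, gnap_e, gh_e = (
        _garr(network.params_e, n)
        for n in ("g_na", "g_k", "g_l", "g_nap", "g_h"))

    # drive waveforms sampled on the step grid
    t_steps = np.arange(n_steps) * dt
    th_i = theta_conductance(t_steps, ThetaDriveSpec(net_cfg.f_theta, net_cfg.g_peak_i))
    th_e = theta_conductance(t_steps, ThetaDriveSpec(net_cfg.f_theta, net_cfg.g_peak_e))
    ou_a = np.exp(-dt / net_cfg.noise_tau)
    ou_b = net_cfg.noise_sd_i * np.sqrt(1.0 - ou_a * ou_a)

    # initial conditions and noise seeding (derived from the sim seed)
    ss = np.random.SeedSequence(config.seed).generate_state(3) % (2 ** 31)
    rng = np.random.default_rng(int(ss[0]))
    # initial voltages jittered around rest; starting far hyperpolarized
    # would load the stellate h-current and fire a spurious rebound volley
    v_i = rng.uniform(-68.0, -62.0, n_i)
    v_e = rng.uniform(-66.0, -61.0, n_e)
    fs_cell = CellModel("fs", pi)
    st_cell = CellModel("stellate", pe)
    h_i = np.empty(n_i)
    nn_i = np.empty(n_i)
    for i in range(n_i):
        h_i[i], nn_i[i] = fs_cell.steady_gates(v_i[i])
    m_e = np.empty(n_e)
    he_e = np.empty(n_e)
    nn_e = np.empty(n_e)
    r_e = np.empty(n_e)
    for i in range(n_e):
        m_e[i], he_e[i], nn_e[i], r_e[i] = st_cell.steady_gates(v_e[i])
    x_ou = rng.normal(0.0, net_cfg.noise_sd_i, n_i) if net_cfg.noise_sd_i > 0 \
        else np.zeros(n_i)
    noise_seed = int(ss[1])

    # synapse kinetics
    f_ampa = np.exp(-dt / net_cfg.tau_ampa)
    f_g2d = np.exp(-dt / net_cfg.tau_decay_gaba_ii)
    f_g2r = np.exp(-dt / net_cfg.tau_rise_gaba_ii)
    f_g3d = np.exp(-dt / net_cfg.tau_decay_gaba)
    f_g3r = np.exp(-dt / net_cfg.tau_rise_gaba)
    norm_ii = network.synapse_spec("II").biexp_norm
    norm_ie = network.synapse_spec("IE").biexp_norm

    ei_pre, ei_post = network.edges["EI"]
    ii_pre, ii_post = network.edges["II"]
    ie_pre, ie_post = network.edges["IE"]
    ei_indptr = _csr(ei_pre, n_e)
    ii_indptr = _csr(ii_pre, n_i)
    ie_indptr = _csr(ie_pre, n_i)
    ei_w = network.weights["EI"].astype(np.float64)
    ii_wn = network.weights["II"].astype(np.float64) * norm_ii
    ii_wne = ii_wn * network.e_rev_ii
    ie_wn = network.weights["IE"].astype(np.float64) * norm_ie

    n_it = n_i + n_ro
    n_et = n_e + n_ro
    s_ampa = np.zeros(n_it)
    s2_d = np.zeros(n_it)
    s2_r = np.zeros(n_it)
    s2e_d = np.zeros(n_it)
    s2e_r = np.zeros(n_it)
    s3_d = np.zeros(n_et)
    s3_r = np.zeros(n_et)

    rec_ro_i = np.zeros((n_ro, n_rec))
    rec_ro_e = np.zeros((n_ro, n_rec))
    rec_gids_i = [g for g in config.record_v if g < n_i]
    rec_gids_e = [g for g in config.record_v if n_i <= g < n_i + n_e]
    rec_idx_i = np.asarray(rec_gids_i, dtype=np.int64)
    rec_idx_e = np.asarray([g - n_i for g in rec_gids_e], dtype=np.int64)
    rec_v_i = np.zeros((len(rec_idx_i), n_rec))
    rec_v_e = np.zeros((len(rec_idx_e), n_rec))

    cap = 64 + int((n_i + n_e) * (duration / 1000.0) * 500)
    spike_t = np.empty(cap)
    spike_gid = np.empty(cap, dtype=np.int64)

    v_min, inv_step, T = _kernel.build_tables(dt, pi, pe)
    n_sp, err = _kernel.advance_network(
        n_steps, dt, noise_seed,
        v_min, inv_step, T,
        v_i, h_i, nn_i, gna_i, gk_i, gl_i,
        pi.e_na, pi.e_k, pi.e_l, pi.c_m,
        v_e, m_e, he_e, nn_e, r_e, gna_e, gk_e, gl_e, gnap_e, gh_e,
        pe.e_na, pe.e_k, pe.e_l, pe.e_h, pe.c_m,
        th_i, th_e, net_cfg.e_drive, ou_a, ou_b, x_ou,
        f_ampa, net_cfg.e_ampa, f_g2d, f_g2r, f_g3d, f_g3r,
        ei_indptr, ei_post.astype(np.int64), ei_w,
        ii_indptr, ii_post.astype(np.int64), ii_wn, ii_wne,
        ie_indptr, ie_post.astype(np.int64), ie_wn, net_cfg.e_gaba_ie,
        s_ampa, s2_d, s2_r, s2e_d, s2e_r, s3_d, s3_r,
        n_ro, n_ro, net_cfg.v_clamp, rec_stride,
        rec_ro_i, rec_ro_e, rec_idx_i, rec_idx_e, rec_v_i, rec_v_e,
        spike_t, spike_gid)
    if err == 1:
        raise RuntimeError(
            "numerical blow-up: |V| exceeded 200 mV -- check parameters")
    if err == 2:
        raise RuntimeError("spike buffer overflow -- runaway firing")

    voltages = {}
    for j, g in enumerate(rec_gids_i):
        voltages[g] = rec_v_i[j]
    for j, g in enumerate(rec_gids_e):
        voltages[g] = rec_v_e[j]
    t_rec = np.arange(n_rec) * (rec_stride * dt)
    return SimResult(t_ms=t_rec,
                     spike_times=spike_t[:n_sp].copy(),
                     spike_gids=spike_gid[:n_sp].copy(),
                     clamp_i_pa=rec_ro_i, clamp_e_pa=rec_ro_e,
                     voltages=voltages, network=network, config=config)
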