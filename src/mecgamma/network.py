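"""Construction of the 100-interneuron / 400-stellate-cell mEC network.

The network follows the architecture used for the in-silico theta-drive
experiments: excitatory stellate cells (E) project to fast-spiking PV+
interneurons (I) with probability 0.4 (single-exponential AMPA synapses,
tau = 1 ms, E = 0 mV); interneurons project back to stellate cells with
probability 0.3 (bi-exponential GABA_A synapses, 0.4 ms rise / 6 ms decay,
E = -65 mV, lognormally distributed weights) and to each other (same
kinetics, E_GABA = -75 mV hyperpolarizing by default, overridable per edge
for shunting / distributed-reversal variants).  Stellate cells are never
connected to each other.  An 8 Hz non-negative sinusoidal conductance with
reversal 0 mV emulates the optogenetic theta drive (peak 7 nS onto I cells,
3 nS onto E cells), with a small Ornstein-Uhlenbeck perturbation added to
the I-cell drive so the drive alone cannot synchronize the interneurons.

Five *readout* cells per population are voltage-clamped observers: they
receive afferents sampled by the same rules but emit no spikes and no
efferent events, mirroring the experimental voltage-clamp recordings of
inhibitory currents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .cells import FSParams, StellateParams, PopulationSpec, jitter_population

__all__ = [
    "SynapseSpec",
    "ConnectivityConfig",
    "ThetaDriveSpec",
    "NetworkConfig",
    "Network",
    "sample_connectivity",
    "sample_ie_weights",
    "theta_conductance",
    "make_drive_noise",
    "assemble_network",
    "set_class_conductance",
]


@dataclass
class SynapseSpec:
    """Kinetic scheme of one synapse class; ``g_max`` is the peak conductance."""

    kind: str               # "exp" | "biexp"
    tau_decay: float        # ms
    e_rev: float            # mV
    g_max: float            # nS
    tau_rise: float = 0.0   # ms, biexp only

    def __post_init__(self) -> None:
        if self.kind not in ("exp", "biexp"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be > 0")
        if self.kind == "biexp" and not (0 < self.tau_rise < self.tau_decay):
            raise ValueError("biexp synapse requires 0 < tau_rise < tau_decay")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")

    @property
    def biexp_norm(self) -> float:
        """Scale factor making the bi-exponential difference peak at 1."""
        if self.kind != "biexp":
            return 1.0
        tr, td = self.tau_rise, self.tau_decay
        tp = tr * td / (td - tr) * np.log(td / tr)
        return 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))


@dataclass
class ConnectivityConfig:
    """Random-connectivity probabilities and the I->E weight distribution."""

    p_ei: float = 0.4
    p_ie: float = 0.3
    p_ii: float = 0.3
    ie_weight_median: float = 0.4   # nS; lognormal median exp(mu)
    ie_weight_sigma: float = 0.3    # lognormal sigma (log scale)
    seed: int = 0
    autapses: bool = False

    def __post_init__(self) -> None:
        for name in ("p_ei", "p_ie", "p_ii"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ie_weight_sigma < 0:
            raise ValueError("ie_weight_sigma must be >= 0")


@dataclass
class ThetaDriveSpec:
    """Non-negative sinusoidal optogenetic conductance drive."""

    f_theta: float = 8.0    # Hz
    g_peak: float = 7.0     # nS
    e_rev: float = 0.0      # mV
    noise_sd: float = 0.0   # nS, OU perturbation (I-cell drive only)
    noise_tau: float = 1.0  # ms

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.f_theta


def theta_conductance(t_ms, spec: ThetaDriveSpec) -> np.ndarray:
    """Raised-cosine drive g(t) = (g_peak/2)(1 - cos(2 pi f t)).

    The unique non-negative sinusoid with minimum 0 and maximum ``g_peak``;
    phase 0 (and every whole period) is the drive trough.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    return 0.5 * spec.g_peak * (1.0 - np.cos(2e-3 * np.pi * spec.f_theta * t_ms))


def make_drive_noise(sd: float, tau_ms: float, dt_ms: float,
                     duration_ms: float, seed: int) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck conductance perturbation (nS).

    Exact discretization x[k+1] = a x[k] + sd sqrt(1-a^2) xi, a = exp(-dt/tau),
    initialized from the stationary law; deterministic given ``seed``.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    n = int(round(duration_ms / dt_ms))
    if sd == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    a = np.exp(-dt_ms / tau_ms)
    b = sd * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    xi = rng.standard_normal(n - 1)
    for k in range(1, n):
        x[k] = a * x[k - 1] + b * xi[k - 1]
    return x


# ----------------------------------------------------------------------------
# Connectivity sampling
# ----------------------------------------------------------------------------

def _bernoulli_edges(rng, n_pre: int, n_post: int, p: float, n_post_ro: int = 0,
                     forbid_diag: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Edge lists for independent Bernoulli(p) connections.

    The ``n_post`` active targets are sampled first and the ``n_post_ro``
    readout targets afterwards, so the active-to-active adjacency is
    unchanged by adding or removing readout cells.  ``forbid_diag`` excludes
    (i, i) pairs among active targets (no autapses).
    """
    mask = rng.random((n_pre, n_post)) < p
    if forbid_diag:
        k = min(n_pre, n_post)
        mask[np.arange(k), np.arange(k)] = False
    if n_post_ro:
        mask = np.hstack([mask, rng.random((n_pre, n_post_ro)) < p])
    pre, post = np.nonzero(mask)
    return pre.astype(np.int64), post.astype(np.int64)


def sample_connectivity(config: ConnectivityConfig, n_e: int, n_i: int,
                        n_e_readouts: int = 0, n_i_readouts: int = 0
                        ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Sample the E->I, I->E and I->I adjacency (readout targets included).

    Postsynaptic indices run over the *target* space of each class: I targets
    are the ``n_i`` active interneurons followed by ``n_i_readouts`` readout
    cells, E targets likewise.  No E->E connections are ever created and
    I->I autapses are forbidden.  Deterministic given ``config.seed``.
    """
    # one independent stream per class, so adding/removing readouts of one
    # population never perturbs the others (readout draws follow the active
    # block within each stream)
    r_ei, r_ie, r_ii = (np.random.default_rng([config.seed, k]) for k in range(3))
    edges = {}
    edges["EI"] = _bernoulli_edges(r_ei, n_e, n_i, config.p_ei, n_i_readouts)
    edges["IE"] = _bernoulli_edges(r_ie, n_i, n_e, config.p_ie, n_e_readouts)
    edges["II"] = _bernoulli_edges(r_ii, n_i, n_i, config.p_ii, n_i_readouts,
                                   forbid_diag=not config.autapses)
    return edges


def sample_ie_weights(n_edges: int, median: float, sigma: float,
                      seed: int) -> np.ndarray:
    """Strictly positive lognormal conductances with the given median (nS)."""
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n_edges, float(median))
    return median * np.exp(sigma * rng.standard_normal(n_edges))


# ----------------------------------------------------------------------------
# Network assembly
# ----------------------------------------------------------------------------

EGabaVariant = Union[float, str, Tuple[float, float]]


@dataclass
class NetworkConfig:
    """Complete description of the network; defaults are the study conditions."""

    n_i: int = 100
    n_e: int = 400
    n_readouts: int = 5             # per population, voltage-clamped observers
    fs_params: FSParams = field(default_factory=FSParams)
    stellate_params: StellateParams = field(default_factory=StellateParams)
    jitter_cv_i: float = 0.1        # conductance heterogeneity, interneurons
    jitter_cv_e: float = 0.1        # conductance heterogeneity, stellate cells
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    # synapse kinetics / strengths
    # g_ei is the "average total" E->I conductance -- the sweep axis used in
    # the conductance experiments and the scale on which the physiological
    # range (5-10 nS, from peak-to-peak volley currents / 70 mV) is quoted.
    # It is the summed peak conductance of the ~p_ei * volley-size synapses
    # active in one synchronized volley; the per-edge AMPA peak is
    # g_ei / ei_edge_divisor.  Set ei_edge_divisor = 1 for raw per-edge.
    g_ei: float = 3.6               # nS, on the average-total axis
    ei_edge_divisor: float = 7.0    # axis-to-per-edge conversion
    tau_ampa: float = 1.0           # ms (single exponential)
    e_ampa: float = 0.0             # mV
    g_ii: float = 0.45              # nS, per-edge GABA peak between I cells
    tau_rise_gaba: float = 0.4      # ms (I->E)
    tau_decay_gaba: float = 6.0     # ms (I->E)
    tau_rise_gaba_ii: float = 0.3   # ms (I->I; PV-PV synapses are fast)
    tau_decay_gaba_ii: float = 2.5  # ms (I->I)
    e_gaba_ie: float = -65.0        # mV (I->E)
    e_gaba_ii: EGabaVariant = -75.0  # mV; "distributed" => U(-75, -55) per edge
    # drive
    f_theta: float = 8.0            # Hz
    g_peak_i: float = 7.0           # nS
    g_peak_e: float = 3.0           # nS
    e_drive: float = 0.0            # mV
    noise_sd_i: float = 0.35        # nS (5% of g_peak_i)
    noise_tau: float = 1.0          # ms
    # readout clamp
    v_clamp: float = 0.0            # mV
    # synaptic delay (0 => events take effect on the next time step)
    delay_ms: float = 0.0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        d = yaml.safe_load(text)
        d["fs_params"] = FSParams(**d["fs_params"])
        d["stellate_params"] = StellateParams(**d["stellate_params"])
        d["connectivity"] = ConnectivityConfig(**d["connectivity"])
        if isinstance(d.get("e_gaba_ii"), list):
            d["e_gaba_ii"] = tuple(d["e_gaba_ii"])
        return cls(**d)


@dataclass
class Network:
    """Assembled network: populations, adjacency, weights, drive, readouts."""

    config: NetworkConfig
    seed: int
    params_i: list                  # n_i FSParams
    params_e: list                  # n_e StellateParams
    edges: dict                     # class -> (pre, post) arrays
    weights: dict                   # class -> per-edge peak conductance (nS)
    e_rev_ii: np.ndarray            # per-II-edge reversal potential (mV)

    @property
    def n_i(self) -> int:
        return self.config.n_i

    @property
    def n_e(self) -> int:
        return self.config.n_e

    @property
    def n_readouts(self) -> int:
        return self.config.n_readouts

    def synapse_spec(self, cls: str) -> SynapseSpec:
        c = self.config
        if cls == "EI":
            return SynapseSpec("exp", c.tau_ampa, c.e_ampa, c.g_ei)
        if cls == "IE":
            return SynapseSpec("biexp", c.tau_decay_gaba, c.e_gaba_ie,
                               c.connectivity.ie_weight_median,
                               tau_rise=c.tau_rise_gaba)
        if cls == "II":
            e0 = c.e_gaba_ii if isinstance(c.e_gaba_ii, (int, float)) else -65.0
            return SynapseSpec("biexp", c.tau_decay_gaba_ii, float(e0), c.g_ii,
                               tau_rise=c.tau_rise_gaba_ii)
        raise KeyError(f"unknown synapse class {cls!r}")

    def expected_class_sum(self, cls: str) -> float:
        """Expected summed peak conductance per postsynaptic cell (nS)."""
        pre, post = self.edges[cls]
        n_targets = {"EI": self.n_i, "IE": self.n_e, "II": self.n_i}[cls]
        active = post < n_targets
        if not active.any():
            return 0.0
        return float(self.weights[cls][active].sum() / n_targets)

    def copy(self) -> "Network":
        return Network(
            config=dataclasses.replace(self.config),
            seed=self.seed,
            params_i=list(self.params_i),
            params_e=list(self.params_e),
            edges={k: (p.copy(), q.copy()) for k, (p, q) in self.edges.items()},
            weights={k: w.copy() for k, w in self.weights.items()},
            e_rev_ii=self.e_rev_ii.copy(),
        )

    # -- global cell ids: I 0..n_i-1, E n_i..n_i+n_e-1, then I readouts, E readouts
    def global_id(self, pop: str, idx: int) -> int:
        offs = {"I": 0, "E": self.n_i, "I_readout": self.n_i + self.n_e,
                "E_readout": self.n_i + self.n_e + self.n_readouts}
        return offs[pop] + idx

    def to_edge_dataframe(self) -> pd.DataFrame:
        """Edge list with global ids, class, weight and kinetics."""
        rows = []
        for cls in ("EI", "IE", "II"):
            pre, post = self.edges[cls]
            spec = self.synapse_spec(cls)
            pre_pop = "E" if cls == "EI" else "I"
            tgt_pop, n_t = (("I", self.n_i) if cls in ("EI", "II")
                            else ("E", self.n_e))
            e_rev = (self.e_rev_ii if cls == "II"
                     else np.full(len(pre), spec.e_rev))
            for k in range(len(pre)):
                p_gid = self.global_id(pre_pop, int(pre[k]))
                t = int(post[k])
                if t < n_t:
                    q_gid = self.global_id(tgt_pop, t)
                else:
                    q_gid = self.global_id(f"{tgt_pop}_readout", t - n_t)
                rows.append((p_gid, q_gid, cls, float(self.weights[cls][k]),
                             float(e_rev[k]), spec.tau_rise, spec.tau_decay))
        return pd.DataFrame(rows, columns=["pre_id", "post_id", "class",
                                           "weight_nS", "E_rev_mV",
                                           "tau_rise_ms", "tau_decay_ms"])


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def assemble_network(config: Optional[NetworkConfig] = None,
                     seed: int = 0) -> Network:
    """Build the full network for one connectivity seed.

    ``seed`` determines the conductance jitter of both populations, the
    Bernoulli adjacency, the lognormal I->E weights and (for the distributed
    variant) the per-edge GABA_A reversal potentials.
    """
    config = dataclasses.replace(config) if config is not None else NetworkConfig()
    s_jit_i, s_jit_e, s_conn, s_w, s_egaba = _subseeds(seed, 5)
    params_i = jitter_population(PopulationSpec(
        config.n_i, config.fs_params, config.jitter_cv_i, int(s_jit_i)))
    params_e = jitter_population(PopulationSpec(
        config.n_e, config.stellate_params, config.jitter_cv_e, int(s_jit_e)))
    conn = dataclasses.replace(config.connectivity, seed=int(s_conn))
    edges = sample_connectivity(conn, config.n_e, config.n_i,
                                config.n_readouts, config.n_readouts)
    if config.ei_edge_divisor <= 0:
        raise ValueError("ei_edge_divisor must be > 0")
    g_ei_edge = config.g_ei / config.ei_edge_divisor
    # I->E weights are drawn as a full matrix (active targets first, then
    # readouts) so the active-cell weights do not depend on n_readouts.
    rng_w = np.random.default_rng(int(s_w))
    sig = conn.ie_weight_sigma
    w_act = conn.ie_weight_median * np.exp(
        sig * rng_w.standard_normal((config.n_i, config.n_e)))
    w_ro = conn.ie_weight_median * np.exp(
        sig * rng_w.standard_normal((config.n_i, config.n_readouts)))
    w_full = np.hstack([w_act, w_ro])
    ie_pre, ie_post = edges["IE"]
    weights = {
        "EI": np.full(len(edges["EI"][0]), float(g_ei_edge)),
        "IE": w_full[ie_pre, ie_post],
        "II": np.full(len(edges["II"][0]), float(config.g_ii)),
    }
    n_ii = len(edges["II"][0])
    eg = config.e_gaba_ii
    if isinstance(eg, str):
        if eg != "distributed":
            raise ValueError(f"unknown e_gaba_ii variant {eg!r}")
        eg = (-75.0, -55.0)
    if isinstance(eg, tuple):
        rng = np.random.default_rng(int(s_egaba))
        e_rev_ii = rng.uniform(eg[0], eg[1], n_ii)
    else:
        e_rev_ii = np.full(n_ii, float(eg))
    return Network(config=config, seed=seed, params_i=params_i,
                   params_e=params_e, edges=edges, weights=weights,
                   e_rev_ii=e_rev_ii)


_CLASS_ALIASES = {
    "E->I": "EI", "EI": "EI", "e->i": "EI",
    "I->E": "IE", "IE": "IE", "i->e": "IE",
    "I->I": "II", "II": "II", "i->i": "II",
}


def set_class_conductance(network: Network, cls: str, g: float) -> Network:
    """Return a copy with all edges of one class rescaled to peak ``g`` (nS).

    For the uniform classes (E->I, I->I) every edge is set to ``g``; for the
    lognormal I->E class the weights are rescaled so their median equals
    ``g``, preserving the relative spread.  ``g = 0`` removes the class.
    """
    key = _CLASS_ALIASES.get(cls)
    if key is None:
        raise KeyError(f"unknown synapse class {cls!r}")
    if g < 0:
        raise ValueError("class conductance must be >= 0")
    net = network.copy()
    if key == "EI":
        cfg = net.config
        edge = g / cfg.ei_edge_divisor
        net.weights["EI"] = np.full_like(net.weights["EI"], float(edge))
        cfg.g_ei = g
        return net
    if key == "IE":
        w = net.weights["IE"]
        med = np.median(w)
        net.weights["IE"] = w * (g / med if med > 0 else 0.0)
        net.config.connectivity.ie_weight_median = g
    else:
        net.weights[key] = np.full_like(net.weights[key], float(g))
        net.config.g_ii = g
    return net
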