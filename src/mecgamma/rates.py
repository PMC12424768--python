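"""Voltage-dependent channel kinetics shared by the cell models and the network engine.

All functions take membrane potential in mV and return rates in 1/ms (or
dimensionless steady states / time constants in ms).  They are numba
``njit``-compiled with scalar/array duality, so the same compiled source
serves the Python-level cell objects and the network simulation kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "wb_m_inf",
    "wb_h_alpha",
    "wb_h_beta",
    "wb_n_alpha",
    "wb_n_beta",
    "hh_m_alpha",
    "hh_m_beta",
    "hh_h_alpha",
    "hh_h_beta",
    "hh_n_alpha",
    "hh_n_beta",
    "nap_m_inf",
    "h_r_inf",
    "h_r_tau",
]


@njit(cache=True)
def _linoid(x, k):
    """x / (1 - exp(-x/k)), regularized at the removable singularity x = 0."""
    x = np.where(x == 0.0, 1e-9, x)
    return x / (-np.expm1(-x / k))


# --- Wang-Buzsaki fast-spiking interneuron kinetics (phi applied by caller) ---

@njit(cache=True)
def wb_m_inf(v):
    a = 0.1 * _linoid(v + 35.0, 10.0)
    b = 4.0 * np.exp(-(v + 60.0) / 18.0)
    return a / (a + b)


@njit(cache=True)
def wb_h_alpha(v):
    return 0.07 * np.exp(-(v + 58.0) / 20.0)


@njit(cache=True)
def wb_h_beta(v):
    return 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))


@njit(cache=True)
def wb_n_alpha(v):
    return 0.01 * _linoid(v + 34.0, 10.0)


@njit(cache=True)
def wb_n_beta(v):
    return 0.125 * np.exp(-(v + 44.0) / 80.0)


# --- Classic Hodgkin-Huxley kinetics (resting potential shifted to ~-65 mV) ---

@njit(cache=True)
def hh_m_alpha(v):
    return 0.1 * _linoid(v + 40.0, 10.0)


@njit(cache=True)
def hh_m_beta(v):
    return 4.0 * np.exp(-(v + 65.0) / 18.0)


@njit(cache=True)
def hh_h_alpha(v):
    return 0.07 * np.exp(-(v + 65.0) / 20.0)


@njit(cache=True)
def hh_h_beta(v):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))


@njit(cache=True)
def hh_n_alpha(v):
    return 0.01 * _linoid(v + 55.0, 10.0)


@njit(cache=True)
def hh_n_beta(v):
    return 0.125 * np.exp(-(v + 65.0) / 80.0)


# --- Stellate-cell resonance currents -----------------------------------------

@njit(cache=True)
def nap_m_inf(v):
    """Persistent Na+ activation (instantaneous), Magistretti-Alonso-type."""
    return 1.0 / (1.0 + np.exp(-(v + 48.7) / 4.4))


@njit(cache=True)
def h_r_inf(v):
    """HCN (h-current) activation steady state."""
    return 1.0 / (1.0 + np.exp((v + 79.2) / 9.78))


@njit(cache=True)
def h_r_tau(v):
    """HCN activation time constant (ms); ~80 ms near rest (fast component)."""
    return 0.51 / (np.exp((v - 1.7) / 10.0) + np.exp(-(v + 340.0) / 52.0)) + 1.0
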