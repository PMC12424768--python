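"""Spike-train analysis: detection, theta-phase histograms, interspike-rate
histograms and per-cycle firing statistics.

Phase 0 of the theta cycle is the trough of the optogenetic conductance
drive (zero conductance); cycle windows are [k/f, (k+1)/f) with cycle 0
discarded, matching the scalogram convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "PhaseHistogram",
    "ISIRateHistogram",
    "detect_spikes",
    "phase_histogram",
    "isi_rate_histogram",
    "spikes_per_cycle",
]


@dataclass
class PhaseHistogram:
    """Spike counts in 30 equal phase bins over [0, 2 pi), per theta cycle."""

    bin_edges: np.ndarray       # rad, length n_bins + 1
    counts: np.ndarray          # normalized: spikes per bin per theta cycle
    n_cycles: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "bin_right": self.bin_edges[1:],
                             "normalized_count": self.counts})


@dataclass
class ISIRateHistogram:
    """Instantaneous rate (1/ISI) histogram with 10 Hz bins, per theta cycle."""

    bin_edges: np.ndarray       # Hz
    counts: np.ndarray
    n_cycles: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "bin_right": self.bin_edges[1:],
                             "normalized_count": self.counts})


def detect_spikes(voltage_mv, fs: float, threshold_mv: float = 0.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Action-potential peak times (ms): local maxima above threshold with
    refractory separation."""
    v = np.asarray(voltage_mv, dtype=float)
    distance = max(1, int(round(refractory_ms * fs / 1000.0)))
    peaks, _ = scipy.signal.find_peaks(v, height=threshold_mv,
                                       distance=distance)
    return peaks * 1000.0 / fs


def _analysis_window(spike_times_ms, f_theta: float, n_cycles: int,
                     drop_first: bool) -> np.ndarray:
    t = np.asarray(spike_times_ms, dtype=float)
    period = 1000.0 / f_theta
    t0 = period if drop_first else 0.0
    t1 = t0 + n_cycles * period
    return t[(t >= t0) & (t < t1)]


def phase_histogram(spike_times_ms, f_theta: float = 8.0, n_cycles: int = 40,
                    drop_first: bool = True, n_bins: int = 30) -> PhaseHistogram:
    """Theta-phase histogram: phase = 2 pi frac(t * f); counts / n_cycles."""
    t = _analysis_window(spike_times_ms, f_theta, n_cycles, drop_first)
    phases = 2 * np.pi * np.mod(t * f_theta / 1000.0, 1.0)
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return PhaseHistogram(edges, counts / n_cycles, n_cycles)


def isi_rate_histogram(spike_times_ms, n_cycles: int = 40,
                       f_theta: float = 8.0, drop_first: bool = True,
                       bin_hz: float = 10.0,
                       max_hz: float = 500.0) -> ISIRateHistogram:
    """Histogram of instantaneous rates 1000/ISI (Hz) in left-closed 10 Hz bins.

    Fewer than two spikes in the analysis window yield an empty (all-zero)
    histogram.  Rates at or above ``max_hz`` fall in the last bin.
    """
    t = _analysis_window(spike_times_ms, f_theta, n_cycles, drop_first)
    edges = np.arange(0.0, max_hz + bin_hz, bin_hz)
    if len(t) < 2:
        return ISIRateHistogram(edges, np.zeros(len(edges) - 1), n_cycles)
    rates = 1000.0 / np.diff(np.sort(t))
    rates = np.clip(rates, None, max_hz - 1e-9)
    counts, _ = np.histogram(rates, bins=edges)
    return ISIRateHistogram(edges, counts / n_cycles, n_cycles)


def spikes_per_cycle(spike_times_ms, n_cycles: int = 40,
                     f_theta: float = 8.0,
                     drop_first: bool = True) -> Tuple[float, float]:
    """Mean spikes per theta cycle and its SEM across cycles."""
    t = _analysis_window(spike_times_ms, f_theta, n_cycles, drop_first)
    period = 1000.0 / f_theta
    t0 = period if drop_first else 0.0
    cycle_idx = ((t - t0) // period).astype(int)
    counts = np.bincount(cycle_idx, minlength=n_cycles)[:n_cycles]
    mean = float(counts.mean())
    sem = float(counts.std(ddof=1) / np.sqrt(n_cycles)) if n_cycles > 1 else 0.0
    return mean, sem
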