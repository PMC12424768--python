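"""Time-frequency analysis of clamp-current traces.

Pipeline (matching the experimental current analysis): zero-phase 4th-order
Butterworth band-pass (50-200 Hz, applied forward and reversed), analytic
Morlet scalogram (omega0 = 6, 32 scales per octave), segmentation into theta
cycles with the first cycle discarded and artifact cycles (|I| > 3000 pA)
removed, cycle-averaged power, and extraction of the peak-gamma summary
(frequency, power, FWHM bandwidth, SNR) with the exclusion rules used for
the Thy1 and PV experiment modes.

Scalogram normalization: wavelets are scaled so that a pure sinusoid of
amplitude ``a`` (pA) yields peak power ``a**2`` (pA^2) at its frequency --
the envelope-amplitude-squared convention that makes the absolute pA^2
exclusion thresholds meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.fft
import scipy.signal

__all__ = [
    "FilterSpec",
    "ScalogramSpec",
    "GammaPeakSummary",
    "ExclusionCriteria",
    "ExclusionDecision",
    "CycleScalogram",
    "zero_phase_bandpass",
    "morlet_cwt",
    "cycle_scalograms",
    "peak_gamma",
    "apply_exclusions",
    "analyze_trace",
    "scalogram_to_hdf5",
    "summaries_to_csv",
    "EmptyScalogramError",
    "FlatScalogramError",
]


class EmptyScalogramError(ValueError):
    """Every theta cycle was excluded; no average scalogram exists."""


class FlatScalogramError(ValueError):
    """The average scalogram is flat; the peak is undefined."""


@dataclass
class FilterSpec:
    """Zero-phase Butterworth band-pass specification."""

    band: Tuple[float, float] = (50.0, 200.0)   # Hz
    order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")


@dataclass
class ScalogramSpec:
    """Analytic Morlet scalogram settings."""

    omega0: float = 6.0
    scales_per_octave: int = 32
    f_min: float = 40.0     # Hz, grid covers the filter band with margin
    f_max: float = 250.0    # Hz

    def frequencies(self) -> np.ndarray:
        """Geometric frequency grid at ``scales_per_octave`` per octave."""
        n = int(np.floor(np.log2(self.f_max / self.f_min)
                         * self.scales_per_octave)) + 1
        return self.f_min * 2.0 ** (np.arange(n) / self.scales_per_octave)


@dataclass
class GammaPeakSummary:
    """Peak of the cycle-averaged scalogram within the gamma band."""

    peak_frequency: float   # Hz
    peak_power: float       # pA^2
    bandwidth: float        # Hz, FWHM in frequency at the peak time bin
    snr: float              # peak power / mean power over the scalogram
    n_cycles_used: int
    peak_phase: float = 0.0  # rad, theta phase of the peak time bin


@dataclass
class ExclusionCriteria:
    """Recording-quality thresholds (Thy1 / PV experiment modes)."""

    min_power_thy1: float = 20.0    # pA^2
    min_power_pv: float = 10.0      # pA^2
    max_bandwidth_thy1: float = 100.0   # Hz
    max_bandwidth_pv: float = 110.0     # Hz
    min_snr: float = 5.0
    artifact_amplitude: float = 3000.0  # pA, per-cycle rejection

    def min_power(self, mode: str) -> float:
        return {"thy1": self.min_power_thy1, "pv": self.min_power_pv}[mode]

    def max_bandwidth(self, mode: str) -> float:
        return {"thy1": self.max_bandwidth_thy1,
                "pv": self.max_bandwidth_pv}[mode]


@dataclass
class ExclusionDecision:
    keep: bool
    reason: Optional[str] = None    # "power" | "bandwidth" | "snr"


@dataclass
class CycleScalogram:
    """Per-theta-cycle scalograms and their cycle-average."""

    freqs_hz: np.ndarray        # (n_f,)
    cycle_time_ms: np.ndarray   # (n_t,) time within the theta cycle
    average: np.ndarray         # (n_f, n_t) cycle-averaged power, pA^2
    per_cycle: np.ndarray       # (n_cycles, n_f, n_t) retained cycles
    kept_cycles: np.ndarray     # indices of retained cycles (0 = first)
    n_cycles_used: int
    f_theta: float


def zero_phase_bandpass(trace, fs: float,
                        spec: Optional[FilterSpec] = None) -> np.ndarray:
    """Forward-and-reverse (zero net phase) Butterworth band-pass."""
    spec = spec if spec is not None else FilterSpec()
    lo, hi = spec.band
    if fs <= 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz too low for band edge {hi} Hz")
    sos = scipy.signal.butter(spec.order, spec.band, btype="bandpass",
                              fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def morlet_cwt(trace, fs: float, freqs_hz, omega0: float = 6.0) -> np.ndarray:
    """Analytic Morlet CWT power, shape (n_f, n_t).

    Computed in the frequency domain: W_f = ifft( X(w) * 2 exp(-(s w - w0)^2/2) )
    restricted to positive frequencies, with s = omega0 / (2 pi f).  A tone
    of amplitude ``a`` at frequency f yields |W| = a, hence power a^2.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    s_max = omega0 / (2 * np.pi * freqs_hz.min())
    nfft = scipy.fft.next_fast_len(n + int(np.ceil(8 * s_max * fs)))
    X = scipy.fft.fft(x, nfft)
    w = 2 * np.pi * scipy.fft.fftfreq(nfft, 1.0 / fs)
    power = np.empty((len(freqs_hz), n))
    pos = w > 0
    for j, f in enumerate(freqs_hz):
        s = omega0 / (2 * np.pi * f)
        win = np.zeros(nfft)
        win[pos] = 2.0 * np.exp(-0.5 * (s * w[pos] - omega0) ** 2)
        W = scipy.fft.ifft(X * win)[:n]
        power[j] = np.abs(W) ** 2
    return power


def cycle_scalograms(trace, fs: float, f_theta: float = 8.0,
                     spec: Optional[ScalogramSpec] = None,
                     criteria: Optional[ExclusionCriteria] = None,
                     artifact_trace=None,
                     drop_first: bool = True) -> CycleScalogram:
    """Morlet scalogram segmented into theta cycles, averaged over retained ones.

    The first cycle is dropped (the network/recording settles during it);
    cycles whose raw current exceeds the artifact amplitude are dropped.
    ``artifact_trace`` is the unfiltered trace used for artifact detection
    (defaults to ``trace`` itself).

    Raises :class:`EmptyScalogramError` if every cycle is excluded.
    """
    spec = spec if spec is not None else ScalogramSpec()
    criteria = criteria if criteria is not None else ExclusionCriteria()
    x = np.asarray(trace, dtype=float)
    raw = x if artifact_trace is None else np.asarray(artifact_trace, float)
    if len(raw) != len(x):
        raise ValueError("artifact_trace must have the same length as trace")
    spc = int(round(fs / f_theta))          # samples per theta cycle
    n_cycles = len(x) // spc
    first = 1 if drop_first else 0
    if n_cycles < first + 1:
        raise ValueError("trace spans too few theta cycles")
    freqs = spec.frequencies()
    power = morlet_cwt(x, fs, freqs, spec.omega0)
    kept = []
    for c in range(first, n_cycles):
        seg = raw[c * spc:(c + 1) * spc]
        if np.max(np.abs(seg)) > criteria.artifact_amplitude:
            continue
        kept.append(c)
    if not kept:
        raise EmptyScalogramError("all theta cycles excluded")
    per_cycle = np.stack([power[:, c * spc:(c + 1) * spc] for c in kept])
    return CycleScalogram(
        freqs_hz=freqs,
        cycle_time_ms=np.arange(spc) * 1000.0 / fs,
        average=per_cycle.mean(axis=0),
        per_cycle=per_cycle,
        kept_cycles=np.asarray(kept),
        n_cycles_used=len(kept),
        f_theta=f_theta,
    )


def peak_gamma(cs: CycleScalogram,
               band: Tuple[float, float] = (50.0, 200.0)) -> GammaPeakSummary:
    """Peak of the cycle-averaged scalogram restricted to the filter band.

    SNR is the peak power divided by the mean of the cycle-averaged power
    over all computed scales and times; bandwidth is the full width at half
    maximum along frequency through the peak's time bin (clipped at the
    frequency-grid edges when the half-maximum is not crossed).
    """
    in_band = (cs.freqs_hz >= band[0]) & (cs.freqs_hz <= band[1])
    if not in_band.any():
        raise ValueError("frequency grid does not cover the requested band")
    sub = cs.average[in_band]
    total_mean = cs.average.mean()
    if total_mean <= 0 or np.ptp(cs.average) == 0:
        raise FlatScalogramError("flat scalogram: peak undefined")
    jf, jt = np.unravel_index(np.argmax(sub), sub.shape)
    band_freqs = cs.freqs_hz[in_band]
    peak_f = float(band_freqs[jf])
    peak_p = float(sub[jf, jt])
    # FWHM over the full frequency grid at the peak's time bin
    profile = cs.average[:, jt]
    jf_full = int(np.flatnonzero(in_band)[jf])
    half = peak_p / 2.0
    lo = 0
    for j in range(jf_full, -1, -1):
        if profile[j] < half:
            lo = j
            break
    hi = len(profile) - 1
    for j in range(jf_full, len(profile)):
        if profile[j] < half:
            hi = j
            break
    bandwidth = float(cs.freqs_hz[hi] - cs.freqs_hz[lo])
    phase = 2 * np.pi * cs.cycle_time_ms[jt] / (1000.0 / cs.f_theta)
    return GammaPeakSummary(
        peak_frequency=peak_f,
        peak_power=peak_p,
        bandwidth=bandwidth,
        snr=float(peak_p / total_mean),
        n_cycles_used=cs.n_cycles_used,
        peak_phase=float(phase),
    )


def apply_exclusions(summary: GammaPeakSummary,
                     criteria: Optional[ExclusionCriteria] = None,
                     mode: str = "thy1") -> ExclusionDecision:
    """Keep/drop decision for a recording, with the dominating reason."""
    criteria = criteria if criteria is not None else ExclusionCriteria()
    if mode not in ("thy1", "pv"):
        raise ValueError("mode must be 'thy1' or 'pv'")
    if summary.peak_power < criteria.min_power(mode):
        return ExclusionDecision(False, "power")
    if summary.bandwidth > criteria.max_bandwidth(mode):
        return ExclusionDecision(False, "bandwidth")
    if summary.snr < criteria.min_snr:
        return ExclusionDecision(False, "snr")
    return ExclusionDecision(True)


def scalogram_to_hdf5(cs: CycleScalogram, path) -> None:
    """Write a cycle scalogram (freqs, in-cycle times, power, cycle mask)."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("freqs_hz", data=cs.freqs_hz)
        f.create_dataset("cycle_time_ms", data=cs.cycle_time_ms)
        f.create_dataset("power_pa2", data=cs.average)
        f.create_dataset("per_cycle_power_pa2", data=cs.per_cycle)
        f.create_dataset("kept_cycles", data=cs.kept_cycles)
        f.attrs["f_theta_hz"] = cs.f_theta
        f.attrs["n_cycles_used"] = cs.n_cycles_used


def summaries_to_csv(rows, path) -> None:
    """Write (cell_id, summary, decision) records as a summary table."""
    import pandas as pd
    out = []
    for cell_id, summary, decision in rows:
        out.append({
            "cell_id": cell_id,
            "peak_Hz": summary.peak_frequency,
            "power_pA2": summary.peak_power,
            "bandwidth_Hz": summary.bandwidth,
            "snr": summary.snr,
            "kept": decision.keep,
            "reason": decision.reason,
        })
    pd.DataFrame(out).to_csv(path, index=False)


def analyze_trace(raw_trace, fs: float, f_theta: float = 8.0,
                  mode: str = "thy1",
                  filter_spec: Optional[FilterSpec] = None,
                  scalogram_spec: Optional[ScalogramSpec] = None,
                  criteria: Optional[ExclusionCriteria] = None,
                  drop_first: bool = True):
    """Full current-trace pipeline: filter -> cycle scalogram -> peak -> rules.

    Returns ``(summary, decision, cycle_scalogram)``.
    """
    criteria = criteria if criteria is not None else ExclusionCriteria()
    filt = zero_phase_bandpass(raw_trace, fs, filter_spec)
    cs = cycle_scalograms(filt, fs, f_theta, scalogram_spec, criteria,
                          artifact_trace=raw_trace, drop_first=drop_first)
    band = filter_spec.band if filter_spec is not None else (50.0, 200.0)
    summary = peak_gamma(cs, band)
    decision = apply_exclusions(summary, criteria, mode)
    return summary, decision, cs
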