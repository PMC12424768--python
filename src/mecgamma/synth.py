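"""Ground-truth synthetic signals for testing the analysis pipeline.

Emulates the statistical structure of recorded clamp currents during theta
drive -- a gamma-band carrier gated by a raised-cosine theta envelope, plus
broadband noise and optional large per-cycle artifacts -- and phase-locked
spike trains with closed-form histogram expectations.  Every fixture
carries its generating parameters so analysis tests assert recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["SynthTraceSpec", "make_theta_nested_gamma",
           "make_phase_locked_spikes", "fixture_to_hdf5"]


@dataclass
class SynthTraceSpec:
    """Theta-nested gamma current trace parameters."""

    f_theta: float = 8.0            # Hz
    f_gamma: float = 125.0          # Hz
    amplitude: float = 100.0        # pA, gamma carrier peak (at envelope max)
    noise_sd: float = 0.0           # pA, white noise
    noise_color: Optional[float] = None   # 1/f^alpha exponent; None => white
    artifact_cycles: Sequence[Tuple[int, float]] = ()  # (cycle index, pA)
    n_cycles: int = 41
    fs: float = 10000.0             # Hz

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.f_gamma:
            raise ValueError("fs must exceed twice the gamma frequency")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")


def make_theta_nested_gamma(spec: SynthTraceSpec, seed: int = 0):
    """Trace I(t) = A env(t) sin(2 pi f_gamma t) + noise + artifacts.

    ``env`` is the raised-cosine theta gate (0 at cycle boundaries, 1 at
    mid-cycle).  Artifacts are 5 ms rectangular pulses of the stated
    amplitude at the middle of the listed cycles.  Returns ``(t_ms, trace,
    ground_truth)`` where ``ground_truth`` records every generating
    parameter plus the seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.n_cycles * spec.fs / spec.f_theta))
    t_s = np.arange(n) / spec.fs
    env = 0.5 * (1.0 - np.cos(2 * np.pi * spec.f_theta * t_s))
    x = spec.amplitude * env * np.sin(2 * np.pi * spec.f_gamma * t_s)
    if spec.noise_sd > 0:
        white = rng.standard_normal(n)
        if spec.noise_color is None:
            x = x + spec.noise_sd * white
        else:
            # shape the spectrum as 1/f^(alpha/2) in amplitude, renormalize sd
            W = np.fft.rfft(white)
            f = np.fft.rfftfreq(n, 1.0 / spec.fs)
            f[0] = f[1]
            W = W / f ** (spec.noise_color / 2.0)
            colored = np.fft.irfft(W, n)
            colored *= spec.noise_sd / colored.std()
            x = x + colored
    spc = int(round(spec.fs / spec.f_theta))
    half_pulse = max(1, int(round(0.0025 * spec.fs)))
    for cyc, amp in spec.artifact_cycles:
        mid = cyc * spc + spc // 2
        x[max(0, mid - half_pulse):mid + half_pulse] += amp
    ground_truth = {**asdict(spec), "seed": seed}
    ground_truth["artifact_cycles"] = list(map(tuple, spec.artifact_cycles))
    return t_s * 1000.0, x, ground_truth


def make_phase_locked_spikes(f_theta: float = 8.0,
                             spikes_per_cycle="poisson",
                             rate_per_cycle: float = 2.4,
                             phase_center: float = np.pi,
                             phase_kappa: Optional[float] = None,
                             intraburst_hz: Optional[float] = None,
                             n_cycles: int = 41,
                             seed: int = 0) -> np.ndarray:
    """Spike times (ms) with per-cycle counts and phases of known law.

    ``spikes_per_cycle``: "poisson" (mean ``rate_per_cycle``) or an integer
    fixed count.  Phases are fixed at ``phase_center`` (``phase_kappa`` is
    None) or von-Mises distributed around it.  If ``intraburst_hz`` is set,
    the spikes of a cycle form a burst with that instantaneous rate starting
    at the sampled phase; otherwise each spike gets an independent phase.
    """
    rng = np.random.default_rng(seed)
    period = 1000.0 / f_theta
    times = []
    for c in range(n_cycles):
        if spikes_per_cycle == "poisson":
            k = rng.poisson(rate_per_cycle)
        else:
            k = int(spikes_per_cycle)
        if k == 0:
            continue
        if intraburst_hz:
            ph = (rng.vonmises(phase_center - np.pi, phase_kappa) + np.pi
                  if phase_kappa else phase_center)
            t0 = c * period + ph / (2 * np.pi) * period
            times.extend(t0 + np.arange(k) * 1000.0 / intraburst_hz)
        else:
            if phase_kappa:
                ph = rng.vonmises(phase_center - np.pi, phase_kappa, k) + np.pi
            else:
                ph = np.full(k, phase_center)
            times.extend(c * period + ph / (2 * np.pi) * period)
    return np.sort(np.asarray(times))


def fixture_to_hdf5(path, t_ms, trace, ground_truth: dict) -> None:
    """Persist a synthetic trace with its generating parameters attached."""
    import json

    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("t_ms", data=t_ms)
        f.create_dataset("trace_pa", data=trace)
        f.attrs["ground_truth"] = json.dumps(ground_truth)
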