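"""In-silico experiments: E->I conductance sweeps across connectivity seeds,
simulated AMPA blockade (the in-silico DNQX analog), GABA_A reversal-potential
variants, ING/PING regime classification, and the estimation of the
physiological E->I conductance range from excitatory currents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .network import NetworkConfig, assemble_network, set_class_conductance
from .engine import SimConfig, run
from .spectral import (GammaPeakSummary, ExclusionCriteria, analyze_trace,
                       EmptyScalogramError, FlatScalogramError)

__all__ = [
    "REGIME_THRESHOLD_HZ",
    "ConditionResult",
    "SweepTable",
    "PairedBlockResult",
    "simulate_condition",
    "run_ei_sweep",
    "simulate_ampa_block",
    "run_egaba_variants",
    "classify_regime",
    "estimate_physiological_gei",
]

# Midpoint between the slow PING band (60-80 Hz) and the fast ING band
# (~100-140 Hz); configurable in every classification call.
REGIME_THRESHOLD_HZ = 90.0

DESK_SCALE_CYCLES = 11      # 1 discarded + 10 analyzed
FULL_SCALE_CYCLES = 41      # 1 discarded + 40 analyzed


@dataclass
class ConditionResult:
    """One simulated condition analyzed from the E-readout clamp currents."""

    g_ei: float
    seed: int
    blocked: bool
    summary: Optional[GammaPeakSummary]       # first E readout
    kept: bool
    reason: Optional[str]
    summaries_all: list                       # one per E readout
    regime: Optional[str]
    status: str = "ok"                        # "ok" | "failed"
    result: object = None                     # SimResult if keep_result


def simulate_condition(g_ei: float, seed: int, *,
                       n_cycles: int = DESK_SCALE_CYCLES,
                       e_gaba_ii: Union[float, str, tuple] = -75.0,
                       block_ei: bool = False,
                       base_config: Optional[NetworkConfig] = None,
                       sim_seed: Optional[int] = None,
                       mode: str = "thy1",
                       criteria: Optional[ExclusionCriteria] = None,
                       regime_threshold: float = REGIME_THRESHOLD_HZ,
                       keep_result: bool = False,
                       record_v: Tuple[int, ...] = ()) -> ConditionResult:
    """Assemble, simulate and analyze one network condition.

    ``seed`` fixes the connectivity/heterogeneity; ``sim_seed`` (defaults to
    ``seed``) fixes the drive noise and initial conditions, so a control and
    a ``block_ei=True`` run with the same seeds differ only in the E->I
    conductance (paired-run discipline).
    """
    cfg = dataclasses.replace(base_config) if base_config is not None \
        else NetworkConfig()
    cfg.g_ei = float(g_ei)
    cfg.e_gaba_ii = e_gaba_ii
    net = assemble_network(cfg, seed)
    if block_ei:
        net = set_class_conductance(net, "E->I", 0.0)
    sim_cfg = SimConfig(n_theta_cycles=n_cycles,
                        seed=seed if sim_seed is None else sim_seed,
                        record_v=tuple(record_v))
    try:
        res = run(net, sim_cfg)
    except RuntimeError:
        return ConditionResult(g_ei, seed, block_ei, None, False, "failed",
                               [], None, status="failed")
    summaries = []
    decisions = []
    for j in range(net.n_readouts):
        try:
            s, d, _ = analyze_trace(res.clamp_e_pa[j], res.fs_hz,
                                    cfg.f_theta, mode=mode, criteria=criteria)
        except (EmptyScalogramError, FlatScalogramError):
            s, d = None, None
        summaries.append(s)
        decisions.append(d)
    s0, d0 = summaries[0], decisions[0]
    kept = bool(d0.keep) if d0 is not None else False
    regime = classify_regime(s0, regime_threshold) if (s0 and kept) else None
    return ConditionResult(
        g_ei=float(g_ei), seed=seed, blocked=block_ei, summary=s0,
        kept=kept, reason=(d0.reason if d0 else "empty"),
        summaries_all=summaries, regime=regime,
        result=res if keep_result else None)


@dataclass
class SweepTable:
    """Per-(seed, conductance) peak-gamma records plus box statistics."""

    df: pd.DataFrame

    def box_stats(self, column: str = "peak_hz") -> pd.DataFrame:
        """Median, quartiles and whiskers per swept conductance value."""
        def stats(x):
            x = x.dropna()
            q1, med, q3 = np.percentile(x, [25, 50, 75]) if len(x) else (np.nan,) * 3
            return pd.Series({"median": med, "q1": q1, "q3": q3,
                              "lo": x.min() if len(x) else np.nan,
                              "hi": x.max() if len(x) else np.nan,
                              "n": len(x)})
        return self.df.groupby("g_ei")[column].apply(stats).unstack()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _condition_row(c: ConditionResult) -> dict:
    s = c.summary
    med_all = np.median([x.peak_frequency for x in c.summaries_all if x]) \
        if any(c.summaries_all) else np.nan
    return {
        "seed": c.seed, "g_ei": c.g_ei, "blocked": c.blocked,
        "peak_hz": s.peak_frequency if s else np.nan,
        "power_pa2": s.peak_power if s else np.nan,
        "bandwidth_hz": s.bandwidth if s else np.nan,
        "snr": s.snr if s else np.nan,
        "peak_hz_readout_median": med_all,
        "kept": c.kept, "reason": c.reason,
        "regime": c.regime, "status": c.status,
    }


def run_ei_sweep(g_values: Sequence[float] = (3.6, 6, 8, 10, 12, 14, 18),
                 seeds: Sequence[int] = tuple(range(10)), *,
                 n_cycles: int = DESK_SCALE_CYCLES,
                 e_gaba_ii: Union[float, str, tuple] = -75.0,
                 base_config: Optional[NetworkConfig] = None,
                 regime_threshold: float = REGIME_THRESHOLD_HZ,
                 mode: str = "thy1") -> SweepTable:
    """E->I conductance sweep across connectivity seeds.

    For each (seed, g) pair: full simulation, first-E-readout clamp current,
    scalogram, peak-gamma summary and regime label.  Runs that fail
    numerically are recorded with status "failed", never silently dropped.
    """
    rows = []
    for g in g_values:
        for seed in seeds:
            c = simulate_condition(g, seed, n_cycles=n_cycles,
                                   e_gaba_ii=e_gaba_ii,
                                   base_config=base_config,
                                   regime_threshold=regime_threshold,
                                   mode=mode)
            rows.append(_condition_row(c))
    return SweepTable(pd.DataFrame(rows))


@dataclass
class PairedBlockResult:
    """Control vs E->I-removed (simulated DNQX) pair with identical seeds."""

    control: ConditionResult
    blocked: ConditionResult

    @property
    def delta_frequency_hz(self) -> float:
        return (self.blocked.summary.peak_frequency
                - self.control.summary.peak_frequency)

    @property
    def power_ratio(self) -> float:
        return self.blocked.summary.peak_power / self.control.summary.peak_power


def simulate_ampa_block(g_ei: float, seed: int, *,
                        n_cycles: int = DESK_SCALE_CYCLES,
                        e_gaba_ii: Union[float, str, tuple] = -75.0,
                        base_config: Optional[NetworkConfig] = None,
                        mode: str = "thy1",
                        keep_results: bool = False) -> PairedBlockResult:
    """Paired control / E->I-removed runs with identical connectivity and
    noise realization."""
    kw = dict(n_cycles=n_cycles, e_gaba_ii=e_gaba_ii,
              base_config=base_config, mode=mode, keep_result=keep_results)
    return PairedBlockResult(
        control=simulate_condition(g_ei, seed, block_ei=False, **kw),
        blocked=simulate_condition(g_ei, seed, block_ei=True, **kw))


def run_egaba_variants(g_ei: float = 120.0,
                       variants: Sequence = (-75.0, "distributed", -55.0),
                       seeds: Sequence[int] = (0,), *,
                       n_cycles: int = DESK_SCALE_CYCLES,
                       base_config: Optional[NetworkConfig] = None,
                       mode: str = "thy1") -> pd.DataFrame:
    """GABA_A reversal-potential variants under strong E->I coupling.

    For each variant (hyperpolarizing -75 mV, distributed U(-75, -55) mV,
    shunting -55 mV) a control and an AMPA-blocked run with identical seeds.
    """
    rows = []
    for variant in variants:
        for seed in seeds:
            pair = simulate_ampa_block(g_ei, seed, n_cycles=n_cycles,
                                       e_gaba_ii=variant,
                                       base_config=base_config, mode=mode)
            label = variant if isinstance(variant, str) else f"{variant:g}"
            for c in (pair.control, pair.blocked):
                row = _condition_row(c)
                row["e_gaba_ii"] = label
                rows.append(row)
    return pd.DataFrame(rows)


def classify_regime(summary_or_freq,
                    threshold_hz: float = REGIME_THRESHOLD_HZ) -> str:
    """"PING-dominant" iff the peak frequency is below threshold, else
    "ING-dominant" (peaks exactly at threshold count as ING)."""
    f = getattr(summary_or_freq, "peak_frequency", summary_or_freq)
    if f is None or not np.isfinite(f):
        raise ValueError("cannot classify an excluded/undefined summary")
    return "PING-dominant" if f < threshold_hz else "ING-dominant"


def estimate_physiological_gei(trace_pa, fs: float, *,
                               v_hold: float = -70.0, e_ampa: float = 0.0,
                               f_theta: float = 8.0,
                               drop_first: bool = True) -> Tuple[float, float]:
    """Physiological E->I conductance range from an excitatory current trace.

    Per theta cycle, the peak-to-peak amplitude of the (band-passed) current
    divided by the driving force |V_hold - E_AMPA| gives a conductance; the
    (min, max) over cycles is returned in nS.  A 350 pA swing at -70 mV
    holding is 5 nS.
    """
    x = np.asarray(trace_pa, dtype=float)
    spc = int(round(fs / f_theta))
    n_cycles = len(x) // spc
    first = 1 if drop_first else 0
    drive = abs(v_hold - e_ampa)
    if n_cycles <= first:
        raise ValueError("trace spans too few theta cycles")
    g = [np.ptp(x[c * spc:(c + 1) * spc]) / drive
         for c in range(first, n_cycles)]
    return float(np.min(g)), float(np.max(g))
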