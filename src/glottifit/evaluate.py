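"""Symmetry, success criteria and descriptive group summaries.

A fitted subject is rated *successful* when three criteria hold
simultaneously:

1. the fundamental frequency of the fitted model deviates from the
   recorded trajectory by at most 5% on each side;
2. the model reproduces the presence (or absence) of glottal closure seen
   in the recording;
3. on each side, the model's representative (median) per-cycle peak
   amplitude lies within the min–max envelope of the recorded per-cycle
   peaks.

Left–right asymmetry of the fitted biomechanics is summarized by the
symmetry quotient Q_lr = max(Q_l, Q_r)/min(Q_l, Q_r) ≥ 1 (1 = perfectly
symmetric folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .signals import (
    DEFAULT_CLOSURE_FRACTION,
    TrajectoryPair,
    cycle_statistics,
    detect_closure,
    fundamental_frequency,
)

__all__ = [
    "symmetry_quotient",
    "frequency_deviation",
    "SuccessReport",
    "assess_success",
    "GroupSummary",
    "summarize_group",
]

#: maximal admissible per-side frequency deviation, percent
MAX_FREQUENCY_DEVIATION_PCT = 5.0


def symmetry_quotient(ql: float, qr: float) -> float:
    """Q_lr = max(Q_l, Q_r) / min(Q_l, Q_r); 1 means perfect symmetry."""
    if ql <= 0 or qr <= 0:
        raise DomainError("scaling factors must be strictly positive")
    return max(ql, qr) / min(ql, qr)


def frequency_deviation(f_e: float, f_m: float) -> float:
    """Relative deviation 100·|f_M − f_E|/f_E in percent."""
    if f_e <= 0:
        raise DomainError("experimental frequency must be positive")
    return 100.0 * abs(f_m - f_e) / f_e


@dataclass(frozen=True)
class SuccessReport:
    """Outcome of the three success criteria for one fitted subject."""

    frequency_ok: bool
    closure_ok: bool
    amplitude_ok: bool
    freq_deviation_l: float
    freq_deviation_r: float
    exp_amplitude_range_l: tuple[float, float]
    exp_amplitude_range_r: tuple[float, float]
    model_amplitude_l: float
    model_amplitude_r: float

    @property
    def success(self) -> bool:
        return self.frequency_ok and self.closure_ok and self.amplitude_ok

    def to_dict(self) -> dict:
        return {
            "frequency": self.frequency_ok,
            "closure": self.closure_ok,
            "amplitude": self.amplitude_ok,
            "success": self.success,
            "freq_deviation_pct": [self.freq_deviation_l, self.freq_deviation_r],
            "exp_amplitude_range": [
                list(self.exp_amplitude_range_l),
                list(self.exp_amplitude_range_r),
            ],
            "model_amplitude": [self.model_amplitude_l, self.model_amplitude_r],
        }


def assess_success(
    t_e: TrajectoryPair,
    t_m: TrajectoryPair,
    max_freq_dev_pct: float = MAX_FREQUENCY_DEVIATION_PCT,
    closure_fraction: float = DEFAULT_CLOSURE_FRACTION,
) -> SuccessReport:
    """Evaluate the three success criteria on a fitted subject.

    The frequency criterion is enforced on both sides (the stricter
    reading); the amplitude criterion compares the model's median per-cycle
    peak against the experimental min–max peak envelope, inclusive at the
    boundaries.
    """
    devs = {}
    amp_ok = True
    exp_ranges = {}
    model_amp = {}
    for (side, e), (_, m) in zip(t_e.sides(), t_m.sides()):
        f_e = fundamental_frequency(e, t_e.sample_rate)
        f_m = fundamental_frequency(m, t_m.sample_rate)
        devs[side] = frequency_deviation(f_e, f_m)
        e_stats = cycle_statistics(e, t_e.sample_rate, closure_fraction)
        m_stats = cycle_statistics(m, t_m.sample_rate, closure_fraction)
        lo, hi = e_stats.amplitude_range
        med = float(np.median(m_stats.peaks))
        exp_ranges[side] = (lo, hi)
        model_amp[side] = med
        amp_ok = amp_ok and (lo <= med <= hi)
    freq_ok = all(d <= max_freq_dev_pct for d in devs.values())
    closure_ok = detect_closure(t_e, closure_fraction) == detect_closure(
        t_m, closure_fraction
    )
    return SuccessReport(
        frequency_ok=bool(freq_ok),
        closure_ok=bool(closure_ok),
        amplitude_ok=bool(amp_ok),
        freq_deviation_l=devs["l"],
        freq_deviation_r=devs["r"],
        exp_amplitude_range_l=exp_ranges["l"],
        exp_amplitude_range_r=exp_ranges["r"],
        model_amplitude_l=model_amp["l"],
        model_amplitude_r=model_amp["r"],
    )


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of fitted parameters for one subject group."""

    label: str
    n: int
    stats: dict = field(compare=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": self.label,
                "parameter": name,
                "mean": s["mean"],
                "sd": s["sd"],
                "min": s["min"],
                "max": s["max"],
                "n": s["n"],
            }
            for name, s in self.stats.items()
        ]
        return pd.DataFrame(rows)


def _describe(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    # single observation: SD reported as 0 by convention
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {
        "mean": float(np.mean(values)),
        "sd": sd,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "n": int(values.size),
    }


def summarize_group(fits, label: str, pool_q: bool = True) -> GroupSummary:
    """Mean/SD/min/max of Γ, P_s, Q_l, Q_r and Q_lr over successful fits.

    ``fits`` is a sequence of ``FitResult``.  With ``pool_q`` a merged
    column "Q" pools the left and right scaling factors into one sample
    (doubling n), as is customary when only the magnitude of the scaling
    matters.
    """
    fits = list(fits)
    if not fits:
        raise DomainError("cannot summarize an empty group")
    gammas = np.array([f.best.gamma for f in fits])
    ps = np.array([f.best.params.Ps for f in fits])
    ql = np.array([f.best.params.Ql for f in fits])
    qr = np.array([f.best.params.Qr for f in fits])
    qlr = np.array([symmetry_quotient(a, b) for a, b in zip(ql, qr)])
    stats = {
        "gamma": _describe(gammas),
        "Ps": _describe(ps),
        "Ql": _describe(ql),
        "Qr": _describe(qr),
        "Qlr": _describe(qlr),
    }
    if pool_q:
        stats["Q"] = _describe(np.concatenate([ql, qr]))
    return GroupSummary(label=label, n=len(fits), stats=stats)
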