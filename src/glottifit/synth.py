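"""Synthetic experimental subjects for testing and parameter recovery.

Raw endoscopic recordings behind published trajectory studies are rarely
deposited, so this module generates stand-in experimental data with known
ground truth:

* model-generated subjects — the two-mass model simulated at known
  (Q_l, Q_r, P_s), degraded with the perturbations real phonation shows but
  the time-invariant model cannot produce: per-cycle period perturbation
  (jitter, implemented as cycle-wise time warping), per-cycle amplitude
  perturbation (shimmer), additive amplitude noise, and pixel quantization;
* analytic subjects — raised, optionally clipped sinusoids, for testing
  signal and cost operations independently of the ODE core.

All generation is reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DomainError, NoOscillationError
from .model import simulate
from .parameters import FitVariables, StandardParameters
from .signals import ASSUMED_FOLD_LENGTH_CM, TrajectoryPair, normalize_sex

__all__ = [
    "SyntheticSpec",
    "generate_model_subject",
    "generate_analytic_pair",
    "draw_subject_variables",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic subject.

    ``noise`` is the additive Gaussian noise standard deviation as a
    fraction of the oscillation amplitude; ``jitter``/``shimmer`` are the
    standard deviations of the per-cycle period/amplitude perturbation
    factors; ``px_step`` (cm) quantizes samples to a pixel grid (0 = off).
    """

    fit: FitVariables
    sex: str = "F"
    noise: float = 0.0
    jitter: float = 0.0
    shimmer: float = 0.0
    px_step: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise", "jitter", "shimmer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise DomainError(f"{name} must lie in [0, 0.2], got {v}")
        if self.px_step < 0:
            raise DomainError("px_step must be non-negative")
        normalize_sex(self.sex)


def _cycle_boundaries(x: np.ndarray) -> np.ndarray:
    level = float(np.mean(x))
    idx = np.flatnonzero((x[:-1] < level) & (x[1:] >= level)) + 1
    return idx


def _warp_time(x: np.ndarray, boundaries: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Resample each cycle to a perturbed duration, back onto the uniform grid.

    Sample i gets the local rate of its cycle; the cumulative warped time is
    then inverted by cubic interpolation (linear would shave the waveform
    peaks and bias per-cycle amplitudes low).
    """
    n = x.size
    rate = np.ones(n)
    for (a, b), f in zip(zip(boundaries[:-1], boundaries[1:]), factors):
        rate[a:b] = f
    if boundaries.size >= 2:
        rate[: boundaries[0]] = factors[0]
        rate[boundaries[-1]:] = factors[-1]
    warped_t = np.concatenate([[0.0], np.cumsum(rate)[:-1]])
    uniform_t = np.arange(n, dtype=float)
    spline = CubicSpline(warped_t, x)
    t_clipped = np.clip(uniform_t, warped_t[0], warped_t[-1])
    return spline(t_clipped)


def generate_model_subject(
    spec: SyntheticSpec, std: StandardParameters | None = None
) -> tuple[TrajectoryPair, dict]:
    """Simulate a subject at known parameters and degrade it realistically.

    Returns the 400-sample/4 kHz trajectory pair plus a ground-truth record
    (true parameters, seed, applied perturbation levels).  With all
    perturbations at zero the output is exactly the model's visible-edge
    trajectories.

    Raises ``NoOscillationError`` when the true parameters are below the
    phonation threshold.
    """
    if std is None:
        std = StandardParameters().with_fold_length(
            ASSUMED_FOLD_LENGTH_CM[normalize_sex(spec.sex)]
        )
    sim = simulate(spec.fit, std)
    left, right = sim.t_ml.copy(), sim.t_mr.copy()
    if np.ptp(left) < 1e-6 and np.ptp(right) < 1e-6:
        raise NoOscillationError(
            f"parameters Ps = {spec.fit.Ps} cmH2O (Ql = {spec.fit.Ql}, "
            f"Qr = {spec.fit.Qr}) are below the phonation threshold"
        )
    rng = np.random.default_rng(spec.seed)
    gap = left + right
    boundaries = _cycle_boundaries(gap)
    n_cycles = max(boundaries.size - 1, 0)

    if spec.shimmer > 0.0 and n_cycles > 0:
        for x in (left, right):
            factors = 1.0 + rng.normal(0.0, spec.shimmer, size=n_cycles)
            offset = x.mean()
            for (a, b), f in zip(zip(boundaries[:-1], boundaries[1:]), factors):
                x[a:b] = offset + (x[a:b] - offset) * f

    if spec.jitter > 0.0 and n_cycles > 0:
        factors = 1.0 + rng.normal(0.0, spec.jitter, size=n_cycles)
        left = _warp_time(left, boundaries, factors)
        right = _warp_time(right, boundaries, factors)

    if spec.noise > 0.0:
        amp = 0.5 * (np.ptp(left) + np.ptp(right)) / 2.0
        left = left + rng.normal(0.0, spec.noise * amp, size=left.size)
        right = right + rng.normal(0.0, spec.noise * amp, size=right.size)

    left = np.maximum(left, 0.0)
    right = np.maximum(right, 0.0)

    if spec.px_step > 0.0:
        # round half away from zero on the pixel grid (applied after noise)
        left = np.floor(left / spec.px_step + 0.5) * spec.px_step
        right = np.floor(right / spec.px_step + 0.5) * spec.px_step

    truth = {
        "Ql": spec.fit.Ql,
        "Qr": spec.fit.Qr,
        "Ps_cmH2O": spec.fit.Ps,
        "sex": normalize_sex(spec.sex),
        "noise": spec.noise,
        "jitter": spec.jitter,
        "shimmer": spec.shimmer,
        "px_step": spec.px_step,
        "seed": spec.seed,
    }
    pair = TrajectoryPair(
        left=left, right=right, sample_rate=sim.output_rate, unit="cm",
        meta={"truth": truth},
    )
    return pair, truth


def generate_analytic_pair(
    f0: float,
    amp_l: float = 0.05,
    amp_r: float = 0.05,
    offset: float | None = None,
    closure_fraction: float | None = None,
    n_samples: int = 400,
    sample_rate: float = 4000.0,
    phase: float = 0.0,
    seed: int | None = None,
) -> TrajectoryPair:
    """Raised, clipped sinusoids: T_α(t) = max(0, offset + A_α·sin(2πf₀t+φ)).

    ``closure_fraction`` (fraction of each cycle spent clipped at zero) may
    be given instead of ``offset``; with neither, the offset equals the
    larger amplitude so the pair touches zero without clipping.  A seed, if
    given, randomizes the common phase.
    """
    if not 50.0 <= f0 <= 500.0:
        raise DomainError("f0 must lie in the phonatory range [50, 500] Hz")
    if seed is not None:
        phase = float(np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi))
    amp = max(amp_l, amp_r)
    if offset is None:
        if closure_fraction is not None:
            if not 0.0 <= closure_fraction < 0.5:
                raise DomainError("closure_fraction must lie in [0, 0.5)")
            # fraction q of a cycle satisfies sin θ < -offset/A
            offset = amp * np.sin(np.pi * (1.0 - 2.0 * closure_fraction) / 2.0)
        else:
            offset = amp
    t = np.arange(n_samples) / sample_rate
    s = np.sin(2.0 * np.pi * f0 * t + phase)
    return TrajectoryPair(
        left=np.maximum(offset + amp_l * s, 0.0),
        right=np.maximum(offset + amp_r * s, 0.0),
        sample_rate=sample_rate,
        unit="cm",
    )


def draw_subject_variables(
    rng: np.random.Generator,
    q_range: tuple[float, float] = (0.8, 3.3),
    ps_range: tuple[float, float] = (10.0, 35.0),
    max_qlr: float = 1.25,
    max_tries: int = 50,
    std: StandardParameters | None = None,
) -> FitVariables:
    """Draw physiologically plausible (Q_l, Q_r, P_s) that actually phonate.

    Q is drawn uniformly from the observed healthy-adult range, the
    contralateral Q within a physiologic asymmetry bound (Q_lr ≤ 1.25), and
    P_s uniformly from the observed pressure range; draws below the
    phonation threshold of the model are rejected and redrawn.
    """
    for _ in range(max_tries):
        ql = rng.uniform(*q_range)
        ratio = rng.uniform(1.0, max_qlr)
        qr = ql * ratio if rng.uniform() < 0.5 else ql / ratio
        qr = float(np.clip(qr, *q_range))
        ps = rng.uniform(*ps_range)
        fit = FitVariables(ql, qr, ps)
        try:
            generate_model_subject(SyntheticSpec(fit=fit))
        except NoOscillationError:
            continue
        return fit
    raise NoOscillationError("could not draw oscillating parameters")
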