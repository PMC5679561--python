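"""Cost functions comparing simulated and recorded trajectory pairs.

Three optimization costs are available, all non-negative and zero exactly
when model and experiment coincide under the cost's representation:

Γ₁ (frequency domain)
    Euclidean distances between the magnitudes and between the (wrapped)
    phases of the dominant experimental harmonics and the model
    coefficients at the same DFT bins; a scale factor ``s`` balances the
    magnitude against the phase contribution.

Γ₂ (time domain)
    Plain Euclidean distance between the trajectory pairs, after a common
    circular phase alignment (the model's steady-state phase is arbitrary).

Γ₃ (normalized frequency domain)
    Γ₁ with each side's magnitude vector normalized by its own dominant
    coefficient, plus a regularization term: the Euclidean distance of the
    un-normalized fundamental magnitudes of the two sides.

The final selection metric Γ is the normalized squared Euclidean distance
    Γ = ½·[ Σ(T_El−T_Ml)²/Σ T_El² + Σ(T_Er−T_Mr)²/Σ T_Er² ],
used to pick the best of several optimizer runs regardless of which cost
drove them (Γ = 0 means a perfect fit; Γ = 1 is the score of a silent
model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .signals import TrajectoryPair, select_harmonics

__all__ = [
    "CostValue",
    "align_model_to_experiment",
    "default_scale",
    "gamma1",
    "gamma2",
    "gamma3",
    "gamma_final",
    "COST_FUNCTIONS",
]


@dataclass(frozen=True)
class CostValue:
    """A non-negative cost with its labeled sub-terms for audit."""

    value: float
    components: dict

    def __float__(self) -> float:
        return self.value


def _check_compatible(t_e: TrajectoryPair, t_m: TrajectoryPair) -> None:
    if t_e.n_samples != t_m.n_samples:
        raise DomainError("experimental and model trajectories differ in length")
    if t_e.sample_rate != t_m.sample_rate:
        raise DomainError("experimental and model sampling rates differ")


def align_model_to_experiment(t_e: TrajectoryPair, t_m: TrajectoryPair) -> TrajectoryPair:
    """Circularly shift the model pair into phase with the experiment.

    A single common shift (applied to both sides) maximizing the summed
    circular cross-correlation is used; ties break to the smallest shift.
    The oscillation phase of a steady-state simulation carries no
    information, so time-domain comparisons are made after this alignment.
    """
    _check_compatible(t_e, t_m)
    n = t_e.n_samples
    cc = np.zeros(n)
    for (_, e), (_, m) in zip(t_e.sides(), t_m.sides()):
        cc += np.fft.irfft(np.fft.rfft(e) * np.conj(np.fft.rfft(m)), n=n)
    # ties within float noise break toward the smallest circular shift, so
    # exactly periodic signals (period dividing n) keep a zero shift
    cc_max = float(np.max(cc))
    near = np.flatnonzero(cc >= cc_max - 1e-9 * abs(cc_max))
    shift = int(near[np.argmin(np.minimum(near, n - near))])
    if shift == 0:
        return t_m
    return TrajectoryPair(
        left=np.roll(t_m.left, shift),
        right=np.roll(t_m.right, shift),
        sample_rate=t_m.sample_rate,
        unit=t_m.unit,
        px_scale=t_m.px_scale,
    )


def _wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (−π, π]."""
    w = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    w[np.isclose(w, -np.pi)] = np.pi
    return w


def _phase_distance(e: np.ndarray, sm: np.ndarray) -> float:
    """‖wrapped phase differences‖₂ over bins that carry actual energy.

    Selected neighbour bins of an exactly periodic signal hold only float
    noise; their phases are meaningless, so bins whose magnitude is below
    1e-9 of the dominant experimental magnitude on either side are skipped.
    """
    floor = 1e-9 * float(np.max(np.abs(e)))
    keep = (np.abs(e) > floor) & (np.abs(sm) > floor)
    if not np.any(keep):
        return 0.0
    return float(np.linalg.norm(_wrap_phase(np.angle(e[keep]) - np.angle(sm[keep]))))


def _side_coeffs(t_e: TrajectoryPair, t_m: TrajectoryPair):
    """Experimental harmonic selection and model coefficients per side."""
    out = []
    for (_, e), (_, m) in zip(t_e.sides(), t_m.sides()):
        sel = select_harmonics(e, t_e.sample_rate)
        s_coeffs = np.fft.rfft(m - m.mean())[sel.indices]
        out.append((sel, sel.coefficients, s_coeffs))
    return out


def default_scale(t_e: TrajectoryPair) -> float:
    """Default magnitude/phase balancing factor ``s`` for Γ₁ and Γ₃.

    s = (π·√L)/‖(|e₁|,…,|e_L|)‖₂ averaged over sides, so that a maximal
    phase error (π per selected bin) and a total magnitude error of the
    size of the experimental spectrum contribute comparably.
    """
    scales = []
    for _, e in t_e.sides():
        sel = select_harmonics(e, t_e.sample_rate)
        mags = np.abs(sel.coefficients)
        scales.append(np.pi * np.sqrt(mags.size) / np.linalg.norm(mags))
    return float(np.mean(scales))


def gamma1(t_e: TrajectoryPair, t_m: TrajectoryPair, s: float | None = None) -> CostValue:
    """Frequency-domain cost Γ₁ over the selected experimental harmonics."""
    _check_compatible(t_e, t_m)
    if s is None:
        s = default_scale(t_e)
    components = {}
    total = 0.0
    for side, (sel, e, sm) in zip("lr", _side_coeffs(t_e, t_m)):
        dmag = float(np.linalg.norm(np.abs(e) - np.abs(sm)))
        dph = _phase_distance(e, sm)
        components[f"magnitude_{side}"] = s * dmag
        components[f"phase_{side}"] = dph
        total += s * dmag + dph
    return CostValue(value=total, components=components)


def gamma2(t_e: TrajectoryPair, t_m: TrajectoryPair, align: bool = True) -> CostValue:
    """Time-domain cost Γ₂: per-side Euclidean distances, summed."""
    _check_compatible(t_e, t_m)
    if align:
        t_m = align_model_to_experiment(t_e, t_m)
    dl = float(np.linalg.norm(t_e.left - t_m.left))
    dr = float(np.linalg.norm(t_e.right - t_m.right))
    return CostValue(value=dl + dr, components={"euclidean_l": dl, "euclidean_r": dr})


def gamma3(t_e: TrajectoryPair, t_m: TrajectoryPair, s: float | None = None) -> CostValue:
    """Normalized frequency-domain cost Γ₃.

    As Γ₁, but each side's magnitude vector is normalized by its own
    dominant coefficient (so uniform amplitude scaling cancels), and a
    regularization term — the Euclidean distance of the un-normalized
    fundamental magnitudes over both sides — restores sensitivity to the
    absolute oscillation amplitude.
    """
    _check_compatible(t_e, t_m)
    if s is None:
        s = default_scale(t_e)
    components = {}
    total = 0.0
    reg_sq = 0.0
    for side, (sel, e, sm) in zip("lr", _side_coeffs(t_e, t_m)):
        e_mag, s_mag = np.abs(e), np.abs(sm)
        e_norm = e_mag / e_mag.max()
        s_norm = s_mag / s_mag.max() if s_mag.max() > 0 else s_mag
        dmag = float(np.linalg.norm(e_norm - s_norm))
        dph = _phase_distance(e, sm)
        components[f"magnitude_{side}"] = s * dmag
        components[f"phase_{side}"] = dph
        total += s * dmag + dph
        pos = sel.dominant_position
        reg_sq += (e_mag[pos] - s_mag[pos]) ** 2
    reg = float(np.sqrt(reg_sq))
    components["regularization"] = reg
    return CostValue(value=total + reg, components=components)


def gamma_final(t_e: TrajectoryPair, t_m: TrajectoryPair, align: bool = True) -> float:
    """Selection metric Γ: normalized squared distance averaged over sides."""
    _check_compatible(t_e, t_m)
    if align:
        t_m = align_model_to_experiment(t_e, t_m)
    total = 0.0
    for (_, e), (_, m) in zip(t_e.sides(), t_m.sides()):
        energy = float(np.sum(e**2))
        if energy <= 0.0:
            raise DomainError("experimental side has zero energy")
        total += float(np.sum((e - m) ** 2)) / energy
    return 0.5 * total


#: costs addressable by name in configuration and on the command line
COST_FUNCTIONS = {"gamma1": gamma1, "gamma2": gamma2, "gamma3": gamma3}
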