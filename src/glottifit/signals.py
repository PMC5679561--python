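"""Trajectory preprocessing and spectral/cycle feature extraction.

Experimental vocal-fold trajectories are the per-frame distances of the
left/right medial fold edge from the glottal midline, extracted from
high-speed videoendoscopy at a fixed mid-membranous position (4000 frames/s,
100 ms windows of 400 samples in the reference protocol).  This module
converts pixel-scaled trajectories to metric units, estimates per-subject
rest geometry, and computes the spectral and per-cycle features that the
cost functions and success criteria consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientCyclesError,
    NoOscillationError,
)
from .parameters import StandardParameters

#: assumed vibrating vocal-fold lengths (cm) by sex, used for the
#: pixel -> metric conversion when no calibration is available
ASSUMED_FOLD_LENGTH_CM = {"F": 1.0, "M": 1.6}

#: per-cycle gap minima below this fraction of the median peak gap count
#: as glottal closure
DEFAULT_CLOSURE_FRACTION = 0.05


def normalize_sex(sex: str) -> str:
    s = str(sex).strip().upper()[:1]
    if s not in ("F", "M"):
        raise DomainError(f"sex must be female/male (F/M), got {sex!r}")
    return s


@dataclass(frozen=True)
class TrajectoryPair:
    """Left/right medial-edge distance signals on a uniform time grid.

    Values are non-negative distances from the glottal midline, in ``unit``
    ('cm' or 'px').  Both experimental and simulated trajectories use this
    container.
    """

    left: np.ndarray
    right: np.ndarray
    sample_rate: float = 4000.0
    unit: str = "cm"
    px_scale: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        if left.ndim != 1 or right.ndim != 1 or left.size != right.size:
            raise DomainError("left/right trajectories must be 1-D and equal length")
        if left.size < 2:
            raise DomainError("trajectories need at least two samples")
        if self.sample_rate <= 0:
            raise DomainError("sample_rate must be positive")
        if (left < -1e-12).any() or (right < -1e-12).any():
            raise DomainError("trajectories must be non-negative edge distances")
        if self.unit not in ("cm", "px"):
            raise DomainError(f"unit must be 'cm' or 'px', got {self.unit!r}")

    @property
    def n_samples(self) -> int:
        return int(self.left.size)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sample_rate

    def sides(self):
        return (("l", self.left), ("r", self.right))


def pixel_to_metric(pair: TrajectoryPair, axis_length_px: float, sex: str) -> TrajectoryPair:
    """Convert a pixel-scaled trajectory pair to centimetres.

    Without metric calibration in the endoscopic recording, the visible
    glottal-axis length in pixels is mapped onto an assumed vibrating fold
    length: 10 mm for women, 16 mm for men.  The resulting cm/px scale
    multiplies every sample.
    """
    if axis_length_px <= 0:
        raise DomainError("axis_length_px must be strictly positive")
    scale = ASSUMED_FOLD_LENGTH_CM[normalize_sex(sex)] / float(axis_length_px)
    return TrajectoryPair(
        left=pair.left * scale,
        right=pair.right * scale,
        sample_rate=pair.sample_rate,
        unit="cm",
        px_scale=scale,
        meta=dict(pair.meta),
    )


def estimate_rest_geometry(pair: TrajectoryPair, std: StandardParameters):
    """Subject-specific rest geometry (x01, x02, a01, a02) from mean amplitude.

    The rest half-gap of both masses is taken as the time- and side-averaged
    edge distance; the rest areas follow from the rectangular-glottis
    identity a0i = 2·l·x0i.
    """
    if pair.unit != "cm":
        raise DomainError("rest geometry requires metric (cm) trajectories")
    x0 = 0.5 * (float(np.mean(pair.left)) + float(np.mean(pair.right)))
    if x0 <= 0.0:
        raise DegenerateInputError("all-zero trajectories: no rest geometry")
    a0 = 2.0 * std.l * x0
    return x0, x0, a0, a0


def subject_parameters(pair: TrajectoryPair, std: StandardParameters) -> StandardParameters:
    """Standard parameters with this subject's rest geometry substituted."""
    x01, x02, a01, a02 = estimate_rest_geometry(pair, std)
    return std.with_geometry(x01, x02, a01, a02)


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

def _centered_spectrum(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    coeffs = np.fft.rfft(x - x.mean())
    mags = np.abs(coeffs)
    # bin 0 (DC) is excluded from all harmonic logic
    if mags.size < 2 or np.max(mags[1:]) <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        raise NoOscillationError("signal has no oscillatory energy above the noise floor")
    return coeffs, mags


def fundamental_frequency(x: np.ndarray, sample_rate: float) -> float:
    """Fundamental frequency (Hz) via the dominant DFT bin.

    The largest non-DC magnitude bin is refined to sub-bin resolution by
    interpolation over the peak and its two neighbours (complex-ratio
    estimator, which is nearly exact for an unwindowed sinusoid).  Ties
    break to the lower bin.
    """
    coeffs, mags = _centered_spectrum(x)
    n = np.asarray(x).size
    k = int(np.argmax(mags[1:])) + 1
    delta = 0.0
    if 1 <= k - 1 and k + 1 < mags.size:
        denom = 2.0 * coeffs[k] - coeffs[k - 1] - coeffs[k + 1]
        if abs(denom) > 0.0:
            delta = -float(np.real((coeffs[k + 1] - coeffs[k - 1]) / denom))
            delta = float(np.clip(delta, -0.5, 0.5))
    return (k + delta) * sample_rate / n


@dataclass(frozen=True)
class SpectralSelection:
    """Dominant-harmonic selection of a trajectory spectrum.

    ``indices`` are the selected DFT bins (DC excluded): every bin whose
    magnitude reaches 25% of the dominant one, plus the immediate left and
    right neighbours of each such bin.  ``dominant`` is the index of the
    largest-magnitude bin (the fundamental for periodic signals).
    """

    indices: np.ndarray
    coefficients: np.ndarray
    dominant: int

    @property
    def dominant_position(self) -> int:
        """Position of the dominant bin inside ``indices``."""
        return int(np.searchsorted(self.indices, self.dominant))


def select_harmonics(x: np.ndarray, sample_rate: float = 4000.0) -> SpectralSelection:
    """Select the dominant harmonics of a trajectory.

    Bins with magnitude ≥ 25% of the dominant bin are kept, together with
    each one's direct spectral neighbours (to tolerate slight harmonic
    drift).  The dominant bin (lowest index on ties) is always included.
    """
    coeffs, mags = _centered_spectrum(x)
    dominant = int(np.argmax(mags[1:])) + 1  # argmax -> lowest index on ties
    passing = np.flatnonzero(mags >= 0.25 * mags[dominant])
    passing = passing[passing >= 1]
    neighbors = np.concatenate([passing - 1, passing, passing + 1])
    sel = np.unique(neighbors)
    sel = sel[(sel >= 1) & (sel < mags.size)]
    return SpectralSelection(indices=sel, coefficients=coeffs[sel], dominant=dominant)


# ---------------------------------------------------------------------------
# cycle features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleStats:
    """Per-cycle features of a single trajectory.

    Cycles are delimited by positive-going crossings of the mean level
    (robust to amplitude modulation).  ``peaks`` and ``minima`` are the
    per-cycle maxima/minima of the raw signal, ``amplitude_range`` the
    [min, max] of the per-cycle peaks, and ``closed`` whether per-cycle
    minima drop below ``closure_fraction`` of the median peak in at least
    half of the cycles.
    """

    boundaries: np.ndarray
    peaks: np.ndarray
    minima: np.ndarray
    amplitude_range: tuple[float, float]
    closed: bool

    @property
    def n_cycles(self) -> int:
        return int(self.peaks.size)

    @property
    def mean_period_samples(self) -> float:
        return float(np.mean(np.diff(self.boundaries)))


def cycle_statistics(
    x: np.ndarray,
    sample_rate: float = 4000.0,
    closure_fraction: float = DEFAULT_CLOSURE_FRACTION,
) -> CycleStats:
    """Segment a quasi-periodic trajectory into cycles and collect features.

    Raises ``InsufficientCyclesError`` when fewer than 3 complete cycles are
    delimited, and ``NoOscillationError`` for flat signals.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        raise NoOscillationError("flat signal: cannot segment cycles")
    level = float(np.mean(x))
    below = x[:-1] < level
    atabove = x[1:] >= level
    boundaries = np.flatnonzero(below & atabove) + 1
    if boundaries.size < 4:  # need >= 3 complete cycles
        raise InsufficientCyclesError(
            f"only {max(boundaries.size - 1, 0)} complete cycles; need at least 3"
        )
    peaks = np.array([x[a:b].max() for a, b in zip(boundaries[:-1], boundaries[1:])])
    minima = np.array([x[a:b].min() for a, b in zip(boundaries[:-1], boundaries[1:])])
    med_peak = float(np.median(peaks))
    # inclusive boundary, guarded against float rounding
    closed_cycles = minima <= closure_fraction * med_peak * (1.0 + 1e-9) + 1e-15
    closed = bool(np.count_nonzero(closed_cycles) * 2 >= minima.size)
    return CycleStats(
        boundaries=boundaries,
        peaks=peaks,
        minima=minima,
        amplitude_range=(float(peaks.min()), float(peaks.max())),
        closed=closed,
    )


def detect_closure(
    pair: TrajectoryPair, closure_fraction: float = DEFAULT_CLOSURE_FRACTION
) -> bool:
    """Whether the glottis closes, judged on the total gap T_l + T_r.

    Closure is declared when the per-cycle minimum of the summed gap falls
    to or below ``closure_fraction`` of the median per-cycle peak gap in at
    least half of the cycles — a resolution-scaled proxy for visible
    closure in endoscopic footage.
    """
    gap = pair.left + pair.right
    stats = cycle_statistics(gap, pair.sample_rate, closure_fraction)
    return stats.closed
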