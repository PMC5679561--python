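# Methods

## The two-mass model

Each vocal fold is reduced to two vertically stacked point masses — a
heavier lower mass m₁ (0.125 g) carrying most of the tissue and a lighter
upper mass m₂ (0.025 g) representing the superior fold edge — connected to
the laryngeal wall by springs k₁, k₂ and to each other by a coupling
spring k_c, with viscous damping r₁ = r₂ = 0.02 g/ms.  The classical
reference values (Table below) describe a modal, symmetric adult
phonation pattern.  The model works in cgs-ms units (g, cm, ms); the
pressure unit is then g·cm⁻¹·ms⁻² = 10⁵ Pa, so a clinical cmH₂O converts
with 98.0665/10⁵ (8 cmH₂O ≈ 0.00785 internal units).

| symbol | value | unit | meaning |
| --- | --- | --- | --- |
| m₁, m₂ | 0.125, 0.025 | g | lower/upper mass |
| k₁, k₂, k_c | 0.08, 0.008, 0.025 | g/ms² | anchor and coupling springs |
| r₁, r₂ | 0.02 | g/ms | damping |
| c₁, c₂ | 3k₁, 3k₂ | g/ms² | collision springs |
| x₀₁, x₀₂ | 0.0179 | cm | rest half-gap |
| a₀₁, a₀₂ | 0.05 | cm² | rest glottal areas (= 2·l·x₀ᵢ) |
| d₁ | 0.25 | cm | lower-mass (pressure-bearing) thickness |
| l | 1.4 | cm | vibrating fold length |
| P_s | 8.0 | cmH₂O | default subglottal pressure |

Self-oscillation arises from the interplay of three nonlinearities on the
glottal areas a_i = a₀ᵢ + l·(x_il + x_ir):

* **Bernoulli driving pressure** on the lower masses,
  P₁ = P_s·[1 − Θ(a_min)(a_min/a₁)²]·Θ(a₁) with a_min = min(a₁, a₂): zero
  for a rectangular or divergent open glottis, the full P_s when the upper
  glottis is closed, zero when the lower glottis is closed.  The force per
  side is P₁·l·d₁.
* **Collision accelerations** I_iα = −Θ(−a_i)·(c_iα/m_iα)·(a_i/2l),
  restoring overlap of the folds with a spring three times the tissue
  stiffness.
* **Q-scaling**: per side, k_iα = Q_α·k_i0 and m_iα = m_i0/Q_α — a tauter
  fold vibrates with less effective mass.  Q_l ≠ Q_r expresses left–right
  biomechanical asymmetry; Q_lr = max/min ≥ 1 summarizes it.

At the exact rest state the two areas are equal and the Bernoulli bracket
vanishes, so integration starts from a small symmetric displacement
(x_iα = 0.01 cm) instead; this choice preserves the left–right symmetry
invariant (Q_l = Q_r ⇒ identical sides to machine precision).

What the model deliberately omits: vertical (inferior–superior) and
anterior–posterior motion, a vocal tract load, acoustic output, and any
time variation of parameters within a run.  All trajectories refer to one
mid-membranous coronal plane.

## Integration

A fixed-step classical RK4 scheme at 0.01 ms (100 kHz) is decimated to
4000 Hz output to match HSV frame rates.  The right-hand side is only
piecewise smooth: the gates Θ switch on the signs of a₁, a₂ and a₁ − a₂.
Stepping blindly across those switching surfaces destroys the scheme's
order and leaves a step-size-dependent phase drift that does not shrink
cleanly with the step.  Steps that straddle a switching surface are
therefore shortened to end just past the crossing (regula falsi on the
switching value, ≤ 12 probes); with event location the default step agrees
with a 10× finer reference to ~10⁻⁶ cm on the final 100 ms, two orders
inside the 10⁻⁴ cm tolerance the test suite enforces.  A tanh-smoothed
gate variant exists (`smooth > 0`) but is off by default: an unresolved
smoothing layer is *worse* than the sharp gate, and a resolvable layer
would visibly alter the dynamics.

Runs simulate 500 ms and discard the first 400 ms as onset transient;
comparisons use the final 100 ms (400 samples), which holds 10–50
oscillation cycles across the phonatory frequency range.  A state
exceeding 10³ cm or turning non-finite raises a blow-up error carrying the
failure time; inside optimization objectives a blow-up instead returns a
large finite penalty (10⁶) so stochastic searches continue.

## Preprocessing of recorded trajectories

HSV gives pixel distances only.  Without optical calibration, the visible
glottal-axis length in pixels is mapped onto an assumed vibrating fold
length — 10 mm for women, 16 mm for men (population averages) — which
yields a cm/px scale.  The subject's rest geometry is estimated as the
time- and side-averaged edge distance (x₀₁ = x₀₂ = mean, a₀ᵢ = 2·l·x₀ᵢ);
the sides are averaged because a per-mass split is not observable from
above.  This estimate is biased upward when the glottis spends part of the
cycle closed (clamped at zero), which is the main reason fitted parameters
on synthetic data deviate by a few percent when the pipeline estimates
geometry instead of using the generator's values.

Spectral features use an un-windowed length-N DFT of mean-centered
signals.  The fundamental is the largest non-DC bin refined by a
complex-ratio interpolator (near-exact for rectangular windows; a plain
magnitude parabola was biased by up to 2 Hz and is not used).  Harmonic
selection keeps every bin at ≥ 25% of the dominant magnitude plus each
one's direct neighbours; the dominant bin tie-breaks to the lower index.
Cycles are delimited by positive-going crossings of the mean level
(robust under amplitude modulation); at least three complete cycles are
required.  Glottal closure is declared when the per-cycle minimum of the
summed gap T_l + T_r falls to ≤ 5% of the median per-cycle peak gap in at
least half the cycles — a resolution-scaled proxy, since "visible closure"
has no universal quantitative definition.

## Cost functions

* **Γ₁ (frequency domain)**: per side, the Euclidean distance between the
  selected experimental harmonic magnitudes and the model coefficients at
  the same bins, plus the distance of their phases wrapped to (−π, π].
  The balance factor defaults to s = π√L/‖|e|‖₂ averaged over sides, so a
  maximal phase error and a total magnitude error contribute comparably;
  it is overridable.  Phase differences are only accumulated on bins whose
  magnitude exceeds 10⁻⁹ of the dominant on both sides — the phases of
  numerically empty neighbour bins are noise.
* **Γ₂ (time domain)**: the per-side Euclidean distances between the
  trajectory pairs, summed, after a single common circular shift
  maximizing the summed cross-correlation (a steady-state simulation has
  no preferred phase; ties break toward zero shift so identical pairs
  score exactly 0).
* **Γ₃ (normalized frequency domain)**: Γ₁ with each side's magnitude
  vector divided by its own dominant coefficient — uniform amplitude
  scaling cancels — plus a regularization term, the Euclidean distance of
  the two sides' un-normalized fundamental magnitudes.  The normalization
  is read as unit-maximum (dominant = 1) rather than unit-norm, isolated
  in this one operation.
* **Γ (selection)**: the normalized squared distance
  ½·[Σ(ΔT_l)²/ΣT_El² + Σ(ΔT_r)²/ΣT_Er²], evaluated after the same
  alignment.  Γ = 0 is perfection; a silent model scores exactly 1.

## Optimization

The search box is Q_l, Q_r ∈ [0.5, 6.0], P_s ∈ [5, 50] cmH₂O, covering
the parameter ranges observed for healthy adults with margin.  Three
derivative-free algorithms run against each cost (nine runs per subject),
all bounded, seeded and reproducible:

* **Nelder–Mead** (scipy backend; reflection 1, expansion 2, contraction
  0.5, shrink 0.5), out-of-bounds points projected with a quadratic
  penalty, started from the best initial-search point with a basin-sized
  initial simplex (0.02 in Q, 0.5 cmH₂O in P_s).
* **Particle swarm**: 30 particles, inertia 0.72, cognitive = social =
  1.49, velocities clamped to half the range, reflecting bounds; the top-5
  initial-search points are injected as particles.
* **Artificial bee colony**: 30 food sources, abandonment limit 20, one
  scout per cycle, uniform random initialization (no grid seeding).

Default budget is 2000 objective evaluations per run; a fast profile of
300 supports quick studies and the test suite.  Simulated trajectories are
cached on the parameter triple rounded to 10⁻⁶, so the nine runs and the
initial search share simulations.

**Initial-value search.**  A regular coarse grid (steps 0.5 in Q, 5 cmH₂O
in P_s) brackets the box, but cannot by itself seed a local search: the
costs only leave their decorrelation plateau once the model's f₀ matches
the recording to roughly one DFT bin, which makes the useful basin ~0.02
wide in Q — far below any affordable grid.  A frequency-guided refinement
therefore (1) scans symmetric Q at four pressures for the best f₀ match
(exploiting the model's monotone frequency–stiffness relation), (2) lays
a local left/right-asymmetry grid around the matched point, and (3) a
micro-grid around its best point.  The pool is laid out once under the
time-domain cost and re-ranked per cost from cached simulations.  On ten
noisy synthetic subjects (2% noise, 0.5% jitter) at the fast budget this
pipeline recovers Q to a median relative error well under 1% and P_s
under 1%, with all three success criteria met in 10/10 — the test suite
asserts the looser 10%/25% and 8/10 thresholds.

The nine candidates are compared by Γ, never by their own cost values
(which live on incompatible scales).  Success is rated on the Γ-selected
candidate: frequency deviation ≤ 5% on *both* sides (the stricter reading
of a per-subject criterion), closure behaviour reproduced, and the model's
median per-cycle peak inside the experimental min–max peak envelope per
side (the model's steady state has near-constant peaks, so the median is
its natural representative).

## Synthetic subjects

Raw clinical HSV recordings are typically not shareable, so validation
uses generated subjects with known ground truth.  `generate_model_subject`
simulates the model at true (Q_l, Q_r, P_s) and then degrades the
trajectories with exactly the features a time-invariant two-mass model
cannot reproduce:

* **jitter** — per-cycle period perturbation, implemented as cycle-wise
  time warping (each cycle resampled to a length factor 1 + N(0, σ_j))
  with cubic interpolation; linear interpolation would shave the waveform
  peaks and bias per-cycle amplitudes low by ~1%;
* **shimmer** — per-cycle amplitude factors 1 + N(0, σ_s) about the mean
  level, independent per side;
* **additive noise** — Gaussian, scaled to the oscillation amplitude;
* **pixel quantization** — round-half-away-from-zero on a configurable
  cm/px grid, applied after noise, with the clamp at zero before it.

Default study conditions for recovery experiments are 2% noise and 0.5%
jitter; ground-truth parameters are drawn uniformly from the ranges
observed in healthy adults (Q ∈ [0.8, 3.3], P_s ∈ [10, 35] cmH₂O,
Q_lr ≤ 1.25), rejecting draws below the phonation threshold.  What the
generator does *not* emulate: segmentation artifacts, camera motion,
mucosal-wave shape differences between model and tissue, and
inter-cycle closure variability; passing recovery tests therefore shows
identifiability of the inverse problem under controlled degradation, not
clinical accuracy on real footage.

The analytic generator (raised, optionally clipped sinusoids) supports
cost-function and signal-feature tests independently of the ODE core.

## Numerical conventions and edge cases

* Dominant-bin ties break to the lowest index; the closure boundary is
  inclusive (a minimum exactly at 5% counts as closed, guarded to one
  part in 10⁹ against float rounding).
* `gamma_final` refuses a zero-energy experimental side; flat signals
  raise a no-oscillation error; fewer than three cycles raise an
  insufficient-cycles error.
* Group summaries use the sample SD (ddof = 1) with the n = 1 case
  reported as SD 0 by convention; Q_l and Q_r can be pooled into a merged
  "Q" sample when only magnitudes matter.
* Problem sizes in the test suite — 10 recovery subjects at the
  300-evaluation fast budget, 8-seed jitter and 20-seed shimmer
  calibrations, a 0.27-step Q sweep for the frequency–stiffness check —
  were chosen as the smallest sizes at which the checked statistics are
  stable.

## Known limitations

* Fitted P_s systematically exceeds physiological subglottal pressures;
  the model family shares this bias, and the quantities are to be read as
  effective model parameters, not gauge measurements.
* The mean-amplitude rest-geometry estimate is biased when closure is
  present (see above); fits on real data inherit that bias.
* The mass/stiffness coupling m → m/Q, k → Q·k cannot represent
  configurations where mass and stiffness vary independently.
* Only the mid-membranous plane is modelled; anterior–posterior phase
  differences and posterior gaps are invisible to the fit.
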