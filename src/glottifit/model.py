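"""Self-oscillating two-mass vocal-fold model.

Each vocal fold (α = l, r) is a pair of vertically stacked, spring-coupled
masses.  The state of the system is

    y = (x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r)

with displacements x (cm) measured laterally from the rest position and
velocities v (cm/ms).  The folds interact through the glottal areas

    a_i = a0i + l·(x_il + x_ir),        i = 1 (lower), 2 (upper),

which become negative when the folds overlap (collision).  Three nonlinear
components close the system:

* a Bernoulli driving pressure acting on the lower masses,
  P1 = Ps·[1 − Θ(a_min)·(a_min/a1)²]·Θ(a1)  with a_min = min(a1, a2),
* collision accelerations I_iα = −Θ(−a_i)·(c_iα/m_iα)·(a_i/2l) restoring
  the masses when the glottis is (partially) closed,
* linear spring/damper forces including the coupling spring kc.

Integration is a fixed-step classical Runge–Kutta (RK4) scheme at a 0.01 ms
internal step, decimated to the requested output rate (4 kHz by default to
match high-speed videoendoscopy).  The inner loop is numba-jitted; the
NumPy `derivatives` function is the readable reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DomainError, IntegrationBlowupError
from .parameters import EffectiveParameters, FitVariables, StandardParameters, apply_scaling

__all__ = [
    "ModelState",
    "SimulationResult",
    "glottal_areas",
    "driving_force",
    "impact_accelerations",
    "derivatives",
    "simulate",
    "visible_edge_trajectory",
    "DEFAULT_INTERNAL_DT",
]

#: internal integration step in ms (100 kHz)
DEFAULT_INTERNAL_DT = 0.01


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of the eight-dimensional oscillator."""

    x1l: float = 0.0; v1l: float = 0.0; x2l: float = 0.0; v2l: float = 0.0
    x1r: float = 0.0; v1r: float = 0.0; x2r: float = 0.0; v2r: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x1l, self.v1l, self.x2l, self.v2l,
             self.x1r, self.v1r, self.x2r, self.v2r], dtype=np.float64)

    @classmethod
    def from_array(cls, y) -> "ModelState":
        return cls(*map(float, y))


#: symmetric small perturbation used as the default initial condition
DEFAULT_INIT = ModelState(x1l=0.01, x2l=0.01, x1r=0.01, x2r=0.01)


def _step(x: float, eps: float) -> float:
    """Unit step Θ, optionally tanh-smoothed with width ``eps``."""
    if eps > 0.0:
        return 0.5 * (1.0 + np.tanh(x / eps))
    return 1.0 if x > 0.0 else 0.0


def glottal_areas(state, params: EffectiveParameters):
    """Lower and upper glottal areas (cm²) for a state or state series.

    a_i = a0i + l·(x_il + x_ir); negative values signal fold collision.
    """
    if isinstance(state, ModelState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    x1l, x2l = y[..., 0], y[..., 2]
    x1r, x2r = y[..., 4], y[..., 6]
    a1 = params.a01 + params.l * (x1l + x1r)
    a2 = params.a02 + params.l * (x2l + x2r)
    return a1, a2


def driving_force(a1: float, a2: float, params: EffectiveParameters,
                  smooth: float = 0.0) -> float:
    """Bernoulli pressure force (g·cm/ms²) on each lower mass.

    The jet pressure on the lower masses is the subglottal pressure reduced
    by the Bernoulli term at the narrowest section: zero for a rectangular
    or divergent open glottis (a1 ≥ a_min = a2), the full P_s when the upper
    glottis is closed, and zero when the lower glottis itself is closed.
    """
    a_min = min(a1, a2)
    if a1 <= 0.0:
        return 0.0
    bern = 1.0 - _step(a_min, smooth) * (a_min / a1) ** 2
    p1 = params.ps_internal * bern * _step(a1, smooth)
    return p1 * params.l * params.d1


def impact_accelerations(a1: float, a2: float, params: EffectiveParameters,
                         smooth: float = 0.0):
    """Collision accelerations (cm/ms²) (I_1l, I_1r, I_2l, I_2r).

    Active only while the corresponding glottal area is negative; the
    collision spring c_iα pushes the mass back toward the open position.
    """
    two_l = 2.0 * params.l
    h1 = _step(-a1, smooth)
    h2 = _step(-a2, smooth)
    i1l = -h1 * (params.c1l / params.m1l) * (a1 / two_l)
    i1r = -h1 * (params.c1r / params.m1r) * (a1 / two_l)
    i2l = -h2 * (params.c2l / params.m2l) * (a2 / two_l)
    i2r = -h2 * (params.c2r / params.m2r) * (a2 / two_l)
    return i1l, i1r, i2l, i2r


def derivatives(state, params: EffectiveParameters, smooth: float = 0.0) -> np.ndarray:
    """Time derivative of the state vector (reference NumPy implementation).

    dv_1α = [−(k_1α+kc_α)x_1α − r_1α v_1α + kc_α x_2α]/m_1α + I_1α + F_1/m_1α
    dv_2α = [kc_α x_1α − (k_2α+kc_α)x_2α − r_2α v_2α]/m_2α + I_2α
    """
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, float)
    x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r = y
    p = params
    a1, a2 = glottal_areas(y, p)
    f1 = driving_force(float(a1), float(a2), p, smooth)
    i1l, i1r, i2l, i2r = impact_accelerations(float(a1), float(a2), p, smooth)

    dv1l = (-(p.k1l + p.kcl) * x1l - p.r1l * v1l + p.kcl * x2l) / p.m1l + i1l + f1 / p.m1l
    dv2l = (p.kcl * x1l - (p.k2l + p.kcl) * x2l - p.r2l * v2l) / p.m2l + i2l
    dv1r = (-(p.k1r + p.kcr) * x1r - p.r1r * v1r + p.kcr * x2r) / p.m1r + i1r + f1 / p.m1r
    dv2r = (p.kcr * x1r - (p.k2r + p.kcr) * x2r - p.r2r * v2r) / p.m2r + i2r
    return np.array([v1l, dv1l, v2l, dv2l, v1r, dv1r, v2r, dv2r])


# ---------------------------------------------------------------------------
# jitted core
# ---------------------------------------------------------------------------

@njit(cache=False)
def _deriv_core(x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r,
                m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
                m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
                a01, a02, d1, l, ps, smooth):
    a1 = a01 + l * (x1l + x1r)
    a2 = a02 + l * (x2l + x2r)
    amin = a1 if a1 < a2 else a2

    if smooth > 0.0:
        th_amin = 0.5 * (1.0 + np.tanh(amin / smooth))
        th_a1 = 0.5 * (1.0 + np.tanh(a1 / smooth))
        th_n1 = 0.5 * (1.0 + np.tanh(-a1 / smooth))
        th_n2 = 0.5 * (1.0 + np.tanh(-a2 / smooth))
    else:
        th_amin = 1.0 if amin > 0.0 else 0.0
        th_a1 = 1.0 if a1 > 0.0 else 0.0
        th_n1 = 1.0 if a1 < 0.0 else 0.0
        th_n2 = 1.0 if a2 < 0.0 else 0.0

    if a1 > 0.0:
        f1 = ps * (1.0 - th_amin * (amin / a1) ** 2) * th_a1 * l * d1
    else:
        f1 = 0.0

    two_l = 2.0 * l
    i1l = -th_n1 * (c1l / m1l) * (a1 / two_l)
    i1r = -th_n1 * (c1r / m1r) * (a1 / two_l)
    i2l = -th_n2 * (c2l / m2l) * (a2 / two_l)
    i2r = -th_n2 * (c2r / m2r) * (a2 / two_l)

    dv1l = (-(k1l + kcl) * x1l - r1l * v1l + kcl * x2l) / m1l + i1l + f1 / m1l
    dv2l = (kcl * x1l - (k2l + kcl) * x2l - r2l * v2l) / m2l + i2l
    dv1r = (-(k1r + kcr) * x1r - r1r * v1r + kcr * x2r) / m1r + i1r + f1 / m1r
    dv2r = (kcr * x1r - (k2r + kcr) * x2r - r2r * v2r) / m2r + i2r
    return v1l, dv1l, v2l, dv2l, v1r, dv1r, v2r, dv2r


@njit(cache=False)
def _rk4_step(x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r, h,
              m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
              m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
              a01, a02, d1, l, ps, smooth):
    """One classical RK4 step of size h on the scalar state."""
    h2 = 0.5 * h
    a0, b0, c0, d0, e0, f0, g0, i0 = _deriv_core(
        x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r,
        m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
        m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
        a01, a02, d1, l, ps, smooth)
    a1_, b1_, c1_, d1_, e1_, f1_, g1_, i1_ = _deriv_core(
        x1l + h2 * a0, v1l + h2 * b0, x2l + h2 * c0, v2l + h2 * d0,
        x1r + h2 * e0, v1r + h2 * f0, x2r + h2 * g0, v2r + h2 * i0,
        m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
        m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
        a01, a02, d1, l, ps, smooth)
    a2_, b2_, c2_, d2_, e2_, f2_, g2_, i2_ = _deriv_core(
        x1l + h2 * a1_, v1l + h2 * b1_, x2l + h2 * c1_, v2l + h2 * d1_,
        x1r + h2 * e1_, v1r + h2 * f1_, x2r + h2 * g1_, v2r + h2 * i1_,
        m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
        m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
        a01, a02, d1, l, ps, smooth)
    a3_, b3_, c3_, d3_, e3_, f3_, g3_, i3_ = _deriv_core(
        x1l + h * a2_, v1l + h * b2_, x2l + h * c2_, v2l + h * d2_,
        x1r + h * e2_, v1r + h * f2_, x2r + h * g2_, v2r + h * i2_,
        m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
        m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
        a01, a02, d1, l, ps, smooth)
    h6 = h / 6.0
    return (x1l + h6 * (a0 + 2.0 * (a1_ + a2_) + a3_),
            v1l + h6 * (b0 + 2.0 * (b1_ + b2_) + b3_),
            x2l + h6 * (c0 + 2.0 * (c1_ + c2_) + c3_),
            v2l + h6 * (d0 + 2.0 * (d1_ + d2_) + d3_),
            x1r + h6 * (e0 + 2.0 * (e1_ + e2_) + e3_),
            v1r + h6 * (f0 + 2.0 * (f1_ + f2_) + f3_),
            x2r + h6 * (g0 + 2.0 * (g1_ + g2_) + g3_),
            v2r + h6 * (i0 + 2.0 * (i1_ + i2_) + i3_))


@njit(cache=False)
def _gate_signature(x1l, x2l, x1r, x2r, a01, a02, l):
    """Sign pattern of the switching surfaces (a1, a2, a1 - a2)."""
    a1 = a01 + l * (x1l + x1r)
    a2 = a02 + l * (x2l + x2r)
    s1 = 1 if a1 > 0.0 else 0
    s2 = 1 if a2 > 0.0 else 0
    s3 = 1 if a1 > a2 else 0
    return s1 * 4 + s2 * 2 + s3


@njit(cache=False)
def _gate_values(x1l, x2l, x1r, x2r, a01, a02, l):
    a1 = a01 + l * (x1l + x1r)
    a2 = a02 + l * (x2l + x2r)
    return a1, a2, a1 - a2


@njit(cache=False)
def _integrate(y0, p, dt, n_out, decim, smooth):
    """Event-located RK4 with decimated output.

    The right-hand side is only piecewise smooth (the collision terms and
    the Bernoulli gating switch on the signs of a1, a2 and a1 - a2), so a
    naive fixed-step scheme loses its order at every switching crossing.
    Steps that straddle a switching surface are shortened to end just past
    the crossing (regula falsi on the switching value), making each
    sub-step smooth and restoring clean step-size convergence.

    Returns (states[n_out, 8], blow_time); blow_time < 0 means success.
    Sample j of the output corresponds to t = j * decim * dt.
    """
    (m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
     m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r) = p[0:18]
    a01, a02 = p[20], p[21]
    d1, l, ps = p[22], p[23], p[24]
    x1l, v1l, x2l, v2l = y0[0], y0[1], y0[2], y0[3]
    x1r, v1r, x2r, v2r = y0[4], y0[5], y0[6], y0[7]

    out = np.empty((n_out, 8))
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = x1l, v1l, x2l, v2l
    out[0, 4], out[0, 5], out[0, 6], out[0, 7] = x1r, v1r, x2r, v2r
    out_dt = dt * decim
    locate_events = smooth == 0.0
    min_h = dt * 1e-9
    h2 = 0.5 * dt
    h6 = dt / 6.0
    for j in range(1, n_out):
        t_in = 0.0
        while out_dt - t_in > min_h:
            h = dt if out_dt - t_in > dt else out_dt - t_in
            if h == dt:
                hh2 = h2
                hh6 = h6
            else:
                hh2 = 0.5 * h
                hh6 = h / 6.0
            a0, b0, c0, d0, e0, f0, g0, i0 = _deriv_core(
                x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r,
                m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
                m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
                a01, a02, d1, l, ps, smooth)
            a1_, b1_, c1_, d1_, e1_, f1_, g1_, i1_ = _deriv_core(
                x1l + hh2 * a0, v1l + hh2 * b0, x2l + hh2 * c0, v2l + hh2 * d0,
                x1r + hh2 * e0, v1r + hh2 * f0, x2r + hh2 * g0, v2r + hh2 * i0,
                m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
                m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
                a01, a02, d1, l, ps, smooth)
            a2_, b2_, c2_, d2_, e2_, f2_, g2_, i2_ = _deriv_core(
                x1l + hh2 * a1_, v1l + hh2 * b1_, x2l + hh2 * c1_, v2l + hh2 * d1_,
                x1r + hh2 * e1_, v1r + hh2 * f1_, x2r + hh2 * g1_, v2r + hh2 * i1_,
                m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
                m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
                a01, a02, d1, l, ps, smooth)
            a3_, b3_, c3_, d3_, e3_, f3_, g3_, i3_ = _deriv_core(
                x1l + h * a2_, v1l + h * b2_, x2l + h * c2_, v2l + h * d2_,
                x1r + h * e2_, v1r + h * f2_, x2r + h * g2_, v2r + h * i2_,
                m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
                m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
                a01, a02, d1, l, ps, smooth)
            n1 = x1l + hh6 * (a0 + 2.0 * (a1_ + a2_) + a3_)
            n2 = v1l + hh6 * (b0 + 2.0 * (b1_ + b2_) + b3_)
            n3 = x2l + hh6 * (c0 + 2.0 * (c1_ + c2_) + c3_)
            n4 = v2l + hh6 * (d0 + 2.0 * (d1_ + d2_) + d3_)
            n5 = x1r + hh6 * (e0 + 2.0 * (e1_ + e2_) + e3_)
            n6 = v1r + hh6 * (f0 + 2.0 * (f1_ + f2_) + f3_)
            n7 = x2r + hh6 * (g0 + 2.0 * (g1_ + g2_) + g3_)
            n8 = v2r + hh6 * (i0 + 2.0 * (i1_ + i2_) + i3_)
            if locate_events:
                g0a, g0b, g0c = _gate_values(x1l, x2l, x1r, x2r, a01, a02, l)
                g1a, g1b, g1c = _gate_values(n1, n3, n5, n7, a01, a02, l)
                # first switching value whose sign flips over this step
                gs, ge = 0.0, 0.0
                flipped = False
                if (g0a > 0.0) != (g1a > 0.0):
                    gs, ge, flipped = g0a, g1a, True
                elif (g0b > 0.0) != (g1b > 0.0):
                    gs, ge, flipped = g0b, g1b, True
                elif (g0c > 0.0) != (g1c > 0.0):
                    gs, ge, flipped = g0c, g1c, True
                if flipped and h > 16.0 * min_h:
                    lam_a, lam_b = 0.0, 1.0
                    ga, gb = gs, ge
                    for _ in range(12):
                        if lam_b - lam_a < 1e-9:
                            break
                        denom = gb - ga
                        if denom != 0.0:
                            lam = lam_a - ga * (lam_b - lam_a) / denom
                        else:
                            lam = 0.5 * (lam_a + lam_b)
                        lo = lam_a + 0.02 * (lam_b - lam_a)
                        hi = lam_b - 0.02 * (lam_b - lam_a)
                        if lam < lo:
                            lam = lo
                        elif lam > hi:
                            lam = hi
                        m1_, m2_, m3_, m4_, m5_, m6_, m7_, m8_ = _rk4_step(
                            x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r, lam * h,
                            m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
                            m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
                            a01, a02, d1, l, ps, smooth)
                        ja, jb, jc = _gate_values(m1_, m3_, m5_, m7_, a01, a02, l)
                        if gs == g0a:
                            g = ja
                        elif gs == g0b:
                            g = jb
                        else:
                            g = jc
                        if (g > 0.0) == (gs > 0.0):
                            lam_a, ga = lam, g
                        else:
                            lam_b, gb = lam, g
                    # end the step just past the crossing
                    h = lam_b * h
                    if h < min_h:
                        h = min_h
                    n1, n2, n3, n4, n5, n6, n7, n8 = _rk4_step(
                        x1l, v1l, x2l, v2l, x1r, v1r, x2r, v2r, h,
                        m1l, m2l, k1l, k2l, kcl, c1l, c2l, r1l, r2l,
                        m1r, m2r, k1r, k2r, kcr, c1r, c2r, r1r, r2r,
                        a01, a02, d1, l, ps, smooth)
            x1l, v1l, x2l, v2l = n1, n2, n3, n4
            x1r, v1r, x2r, v2r = n5, n6, n7, n8
            t_in += h
        s = abs(x1l) + abs(v1l) + abs(x2l) + abs(v2l) \
            + abs(x1r) + abs(v1r) + abs(x2r) + abs(v2r)
        if not np.isfinite(s) or s > 1e3:
            return out, j * out_dt
        out[j, 0], out[j, 1], out[j, 2], out[j, 3] = x1l, v1l, x2l, v2l
        out[j, 4], out[j, 5], out[j, 6], out[j, 7] = x1r, v1r, x2r, v2r
    return out, -1.0


@dataclass(frozen=True)
class SimulationResult:
    """Post-transient model output sampled at the output rate.

    ``states`` holds the eight state variables row-wise on ``time`` (ms);
    ``a1``/``a2`` are the lower/upper glottal areas (cm²) and ``t_ml``/
    ``t_mr`` the visible-edge trajectories (cm, clamped at the midline).
    """

    time: np.ndarray
    states: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    t_ml: np.ndarray
    t_mr: np.ndarray
    output_rate: float
    transient_ms: float
    params: EffectiveParameters


def visible_edge_trajectory(states: np.ndarray, params: EffectiveParameters):
    """Visible-edge trajectories (T_Ml, T_Mr) from a state series.

    Seen from above, the more medial of the two mass edges on each side is
    the one an endoscopic camera observes: T_Mα = max(0, min(x01 + x_1α,
    x02 + x_2α)), with the clamp expressing that a fold cannot be seen past
    the glottal midline.
    """
    y = np.atleast_2d(np.asarray(states, dtype=float))
    t_ml = np.minimum(params.x01 + y[:, 0], params.x02 + y[:, 2])
    t_mr = np.minimum(params.x01 + y[:, 4], params.x02 + y[:, 6])
    return np.maximum(t_ml, 0.0), np.maximum(t_mr, 0.0)


def simulate(
    fit: FitVariables,
    std: StandardParameters | None = None,
    total_ms: float = 500.0,
    output_rate: float = 4000.0,
    transient_ms: float = 400.0,
    init: ModelState | None = None,
    internal_dt: float = DEFAULT_INTERNAL_DT,
    smooth: float = 0.0,
) -> SimulationResult:
    """Integrate the two-mass model and return post-transient output.

    The model is integrated for ``total_ms`` from ``init`` (a small
    symmetric displacement by default), the first ``transient_ms`` are
    discarded as onset transient, and the remainder is returned sampled at
    ``output_rate``.  Deterministic for identical inputs.

    Raises
    ------
    IntegrationBlowupError
        if the state becomes non-finite, reporting the failure time.
    """
    if std is None:
        std = StandardParameters()
    if init is None:
        init = DEFAULT_INIT
    if total_ms <= transient_ms:
        raise DomainError("total_ms must exceed transient_ms")
    out_dt = 1000.0 / output_rate
    decim = int(round(out_dt / internal_dt))
    if decim < 1 or abs(decim * internal_dt - out_dt) > 1e-9:
        raise DomainError("output_rate must divide the internal integration rate")

    params = apply_scaling(std, fit)
    n_out = int(round(total_ms / out_dt))
    states, blow = _integrate(
        init.as_array(), params.as_vector(), internal_dt, n_out, decim, smooth
    )
    if blow >= 0.0:
        raise IntegrationBlowupError(blow)

    keep = int(round(transient_ms / out_dt))
    states = states[keep:]
    time = (np.arange(keep, n_out) * out_dt)
    a1, a2 = glottal_areas(states, params)
    t_ml, t_mr = visible_edge_trajectory(states, params)
    return SimulationResult(
        time=time, states=states, a1=a1, a2=a2, t_ml=t_ml, t_mr=t_mr,
        output_rate=output_rate, transient_ms=transient_ms, params=params,
    )
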