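"""Parameter sets of the lumped-element two-mass vocal-fold model.

The model works in an internal cgs-ms unit system (gram, centimetre,
millisecond).  In these units the pressure unit is g·cm⁻¹·ms⁻² = 10⁵ Pa,
so the conventional clinical unit cmH₂O converts with the factor
98.0665 / 10⁵ (1 cmH₂O = 98.0665 Pa).

Three parameter containers are defined:

``StandardParameters``
    The classical reference parameter set of the symmetric two-mass model
    (Ishizaka–Flanagan values as used by Steinecke & Herzel): two masses per
    fold, three springs, viscous damping, collision springs three times the
    corresponding tissue stiffness, rest half-gaps and rest areas.

``FitVariables``
    The three quantities varied during inverse fitting: the per-side
    tension/mass scaling factors Q_l, Q_r and the subglottal pressure P_s.

``EffectiveParameters``
    The per-side parameter set after Q-scaling, i.e. what the ODE system
    actually integrates, with the pressure already converted to internal
    units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

#: cmH2O -> g cm^-1 ms^-2 (= 1e5 Pa)
CMH2O_TO_INTERNAL = 98.0665 / 1e5


@dataclass(frozen=True)
class StandardParameters:
    """Reference parameter set of the symmetric two-mass model.

    Masses in g, stiffnesses in g/ms², damping in g/ms, lengths in cm,
    areas in cm², pressure in cmH₂O.  Collision stiffnesses ``c1_0``/``c2_0``
    are tied to the tissue stiffnesses as 3·k1 and 3·k2 and are derived
    automatically when left at ``None``.
    """

    m1_0: float = 0.125
    m2_0: float = 0.025
    k1_0: float = 0.08
    k2_0: float = 0.008
    kc_0: float = 0.025
    r1_0: float = 0.02
    r2_0: float = 0.02
    c1_0: float | None = None
    c2_0: float | None = None
    x01: float = 0.0179
    x02: float = 0.0179
    a01: float = 0.05
    a02: float = 0.05
    d1: float = 0.25
    l: float = 1.4
    Ps_default: float = 8.0

    def __post_init__(self) -> None:
        if self.c1_0 is None:
            object.__setattr__(self, "c1_0", 3.0 * self.k1_0)
        if self.c2_0 is None:
            object.__setattr__(self, "c2_0", 3.0 * self.k2_0)
        for name in ("m1_0", "m2_0", "k1_0", "k2_0", "kc_0", "d1", "l"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.r1_0 < 0 or self.r2_0 < 0:
            raise DomainError("damping must be non-negative")
        if not np.isclose(self.c1_0, 3.0 * self.k1_0, rtol=1e-12):
            raise DomainError("c1_0 must equal 3*k1_0")
        if not np.isclose(self.c2_0, 3.0 * self.k2_0, rtol=1e-12):
            raise DomainError("c2_0 must equal 3*k2_0")
        # rest areas and rest half-gaps must describe the same geometry
        for a0, x0, name in ((self.a01, self.x01, "a01"), (self.a02, self.x02, "a02")):
            if not np.isclose(a0, 2.0 * self.l * x0, rtol=0.01):
                raise DomainError(
                    f"{name} = {a0} inconsistent with 2*l*x0 = {2.0 * self.l * x0:.5f}"
                )

    def with_geometry(
        self, x01: float, x02: float, a01: float, a02: float
    ) -> "StandardParameters":
        """Return a copy with subject-specific rest geometry."""
        return dataclasses.replace(self, x01=x01, x02=x02, a01=a01, a02=a02)

    def with_fold_length(self, l: float) -> "StandardParameters":
        """Return a copy with vibrating length ``l`` (cm), rest areas rescaled."""
        return dataclasses.replace(
            self, l=l, a01=2.0 * l * self.x01, a02=2.0 * l * self.x02
        )

    # --- JSON round-trip using the conventional symbol names -------------
    _JSON_KEYS = {
        "m1": "m1_0", "m2": "m2_0", "k1": "k1_0", "k2": "k2_0", "kc": "kc_0",
        "r1": "r1_0", "r2": "r2_0", "c1": "c1_0", "c2": "c2_0",
        "x01": "x01", "x02": "x02", "a01": "a01", "a02": "a02",
        "d1": "d1", "l": "l", "Ps": "Ps_default",
    }

    def to_dict(self) -> dict:
        return {k: getattr(self, attr) for k, attr in self._JSON_KEYS.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardParameters":
        return cls(**{attr: d[k] for k, attr in cls._JSON_KEYS.items() if k in d})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "StandardParameters":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class FitVariables:
    """The optimized triple: scaling factors Q_l, Q_r and pressure P_s [cmH₂O].

    Q_α multiplies every stiffness of side α and divides its masses, so a
    large Q means a stiff, light (high-pitched) fold.
    """

    Ql: float
    Qr: float
    Ps: float

    def __post_init__(self) -> None:
        if self.Ql <= 0 or self.Qr <= 0:
            raise DomainError("scaling factors Ql, Qr must be strictly positive")
        if self.Ps <= 0:
            raise DomainError("subglottal pressure Ps must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Ql, self.Qr, self.Ps], dtype=float)

    @classmethod
    def from_array(cls, x) -> "FitVariables":
        return cls(float(x[0]), float(x[1]), float(x[2]))


@dataclass(frozen=True)
class EffectiveParameters:
    """Q-scaled per-side parameters in internal units (g, cm, ms)."""

    m1l: float; m2l: float; k1l: float; k2l: float; kcl: float
    c1l: float; c2l: float; r1l: float; r2l: float
    m1r: float; m2r: float; k1r: float; k2r: float; kcr: float
    c1r: float; c2r: float; r1r: float; r2r: float
    x01: float; x02: float; a01: float; a02: float
    d1: float; l: float
    ps_internal: float
    fit: FitVariables = field(compare=False)

    def as_vector(self) -> np.ndarray:
        """Flat float64 vector consumed by the jitted integrator core."""
        return np.array(
            [
                self.m1l, self.m2l, self.k1l, self.k2l, self.kcl,
                self.c1l, self.c2l, self.r1l, self.r2l,
                self.m1r, self.m2r, self.k1r, self.k2r, self.kcr,
                self.c1r, self.c2r, self.r1r, self.r2r,
                self.x01, self.x02, self.a01, self.a02,
                self.d1, self.l, self.ps_internal,
            ],
            dtype=np.float64,
        )


def apply_scaling(std: StandardParameters, fit: FitVariables) -> EffectiveParameters:
    """Q-scale the standard parameters and convert the pressure.

    Per side α: k_iα = Q_α·k_i0, kc_α = Q_α·kc_0, c_iα = Q_α·c_i0 and
    m_iα = m_i0 / Q_α — stiffer folds carry less vibrating mass.  Damping and
    geometry are copied unchanged; P_s is converted from cmH₂O to the
    internal pressure unit g·cm⁻¹·ms⁻².
    """
    ql, qr = fit.Ql, fit.Qr
    return EffectiveParameters(
        m1l=std.m1_0 / ql, m2l=std.m2_0 / ql,
        k1l=ql * std.k1_0, k2l=ql * std.k2_0, kcl=ql * std.kc_0,
        c1l=ql * std.c1_0, c2l=ql * std.c2_0,
        r1l=std.r1_0, r2l=std.r2_0,
        m1r=std.m1_0 / qr, m2r=std.m2_0 / qr,
        k1r=qr * std.k1_0, k2r=qr * std.k2_0, kcr=qr * std.kc_0,
        c1r=qr * std.c1_0, c2r=qr * std.c2_0,
        r1r=std.r1_0, r2r=std.r2_0,
        x01=std.x01, x02=std.x02, a01=std.a01, a02=std.a02,
        d1=std.d1, l=std.l,
        ps_internal=fit.Ps * CMH2O_TO_INTERNAL,
        fit=fit,
    )
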