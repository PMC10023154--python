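"""Kinematics and constitutive mechanics of an incompressible axisymmetric vessel.

The wall is modelled with a four-fiber-family hyperelastic strain energy:
an isotropic (neo-Hookean) ground matrix of modulus ``c`` plus exponential
fiber families oriented axially, circumferentially, and along two symmetric
diagonals at +/- alpha0 from the axial direction,

    W = c/2 (I_C - 3)
        + sum_i c1_i / (4 c2_i) * {exp[c2_i (IV_C^i - 1)^2] - 1},

with I_C = lam_r^2 + lam_theta^2 + lam_z^2 and
IV_C^i = lam_theta^2 sin^2(alpha_i) + lam_z^2 cos^2(alpha_i).
Incompressibility (lam_r lam_theta lam_z = 1) eliminates the radial stretch,
and the Lagrange multiplier is eliminated from load predictions by working
with Cauchy stress differences.

Load predictions use a mid-wall (mean-wall) evaluation of equilibrium:
the pressure from thin-wall circumferential equilibrium and the transducer
axial force with the pressure-on-cap term removed,

    P = (sig_tt - sig_rr) h / r_mid,
    f = pi h (2a + h) (sig_zz - sig_rr - P/2) - pi a^2 P.

The two fiber families at +/- alpha0 share one (c1, c2) pair, giving eight
independent parameters in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .exceptions import (
    ConfigurationNotFoundError,
    EnergyOverflowError,
    WallVolumeError,
)
from .units import KPA_TO_MMHG, MMHG_TO_KPA, UM2_TO_MM2

__all__ = [
    "ConstitutiveParams",
    "DeformationState",
    "LoadedGeometry",
    "StiffnessTensor",
    "deformed_state",
    "strain_energy",
    "cauchy_extra_stress",
    "predicted_loads",
    "solve_diameter",
    "linearized_stiffness",
    "stiffness_at_state",
]

# Saturation bound for exponential arguments.  Physical fits never approach
# it; it only guards the wide brackets used by the equilibrium root solves.
_EXP_SAT = 500.0


def _exp_safe(x):
    return np.exp(np.minimum(x, _EXP_SAT))


@dataclass(frozen=True)
class ConstitutiveParams:
    """Eight parameters of the four-fiber-family strain energy.

    ``c`` and the ``c1_*`` have units of kPa, the ``c2_*`` are dimensionless,
    and ``alpha0`` (radians) is the diagonal-family angle measured from the
    axial direction.  The two diagonal families share (c1_diag, c2_diag)
    and the angle pair +/- alpha0.
    """

    c: float
    c1_axial: float
    c2_axial: float
    c1_circ: float
    c2_circ: float
    c1_diag: float
    c2_diag: float
    alpha0: float

    def __post_init__(self):
        for name in ("c", "c1_axial", "c2_axial", "c1_circ", "c2_circ",
                     "c1_diag", "c2_diag"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.alpha0 <= math.pi / 2:
            raise ValueError(f"alpha0 must lie in [0, pi/2], got {self.alpha0}")

    def to_array(self) -> np.ndarray:
        return np.array([self.c, self.c1_axial, self.c2_axial, self.c1_circ,
                         self.c2_circ, self.c1_diag, self.c2_diag, self.alpha0])

    @classmethod
    def from_array(cls, x) -> "ConstitutiveParams":
        x = np.asarray(x, dtype=float)
        return cls(*x.tolist())


@dataclass(frozen=True)
class DeformationState:
    """Principal mid-wall stretches of an incompressible deformation."""

    lam_r: float
    lam_theta: float
    lam_z: float

    def __post_init__(self):
        lr = np.asarray(self.lam_r, dtype=float)
        lt = np.asarray(self.lam_theta, dtype=float)
        lz = np.asarray(self.lam_z, dtype=float)
        if np.any(lr <= 0) or np.any(lt <= 0) or np.any(lz <= 0):
            raise ValueError("stretches must be positive")
        if np.any(np.abs(lr * lt * lz - 1.0) > 1e-10):
            raise ValueError("stretches violate incompressibility det F = 1")

    @classmethod
    def biaxial(cls, lam_theta, lam_z) -> "DeformationState":
        """Build an incompressible state from the in-plane stretches."""
        lam_theta = np.asarray(lam_theta, dtype=float)
        lam_z = np.asarray(lam_z, dtype=float)
        lam_r = 1.0 / (lam_theta * lam_z)
        if lam_r.ndim == 0:
            return cls(float(lam_r), float(lam_theta), float(lam_z))
        return cls(lam_r, lam_theta, lam_z)

    @property
    def I_C(self):
        return (np.asarray(self.lam_r) ** 2 + np.asarray(self.lam_theta) ** 2
                + np.asarray(self.lam_z) ** 2)


@dataclass(frozen=True)
class LoadedGeometry:
    """Deformed cross-sectional geometry (micrometres)."""

    a: float
    h: float

    def __post_init__(self):
        if np.any(np.asarray(self.a) <= 0) or np.any(np.asarray(self.h) <= 0):
            raise ValueError("inner radius and thickness must be positive")

    @property
    def r_mid(self):
        return np.asarray(self.a) + np.asarray(self.h) / 2.0

    @property
    def r_outer(self):
        return np.asarray(self.a) + np.asarray(self.h)


@dataclass(frozen=True)
class StiffnessTensor:
    """Circumferential and axial stiffness components at an evaluation point."""

    C_tttt_kpa: float
    C_zzzz_kpa: float
    pressure_mmhg: float
    axial_stretch: float

    @property
    def C_tttt_mpa(self) -> float:
        return self.C_tttt_kpa / 1.0e3

    @property
    def C_zzzz_mpa(self) -> float:
        return self.C_zzzz_kpa / 1.0e3


def _family_arrays(params: ConstitutiveParams):
    """(c1, c2, sin^2 alpha, cos^2 alpha, multiplicity) per distinct family."""
    s2d = math.sin(params.alpha0) ** 2
    c2d = math.cos(params.alpha0) ** 2
    c1 = np.array([params.c1_axial, params.c1_circ, params.c1_diag])
    c2 = np.array([params.c2_axial, params.c2_circ, params.c2_diag])
    sin2 = np.array([0.0, 1.0, s2d])
    cos2 = np.array([1.0, 0.0, c2d])
    mult = np.array([1.0, 1.0, 2.0])  # the +/- alpha0 pair counts twice
    return c1, c2, sin2, cos2, mult


def _fiber_invariants(params, lam_theta, lam_z):
    c1, c2, sin2, cos2, mult = _family_arrays(params)
    lt2 = np.asarray(lam_theta, dtype=float) ** 2
    lz2 = np.asarray(lam_z, dtype=float) ** 2
    # broadcast family axis last
    IV = lt2[..., None] * sin2 + lz2[..., None] * cos2
    return c1, c2, sin2, cos2, mult, IV


def deformed_state(R_o, H, lam_z, outer_diameter):
    """Deformed geometry and mid-wall stretches from a diameter measurement.

    Parameters are the unloaded outer radius ``R_o`` and thickness ``H``
    (micrometres), the axial stretch ``lam_z`` and the measured deformed
    outer diameter (micrometres).  Incompressibility of the wall gives the
    inner radius ``a = sqrt(r_o^2 - (R_o^2 - R_i^2)/lam_z)``; the mid-wall
    circumferential stretch is the ratio of deformed to unloaded mid-wall
    radii.
    """
    R_o = float(R_o)
    H = float(H)
    if not R_o > H > 0:
        raise ValueError("require R_o > H > 0")
    R_i = R_o - H
    lam_z = np.asarray(lam_z, dtype=float)
    r_o = np.asarray(outer_diameter, dtype=float) / 2.0
    arg = r_o**2 - (R_o**2 - R_i**2) / lam_z
    if np.any(arg < 0):
        raise WallVolumeError(
            "wall volume inconsistency: measured outer radius too small for "
            "the unloaded wall volume at this axial stretch")
    a = np.sqrt(arg)
    h = r_o - a
    lam_theta = (a + h / 2.0) / (R_i + H / 2.0)
    if a.ndim == 0:
        geom = LoadedGeometry(float(a), float(h))
        state = DeformationState.biaxial(float(lam_theta), float(lam_z))
    else:
        geom = LoadedGeometry(a, h)
        state = DeformationState.biaxial(lam_theta, lam_z)
    return geom, state


def strain_energy(params: ConstitutiveParams, state: DeformationState):
    """Strain energy density W (kPa) at a deformation state."""
    c1, c2, sin2, cos2, mult, IV = _fiber_invariants(
        params, state.lam_theta, state.lam_z)
    e = IV - 1.0
    arg = c2 * e**2
    if np.any(arg > _EXP_SAT):
        raise EnergyOverflowError(
            f"exponent {float(np.max(arg)):.3g} exceeds saturation bound "
            f"{_EXP_SAT}; deformation state is outside the admissible range")
    W_iso = params.c / 2.0 * (state.I_C - 3.0)
    # c2 -> 0 limit of c1/(4 c2) (exp(c2 e^2) - 1) is c1 e^2 / 4
    safe_c2 = np.where(c2 > 0, c2, 1.0)
    per_family = np.where(c2 > 0,
                          c1 / (4.0 * safe_c2) * (np.exp(arg) - 1.0),
                          c1 * e**2 / 4.0)
    W_fib = np.sum(mult * per_family, axis=-1)
    W = W_iso + W_fib
    return float(W) if np.ndim(W) == 0 else W


def _stress_differences(params, lam_theta, lam_z):
    """sig_tt - sig_rr and sig_zz - sig_rr (kPa), Lagrange-multiplier free."""
    lam_theta = np.asarray(lam_theta, dtype=float)
    lam_z = np.asarray(lam_z, dtype=float)
    lam_r2 = 1.0 / (lam_theta * lam_z) ** 2
    c1, c2, sin2, cos2, mult, IV = _fiber_invariants(params, lam_theta, lam_z)
    e = IV - 1.0
    g = c1 * e * _exp_safe(c2 * e**2) * mult  # 2 * dW/dIV per family
    lt2 = lam_theta**2
    lz2 = lam_z**2
    dtt = params.c * (lt2 - lam_r2) + lt2 * np.sum(g * sin2, axis=-1)
    dzz = params.c * (lz2 - lam_r2) + lz2 * np.sum(g * cos2, axis=-1)
    return dtt, dzz


def cauchy_extra_stress(params: ConstitutiveParams, state: DeformationState):
    """Extra (non-Lagrange) Cauchy stresses (sig_rr, sig_tt, sig_zz) in kPa.

    These are the components of 2 F (dW/dC) F^T with diagonal F; only
    differences between them enter load predictions, so any constant added
    to the reaction pressure cancels.
    """
    lam_r2 = np.asarray(state.lam_r, dtype=float) ** 2
    dtt, dzz = _stress_differences(params, state.lam_theta, state.lam_z)
    sig_rr = params.c * lam_r2
    return sig_rr, sig_rr + dtt, sig_rr + dzz


def _loads_from_geometry(params, geom_a, geom_h, lam_theta, lam_z):
    """(P in mmHg, f in mN) from mid-wall equilibrium; fully vectorized."""
    dtt, dzz = _stress_differences(params, lam_theta, lam_z)
    a = np.asarray(geom_a, dtype=float)
    h = np.asarray(geom_h, dtype=float)
    r_mid = a + h / 2.0
    P_kpa = dtt * h / r_mid
    ring_area = np.pi * h * (2.0 * a + h) * UM2_TO_MM2  # mm^2
    cap_area = np.pi * a**2 * UM2_TO_MM2
    f_mn = ring_area * (dzz - P_kpa / 2.0) - cap_area * P_kpa
    return P_kpa * KPA_TO_MMHG, f_mn


def predicted_loads(params: ConstitutiveParams, R_o, H, lam_z, outer_diameter):
    """Predicted luminal pressure (mmHg) and transducer axial force (mN).

    The axial force is the force read by an in-line transducer with the
    vessel capped: the pressure force on the closed end (pi a^2 P) is
    subtracted from the wall tension integral.
    """
    geom, state = deformed_state(R_o, H, lam_z, outer_diameter)
    P, f = _loads_from_geometry(params, geom.a, geom.h,
                                state.lam_theta, state.lam_z)
    if np.ndim(P) == 0:
        return float(P), float(f)
    return P, f


def solve_diameter(params: ConstitutiveParams, R_o, H, lam_z, pressure_mmhg,
                   tol_mmhg: float = 1e-3, max_iter: int = 200):
    """Outer diameter (um) at which predicted pressure equals the target.

    Bisection on the outer diameter between the zero-lumen limit and
    3 R_o; vectorized over (lam_z, pressure) arrays.  Raises
    ConfigurationNotFoundError when no sign change exists in the bracket.
    """
    R_o = float(R_o)
    H = float(H)
    R_i = R_o - H
    lam_z = np.asarray(lam_z, dtype=float)
    target = np.asarray(pressure_mmhg, dtype=float)
    lam_z_b, target_b = np.broadcast_arrays(lam_z, target)
    scalar = lam_z_b.ndim == 0
    lam_z_b = np.atleast_1d(lam_z_b).astype(float)
    target_b = np.atleast_1d(target_b).astype(float)

    wall_term = (R_o**2 - R_i**2) / lam_z_b
    lo = 2.0 * np.sqrt(wall_term) * (1.0 + 1e-9)  # a -> 0+
    hi = np.full_like(lo, 6.0 * R_o)              # outer diameter 3 R_o

    def resid(d):
        geom, state = deformed_state(R_o, H, lam_z_b, d)
        P, _ = _loads_from_geometry(params, geom.a, geom.h,
                                    state.lam_theta, state.lam_z)
        return P - target_b

    f_lo = resid(lo * (1 + 1e-12) + 1e-9)
    f_hi = resid(hi)
    if np.any(f_lo > 0) or np.any(f_hi < 0):
        raise ConfigurationNotFoundError(
            "configuration not found: no equilibrium diameter in "
            "[zero-lumen, 3 R_o] for the requested pressure")
    f_mid = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = resid(mid)
        take_hi = f_mid > 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
        if np.all(hi - lo < 1e-9 * R_o) and np.all(np.abs(f_mid) < tol_mmhg):
            break
    d = 0.5 * (lo + hi)
    return float(d[0]) if scalar else d.reshape(np.broadcast(lam_z, target).shape)


def _dW_terms(params, lam_theta, lam_z):
    """First and second derivatives of W wrt C_tt and C_zz (independent C)."""
    c1, c2, sin2, cos2, mult, IV = _fiber_invariants(params, lam_theta, lam_z)
    e = IV - 1.0
    ex = _exp_safe(c2 * e**2)
    dW_dIV = 0.5 * c1 * e * ex              # per family
    d2W_dIV2 = 0.5 * c1 * ex * (1.0 + 2.0 * c2 * e**2)
    dW_dCtt = params.c / 2.0 + np.sum(mult * dW_dIV * sin2, axis=-1)
    dW_dCzz = params.c / 2.0 + np.sum(mult * dW_dIV * cos2, axis=-1)
    d2W_dCtt2 = np.sum(mult * d2W_dIV2 * sin2**2, axis=-1)
    d2W_dCzz2 = np.sum(mult * d2W_dIV2 * cos2**2, axis=-1)
    return dW_dCtt, dW_dCzz, d2W_dCtt2, d2W_dCzz2


def stiffness_at_state(params: ConstitutiveParams, state: DeformationState):
    """Analytic (C_tttt, C_zzzz) in kPa, linearized about the given state.

    For diagonal F the circumferential component reduces to
    C_tttt = 4 lam_t^2 dW/dC_tt + 4 lam_t^4 d2W/dC_tt^2 and analogously
    for the axial component.
    """
    lt = np.asarray(state.lam_theta, dtype=float)
    lz = np.asarray(state.lam_z, dtype=float)
    dW_dCtt, dW_dCzz, d2W_dCtt2, d2W_dCzz2 = _dW_terms(params, lt, lz)
    C_tttt = 4.0 * lt**2 * dW_dCtt + 4.0 * lt**4 * d2W_dCtt2
    C_zzzz = 4.0 * lz**2 * dW_dCzz + 4.0 * lz**4 * d2W_dCzz2
    if np.ndim(C_tttt) == 0:
        return float(C_tttt), float(C_zzzz)
    return C_tttt, C_zzzz


def linearized_stiffness(params: ConstitutiveParams, R_o, H, pressure_mmhg,
                         lam_z) -> StiffnessTensor:
    """Stiffness tensor components at the equilibrium configuration for
    (pressure, axial stretch), found by the inverse diameter solve."""
    d = solve_diameter(params, R_o, H, lam_z, pressure_mmhg)
    _, state = deformed_state(R_o, H, lam_z, d)
    C_tttt, C_zzzz = stiffness_at_state(params, state)
    return StiffnessTensor(C_tttt, C_zzzz, float(pressure_mmhg), float(lam_z))
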