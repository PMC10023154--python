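"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they check: the energy oracle uses
sympy arbitrary-precision evaluation of the strain-energy formula, the
stiffness oracle uses central finite differences of the circumferential /
axial extra stress, and the pressure oracle integrates thick-wall radial
equilibrium by quadrature instead of the mid-wall approximation.
"""

import math

import numpy as np
import sympy as sp


def energy_mpmath(params, lam_theta, lam_z, dps=50):
    """Arbitrary-precision evaluation of the four-fiber-family energy."""
    lt, lz = sp.Rational(str(lam_theta)), sp.Rational(str(lam_z))
    lr = 1 / (lt * lz)
    IC = lr**2 + lt**2 + lz**2
    c = sp.Float(params.c, dps)
    W = c / 2 * (IC - 3)
    fams = [(params.c1_axial, params.c2_axial, 0.0),
            (params.c1_circ, params.c2_circ, math.pi / 2),
            (params.c1_diag, params.c2_diag, params.alpha0),
            (params.c1_diag, params.c2_diag, -params.alpha0)]
    for c1, c2, alpha in fams:
        if c1 == 0:
            continue
        IV = lt**2 * sp.sin(sp.Float(alpha, dps))**2 \
            + lz**2 * sp.cos(sp.Float(alpha, dps))**2
        W += sp.Float(c1, dps) / (4 * sp.Float(c2, dps)) * \
            (sp.exp(sp.Float(c2, dps) * (IV - 1)**2) - 1)
    return float(sp.N(W, dps))


def stress_differences_fd(params, lam_theta, lam_z, step=1e-6):
    """(sig_tt - sig_rr, sig_zz - sig_rr) from central finite differences of
    the incompressibility-reduced energy W_hat(lam_t, lam_z)."""
    from vesselmech.mechanics import DeformationState, strain_energy

    def W(lt, lz):
        return strain_energy(params, DeformationState.biaxial(lt, lz))

    d_tt = lam_theta * (W(lam_theta + step, lam_z)
                        - W(lam_theta - step, lam_z)) / (2 * step)
    d_zz = lam_z * (W(lam_theta, lam_z + step)
                    - W(lam_theta, lam_z - step)) / (2 * step)
    return d_tt, d_zz


def _extra_stress_tt(params, lt, lz):
    """2 lam_t^2 dW/dC_tt with C components treated as independent."""
    s2 = math.sin(params.alpha0) ** 2
    c2a = math.cos(params.alpha0) ** 2
    out = params.c * lt**2
    for c1, c2, sin2, cos2, mult in [
            (params.c1_axial, params.c2_axial, 0.0, 1.0, 1.0),
            (params.c1_circ, params.c2_circ, 1.0, 0.0, 1.0),
            (params.c1_diag, params.c2_diag, s2, c2a, 2.0)]:
        IV = lt**2 * sin2 + lz**2 * cos2
        e = IV - 1.0
        out += mult * c1 * e * math.exp(c2 * e**2) * lt**2 * sin2
    return out


def _extra_stress_zz(params, lt, lz):
    s2 = math.sin(params.alpha0) ** 2
    c2a = math.cos(params.alpha0) ** 2
    out = params.c * lz**2
    for c1, c2, sin2, cos2, mult in [
            (params.c1_axial, params.c2_axial, 0.0, 1.0, 1.0),
            (params.c1_circ, params.c2_circ, 1.0, 0.0, 1.0),
            (params.c1_diag, params.c2_diag, s2, c2a, 2.0)]:
        IV = lt**2 * sin2 + lz**2 * cos2
        e = IV - 1.0
        out += mult * c1 * e * math.exp(c2 * e**2) * lz**2 * cos2
    return out


def stiffness_fd(params, lam_theta, lam_z, rel_step=1e-6):
    """Central-difference construction of (C_tttt, C_zzzz):
    C_tttt = lam_t * d sigma_tt / d lam_t at fixed lam_z (independent-C
    extra stress), and analogously for the axial component."""
    ht = rel_step * lam_theta
    hz = rel_step * lam_z
    C_t = lam_theta * (_extra_stress_tt(params, lam_theta + ht, lam_z)
                       - _extra_stress_tt(params, lam_theta - ht, lam_z)) \
        / (2 * ht)
    C_z = lam_z * (_extra_stress_zz(params, lam_theta, lam_z + hz)
                   - _extra_stress_zz(params, lam_theta, lam_z - hz)) / (2 * hz)
    return C_t, C_z


def thick_wall_pressure(params, R_o, H, lam_z, outer_radius_um, n_quad=100):
    """Luminal pressure (mmHg) from the thick-wall equilibrium integral
    P = int_a^{r_o} (sig_tt - sig_rr) / r dr with the radially resolved
    incompressible kinematics r(R) = sqrt(a^2 + (R^2 - R_i^2)/lam_z)."""
    from vesselmech.units import KPA_TO_MMHG

    R_i = R_o - H
    a2 = outer_radius_um**2 - (R_o**2 - R_i**2) / lam_z
    if a2 <= 0:
        raise ValueError("geometry inconsistent with wall volume")
    a = math.sqrt(a2)
    r = np.linspace(a, outer_radius_um, n_quad)
    R = np.sqrt(R_i**2 + lam_z * (r**2 - a**2))
    lam_t = r / R
    lam_r2 = 1.0 / (lam_t * lam_z) ** 2
    d_tt = np.array([_extra_stress_tt(params, lt, lam_z) for lt in lam_t]) \
        - params.c * lam_r2
    P_kpa = np.trapezoid(d_tt / r, r)
    return P_kpa * KPA_TO_MMHG
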