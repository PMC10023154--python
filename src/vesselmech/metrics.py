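"""Working-point biomechanical phenotype of a fitted vessel.

Five scalar metrics summarize the passive phenotype at a physiologic
working point (distending pressure at the in vivo axial stretch): mean
circumferential and axial wall stress, linearized circumferential and axial
material stiffness, and the elastically stored energy.  Pulse wave velocity
is computed two independent ways:

* Moens-Korteweg, from material stiffness and loaded geometry:
  ``PWV = sqrt(E h / (2 rho a))`` with E the circumferential stiffness
  ``C_tttt``;
* Bramwell-Hill, from the pressure-diameter relation through the clinical
  distensibility ``D = (d_sys - d_dias) / ((P_sys - P_dias) d_dias)``:
  ``PWV = sqrt(1 / (rho D))``.

Agreement between the two is an internal consistency check of the fitted
model and geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .exceptions import VesselMechError
from .mechanics import (ConstitutiveParams, LoadedGeometry, deformed_state,
                        solve_diameter, stiffness_at_state, strain_energy,
                        _loads_from_geometry)
from .units import KPA_TO_PA, MMHG_TO_KPA, RHO_BLOOD, UM2_TO_MM2, UM_TO_M

__all__ = ["MetricSet", "wall_stresses", "pwv_moens_korteweg",
           "pwv_bramwell_hill", "stored_energy_at", "compute_metrics"]


@dataclass(frozen=True)
class MetricSet:
    """Derived metrics of one specimen at its working point."""

    pressure_mmhg: float
    lam_z: float
    a_um: float
    h_um: float
    sigma_theta_kpa: float
    sigma_z_kpa: float
    C_tttt_mpa: float
    C_zzzz_mpa: float
    W_kpa: float
    distensibility_per_pa: float
    pwv_mk_m_s: float
    pwv_bh_m_s: float
    rho_blood: float

    def to_dict(self) -> dict:
        return asdict(self)


def wall_stresses(pressure_mmhg: float, force_mn: float,
                  geometry: LoadedGeometry):
    """Mean circumferential and axial wall stress (kPa) from measured loads.

    sigma_theta = P a / h (Laplace);
    sigma_z = (f + pi a^2 P) / (pi h (2a + h)), the transducer force plus
    the pressure force on the closed end spread over the wall annulus.
    """
    if pressure_mmhg < 0:
        raise ValueError("pressure must be >= 0")
    P_kpa = pressure_mmhg * MMHG_TO_KPA
    a, h = geometry.a, geometry.h
    sigma_theta = P_kpa * a / h
    ring_area = math.pi * h * (2.0 * a + h) * UM2_TO_MM2   # mm^2
    cap_force = math.pi * a**2 * UM2_TO_MM2 * P_kpa        # mN
    sigma_z = (force_mn + cap_force) / ring_area
    return sigma_theta, sigma_z


def pwv_moens_korteweg(E_pa: float, h_m: float, a_m: float,
                       rho: float = RHO_BLOOD) -> float:
    """Moens-Korteweg pulse wave velocity (m/s) from material stiffness E
    (Pa), wall thickness and luminal radius (m) and blood density (kg/m^3)."""
    if min(E_pa, h_m, a_m, rho) <= 0:
        raise ValueError("all Moens-Korteweg inputs must be positive")
    return math.sqrt(E_pa * h_m / (2.0 * rho * a_m))


def pwv_bramwell_hill(d_sys_um: float, d_dias_um: float, P_sys_mmhg: float,
                      P_dias_mmhg: float, rho: float = RHO_BLOOD):
    """Distensibility (1/Pa) and Bramwell-Hill pulse wave velocity (m/s).

    Diameters are the inner (luminal) diameters at systolic and diastolic
    pressure.  A rigid response (d_sys == d_dias) has infinite PWV and is
    rejected.
    """
    if d_dias_um <= 0:
        raise ValueError("diastolic diameter must be positive")
    if P_sys_mmhg <= P_dias_mmhg:
        raise ValueError("systolic pressure must exceed diastolic")
    if d_sys_um < d_dias_um:
        raise ValueError("systolic diameter must be >= diastolic")
    if d_sys_um == d_dias_um:
        raise VesselMechError(
            "rigid vessel: zero diameter change gives infinite PWV")
    dP_pa = (P_sys_mmhg - P_dias_mmhg) * MMHG_TO_KPA * KPA_TO_PA
    D = (d_sys_um - d_dias_um) / (dP_pa * d_dias_um)
    return D, math.sqrt(1.0 / (rho * D))


def stored_energy_at(params: ConstitutiveParams, R_o: float, H: float,
                     lam_z: float, pressure_mmhg: float = 100.0) -> float:
    """Stored energy density W (kPa) at the equilibrium configuration for
    the given pressure and axial stretch."""
    d = solve_diameter(params, R_o, H, lam_z, pressure_mmhg)
    _, state = deformed_state(R_o, H, lam_z, d)
    return strain_energy(params, state)


def compute_metrics(params: ConstitutiveParams, R_o: float, H: float,
                    lam_iv: float, working_pressure_mmhg: float = 100.0,
                    sys_dias_mmhg=(120.0, 80.0),
                    rho: float = RHO_BLOOD) -> MetricSet:
    """Full derived-metric set for one specimen.

    Stresses, stiffness and energy are evaluated at the working pressure and
    the in vivo axial stretch; distensibility and Bramwell-Hill PWV use the
    model-predicted inner diameters at the systolic/diastolic pressure pair
    (defaults 120/80 mmHg).
    """
    P_sys, P_dias = sys_dias_mmhg
    d = solve_diameter(params, R_o, H, lam_iv, working_pressure_mmhg)
    geom, state = deformed_state(R_o, H, lam_iv, d)
    P_hat, f_hat = _loads_from_geometry(params, geom.a, geom.h,
                                        state.lam_theta, state.lam_z)
    sigma_theta, sigma_z = wall_stresses(P_hat, f_hat, geom)
    C_tttt, C_zzzz = stiffness_at_state(params, state)
    W = strain_energy(params, state)
    pwv_mk = pwv_moens_korteweg(C_tttt * KPA_TO_PA, geom.h * UM_TO_M,
                                geom.a * UM_TO_M, rho)
    d_pair = solve_diameter(params, R_o, H, lam_iv, [P_sys, P_dias])
    geom_sys, _ = deformed_state(R_o, H, lam_iv, d_pair[0])
    geom_dias, _ = deformed_state(R_o, H, lam_iv, d_pair[1])
    D, pwv_bh = pwv_bramwell_hill(2 * geom_sys.a, 2 * geom_dias.a,
                                  P_sys, P_dias, rho)
    return MetricSet(
        pressure_mmhg=float(working_pressure_mmhg), lam_z=float(lam_iv),
        a_um=float(geom.a), h_um=float(geom.h),
        sigma_theta_kpa=float(sigma_theta), sigma_z_kpa=float(sigma_z),
        C_tttt_mpa=C_tttt / 1e3, C_zzzz_mpa=C_zzzz / 1e3, W_kpa=float(W),
        distensibility_per_pa=float(D), pwv_mk_m_s=float(pwv_mk),
        pwv_bh_m_s=float(pwv_bh), rho_blood=float(rho))
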