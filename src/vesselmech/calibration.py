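"""Frozen ground-truth study conditions for the synthetic data generator.

Each study group/age/vessel carries a fixed constitutive parameter set and
unloaded geometry chosen once so that the derived working-point metrics
(inner radius, wall thickness, circumferential/axial material stiffness and
stored energy at the working pressure and in vivo axial stretch) equal the
published group means for wild-type, untreated progeria and lonafarnib- or
rapamycin-treated progeria mice.  Where a group mean was not published the
value is an interpolated or field-plausible choice, made once and kept.

These constants define the emulated study; they are not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mechanics import ConstitutiveParams

__all__ = [
    "GroundTruth", "CALIBRATION", "ACTIVE_RESPONSE", "ECHO_GROUPS",
    "HISTOLOGY_GROUPS", "SURVIVAL", "WORKING_PRESSURE",
    "ground_truth_for", "active_response_for",
]

#: working (distending) pressure for derived metrics, mmHg, per vessel
WORKING_PRESSURE = {"DTA": 100.0, "MA": 60.0}


@dataclass(frozen=True)
class GroundTruth:
    """True constitutive parameters and unloaded geometry of a group mean."""

    params: ConstitutiveParams
    R_o: float      # unloaded outer radius, um
    H: float        # unloaded thickness, um
    lam_iv: float   # in vivo axial stretch
    L: float = 5.0  # unloaded length, mm (3.0 for MA)


# keyed by (group, age_days, vessel)
CALIBRATION = {
    # wild-type littermates: stable phenotype across the study window
    ("WT", 42, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=16.491, c1_axial=0.136489, c2_axial=1.0,
                                  c1_circ=0.0814396, c2_circ=1.0,
                                  c1_diag=18.6256, c2_diag=0.2,
                                  alpha0=0.785398),
        R_o=465.503, H=117.067, lam_iv=1.65),
    ("GG", 42, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=11.6903, c1_axial=0.24888, c2_axial=2.0,
                                  c1_circ=0.00781776, c2_circ=1.0,
                                  c1_diag=32.0505, c2_diag=0.2,
                                  alpha0=0.872665),
        R_o=372.875, H=87.75, lam_iv=1.5),
    ("GG", 100, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=8.4925, c1_axial=1.7754, c2_axial=1.0,
                                  c1_circ=12.7616, c2_circ=1.0,
                                  c1_diag=12.5399, c2_diag=1.0,
                                  alpha0=0.523599),
        R_o=394.514, H=117.6, lam_iv=1.4),
    ("GG", 140, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=3.47281, c1_axial=9.30772, c2_axial=1.0,
                                  c1_circ=8.29475, c2_circ=4.0,
                                  c1_diag=4.9534, c2_diag=4.0,
                                  alpha0=0.523599),
        R_o=422.536, H=149.76, lam_iv=1.3),
    # perimorbid untreated progeria: very stiff, nearly inextensible wall
    ("GG", 168, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=2.061162, c1_axial=1.8285612, c2_axial=4.0,
                                  c1_circ=11.607607, c2_circ=16.0,
                                  c1_diag=0.37968406, c2_diag=32.0,
                                  alpha0=0.6981317),
        R_o=451.9587, H=158.7, lam_iv=1.2),
    ("GG+L(P21)", 168, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=3.15595, c1_axial=5.23726, c2_axial=4.0,
                                  c1_circ=18.9327, c2_circ=1.0,
                                  c1_diag=3.5427, c2_diag=8.0,
                                  alpha0=0.785398),
        R_o=448.219, H=148.438, lam_iv=1.25),
    ("GG+L(P100)", 168, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=2.88708, c1_axial=3.06539, c2_axial=8.0,
                                  c1_circ=5.40428, c2_circ=1.0,
                                  c1_diag=8.3856, c2_diag=8.0,
                                  alpha0=0.872665),
        R_o=452.079, H=150.06, lam_iv=1.23),
    ("GG+L+R", 168, "DTA"): GroundTruth(
        params=ConstitutiveParams(c=0.96082197, c1_axial=3.0895786, c2_axial=8.0,
                                  c1_circ=25.667821, c2_circ=4.0,
                                  c1_diag=0.28448571, c2_diag=32.0,
                                  alpha0=0.7853982),
        R_o=449.01487, H=154.44, lam_iv=1.2),
    # second-order branch mesenteric artery (muscular)
    ("WT", 168, "MA"): GroundTruth(
        params=ConstitutiveParams(c=1.29751, c1_axial=0.0229751, c2_axial=8.0,
                                  c1_circ=1.61159, c2_circ=1.0,
                                  c1_diag=5.41021, c2_diag=1.0,
                                  alpha0=0.959931),
        R_o=130.619, H=54.81, lam_iv=1.35, L=3.0),
    ("GG", 168, "MA"): GroundTruth(
        params=ConstitutiveParams(c=0.465585, c1_axial=0.643181, c2_axial=8.0,
                                  c1_circ=4.96279, c2_circ=1.0,
                                  c1_diag=3.81854, c2_diag=8.0,
                                  alpha0=0.872665),
        R_o=138.333, H=60.0, lam_iv=1.25, L=3.0),
    ("GG+L(P21)", 168, "MA"): GroundTruth(
        params=ConstitutiveParams(c=0.984805, c1_axial=1.83668, c2_axial=4.0,
                                  c1_circ=0.345688, c2_circ=1.0,
                                  c1_diag=4.83309, c2_diag=4.0,
                                  alpha0=0.959931),
        R_o=126.438, H=56.875, lam_iv=1.3, L=3.0),
}

# wild-types are phenotypically stable: reuse the same ground truth at all ages
for _age in (100, 140, 168):
    CALIBRATION[("WT", _age, "DTA")] = CALIBRATION[("WT", 42, "DTA")]


@dataclass(frozen=True)
class ActiveResponse:
    """Mono-exponential vasoactive response amplitudes (fractions of the
    baseline isobaric diameter) and the ACh recovery fraction of the PE
    pre-constriction."""

    kcl_amplitude: float
    pe_amplitude: float
    ach_recovery: float
    tau: float = 60.0  # s


ACTIVE_RESPONSE = {
    # aorta: progressive loss of contractility, complete by P168,
    # not rescued by treatment
    ("WT", 42, "DTA"): ActiveResponse(0.28, 0.22, 0.10),
    ("WT", 100, "DTA"): ActiveResponse(0.28, 0.22, 0.10),
    ("WT", 140, "DTA"): ActiveResponse(0.27, 0.21, 0.10),
    ("WT", 168, "DTA"): ActiveResponse(0.27, 0.21, 0.10),
    ("GG", 42, "DTA"): ActiveResponse(0.15, 0.12, 0.08),
    ("GG", 100, "DTA"): ActiveResponse(0.08, 0.06, 0.05),
    ("GG", 140, "DTA"): ActiveResponse(0.015, 0.012, 0.02),
    ("GG", 168, "DTA"): ActiveResponse(0.004, 0.003, 0.0),
    ("GG+L(P21)", 168, "DTA"): ActiveResponse(0.01, 0.008, 0.0),
    ("GG+L(P100)", 168, "DTA"): ActiveResponse(0.01, 0.008, 0.0),
    ("GG+L+R", 168, "DTA"): ActiveResponse(0.004, 0.003, 0.0),
    # mesenteric artery: milder decline, largely rescued by lonafarnib
    ("WT", 168, "MA"): ActiveResponse(0.35, 0.30, 0.70),
    ("GG", 168, "MA"): ActiveResponse(0.05, 0.04, 0.10),
    ("GG+L(P21)", 168, "MA"): ActiveResponse(0.30, 0.26, 0.60),
    ("GG+L(P100)", 168, "MA"): ActiveResponse(0.25, 0.21, 0.50),
}


@dataclass(frozen=True)
class EchoGroup:
    """Group means for the echocardiographic generator (P168)."""

    LVIDd: float         # mm
    EF: float            # %
    heart_rate: float    # bpm
    e_prime: float       # mm/s
    E_over_eprime: float
    E_over_A: float
    DT: float            # ms
    body_mass: float     # g


ECHO_GROUPS = {
    "WT": EchoGroup(LVIDd=3.2, EF=60.0, heart_rate=400.0, e_prime=19.0,
                    E_over_eprime=42.0, E_over_A=1.5, DT=30.0, body_mass=30.0),
    "GG": EchoGroup(LVIDd=2.6, EF=60.0, heart_rate=470.0, e_prime=9.0,
                    E_over_eprime=81.0, E_over_A=1.25, DT=22.0, body_mass=10.0),
    "GG+L(P21)": EchoGroup(LVIDd=3.0, EF=62.0, heart_rate=530.0, e_prime=18.0,
                           E_over_eprime=43.0, E_over_A=1.45, DT=28.0,
                           body_mass=11.0),
    "GG+L+R": EchoGroup(LVIDd=2.6, EF=60.0, heart_rate=470.0, e_prime=17.0,
                        E_over_eprime=45.0, E_over_A=1.3, DT=23.0,
                        body_mass=10.0),
}


@dataclass(frozen=True)
class HistologyGroup:
    """Medial Movat class fractions and Alizarin calcified fraction."""

    elastin: float
    cytoplasm: float
    proteoglycan: float
    collagen: float
    calcified: float

    def movat_fractions(self) -> dict:
        return {"elastin": self.elastin, "cytoplasm": self.cytoplasm,
                "proteoglycan": self.proteoglycan, "collagen": self.collagen}


HISTOLOGY_GROUPS = {
    "WT": HistologyGroup(elastin=0.40, cytoplasm=0.314, proteoglycan=0.124,
                         collagen=0.094, calcified=0.005),
    "GG": HistologyGroup(elastin=0.35, cytoplasm=0.065, proteoglycan=0.480,
                         collagen=0.046, calcified=0.25),
    "GG+L(P21)": HistologyGroup(elastin=0.38, cytoplasm=0.104,
                                proteoglycan=0.372, collagen=0.090,
                                calcified=0.10),
}

#: per-group survival: total n and the death days (deaths on day 169
#: followed anesthesia and echocardiography on day 168)
SURVIVAL = {
    "WT": {"n_total": 5, "death_days": []},
    "GG": {"n_total": 19,
           "death_days": [120, 128, 135, 141, 147, 152, 158, 162, 166,
                          169, 169, 169]},
    "GG+L(P21)": {"n_total": 6, "death_days": [169]},
    "GG+L(P100)": {"n_total": 4, "death_days": []},
    "GG+L+R": {"n_total": 6, "death_days": [130, 145, 160]},
}


def ground_truth_for(group: str, age: float, vessel: str) -> GroundTruth:
    try:
        return CALIBRATION[(group, int(age), vessel)]
    except KeyError:
        raise KeyError(
            f"no calibrated ground truth for group={group!r} age={age} "
            f"vessel={vessel!r}") from None


def active_response_for(group: str, age: float, vessel: str) -> ActiveResponse:
    try:
        return ACTIVE_RESPONSE[(group, int(age), vessel)]
    except KeyError:
        raise KeyError(
            f"no calibrated active response for group={group!r} age={age} "
            f"vessel={vessel!r}") from None
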