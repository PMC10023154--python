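"""Synthetic study generator.

Forward-simulates every input the analysis pipeline consumes — biaxial
passive protocol traces, isobaric vasoactive time courses, echo measurement
tables, stained-section images and survival tables — from the frozen
ground-truth conditions in :mod:`vesselmech.calibration`.

Passive traces are exact equilibrium solutions of the four-fiber-family
model along the vessel-specific protocol paths (three pressure-diameter
sweeps at fixed axial stretch, four force-length sweeps at fixed pressure),
with multiplicative Gaussian noise on the measured diameter (default CV 1%)
and additive Gaussian noise on the measured axial force (default SD
0.1 mN).  Controlled variables (pressure set-point, axial stretch) are
recorded noise-free.

A single global seed fans out to per-specimen streams through
``numpy.random.SeedSequence`` keyed by a CRC32 of the specimen id, so any
specimen regenerates identically regardless of cohort composition.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import calibration as cal
from .exceptions import ConfigurationNotFoundError, VesselMechError
from .io import (ActiveTrace, EchoRecord, ProtocolTrace, SpecimenDataset,
                 SpecimenRecord, protocol_design)
from .mechanics import ConstitutiveParams, predicted_loads, solve_diameter

__all__ = [
    "GeneratorConfig", "StudyConfig", "StudyData", "DEFAULT_STUDY",
    "rng_for", "generate_passive_dataset", "generate_active_traces",
    "generate_echo_records", "generate_histology_image", "generate_cohorts",
]


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-item RNG: global seed + stable hash of the label."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise and sampling conditions of the emulated test rig."""

    n_points_per_protocol: int = 400
    diameter_noise_cv: float = 0.01   # multiplicative, on measured diameter
    force_noise_sd: float = 0.1      # mN, additive, on measured force
    parameter_cv: float = 0.08       # specimen-to-specimen stiffness scale
    geometry_cv: float = 0.02        # specimen-to-specimen size scale
    lam_iv_sd: float = 0.015         # jitter on the in vivo axial stretch


DEFAULT_GENERATOR = GeneratorConfig()


def _specimen_ground_truth(group, age, vessel, rng, config):
    """Draw one specimen's true parameters and geometry around the group mean.

    All stress-like parameters (c, c1_*) share one lognormal scale factor so
    the specimen keeps the group's nonlinearity while varying in stiffness;
    geometry gets an independent lognormal size factor.
    """
    gt = cal.ground_truth_for(group, age, vessel)
    s = float(np.exp(rng.normal(0.0, config.parameter_cv)))
    g = float(np.exp(rng.normal(0.0, config.geometry_cv)))
    p = gt.params
    params = ConstitutiveParams(
        c=p.c * s, c1_axial=p.c1_axial * s, c2_axial=p.c2_axial,
        c1_circ=p.c1_circ * s, c2_circ=p.c2_circ,
        c1_diag=p.c1_diag * s, c2_diag=p.c2_diag, alpha0=p.alpha0)
    lam_iv = float(max(1.0, gt.lam_iv + rng.normal(0.0, config.lam_iv_sd)))
    return replace(gt, params=params, R_o=gt.R_o * g, H=gt.H * g,
                   lam_iv=lam_iv)


def _axial_force_at(params, R_o, H, pressure, lam_z):
    d = solve_diameter(params, R_o, H, lam_z, pressure)
    _, f = predicted_loads(params, R_o, H, lam_z, d)
    return f


def _solve_stretch_for_force(params, R_o, H, pressure, f_target,
                             lam_lo=0.5, lam_hi=2.8):
    """Axial stretch at which the transducer force equals f_target at the
    given pressure.  The force is increasing in stretch over the bracket."""
    def fn(lz):
        return _axial_force_at(params, R_o, H, pressure, lz) - f_target

    # skip stretches at which no equilibrium diameter exists (strongly
    # stretched diagonal fibers can keep the hoop stress positive at any
    # lumen size, putting low pressures out of reach)
    grid = np.linspace(lam_lo, lam_hi, 48)
    vals = []
    for lz in grid:
        try:
            vals.append(fn(lz))
        except ConfigurationNotFoundError:
            vals.append(np.nan)
    for k in range(len(grid) - 1):
        if np.isfinite(vals[k]) and np.isfinite(vals[k + 1]) \
                and vals[k] <= 0 <= vals[k + 1]:
            return brentq(fn, grid[k], grid[k + 1], xtol=1e-10)
    raise VesselMechError(
        f"generation error: no axial stretch in [{lam_lo}, {lam_hi}] gives "
        f"force {f_target:.3g} mN at {pressure:g} mmHg")


def generate_passive_dataset(group, age, vessel, specimen_id=None, seed=0,
                             config: GeneratorConfig = DEFAULT_GENERATOR):
    """Generate one specimen's full passive dataset (3 Pd + 4 fl traces).

    Returns ``(SpecimenDataset, GroundTruth)`` where the second element is
    the specimen-level truth for recovery testing.
    """
    if specimen_id is None:
        specimen_id = f"{group}_{vessel}_P{int(age)}_s{seed}"
    rng = rng_for(seed, specimen_id)
    truth = _specimen_ground_truth(group, age, vessel, rng, config)
    design = protocol_design(vessel)
    p_lo, p_hi = design["pd_range"]
    n = config.n_points_per_protocol

    record = SpecimenRecord(
        specimen_id=specimen_id, group=group, age=float(age), vessel=vessel,
        R_o=truth.R_o, H=truth.H, L=truth.L, lam_iv=truth.lam_iv)

    def measure(d_true, f_true):
        d = d_true * (1.0 + config.diameter_noise_cv
                      * rng.standard_normal(d_true.shape))
        f = f_true + config.force_noise_sd * rng.standard_normal(f_true.shape)
        return d, f

    traces = []
    # three P-d protocols, unloading pass: pressure swept high -> low
    pressures = np.linspace(p_hi, p_lo, n)
    f_ceiling = None
    for factor in (0.95, 1.0, 1.05):
        lam_z = factor * truth.lam_iv
        d_true = solve_diameter(truth.params, truth.R_o, truth.H,
                                lam_z, pressures)
        _, f_true = predicted_loads(truth.params, truth.R_o, truth.H,
                                    lam_z, d_true)
        if factor == 1.05:
            f_ceiling = float(np.max(f_true))
        d_meas, f_meas = measure(d_true, f_true)
        traces.append(ProtocolTrace(
            protocol_kind="Pd", control_value=float(lam_z), is_unloading=True,
            samples=pd.DataFrame({
                "pressure_mmHg": pressures,
                "outer_diameter_um": d_meas,
                "axial_force_mN": f_meas,
                "axial_stretch": np.full(n, lam_z),
            })))

    # four f-l protocols at fixed pressure, force cycled 0 -> ceiling;
    # unloading pass recorded force high -> low
    for fp in design["fl_pressures"]:
        lam_top = _solve_stretch_for_force(truth.params, truth.R_o, truth.H,
                                           fp, f_ceiling)
        lam_bot = _solve_stretch_for_force(truth.params, truth.R_o, truth.H,
                                           fp, 0.0)
        lam_grid = np.linspace(lam_top, lam_bot, n)
        d_true = solve_diameter(truth.params, truth.R_o, truth.H,
                                lam_grid, fp)
        _, f_true = predicted_loads(truth.params, truth.R_o, truth.H,
                                    lam_grid, d_true)
        d_meas, f_meas = measure(d_true, f_true)
        traces.append(ProtocolTrace(
            protocol_kind="fl", control_value=float(fp), is_unloading=True,
            samples=pd.DataFrame({
                "pressure_mmHg": np.full(n, float(fp)),
                "outer_diameter_um": d_meas,
                "axial_force_mN": f_meas,
                "axial_stretch": lam_grid,
            })))

    dataset = SpecimenDataset(record=record, passive=traces).validate()
    return dataset, truth


def generate_active_traces(group, age, vessel, truth=None, seed=0,
                           specimen_id=None, duration=900.0, dt=2.0,
                           noise_cv=0.002):
    """Isobaric KCl / PE / ACh diameter time courses for one specimen.

    Diameter follows a mono-exponential approach to plateau,
    ``d(t) = d0 - A d0 (1 - exp(-t/tau))``; the ACh trace starts from the PE
    plateau and recovers a group-specific fraction of the pre-constriction.
    """
    if specimen_id is None:
        specimen_id = f"{group}_{vessel}_P{int(age)}_s{seed}"
    rng = rng_for(seed, specimen_id + "/active")
    resp = cal.active_response_for(group, age, vessel)
    if truth is None:
        truth = cal.ground_truth_for(group, age, vessel)
    pressure = protocol_design(vessel)["active_pressure"]
    d0 = solve_diameter(truth.params, truth.R_o, truth.H, truth.lam_iv,
                        pressure)
    t = np.arange(0.0, duration + dt / 2, dt)
    decay = 1.0 - np.exp(-t / resp.tau)

    def noisy(d):
        out = d * (1.0 + noise_cv * rng.standard_normal(d.shape))
        out[0] = d[0]  # baseline recorded exactly at t=0
        return out

    kcl_amp = max(0.0, resp.kcl_amplitude * (1 + 0.05 * rng.standard_normal()))
    pe_amp = max(0.0, resp.pe_amplitude * (1 + 0.05 * rng.standard_normal()))
    d_kcl = d0 * (1.0 - kcl_amp * decay)
    d_pe = d0 * (1.0 - pe_amp * decay)
    pe_plateau = d0 * (1.0 - pe_amp)
    recovery = np.clip(resp.ach_recovery * (1 + 0.05 * rng.standard_normal()),
                       0.0, 1.0)
    d_ach = pe_plateau + recovery * (d0 - pe_plateau) * decay
    return [
        ActiveTrace("KCl100mM", pressure, t, noisy(d_kcl)),
        ActiveTrace("PE1uM", pressure, t, noisy(d_pe)),
        ActiveTrace("ACh10uM", pressure, t, noisy(d_ach)),
    ]


def _teichholz_ml(D_cm):
    return 7.0 / (2.4 + D_cm) * D_cm**3


def generate_echo_records(group, seed=0, n_animals=6, n_replicates=6,
                          animal_cv=0.03, technical_cv=0.005):
    """Echo acquisition tables for one group at the study end-point.

    Returns a list (one per animal) of lists of replicate
    :class:`~vesselmech.io.EchoRecord`.  The E wave is generated through a
    per-animal E/e' ratio so the cohort mean lands on the group target.
    """
    g = cal.ECHO_GROUPS[group]
    rng = rng_for(seed, f"echo/{group}")
    animals = []
    for i in range(n_animals):
        lvidd = g.LVIDd * np.exp(rng.normal(0, animal_cv))
        ef = np.clip(g.EF * (1 + rng.normal(0, animal_cv)), 10, 95)
        # invert Teichholz for the end-systolic dimension giving this EF
        edv = _teichholz_ml(lvidd / 10.0)
        esv_target = edv * (1 - ef / 100.0)
        lvids = 10.0 * brentq(lambda D: _teichholz_ml(D) - esv_target,
                              1e-6, lvidd / 10.0)
        ratio = g.E_over_eprime * (1 + rng.normal(0, animal_cv))
        e_prime = g.e_prime * (1 + rng.normal(0, animal_cv))
        E = ratio * e_prime
        A = E / (g.E_over_A * (1 + rng.normal(0, animal_cv)))
        hr = g.heart_rate * (1 + rng.normal(0, animal_cv))
        dt_ms = g.DT * (1 + rng.normal(0, animal_cv))
        mass = g.body_mass * (1 + rng.normal(0, animal_cv))
        reps = []
        for _ in range(n_replicates):
            jit = lambda v: float(v * (1 + rng.normal(0, technical_cv)))
            reps.append(EchoRecord(
                LVIDd=jit(lvidd), LVIDs=jit(lvids), heart_rate=jit(hr),
                E=jit(E), A=jit(A), e_prime=jit(e_prime), DT=jit(dt_ms),
                body_mass=float(mass)))
        animals.append(reps)
    return animals


# ---------------------------------------------------------------------------
# histology image synthesis

# representative stain colors (RGB, uint8); chosen inside the segmenter's
# default hue/saturation/value bands
MOVAT_COLORS = {
    "elastin": (20, 18, 22),
    "cytoplasm": (185, 40, 55),
    "proteoglycan": (60, 110, 200),
    "collagen": (220, 190, 70),
    "unclassified": (150, 148, 152),
}
ALIZARIN_COLORS = {
    "calcified": (140, 25, 35),
    "tissue": (235, 190, 195),
}
BACKGROUND_COLOR = (248, 248, 250)

#: fixed adventitial composition painted outside the media
ADVENTITIA_FRACTIONS = {"elastin": 0.05, "cytoplasm": 0.10,
                        "proteoglycan": 0.05, "collagen": 0.70}


def _annulus_masks(size, r_inner=0.28, r_media=0.42, r_outer=0.48):
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = np.hypot(yy - c, xx - c) / size
    tissue = (r >= r_inner) & (r <= r_outer)
    media = (r >= r_inner) & (r <= r_media)
    return tissue, media


def _paint(labels, image, mask, fractions, colors, rng, jitter=6):
    """Assign classes to exact pixel quotas within mask and color them."""
    idx = np.flatnonzero(mask.ravel())
    rng.shuffle(idx)
    n = idx.size
    start = 0
    names = list(fractions)
    counts = [int(round(f * n)) for f in fractions.values()]
    for name, cnt in zip(names, counts):
        sel = idx[start:start + cnt]
        start += cnt
        labels.ravel()[sel] = name_code(name)
        col = np.array(colors[name], dtype=float)
        pix = col + rng.integers(-jitter, jitter + 1, size=(sel.size, 3))
        image.reshape(-1, 3)[sel] = np.clip(pix, 0, 255).astype(np.uint8)
    # remainder of the mask stays "unclassified"
    sel = idx[start:]
    labels.ravel()[sel] = name_code("unclassified")
    col = np.array(colors["unclassified"], dtype=float)
    pix = col + rng.integers(-3, 4, size=(sel.size, 3))
    image.reshape(-1, 3)[sel] = np.clip(pix, 0, 255).astype(np.uint8)


_CLASS_CODES = {"background": 0, "elastin": 1, "cytoplasm": 2,
                "proteoglycan": 3, "collagen": 4, "unclassified": 5,
                "calcified": 6, "tissue": 7}


def name_code(name: str) -> int:
    return _CLASS_CODES[name]


def generate_histology_image(class_fractions, seed=0, size=256,
                             stain="movat", adventitia=ADVENTITIA_FRACTIONS):
    """Synthesize an annular stained section with painted class quotas.

    ``class_fractions`` are the medial area fractions.  Returns
    ``(rgb_image, truth)`` where truth carries the tissue and media masks and
    the exact painted per-class fractions for oracle tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xb10]))
    tissue, media = _annulus_masks(size)
    image = np.empty((size, size, 3), dtype=np.uint8)
    image[:] = BACKGROUND_COLOR
    image += rng.integers(0, 3, size=image.shape).astype(np.uint8)
    labels = np.zeros((size, size), dtype=np.uint8)

    if stain == "movat":
        fr = dict(class_fractions)
        unknown = set(fr) - {"elastin", "cytoplasm", "proteoglycan", "collagen"}
        if unknown:
            raise ValueError(f"unknown Movat classes {sorted(unknown)}")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        _paint(labels, image, media, fr, MOVAT_COLORS, rng)
        _paint(labels, image, tissue & ~media, adventitia, MOVAT_COLORS, rng)
    elif stain == "alizarin":
        fr = {"calcified": float(class_fractions["calcified"])}
        colors = dict(ALIZARIN_COLORS)
        colors["unclassified"] = ALIZARIN_COLORS["tissue"]
        _paint(labels, image, media, fr, colors, rng)
        _paint(labels, image, tissue & ~media, {"calcified": 0.0}, colors, rng)
    else:
        raise ValueError(f"unknown stain {stain!r}")

    painted = {}
    n_media = int(media.sum())
    for name in (fr if stain == "movat" else ["calcified"]):
        painted[name] = float((labels[media] == name_code(name)).sum() / n_media)
    truth = {"tissue_mask": tissue, "media_mask": media,
             "media_fractions": painted}
    return image, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    group: str
    age: int
    vessel: str
    n_specimens: int
    with_active: bool = True


@dataclass
class StudyConfig:
    """Composition of a full synthetic study."""

    cohorts: list
    echo_groups: dict          # group -> n animals
    histology_groups: dict     # group -> (n specimens, n replicate sections)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


DEFAULT_STUDY = StudyConfig(
    cohorts=[
        CohortSpec("WT", 168, "DTA", 5),
        CohortSpec("GG", 42, "DTA", 5),
        CohortSpec("GG", 100, "DTA", 5),
        CohortSpec("GG", 140, "DTA", 5),
        CohortSpec("GG", 168, "DTA", 5),
        CohortSpec("GG+L(P21)", 168, "DTA", 5),
        CohortSpec("GG+L(P100)", 168, "DTA", 4),
        CohortSpec("GG+L+R", 168, "DTA", 5),
        CohortSpec("WT", 168, "MA", 5),
        CohortSpec("GG", 168, "MA", 5),
        CohortSpec("GG+L(P21)", 168, "MA", 4),
    ],
    echo_groups={"WT": 6, "GG": 6, "GG+L(P21)": 6, "GG+L+R": 5},
    histology_groups={"WT": (5, 3), "GG": (5, 3), "GG+L(P21)": (5, 3)},
)


@dataclass
class StudyData:
    """In-memory synthetic study: everything the pipeline consumes."""

    specimens: list            # (SpecimenDataset, GroundTruth)
    echo: dict                 # group -> list of animals (replicate lists)
    histology: dict            # group -> list of (image, truth) sections
    survival: dict             # group -> {n_total, death_days}
    config: StudyConfig
    seed: int


def generate_cohorts(config: StudyConfig = DEFAULT_STUDY, seed: int = 0,
                     with_histology: bool = True) -> StudyData:
    """Generate the full synthetic study for one global seed."""
    specimens = []
    for spec in config.cohorts:
        for i in range(spec.n_specimens):
            sid = f"{spec.group}_{spec.vessel}_P{spec.age}_{i:02d}"
            ds, truth = generate_passive_dataset(
                spec.group, spec.age, spec.vessel, specimen_id=sid,
                seed=seed, config=config.generator)
            if spec.with_active:
                ds.active = generate_active_traces(
                    spec.group, spec.age, spec.vessel, truth=truth,
                    seed=seed, specimen_id=sid)
            specimens.append((ds, truth))

    echo = {g: generate_echo_records(g, seed=seed, n_animals=n)
            for g, n in config.echo_groups.items()}

    histology = {}
    if with_histology:
        for g, (n_spec, n_rep) in config.histology_groups.items():
            hg = cal.HISTOLOGY_GROUPS[g]
            sections = []
            for i in range(n_spec):
                for r in range(n_rep):
                    sec_seed = int(rng_for(seed, f"hist/{g}/{i}/{r}")
                                   .integers(0, 2**31 - 1))
                    img, truth = generate_histology_image(
                        hg.movat_fractions(), seed=sec_seed)
                    cal_img, cal_truth = generate_histology_image(
                        {"calcified": hg.calcified}, seed=sec_seed,
                        stain="alizarin")
                    sections.append({"specimen": i, "replicate": r,
                                     "movat": (img, truth),
                                     "alizarin": (cal_img, cal_truth)})
            histology[g] = sections

    return StudyData(specimens=specimens, echo=echo, histology=histology,
                     survival={g: dict(v) for g, v in cal.SURVIVAL.items()},
                     config=config, seed=seed)
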