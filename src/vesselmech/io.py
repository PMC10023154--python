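"""On-disk data model for biaxial vessel test datasets.

A specimen lives in one directory:

    specimen_dir/
      manifest.yaml        # identity, group, unloaded geometry, protocol index
      pd_*.csv             # pressure-diameter protocols (fixed axial stretch)
      fl_*.csv             # axial force-length protocols (fixed pressure)
      active_*.csv         # isobaric diameter time courses (optional)

Passive protocol CSVs carry four columns in fixed units:
``pressure_mmHg, outer_diameter_um, axial_force_mN, axial_stretch``.
Active CSVs carry ``time_s, outer_diameter_um``.  Floats are written with
17 significant digits, which round-trips float64 bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import IncompleteDatasetError, ValidationError

__all__ = [
    "GROUPS", "VESSELS", "STIMULI",
    "SpecimenRecord", "ProtocolTrace", "ActiveTrace", "EchoRecord",
    "SpecimenDataset", "ProtocolDesignReport",
    "read_specimen_dataset", "write_specimen_dataset",
    "validate_protocol_design", "protocol_design",
]

GROUPS = ("WT", "GG", "GG+L(P21)", "GG+L(P100)", "GG+L+R", "GG+R")
VESSELS = ("DTA", "MA")
STIMULI = ("KCl100mM", "PE1uM", "ACh10uM")

PASSIVE_COLUMNS = ["pressure_mmHg", "outer_diameter_um",
                   "axial_force_mN", "axial_stretch"]
ACTIVE_COLUMNS = ["time_s", "outer_diameter_um"]

#: protocol design per vessel: P-d pressure range (mmHg) and the fixed
#: pressures of the four axial force-length tests
PROTOCOL_DESIGN = {
    "DTA": {"pd_range": (10.0, 140.0), "fl_pressures": (10.0, 60.0, 100.0, 140.0),
            "active_pressure": 90.0},
    "MA": {"pd_range": (10.0, 90.0), "fl_pressures": (10.0, 30.0, 60.0, 90.0),
           "active_pressure": 60.0},
}


@dataclass(frozen=True)
class SpecimenRecord:
    """Identity, grouping and unloaded (traction-free) geometry of a vessel.

    Geometry: unloaded outer radius ``R_o`` and wall thickness ``H`` in um,
    unloaded length ``L`` in mm; ``lam_iv`` is the specimen-specific in vivo
    axial stretch.
    """

    specimen_id: str
    group: str
    age: float            # days
    vessel: str
    R_o: float            # um
    H: float              # um
    L: float              # mm
    lam_iv: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.vessel not in VESSELS:
            raise ValidationError(f"unknown vessel {self.vessel!r}")
        if not (self.R_o > self.H > 0):
            raise ValidationError("require R_o > H > 0")
        if not self.L > 0:
            raise ValidationError("require L > 0")
        if not self.lam_iv >= 1:
            raise ValidationError("in vivo axial stretch must be >= 1")
        if not self.age > 0:
            raise ValidationError("age must be positive")

    @property
    def R_i(self) -> float:
        return self.R_o - self.H


@dataclass
class ProtocolTrace:
    """One quasi-static loading protocol.

    ``protocol_kind`` is "Pd" (pressure swept at fixed axial stretch, the
    stretch in ``control_value``) or "fl" (axial force swept at fixed
    pressure, the pressure in mmHg in ``control_value``).  ``samples`` holds
    the four passive columns; ``is_unloading`` marks the (last) unloading
    pass used for fitting.
    """

    protocol_kind: str
    control_value: float
    samples: pd.DataFrame
    is_unloading: bool = True

    def __post_init__(self):
        if self.protocol_kind not in ("Pd", "fl"):
            raise ValidationError(f"unknown protocol kind {self.protocol_kind!r}")
        missing = [c for c in PASSIVE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"samples missing columns {missing}")
        if len(self.samples) < 10:
            raise ValidationError(
                f"protocol traces need >= 10 samples, got {len(self.samples)}")
        p = self.samples["pressure_mmHg"].to_numpy()
        if np.any(p < 0) or np.any(p > 160):
            raise ValidationError("pressures must lie within [0, 160] mmHg")
        if np.any(self.samples["outer_diameter_um"].to_numpy() <= 0):
            raise ValidationError("diameters must be positive")

    @property
    def label(self) -> str:
        if self.protocol_kind == "Pd":
            return f"Pd@lz={self.control_value:g}"
        return f"fl@{self.control_value:g}mmHg"


@dataclass
class ActiveTrace:
    """Isobaric diameter time course under a vasoactive stimulus."""

    stimulus: str
    fixed_pressure: float  # mmHg
    time: np.ndarray       # s
    outer_diameter: np.ndarray  # um

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.outer_diameter = np.asarray(self.outer_diameter, dtype=float)
        if self.stimulus not in STIMULI:
            raise ValidationError(f"unknown stimulus {self.stimulus!r}")
        if self.time.shape != self.outer_diameter.shape or self.time.ndim != 1:
            raise ValidationError("time and diameter must be 1-d and aligned")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if self.time[0] != 0.0:
            raise ValidationError("baseline diameter must be recorded at t=0")
        if np.any(self.outer_diameter <= 0):
            raise ValidationError("diameters must be positive")

    @property
    def baseline_diameter(self) -> float:
        return float(self.outer_diameter[0])


@dataclass(frozen=True)
class EchoRecord:
    """One echocardiographic acquisition (LV dimensions in mm, velocities in
    mm/s, deceleration time in ms, body mass in g)."""

    LVIDd: float
    LVIDs: float
    heart_rate: float
    E: float
    A: float
    e_prime: float
    DT: float
    body_mass: float

    def __post_init__(self):
        if not (self.LVIDd > self.LVIDs > 0):
            raise ValidationError("require LVIDd > LVIDs > 0")
        if self.heart_rate <= 0:
            raise ValidationError("heart rate must be positive")
        for name in ("E", "A", "e_prime"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} velocity must be positive")
        if self.DT <= 0 or self.body_mass <= 0:
            raise ValidationError("DT and body mass must be positive")


@dataclass
class SpecimenDataset:
    """A specimen record together with its passive and active traces."""

    record: SpecimenRecord
    passive: list = field(default_factory=list)
    active: list = field(default_factory=list)

    def validate(self) -> "SpecimenDataset":
        n_pd = sum(1 for t in self.passive if t.protocol_kind == "Pd")
        n_fl = sum(1 for t in self.passive if t.protocol_kind == "fl")
        if (n_pd, n_fl) != (3, 4):
            raise IncompleteDatasetError(
                f"incomplete dataset: expected 3 Pd + 4 fl protocols, "
                f"got {n_pd} Pd + {n_fl} fl")
        return self

    def fitting_traces(self) -> list:
        """The last-unloading-curve traces used for parameter estimation."""
        return [t for t in self.passive if t.is_unloading]


@dataclass
class ProtocolDesignReport:
    """Per-protocol conformance with the vessel-specific test design."""

    vessel: str
    entries: list = field(default_factory=list)   # (label, ok, message)
    missing: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.missing and all(ok for _, ok, _ in self.entries)


def protocol_design(vessel: str) -> dict:
    try:
        return PROTOCOL_DESIGN[vessel]
    except KeyError:
        raise ValidationError(f"unknown vessel {vessel!r}") from None


def validate_protocol_design(traces, vessel: str,
                             pressure_tol: float = 2.0) -> ProtocolDesignReport:
    """Flag traces whose pressure range or fixed pressure deviates from the
    vessel-specific design.  Report only; nothing is raised."""
    design = protocol_design(vessel)
    p_lo, p_hi = design["pd_range"]
    report = ProtocolDesignReport(vessel=vessel)

    pd_traces = [t for t in traces if t.protocol_kind == "Pd"]
    fl_traces = [t for t in traces if t.protocol_kind == "fl"]

    for t in pd_traces:
        p = t.samples["pressure_mmHg"].to_numpy()
        ok = (abs(p.min() - p_lo) <= pressure_tol
              and abs(p.max() - p_hi) <= pressure_tol)
        msg = ("" if ok else
               f"pressure range [{p.min():.1f}, {p.max():.1f}] deviates from "
               f"design [{p_lo:.0f}, {p_hi:.0f}] for {vessel}")
        report.entries.append((t.label, ok, msg))
    for t in fl_traces:
        ok = any(abs(t.control_value - fp) <= pressure_tol
                 for fp in design["fl_pressures"])
        msg = ("" if ok else
               f"fixed pressure {t.control_value:g} not in design set "
               f"{design['fl_pressures']} for {vessel}")
        report.entries.append((t.label, ok, msg))

    for _ in range(len(pd_traces), 3):
        report.missing.append("Pd protocol")
    found_fl = sorted(t.control_value for t in fl_traces)
    for fp in design["fl_pressures"]:
        if not any(abs(v - fp) <= pressure_tol for v in found_fl):
            report.missing.append(f"fl@{fp:g}mmHg")
    return report


# ---------------------------------------------------------------------------
# reading / writing


def _passive_filename(trace: ProtocolTrace, index: int) -> str:
    if trace.protocol_kind == "Pd":
        return f"pd_{index}.csv"
    return f"fl_{index}.csv"


def write_specimen_dataset(dataset: SpecimenDataset, path) -> Path:
    """Write a specimen directory (manifest + one CSV per trace)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec = dataset.record
    manifest = {
        "specimen_id": rec.specimen_id,
        "group": rec.group,
        "age": float(rec.age),
        "vessel": rec.vessel,
        "unloaded_outer_radius_um": float(rec.R_o),
        "unloaded_thickness_um": float(rec.H),
        "unloaded_length_mm": float(rec.L),
        "in_vivo_axial_stretch": float(rec.lam_iv),
        "passive_protocols": [],
        "active_protocols": [],
    }
    for i, trace in enumerate(dataset.passive):
        fname = _passive_filename(trace, i)
        # %.17g guarantees bit-exact float64 round trips
        trace.samples[PASSIVE_COLUMNS].to_csv(path / fname, index=False,
                                              float_format="%.17g")
        manifest["passive_protocols"].append({
            "kind": trace.protocol_kind,
            "control_value": float(trace.control_value),
            "is_unloading": bool(trace.is_unloading),
            "file": fname,
        })
    for i, trace in enumerate(dataset.active):
        fname = f"active_{i}.csv"
        pd.DataFrame({"time_s": trace.time,
                      "outer_diameter_um": trace.outer_diameter}
                     ).to_csv(path / fname, index=False,
                              float_format="%.17g")
        manifest["active_protocols"].append({
            "stimulus": trace.stimulus,
            "fixed_pressure_mmHg": float(trace.fixed_pressure),
            "file": fname,
        })
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_specimen_dataset(path, validate: bool = True) -> SpecimenDataset:
    """Read and validate a specimen directory written by
    :func:`write_specimen_dataset` (or by hand in the same layout)."""
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise IncompleteDatasetError(f"incomplete dataset: no manifest.yaml in {path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    record = SpecimenRecord(
        specimen_id=manifest["specimen_id"],
        group=manifest["group"],
        age=manifest["age"],
        vessel=manifest["vessel"],
        R_o=manifest["unloaded_outer_radius_um"],
        H=manifest["unloaded_thickness_um"],
        L=manifest["unloaded_length_mm"],
        lam_iv=manifest["in_vivo_axial_stretch"],
    )
    passive = []
    for entry in manifest.get("passive_protocols", []):
        fpath = path / entry["file"]
        if not fpath.exists():
            kind = entry["kind"]
            label = (f"Pd@lz={entry['control_value']:g}" if kind == "Pd"
                     else f"fl@{entry['control_value']:g}mmHg")
            raise IncompleteDatasetError(
                f"incomplete dataset: missing protocol file for {label}")
        samples = pd.read_csv(fpath, float_precision="round_trip",
                                dtype=float)
        passive.append(ProtocolTrace(
            protocol_kind=entry["kind"],
            control_value=entry["control_value"],
            samples=samples,
            is_unloading=entry.get("is_unloading", True),
        ))
    active = []
    for entry in manifest.get("active_protocols", []):
        fpath = path / entry["file"]
        if not fpath.exists():
            raise IncompleteDatasetError(
                f"incomplete dataset: missing active trace {entry['file']}")
        df = pd.read_csv(fpath, float_precision="round_trip",
                         dtype=float)
        active.append(ActiveTrace(
            stimulus=entry["stimulus"],
            fixed_pressure=entry["fixed_pressure_mmHg"],
            time=df["time_s"].to_numpy(),
            outer_diameter=df["outer_diameter_um"].to_numpy(),
        ))
    dataset = SpecimenDataset(record=record, passive=passive, active=active)
    if validate and passive:
        dataset.validate()
    return dataset
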