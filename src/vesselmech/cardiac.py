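"""Left-ventricular systolic and diastolic indices from echo measurements.

LV volumes come from M-mode internal dimensions through the Teichholz
formula ``V(D) = 7.0 / (2.4 + D) * D^3`` (D in cm, V in mL), with the plain
cube method available as an alternative.  Technical replicates of a record
are averaged before indices are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ValidationError
from .io import EchoRecord

__all__ = ["CardiacSummary", "lv_volumes", "systolic_indices",
           "diastolic_indices", "average_replicates", "summarize_echo"]

VOLUME_METHODS = ("teichholz", "cube")


@dataclass(frozen=True)
class CardiacSummary:
    EDV_ul: float
    ESV_ul: float
    SV_ul: float
    EF_pct: float
    FS_pct: float
    CO_ml_min: float
    E_over_A: float
    E_over_eprime: float
    DT_ms: float

    def to_dict(self) -> dict:
        return asdict(self)


def _volume_ul(D_mm: float, method: str) -> float:
    D_cm = D_mm / 10.0
    if method == "teichholz":
        v_ml = 7.0 / (2.4 + D_cm) * D_cm**3
    elif method == "cube":
        v_ml = D_cm**3
    else:
        raise ValueError(f"unknown volume method {method!r}; "
                         f"choose from {VOLUME_METHODS}")
    return 1000.0 * v_ml


def lv_volumes(LVIDd_mm: float, LVIDs_mm: float, method: str = "teichholz"):
    """End-diastolic and end-systolic LV volumes (uL)."""
    if not LVIDd_mm > LVIDs_mm > 0:
        raise ValidationError("require LVIDd > LVIDs > 0")
    return _volume_ul(LVIDd_mm, method), _volume_ul(LVIDs_mm, method)


def systolic_indices(record: EchoRecord, method: str = "teichholz"):
    """(EF %, FS %, SV uL, CO mL/min) of one (possibly averaged) record."""
    edv, esv = lv_volumes(record.LVIDd, record.LVIDs, method)
    sv = edv - esv
    ef = 100.0 * sv / edv
    fs = 100.0 * (record.LVIDd - record.LVIDs) / record.LVIDd
    co = sv * record.heart_rate / 1000.0  # uL/beat * bpm -> mL/min
    return ef, fs, sv, co


def diastolic_indices(record: EchoRecord):
    """(E/A, E/e', DT ms) of one (possibly averaged) record."""
    if record.A <= 0 or record.e_prime <= 0:
        raise ValidationError("A and e' must be positive")
    return record.E / record.A, record.E / record.e_prime, record.DT


def average_replicates(records) -> EchoRecord:
    """Mean of technical replicate acquisitions, field by field."""
    records = list(records)
    if not records:
        raise ValidationError("no echo records to average")
    fields = ("LVIDd", "LVIDs", "heart_rate", "E", "A", "e_prime", "DT",
              "body_mass")
    means = {f: float(np.mean([getattr(r, f) for r in records]))
             for f in fields}
    return EchoRecord(**means)


def summarize_echo(records, method: str = "teichholz") -> CardiacSummary:
    """Replicate-averaged systolic and diastolic indices of one animal."""
    rec = average_replicates(records)
    ef, fs, sv, co = systolic_indices(rec, method)
    edv, esv = lv_volumes(rec.LVIDd, rec.LVIDs, method)
    e_a, e_ep, dt = diastolic_indices(rec)
    return CardiacSummary(EDV_ul=edv, ESV_ul=esv, SV_ul=sv, EF_pct=ef,
                          FS_pct=fs, CO_ml_min=co, E_over_A=e_a,
                          E_over_eprime=e_ep, DT_ms=dt)
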