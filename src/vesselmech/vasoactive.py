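"""Vasoactive function from isobaric diameter time courses.

Constriction to a depolarizing stimulus (100 mM KCl) or an agonist (1 uM
phenylephrine) is quantified as the percent diameter reduction from the
t = 0 baseline to the steady state at 10 min, plus the time to half of the
total response.  Endothelium-dependent dilation (10 uM acetylcholine after
phenylephrine pre-constriction) is the percent of the pre-constriction
recovered; it is undefined when the vessel failed to pre-constrict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io import ActiveTrace

__all__ = ["VasoactiveSummary", "constriction_metrics", "dilation_metrics"]

STEADY_STATE_TIME = 600.0     # s; "steady-state response at 10 min"
TRAILING_WINDOW = 30.0        # s of trailing median around the read-out
NO_RESPONSE_FRACTION = 0.01   # constriction below 1% of baseline


@dataclass
class VasoactiveSummary:
    baseline_d: float
    plateau_d: float
    percent_constriction: float
    time_to_half_response: float        # s; nan when flagged
    percent_dilation: float = float("nan")
    flags: list = field(default_factory=list)


def constriction_metrics(trace: ActiveTrace,
                         steady_time: float = STEADY_STATE_TIME,
                         window: float = TRAILING_WINDOW) -> VasoactiveSummary:
    """Constriction magnitude and half-response time of one active trace.

    The steady-state diameter is the median over the trailing ``window``
    seconds up to ``steady_time`` (noise suppression); the half-response
    time is the first sample at which the diameter has fallen halfway from
    baseline to plateau.
    """
    t = trace.time
    d = trace.outer_diameter
    if t[-1] < steady_time:
        raise ValidationError(
            f"trace spans {t[-1]:.0f} s; need >= {steady_time:.0f} s "
            "to read the steady-state response")
    baseline = float(d[0])
    sel = (t >= steady_time - window) & (t <= steady_time)
    plateau = float(np.median(d[sel]))
    pct = 100.0 * (baseline - plateau) / baseline

    flags = []
    if baseline - plateau < NO_RESPONSE_FRACTION * baseline:
        flags.append("no_response")
        t_half = float("nan")
    else:
        half_level = baseline - 0.5 * (baseline - plateau)
        below = np.flatnonzero(d <= half_level)
        t_half = float(t[below[0]]) if below.size else float("nan")
        if not below.size:
            flags.append("half_response_not_reached")
    return VasoactiveSummary(baseline_d=baseline, plateau_d=plateau,
                             percent_constriction=pct,
                             time_to_half_response=t_half, flags=flags)


def dilation_metrics(baseline_d: float, d_pe: float, d_ach: float,
                     min_preconstriction: float = NO_RESPONSE_FRACTION):
    """Percent ACh dilation relative to the PE pre-constriction.

    Returns ``(percent_dilation, flags)``.  When the pre-constriction is
    below ``min_preconstriction`` of baseline the dilation is undefined (a
    vessel that cannot contract provides no information on
    endothelium-dependent dilation) and nan is returned with a
    ``no_preconstriction`` flag.
    """
    if d_pe > baseline_d:
        raise ValidationError("PE diameter exceeds baseline; "
                              "pre-constriction not attempted?")
    depth = baseline_d - d_pe
    if depth < min_preconstriction * baseline_d:
        return float("nan"), ["no_preconstriction"]
    return 100.0 * (d_ach - d_pe) / depth, []
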