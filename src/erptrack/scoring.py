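"""Component scoring: mean amplitude, peak latency, peak-to-trough, difference.

All measures operate on a subject-visit :class:`~erptrack.preprocess.SubjectERP`.
Mean amplitude is the arithmetic mean over the component's closed time window
and then over its critical electrodes. Peak latency is the per-electrode
extreme-sample time (max for positive, min for negative components; earliest
sample on ties) averaged across electrodes on the 512 Hz grid — no
sub-sample interpolation. Peak-to-trough corrects a component's mean
amplitude for carryover from the preceding deflection: the P1 subtracts the
70–90 ms N80 *mean*, while the N290 and P400 subtract the preceding
component's extreme-sample *peak value*, evaluated on the current
component's electrode set for a consistent subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import COMPONENTS, CONDITIONS, FAMILY_OF, SCORED_COMPONENTS, ComponentDef, channel_index
from .preprocess import SubjectERP


class NotIncludedError(ValueError):
    """Subject-visit does not meet the inclusion rule for this component."""


class UnsupportedMeasureError(ValueError):
    """Measure not defined for this component/condition (e.g. N290 house latency)."""


@dataclass(frozen=True)
class LatencyResult:
    """Peak latency in ms with a low-confidence flag for all-tie (flat) windows."""

    value_ms: float
    per_electrode_ms: tuple[float, ...]
    low_confidence: bool


@dataclass(frozen=True)
class ComponentScore:
    subject: str
    visit: int
    component: str
    condition: str
    mean_amplitude: float
    peak_latency: float | None = None
    peak_to_trough: float | None = None


@dataclass(frozen=True)
class DifferenceScore:
    subject: str
    visit: int
    component: str
    value: float  # face mean amplitude − house mean amplitude, μV


def _require_included(erp: SubjectERP, cdef: ComponentDef) -> None:
    fam = FAMILY_OF[cdef.name]
    if not erp.family_included.get(fam, False):
        raise NotIncludedError(
            f"{erp.subject} visit {erp.visit} not included for family {fam!r}"
        )
    idx = channel_index(erp.channels, cdef.electrodes)
    if erp.electrode_rejected[idx].any():
        raise NotIncludedError(
            f"critical electrode rejected for {cdef.name} in {erp.subject} visit {erp.visit}"
        )


def mean_amplitude(erp: SubjectERP, cdef: ComponentDef, condition: str) -> float:
    """Mean μV over the component window, averaged across critical electrodes."""
    _require_included(erp, cdef)
    idx = channel_index(erp.channels, cdef.electrodes)
    win = erp.sample_window(*cdef.window)
    return float(erp.waveforms[condition][idx, win].mean())


def peak_latency(erp: SubjectERP, cdef: ComponentDef, condition: str) -> LatencyResult:
    """Latency of the extreme sample per electrode, averaged across electrodes.

    The N290 has no detectable house peak; requesting it raises
    :class:`UnsupportedMeasureError`. A completely flat window returns the
    window-start sample flagged low-confidence.
    """
    if cdef.name == "N290" and condition == "house":
        raise UnsupportedMeasureError("N290 peak latency is defined for faces only")
    _require_included(erp, cdef)
    idx = channel_index(erp.channels, cdef.electrodes)
    win = erp.sample_window(*cdef.window)
    seg = erp.waveforms[condition][idx, win]
    # argmax/argmin return the earliest sample on exact ties
    pick = seg.argmax(axis=1) if cdef.polarity == "positive" else seg.argmin(axis=1)
    t0 = erp.first_sample + win.start
    lats = (t0 + pick) * 1000.0 / erp.fs
    flat = bool(np.all(seg == seg[:, :1]))
    return LatencyResult(float(lats.mean()), tuple(float(v) for v in lats), flat)


def _preceding_peak_value(erp: SubjectERP, cdef: ComponentDef, condition: str,
                          peak_electrodes: str = "current") -> float:
    """Extreme-sample amplitude of the preceding component inside *its* window,
    averaged over either the current or the preceding component's electrodes."""
    prev = COMPONENTS[cdef.preceding]
    electrodes = cdef.electrodes if peak_electrodes == "current" else prev.electrodes
    idx = channel_index(erp.channels, electrodes)
    win = erp.sample_window(*prev.window)
    seg = erp.waveforms[condition][idx, win]
    ext = seg.max(axis=1) if prev.polarity == "positive" else seg.min(axis=1)
    return float(ext.mean())


def peak_to_trough(erp: SubjectERP, cdef: ComponentDef, condition: str,
                   peak_electrodes: str = "current") -> float:
    """Carryover-corrected amplitude, defined for the P1, N290 and P400.

    P1: mean(P1 window) − mean(N80 window). N290: mean(N290 window) − most
    positive P1 sample. P400: mean(P400 window) − most negative N290 sample.
    ``peak_electrodes`` selects where the preceding peak is evaluated:
    ``"current"`` (default) uses the current component's electrode set so the
    subtraction compares like with like; ``"preceding"`` uses the preceding
    component's own electrodes.
    """
    if cdef.name not in ("P1", "N290", "P400"):
        raise UnsupportedMeasureError(f"peak-to-trough is not defined for {cdef.name}")
    if peak_electrodes not in ("current", "preceding"):
        raise ValueError("peak_electrodes must be 'current' or 'preceding'")
    base = mean_amplitude(erp, cdef, condition)
    if cdef.name == "P1":
        n80 = COMPONENTS["N80"]
        electrodes = cdef.electrodes if peak_electrodes == "current" else n80.electrodes
        idx = channel_index(erp.channels, electrodes)
        win = erp.sample_window(*n80.window)
        ref = float(erp.waveforms[condition][idx, win].mean())
    else:
        ref = _preceding_peak_value(erp, cdef, condition, peak_electrodes)
    return base - ref


def difference_score(face: ComponentScore, house: ComponentScore) -> DifferenceScore:
    """Face − house mean amplitude for matching subject/visit/component."""
    if (face.subject, face.visit, face.component) != (house.subject, house.visit, house.component):
        raise ValueError("mismatched subject/visit/component keys")
    if (face.condition, house.condition) != ("face", "house"):
        raise ValueError("arguments must be the face and house scores, in that order")
    return DifferenceScore(
        face.subject, face.visit, face.component,
        face.mean_amplitude - house.mean_amplitude,
    )


def score_subject(erp: SubjectERP) -> pd.DataFrame:
    """Tidy long table of every defined measure for one subject-visit.

    Columns: subject, visit, component, condition, measure, value. Components
    whose inclusion family fails the ≥10-trial rule are omitted (exclusion
    propagates, it is not an error). Measures: mean_amplitude for all scored
    components; peak_to_trough for P1/N290/P400; peak_latency for P1 (both
    conditions) and the N290 (faces only).
    """
    rows = []

    def add(component: str, condition: str, measure: str, value: float) -> None:
        rows.append({
            "subject": erp.subject, "visit": erp.visit, "component": component,
            "condition": condition, "measure": measure, "value": value,
        })

    for comp in SCORED_COMPONENTS:
        cdef = COMPONENTS[comp]
        try:
            _require_included(erp, cdef)
        except NotIncludedError:
            continue
        for cond in CONDITIONS:
            add(comp, cond, "mean_amplitude", mean_amplitude(erp, cdef, cond))
            if comp in ("P1", "N290", "P400"):
                add(comp, cond, "peak_to_trough", peak_to_trough(erp, cdef, cond))
            if comp == "P1" or (comp == "N290" and cond == "face"):
                add(comp, cond, "peak_latency", peak_latency(erp, cdef, cond).value_ms)
    return pd.DataFrame(rows, columns=["subject", "visit", "component", "condition", "measure", "value"])


def differences_from_scores(scores: pd.DataFrame, measure: str = "mean_amplitude") -> pd.DataFrame:
    """Face−house difference per subject/visit/component from a tidy scores table."""
    empty = pd.DataFrame(columns=["subject", "visit", "component", "difference"])
    sub = scores[scores["measure"] == measure]
    if sub.empty:
        return empty
    wide = sub.pivot_table(
        index=["subject", "visit", "component"], columns="condition", values="value",
        aggfunc="first",
    )
    if "face" not in wide.columns or "house" not in wide.columns:
        return empty
    wide = wide.dropna(subset=["face", "house"])
    out = wide.reset_index()
    out["difference"] = out["face"] - out["house"]
    return out[["subject", "visit", "component", "difference"]]
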