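"""ERP component definitions for the infant face-categorization task.

Windows, electrode sets, polarities and the peak-to-trough precedence chain
for the five components scored by this package: the N80 trough, the P1, the
N290, the P400 and the fronto-central Nc. All times are milliseconds
post-stimulus; electrode labels follow the international 10-20 system.
"""

from __future__ import annotations

from dataclasses import dataclass


#: The 32-channel BioSemi 10-20 montage used throughout (28 lateral + 4 midline).
MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F8", "F3", "F4", "AF3", "AF4",
    "FC1", "FC2", "FC5", "FC6", "C3", "C4", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "P3", "P4", "P7", "P8",
    "O1", "O2", "PO3", "PO4", "Fz", "Cz", "Pz", "Oz",
)

P1_ELECTRODES: tuple[str, ...] = ("PO3", "O1", "Oz", "O2", "PO4")
N290_P400_ELECTRODES: tuple[str, ...] = ("P3", "PO3", "O1", "Oz", "O2", "PO4", "P4")
NC_ELECTRODES: tuple[str, ...] = ("Fz", "C3", "C4")


@dataclass(frozen=True)
class ComponentDef:
    """Scoring definition of one ERP component.

    Parameters
    ----------
    name : str
        Component label (``N80``, ``P1``, ``N290``, ``P400`` or ``Nc``).
    window : (float, float)
        Closed scoring window in ms post-stimulus; a sample at time t belongs
        iff ``window[0] <= t <= window[1]``.
    electrodes : tuple of str
        Critical electrodes whose waveforms are averaged for this component.
    polarity : str
        ``"positive"`` or ``"negative"``; the direction of the deflection,
        used for peak-latency extraction.
    preceding : str or None
        Name of the preceding component used by the peak-to-trough
        correction, or None when no correction is defined.
    """

    name: str
    window: tuple[float, float]
    electrodes: tuple[str, ...]
    polarity: str
    preceding: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"invalid window for {self.name}: {self.window}")
        unknown = set(self.electrodes) - set(MONTAGE)
        if unknown:
            raise ValueError(f"electrodes not in montage: {sorted(unknown)}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")


#: Canonical definitions. The precedence chain N80 -> P1 -> N290 -> P400 feeds
#: the peak-to-trough correction; the Nc has no preceding component.
COMPONENTS: dict[str, ComponentDef] = {
    "N80": ComponentDef("N80", (70.0, 90.0), P1_ELECTRODES, "negative"),
    "P1": ComponentDef("P1", (90.0, 180.0), P1_ELECTRODES, "positive", preceding="N80"),
    "N290": ComponentDef("N290", (170.0, 300.0), N290_P400_ELECTRODES, "negative", preceding="P1"),
    "P400": ComponentDef("P400", (300.0, 500.0), N290_P400_ELECTRODES, "positive", preceding="N290"),
    "Nc": ComponentDef("Nc", (300.0, 600.0), NC_ELECTRODES, "negative"),
}

#: Components carrying a face-categorization difference score (N80 is only a
#: correction trough, never analysed on its own).
SCORED_COMPONENTS: tuple[str, ...] = ("P1", "N290", "P400", "Nc")

#: Inclusion families: a subject-visit enters a component's analyses only if
#: every critical electrode of the family retains >= 10 trials per condition.
FAMILIES: dict[str, tuple[str, ...]] = {
    "P1": P1_ELECTRODES,
    "N290/P400": N290_P400_ELECTRODES,
    "Nc": NC_ELECTRODES,
}

#: Which inclusion family gates each component.
FAMILY_OF: dict[str, str] = {
    "N80": "P1",
    "P1": "P1",
    "N290": "N290/P400",
    "P400": "N290/P400",
    "Nc": "Nc",
}

#: Conditions of the passive-viewing contrast.
CONDITIONS: tuple[str, str] = ("face", "house")


def channel_index(labels: tuple[str, ...] | list[str], names: tuple[str, ...] | list[str]) -> list[int]:
    """Indices of ``names`` within ``labels``; raises on unknown labels."""
    lookup = {lab: i for i, lab in enumerate(labels)}
    try:
        return [lookup[n] for n in names]
    except KeyError as exc:
        raise KeyError(f"electrode {exc.args[0]!r} not present in recording") from exc
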