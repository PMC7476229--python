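"""Descriptive Markov transition analysis of longitudinal difference scores.

Each subject's face−house difference is classified at each visit into one of
three states — ``negative`` (< −threshold), ``none`` (|d| ≤ threshold) or
``positive`` (> threshold), threshold 1.5 μV by default — and the 3×3
visit-1 → visit-2 transition counts, row-normalized probabilities and the
dominant-group summary percentages are computed. The model is purely
descriptive: no likelihood is fitted and no stationarity is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

STATES = ("negative", "none", "positive")
DEFAULT_THRESHOLD = 1.5  # μV


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_state(value: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Three-way state of a difference score; boundary |d| = threshold → none."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if value < -threshold:
        return "negative"
    if value > threshold:
        return "positive"
    return "none"


@dataclass
class TransitionTable:
    """3×3 state-transition counts and probabilities for one component.

    Rows index the visit-1 state, columns the visit-2 state, both ordered
    (negative, none, positive). ``probabilities`` rows are normalized counts;
    rows with a zero visit-1 marginal are NaN and listed in
    ``undefined_rows``.
    """

    component: str
    counts: np.ndarray
    n_subjects: int

    probabilities: np.ndarray = field(init=False)
    undefined_rows: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("counts must be 3x3")
        if self.counts.sum() != self.n_subjects:
            raise ValueError("counts must sum to the number of classified subjects")
        row = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.probabilities = self.counts / row[:, None]
        self.undefined_rows = [STATES[i] for i in np.nonzero(row == 0)[0]]
        self.probabilities[row == 0] = np.nan

    @property
    def visit1_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def visit2_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s1 in enumerate(STATES):
            for j, s2 in enumerate(STATES):
                rows.append({
                    "component": self.component, "visit1_state": s1, "visit2_state": s2,
                    "count": int(self.counts[i, j]),
                    "probability": float(self.probabilities[i, j]),
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DominantSummary:
    """Summary percentages around the modal visit-1 state.

    ``dominant_share_v1/v2``: size of the dominant state as % of classified
    subjects per visit; ``persistence_pct``: % of visit-1 dominant subjects
    staying dominant at visit 2; ``mover_share_pct``: % of visit-1
    non-dominant subjects ending dominant at visit 2; ``both_visit_pct``:
    stayers as % of all classified subjects. Percentages are rounded half-up
    to integers, except ``both_visit_pct`` which keeps two decimals when not
    integral. Ties for the modal state are flagged and all tied states
    reported.
    """

    component: str
    dominant_state: str
    tied_states: tuple[str, ...]
    dominant_share_v1: float
    dominant_share_v2: float
    persistence_pct: float
    mover_share_pct: float
    both_visit_pct: float

    @property
    def tie(self) -> bool:
        return len(self.tied_states) > 1


def build_transition_table(states_v1, states_v2, component: str = "") -> TransitionTable:
    """Cross-tabulate per-subject states at the two visits (paired order)."""
    v1 = list(states_v1)
    v2 = list(states_v2)
    if len(v1) != len(v2):
        raise ValueError("states_v1 and states_v2 must describe the same subjects")
    if not v1:
        raise ValueError("empty table: no classified subjects")
    idx = {s: i for i, s in enumerate(STATES)}
    counts = np.zeros((3, 3), dtype=int)
    for a, b in zip(v1, v2):
        counts[idx[a], idx[b]] += 1
    return TransitionTable(component, counts, len(v1))


def _pct(numer: int, denom: int, two_decimals: bool = False) -> float:
    if denom == 0:
        return 0.0
    raw = 100.0 * numer / denom
    if two_decimals:
        r = round_half_up(raw, 2)
        return r if r != int(r) else float(int(r))
    return round_half_up(raw, 0)


def summarize_dominant(table: TransitionTable) -> DominantSummary:
    """Dominant-group shares, persistence and mover percentages.

    The dominant state is the modal visit-1 state; on a tie the first state
    in (negative, none, positive) order is summarized and all tied states are
    reported via ``tied_states``.
    """
    sizes = table.visit1_sizes
    top = sizes.max()
    tied = tuple(STATES[i] for i in np.nonzero(sizes == top)[0])
    d = STATES.index(tied[0])
    n = table.n_subjects
    stayers = int(table.counts[d, d])
    nondom_v1 = int(n - sizes[d])
    movers = int(table.counts[:, d].sum() - stayers)
    return DominantSummary(
        component=table.component,
        dominant_state=tied[0],
        tied_states=tied,
        dominant_share_v1=_pct(int(sizes[d]), n),
        dominant_share_v2=_pct(int(table.visit2_sizes[d]), n),
        persistence_pct=_pct(stayers, int(sizes[d])),
        mover_share_pct=_pct(movers, nondom_v1),
        both_visit_pct=_pct(stayers, n, two_decimals=True),
    )


def component_trajectories(
    differences: pd.DataFrame,
    component: str,
    threshold: float = DEFAULT_THRESHOLD,
    value_col: str = "difference",
) -> TransitionTable | None:
    """Classify + tabulate one component from a tidy differences frame.

    ``differences`` needs columns subject, visit, component and
    ``value_col``. Subjects missing the component at either visit are
    dropped from this component's table only. Returns None when no subject
    has both visits.
    """
    sub = differences[differences["component"] == component]
    wide = sub.pivot_table(index="subject", columns="visit", values=value_col, aggfunc="first")
    wide = wide.dropna()
    if wide.empty:
        return None
    s1 = [classify_state(v, threshold) for v in wide[1]]
    s2 = [classify_state(v, threshold) for v in wide[2]]
    return build_transition_table(s1, s2, component)


def to_dot(table: TransitionTable, summary: DominantSummary | None = None) -> str:
    """Graphviz description of the transition diagram (probabilities as edge
    labels, visit-1 shares inside nodes)."""
    sizes = table.visit1_sizes
    n = table.n_subjects
    lines = [f'digraph "{table.component}" {{', "  rankdir=LR;"]
    for i, s in enumerate(STATES):
        share = 100.0 * sizes[i] / n if n else 0.0
        lines.append(f'  {s} [label="{s}\\n{share:.1f}%"];')
    for i, s1 in enumerate(STATES):
        for j, s2 in enumerate(STATES):
            p = table.probabilities[i, j]
            if np.isfinite(p) and table.counts[i, j] > 0:
                lines.append(f'  {s1} -> {s2} [label="{100 * p:.0f}%"];')
    lines.append("}")
    return "\n".join(lines)
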