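"""Within-subject inferential statistics, implemented from first principles.

Three procedures cover the analysis layer of the longitudinal two-visit
design: a fully-within 2×2 repeated-measures ANOVA (stimulus × visit, each
effect tested against its subject-by-effect interaction, partial η² =
SS_effect / (SS_effect + SS_error)), the classical paired t-test with
Cohen's d = mean(diff) / SD(diff), and the Brown–Forsythe homogeneity test
(one-way ANOVA on absolute deviations from group medians).

With 2-level factors sphericity holds trivially (1 numerator df), so no
correction is applied; all p-values are two-sided. Zero error variance
yields an "undefined" result object rather than an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect in the printed form F(df1, df2)."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    undefined: bool = False


@dataclass(frozen=True)
class AnovaResult:
    stimulus: EffectResult
    visit: EffectResult
    interaction: EffectResult
    n: int
    cell_means: dict[str, float]
    cell_sds: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in (self.stimulus, self.visit, self.interaction):
            rows.append({
                "effect": eff.effect, "F": eff.F, "df1": eff.df1, "df2": eff.df2,
                "p": eff.p, "partial_eta_sq": eff.partial_eta_sq,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float
    mean_diff: float
    undefined: bool = False


@dataclass(frozen=True)
class BrownForsytheResult:
    F: float
    df1: int
    df2: int
    p: float


CELLS = ("face_v1", "face_v2", "house_v1", "house_v2")


def _effect(name: str, ss_eff: float, ss_err: float, n: int) -> EffectResult:
    df1, df2 = 1, n - 1
    if ss_err <= 0.0:
        undef = ss_eff > 0.0
        # zero effect and zero error: F is 0/0; nonzero effect over zero error
        # is reported as undefined rather than infinite
        return EffectResult(name, math.nan, df1, df2, math.nan,
                            math.nan if undef else 0.0, undefined=True)
    f = (ss_eff / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta = ss_eff / (ss_eff + ss_err)
    return EffectResult(name, float(f), df1, df2, p, float(eta))


def rm_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """2×2 fully-within ANOVA on a wide table with columns
    face_v1, face_v2, house_v1, house_v2 (one row per subject, complete cases).

    Decomposition: for factor A (stimulus), SS_A = 2n·Σ_i(m_i − grand)² with
    error SS_{A×S} = 2·Σ_{i,s}(m_{is} − m_i − m_s + grand)², and analogously
    for visit and the interaction (error = three-way residual). Each F has
    (1, n−1) degrees of freedom.
    """
    missing = [c for c in CELLS if c not in table.columns]
    if missing:
        raise ValueError(f"missing cells: {missing}")
    y = table[list(CELLS)].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("complete cases required (NaN cell found)")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    # y columns: (face,v1), (face,v2), (house,v1), (house,v2)
    cube = y.reshape(n, 2, 2)  # subject x stimulus x visit
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))          # subject means
    m_a = cube.mean(axis=(0, 2))          # stimulus means
    m_b = cube.mean(axis=(0, 1))          # visit means
    m_as = cube.mean(axis=2)              # subject x stimulus
    m_bs = cube.mean(axis=1)              # subject x visit
    m_ab = cube.mean(axis=0)              # stimulus x visit

    ss_a = 2 * n * ((m_a - grand) ** 2).sum()
    ss_b = 2 * n * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_axs = 2 * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bxs = 2 * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    resid = (
        cube
        - m_as[:, :, None] - m_bs[:, None, :] - m_ab[None, :, :]
        + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
        - grand
    )
    ss_abxs = (resid ** 2).sum()

    cell_means = {c: float(y[:, i].mean()) for i, c in enumerate(CELLS)}
    cell_sds = {c: float(y[:, i].std(ddof=1)) for i, c in enumerate(CELLS)}
    return AnovaResult(
        _effect("stimulus", ss_a, ss_axs, n),
        _effect("visit", ss_b, ss_bxs, n),
        _effect("stimulus:visit", ss_ab, ss_abxs, n),
        n, cell_means, cell_sds,
    )


def paired_ttest(x, y) -> TTestResult:
    """Classical paired t with Cohen's d on the difference scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    md = float(d.mean())
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(0.0, n - 1, 1.0, 0.0, 0.0, undefined=True)
        return TTestResult(math.nan, n - 1, math.nan, math.nan, md, undefined=True)
    t = md / (sd / math.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return TTestResult(float(t), n - 1, p, float(md / sd), md)


def brown_forsythe(*groups) -> BrownForsytheResult:
    """Brown–Forsythe test: one-way ANOVA on |x − median(group)|.

    Robust check that groups share a common spread; deviations identically
    zero (all groups constant) give F = 0 by convention, df unchanged.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    z = [np.abs(g - np.median(g)) for g in gs]
    k = len(z)
    n_total = sum(g.size for g in z)
    grand = np.concatenate(z).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in z)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else math.inf
        p = 1.0 if ss_between == 0.0 else 0.0
        return BrownForsytheResult(f, df1, df2, p)
    f = (ss_between / df1) / (ss_within / df2)
    return BrownForsytheResult(float(f), df1, df2, float(sps.f.sf(f, df1, df2)))


def anova_table_from_scores(
    scores: pd.DataFrame, component: str, measure: str = "mean_amplitude"
) -> pd.DataFrame:
    """Wide complete-case 2×2 table for one component from the tidy scores TSV."""
    sub = scores[(scores["component"] == component) & (scores["measure"] == measure)]
    if sub.empty:
        return pd.DataFrame(columns=list(CELLS))
    wide = sub.pivot_table(
        index="subject", columns=["condition", "visit"], values="value", aggfunc="first",
    )
    out = pd.DataFrame(index=wide.index)
    for cond in ("face", "house"):
        for visit in (1, 2):
            key = (cond, visit)
            out[f"{cond}_v{visit}"] = wide[key] if key in wide.columns else np.nan
    return out.dropna()
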