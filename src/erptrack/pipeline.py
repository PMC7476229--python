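"""End-to-end pipeline: simulate → preprocess → score → trajectories → stats.

All analysis artifacts are TSV (diff-able and locale-independent); a single
seed drives every source of randomness, so a fixed configuration yields a
byte-identical output bundle. Stages can run in one call
(:func:`run_pipeline`) or individually through the CLI, persisting
intermediates under the output directory:

    raw/                 recording + event tables (generator layout)
    erp/                 per subject-visit average waveforms + metadata
    scores.tsv           tidy (subject, visit, component, condition, measure, value)
    differences.tsv      face−house difference per subject/visit/component
    transitions_<c>.tsv  3×3 counts + probabilities per component
    summaries.tsv        dominant-group summary percentages
    anova.tsv / ttests.tsv / brown_forsythe.tsv
    rejection_log.tsv    per-stage exclusion counts, reconciled
    config.yaml          parameter echo
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .components import CONDITIONS, SCORED_COMPONENTS
from .preprocess import STATUS_INCLUDED, SubjectERP, preprocess_recording
from .scoring import differences_from_scores, score_subject
from .stats import anova_table_from_scores, brown_forsythe, paired_ttest, rm_anova_2x2
from .synthetic import (
    CohortConfig, generate_cohort, read_recording_tsv,
    write_ground_truth_tsv, write_recording_tsv,
)
from .trajectories import (
    DEFAULT_THRESHOLD, component_trajectories, summarize_dominant, to_dot,
)

log = logging.getLogger("erptrack")

SCORE_COLUMNS = ["subject", "visit", "component", "condition", "measure", "value"]


@dataclass
class PipelineConfig:
    """Serializable configuration for a full run; defaults match the study."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    state_threshold: float = DEFAULT_THRESHOLD
    simulate: bool = True
    out_dir: str | None = None
    in_dir: str | None = None        # read raw recordings here when simulate=False
    write_raw: bool = False          # persist raw traces (large) during simulate
    write_erp: bool = False          # persist per-subject average waveforms
    report_precision: int = 6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = {k: tuple(v) if isinstance(v, list) else v for k, v in cohort.items()}
            cohort = CohortConfig(**cohort)
        return cls(cohort=cohort, **d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunLog:
    """Per-stage item counts with exclusion reasons; reconciles across stages."""

    rows: list[dict] = field(default_factory=list)

    def add(self, stage: str, reason: str, count: int) -> None:
        self.rows.append({"stage": stage, "reason": reason, "count": int(count)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "reason", "count"])


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    differences: pd.DataFrame
    transitions: dict
    summaries: pd.DataFrame
    anova: pd.DataFrame
    ttests: pd.DataFrame
    brown_forsythe: pd.DataFrame
    run_log: pd.DataFrame
    ground_truth: object | None = None


# ---------------------------------------------------------------------------
# persistence helpers


def write_table(path, table: pd.DataFrame) -> None:
    """Lossless TSV write (full float precision, '.' decimal separator)."""
    table.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    """Read a tidy scores TSV, diagnosing any missing column by name."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scores table at {path} is missing columns: {missing}")
    return df


def write_subject_erp(erp: SubjectERP, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{erp.subject}_v{erp.visit}"
    times = erp.times_ms
    rows = []
    for cond in CONDITIONS:
        wf = erp.waveforms[cond]
        for c, label in enumerate(erp.channels):
            rows.append(pd.DataFrame({
                "condition": cond, "electrode": label,
                "time_ms": times, "value": wf[c],
            }))
    pd.concat(rows, ignore_index=True).to_csv(out_dir / f"{stem}_waves.tsv", sep="\t", index=False)
    meta = []
    for c, label in enumerate(erp.channels):
        meta.append({
            "electrode": label, "rejected": bool(erp.electrode_rejected[c]),
            **{f"n_trials_{cond}": int(erp.n_trials[cond][c]) for cond in CONDITIONS},
        })
    mf = pd.DataFrame(meta)
    for fam, ok in erp.family_included.items():
        mf[f"included_{fam.replace('/', '_')}"] = bool(ok)
    mf.insert(0, "visit", erp.visit)
    mf.insert(0, "subject", erp.subject)
    mf.to_csv(out_dir / f"{stem}_meta.tsv", sep="\t", index=False)


def grand_average(erps: list[SubjectERP]) -> pd.DataFrame:
    """Long-format grand-average waveforms (electrode, time_ms, condition, visit, μV)."""
    rows = []
    for visit in (1, 2):
        sel = [e for e in erps if e.visit == visit]
        if not sel:
            continue
        times = sel[0].times_ms
        for cond in CONDITIONS:
            acc = np.zeros_like(sel[0].waveforms[cond])
            cnt = np.zeros(acc.shape[0])
            for e in sel:
                use = (~e.electrode_rejected) & (e.n_trials[cond] > 0)
                acc[use] += e.waveforms[cond][use]
                cnt[use] += 1
            with np.errstate(invalid="ignore"):
                avg = np.where(cnt[:, None] > 0, acc / np.maximum(cnt, 1)[:, None], np.nan)
            for c, label in enumerate(sel[0].channels):
                rows.append(pd.DataFrame({
                    "electrode": label, "time_ms": times, "condition": cond,
                    "visit": visit, "value": avg[c],
                }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# stages


def preprocess_cohort(recordings, run_log: RunLog | None = None):
    """Preprocess every recording; yields (EpochSet, SubjectERP) pairs."""
    for raw in recordings:
        yield preprocess_recording(raw)


def score_cohort(recordings, run_log: RunLog | None = None) -> pd.DataFrame:
    """Raw recordings → tidy scores table, accumulating the rejection log."""
    frames = []
    n_trials = {"presented": 0, "included": 0, "lookaway": 0, "artifact-fraction": 0, "no-reference": 0}
    n_sv = 0
    for epochs, erp in preprocess_cohort(recordings):
        n_sv += 1
        n_trials["presented"] += epochs.n_trials
        status = epochs.trial_status.astype(str)
        n_trials["included"] += int((status == STATUS_INCLUDED).sum())
        for key in ("lookaway", "artifact-fraction", "no-reference"):
            n_trials[key] += int((status == f"excluded:{key}").sum())
        frames.append(score_subject(erp))
    if run_log is not None:
        for k, v in n_trials.items():
            run_log.add("preprocess:trials", k, v)
        run_log.add("preprocess", "subject-visits", n_sv)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames else pd.DataFrame(columns=SCORE_COLUMNS)
    )
    return out


def trajectories_stage(differences: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD):
    """Transition tables + dominant summaries for every scored component."""
    tables, summaries = {}, []
    for comp in SCORED_COMPONENTS:
        table = component_trajectories(differences, comp, threshold)
        if table is None:
            continue
        tables[comp] = table
        s = summarize_dominant(table)
        summaries.append({
            "component": comp, "dominant_state": s.dominant_state,
            "tie": s.tie, "n": table.n_subjects,
            "dominant_share_v1": s.dominant_share_v1,
            "dominant_share_v2": s.dominant_share_v2,
            "persistence_pct": s.persistence_pct,
            "mover_share_pct": s.mover_share_pct,
            "both_visit_pct": s.both_visit_pct,
        })
    return tables, pd.DataFrame(summaries)


def stats_stage(scores: pd.DataFrame, differences: pd.DataFrame):
    """ANOVAs (mean amplitude + peak-to-trough + P1 latency), the N290
    latency paired t-test, and per-component Brown–Forsythe across visits."""
    anova_rows, ttest_rows, bf_rows = [], [], []

    def run_anova(component: str, measure: str) -> None:
        table = anova_table_from_scores(scores, component, measure)
        if len(table) < 2:
            return
        res = rm_anova_2x2(table)
        for eff in (res.stimulus, res.visit, res.interaction):
            anova_rows.append({
                "component": component, "measure": measure, "effect": eff.effect,
                "F": eff.F, "df1": eff.df1, "df2": eff.df2, "p": eff.p,
                "partial_eta_sq": eff.partial_eta_sq, "n": res.n,
            })

    for comp in SCORED_COMPONENTS:
        run_anova(comp, "mean_amplitude")
    for comp in ("P1", "N290", "P400"):
        run_anova(comp, "peak_to_trough")
    run_anova("P1", "peak_latency")

    lat = scores[
        (scores["component"] == "N290") & (scores["measure"] == "peak_latency")
        & (scores["condition"] == "face")
    ]
    wide = lat.pivot_table(index="subject", columns="visit", values="value", aggfunc="first").dropna()
    if len(wide) >= 2:
        res = paired_ttest(wide[1].to_numpy(), wide[2].to_numpy())
        ttest_rows.append({
            "component": "N290", "measure": "peak_latency(face) v1-v2",
            "t": res.t, "df": res.df, "p": res.p, "cohen_d": res.cohen_d,
            "mean_diff": res.mean_diff, "n": len(wide),
        })

    for comp in SCORED_COMPONENTS:
        sub = differences[differences["component"] == comp]
        wide = sub.pivot_table(index="subject", columns="visit", values="difference", aggfunc="first").dropna()
        if len(wide) >= 2:
            res = brown_forsythe(wide[1].to_numpy(), wide[2].to_numpy())
            bf_rows.append({
                "component": comp, "F": res.F, "df1": res.df1, "df2": res.df2,
                "p": res.p, "n": len(wide),
            })

    return (
        pd.DataFrame(anova_rows), pd.DataFrame(ttest_rows), pd.DataFrame(bf_rows),
    )


# ---------------------------------------------------------------------------
# orchestration


def load_recordings_from_dir(in_dir) -> list:
    """Read every raw/<stem>.tsv + <stem>_events.tsv pair from a directory."""
    in_dir = Path(in_dir)
    recs = []
    for data_path in sorted(in_dir.glob("*_data.tsv")):
        events_path = data_path.with_name(data_path.name.replace("_data.tsv", "_events.tsv"))
        recs.append(read_recording_tsv(data_path, events_path))
    return recs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) write the artifact bundle."""
    run_log = RunLog()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.yaml")

    truth = None
    if config.simulate:
        recordings, truth = generate_cohort(
            config.cohort, state_threshold=config.state_threshold,
        )
        run_log.add("simulate", "recordings", len(recordings))
        if out:
            write_ground_truth_tsv(
                truth, out / "truth_means.tsv", out / "truth_differences.tsv",
                out / "truth_trials.tsv",
            )
            if config.write_raw:
                raw_dir = out / "raw"
                raw_dir.mkdir(exist_ok=True)
                for rec in recordings:
                    stem = f"{rec.subject}_v{rec.visit}"
                    write_recording_tsv(
                        rec, raw_dir / f"{stem}_data.tsv", raw_dir / f"{stem}_events.tsv",
                    )
    else:
        if not config.in_dir:
            raise ValueError("simulate disabled but no in_dir with recordings given")
        recordings = load_recordings_from_dir(config.in_dir)
        run_log.add("load", "recordings", len(recordings))
        if not recordings:
            raise FileNotFoundError(f"no recordings found under {config.in_dir}")

    if config.write_erp and out:
        erps = []
        scores_frames = []
        n_tr = 0
        for epochs, erp in preprocess_cohort(recordings):
            write_subject_erp(erp, out / "erp")
            erps.append(erp)
            scores_frames.append(score_subject(erp))
            n_tr += epochs.n_trials
        scores = pd.concat(scores_frames, ignore_index=True)
        run_log.add("preprocess", "subject-visits", len(erps))
        run_log.add("preprocess:trials", "presented", n_tr)
        write_table(out / "grand_average.tsv", grand_average(erps))
    else:
        scores = score_cohort(recordings, run_log)

    run_log.add("score", "rows", len(scores))
    differences = differences_from_scores(scores)
    run_log.add("differences", "rows", len(differences))

    tables, summaries = trajectories_stage(differences, config.state_threshold)
    anova, ttests, bf = stats_stage(scores, differences)

    if out:
        write_table(out / "scores.tsv", scores)
        write_table(out / "differences.tsv", differences)
        for comp, table in tables.items():
            write_table(out / f"transitions_{comp}.tsv", table.to_frame())
            (out / f"transitions_{comp}.dot").write_text(to_dot(table))
        write_table(out / "summaries.tsv", summaries)
        write_table(out / "anova.tsv", anova)
        write_table(out / "ttests.tsv", ttests)
        write_table(out / "brown_forsythe.tsv", bf)
        write_table(out / "rejection_log.tsv", run_log.to_frame())

    return PipelineResult(
        scores, differences, tables, summaries, anova, ttests, bf,
        run_log.to_frame(), truth,
    )
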