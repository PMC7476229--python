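"""Synthetic longitudinal ERP cohort generator.

Builds two-visit cohorts of raw 32-channel recordings with known ground
truth, emulating the infant face/house passive-viewing protocol: 48 face and
48 house trials per visit in 4 blocks of 24 (each stimulus identity once per
block, randomized), 1000 ms trials with a 700–1000 ms jittered ISI, 2048 Hz
acquisition on the 10-20 montage.

Component responses are Gaussian bumps in time, constant across a
component's electrode set and zero elsewhere. Per subject-visit-condition the
bump amplitudes are solved jointly so that the *pipeline-measured* windowed
mean of every component (after common-average referencing) equals the
subject's true target mean; overlap between neighbouring windows and the
reference projection are folded into a small linear system. Noise is a
per-channel mixture of 1/f ("pink") and white noise, independent across
channels. Artifacts (amplitude spikes, flatlines, step offsets) and
look-away trials are injected at configurable rates and recorded in the
ground truth, so every downstream rejection rule is testable.

The generator does not model head geometry, spatially correlated noise, or
latency development; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import COMPONENTS, CONDITIONS, MONTAGE, channel_index
from .preprocess import TARGET_FS, RawRecording, sample_range
from .trajectories import classify_state

ARTIFACT_KINDS = ("spike", "flatline", "step")

#: Gaussian bump shape parameters (centre, sd) in ms per component. Widths are
#: narrow enough that the 0.1–30 Hz band-pass leaves windowed means nearly
#: untouched, yet wide enough to survive the 30 Hz low-pass.
TEMPLATE_SHAPES: dict[str, tuple[float, float]] = {
    "N80": (80.0, 10.0),
    "P1": (135.0, 18.0),
    "N290": (235.0, 28.0),
    "P400": (400.0, 45.0),
    "Nc": (450.0, 70.0),
}

# Artifact injection parameters (post-noise, pre-filter) chosen so each kind
# is unambiguously caught by the flagging criteria *after* the 0.1–30 Hz
# zero-phase filter chain: spikes stay > 200 μV, flatlines keep a full 200 ms
# window under the 3 μV range, steps exceed 200 μV within 0–600 ms.
SPIKE_PEAK_UV = 400.0
SPIKE_SD_MS = 15.0
FLATLINE_START_MS = 100.0
FLATLINE_DUR_MS = 400.0
STEP_UV = 300.0
STEP_SPAN_MS = (250.0, 550.0)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults reproduce the study protocol."""

    n_subjects: int = 80
    n_trials_per_condition: int = 48
    n_blocks: int = 4
    trial_duration: float = 1000.0        # ms
    isi_range: tuple[float, float] = (700.0, 1000.0)  # ms
    sample_rate: int = 2048               # Hz, must be a multiple of 512
    n_channels: int = 32
    noise_sd: float = 30.0                # μV, total per-channel noise SD
    pink_noise_fraction: float = 0.5      # variance fraction of 1/f noise
    artifact_rate: float = 0.05           # per trial-electrode
    lookaway_rate: float = 0.25           # per trial
    artifact_kinds: tuple[str, ...] = ARTIFACT_KINDS
    background_uv: float = 4.0            # common-mode ripple amplitude, μV
    background_hz: float = 20.0           # common-mode ripple frequency
    seed: int = 0

    def __post_init__(self) -> None:
        if (2 * self.n_trials_per_condition) % self.n_blocks:
            raise ValueError("n_trials_per_condition x 2 must be divisible by n_blocks")
        if self.n_trials_per_condition % self.n_blocks:
            raise ValueError("each block must show every stimulus identity once per condition")
        if self.isi_range[0] > self.isi_range[1]:
            raise ValueError("isi_range low must be <= high")
        if self.sample_rate % TARGET_FS:
            raise ValueError(f"sample_rate must be divisible by {TARGET_FS}")
        for name in ("artifact_rate", "lookaway_rate", "pink_noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_channels != len(MONTAGE):
            raise ValueError("n_channels must match the 32-channel 10-20 montage")
        unknown = set(self.artifact_kinds) - set(ARTIFACT_KINDS)
        if unknown:
            raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_condition

    @property
    def decimation(self) -> int:
        return self.sample_rate // TARGET_FS


@dataclass(frozen=True)
class ComponentEffect:
    """Population-level truth for one component's condition means (μV).

    ``house_mean``: house-condition mean per visit; ``diff_mean``/``diff_sd``:
    population mean and SD of the face−house difference per visit; ``corr``:
    between-visit correlation of a subject's difference. SDs of exactly zero
    are allowed (degenerate, used by invariance tests).
    """

    house_mean: tuple[float, float]
    diff_mean: tuple[float, float]
    diff_sd: tuple[float, float]
    corr: float = 0.3

    def __post_init__(self) -> None:
        if min(self.diff_sd) < 0:
            raise ValueError("diff_sd must be non-negative")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("corr must lie in [-1, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Cohort-level ground-truth distribution, one entry per component."""

    components: dict[str, ComponentEffect]
    level_sd: float = 5.0   # SD of a subject-visit level offset common to both conditions

    def __post_init__(self) -> None:
        if self.level_sd < 0:
            raise ValueError("level_sd must be non-negative")
        unknown = set(self.components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")


def default_effect_spec() -> EffectSpec:
    """Group-level condition means matching the published cohort.

    House means and visit offsets reconstruct the printed per-condition and
    per-visit marginal means; difference SDs approximate the spread implied
    by the printed subgroup summaries.
    """
    return EffectSpec({
        "N80": ComponentEffect((-3.53, -3.53), (-0.03, -0.03), (1.0, 1.0)),
        "P1": ComponentEffect((10.5, 10.5), (-2.85, -2.85), (7.0, 7.0)),
        "N290": ComponentEffect((14.25, 18.95), (-9.29, -9.29), (6.0, 6.0)),
        "P400": ComponentEffect((22.8, 30.8), (-9.8, -9.8), (7.0, 7.0)),
        "Nc": ComponentEffect((-9.475, -13.125), (2.8, 2.8), (5.5, 5.5)),
    })


# ---------------------------------------------------------------------------
# templates


@dataclass(frozen=True)
class ComponentTemplate:
    """Renderable Gaussian bump for one component.

    ``target_window_mean`` maps (condition, visit) to the requested windowed
    mean in μV; ``amplitude_for`` converts a target into the bump's peak
    amplitude on the 512 Hz scoring grid (no reference compensation).
    """

    component: str
    electrodes: tuple[str, ...]
    center_latency: float   # ms
    width: float            # Gaussian sd, ms
    target_window_mean: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        unknown = set(self.electrodes) - set(MONTAGE)
        if unknown:
            raise ValueError(f"unknown electrode labels: {sorted(unknown)}")
        lo, hi = COMPONENTS[self.component].window
        if not (0.0 <= lo and hi <= 1000.0):
            raise ValueError("component window outside the epoch span")

    def unit_window_mean(self) -> float:
        """Windowed mean of the unit-peak bump over its own scoring window."""
        lo, hi = COMPONENTS[self.component].window
        first, last = sample_range(lo, hi, TARGET_FS)
        t = np.arange(first, last + 1) * 1000.0 / TARGET_FS
        return float(np.exp(-0.5 * ((t - self.center_latency) / self.width) ** 2).mean())

    def amplitude_for(self, target_uv: float) -> float:
        return target_uv / self.unit_window_mean()

    def render(self, t_ms: np.ndarray, target_uv: float) -> np.ndarray:
        """Noise-free waveform at the given times for one electrode."""
        a = self.amplitude_for(target_uv)
        return a * np.exp(-0.5 * ((t_ms - self.center_latency) / self.width) ** 2)


def build_templates(
    config: CohortConfig,
    group_means: dict[str, dict[tuple[str, int], float]],
) -> list[ComponentTemplate]:
    """One template per component, scaled so the noise-free windowed mean at
    its own electrodes equals the requested group mean (within 0.01 μV).

    ``group_means[component][(condition, visit)]`` gives the target in μV.
    """
    templates = []
    for comp, targets in group_means.items():
        if comp not in COMPONENTS:
            raise ValueError(f"unknown component {comp!r}")
        center, width = TEMPLATE_SHAPES[comp]
        templates.append(ComponentTemplate(
            comp, COMPONENTS[comp].electrodes, center, width, dict(targets),
        ))
    return templates


def _solve_matrix() -> tuple[list[str], np.ndarray]:
    """Linear map from bump peak amplitudes to pipeline-measured window means.

    Entry [j, k] is the average-referenced windowed mean that component j's
    measurement reports when component k's bump has unit peak amplitude:
    overlap of electrode sets scaled by the unit bump's mean over window j,
    minus the common-average projection |E_k| / n_channels.
    """
    comps = list(COMPONENTS)
    n_ch = len(MONTAGE)
    m = np.zeros((len(comps), len(comps)))
    for j, cj in enumerate(comps):
        lo, hi = COMPONENTS[cj].window
        first, last = sample_range(lo, hi, TARGET_FS)
        t = np.arange(first, last + 1) * 1000.0 / TARGET_FS
        ej = set(COMPONENTS[cj].electrodes)
        for k, ck in enumerate(comps):
            center, width = TEMPLATE_SHAPES[ck]
            g = float(np.exp(-0.5 * ((t - center) / width) ** 2).mean())
            ek = set(COMPONENTS[ck].electrodes)
            share = len(ej & ek) / len(ej)
            m[j, k] = g * (share - len(ek) / n_ch)
    return comps, m


_COMPS_ORDER, _M = _solve_matrix()
_M_INV = np.linalg.inv(_M)


def solve_amplitudes(targets: dict[str, float]) -> dict[str, float]:
    """Bump peak amplitudes whose average-referenced windowed means equal
    ``targets`` (μV per component). Components absent from ``targets``
    default to 0 μV measured mean."""
    b = np.array([targets.get(c, 0.0) for c in _COMPS_ORDER])
    a = _M_INV @ b
    return dict(zip(_COMPS_ORDER, a))


# ---------------------------------------------------------------------------
# trial plans and recordings


@dataclass
class TrialPlan:
    """Deterministic schedule for one recording."""

    onsets: np.ndarray        # sample index per trial, at config.sample_rate
    conditions: np.ndarray    # str per trial
    blocks: np.ndarray        # int per trial
    lookaway: np.ndarray      # bool per trial
    artifacts: list[tuple[int, int, str]]   # (trial, channel, kind)
    n_samples: int


@dataclass
class SubjectParams:
    """Everything needed to render one subject-visit deterministically."""

    subject: str
    visit: int
    targets: dict[str, dict[str, float]]   # condition -> component -> true window mean (μV)
    seed: np.random.SeedSequence


def plan_trials(config: CohortConfig, rng: np.random.Generator) -> TrialPlan:
    """Draw the block-randomized stimulus order, ISIs, look-aways, artifacts.

    Each block shows every face identity and every house identity exactly
    once in shuffled order. Onsets are snapped to the 512 Hz grid so that
    decimation leaves event timing exact.
    """
    q = config.decimation
    n_ident = config.n_trials_per_condition // config.n_blocks
    conds, blocks = [], []
    for b in range(config.n_blocks):
        block = ["face"] * n_ident + ["house"] * n_ident
        order = rng.permutation(len(block))
        conds.extend(block[i] for i in order)
        blocks.extend([b + 1] * len(block))
    n_trials = len(conds)

    trial_512 = int(round(config.trial_duration * TARGET_FS / 1000.0))
    isi_lo = int(np.ceil(config.isi_range[0] * TARGET_FS / 1000.0))
    isi_hi = int(np.floor(config.isi_range[1] * TARGET_FS / 1000.0))
    onsets = np.empty(n_trials, dtype=int)
    pos = TARGET_FS  # 1 s lead-in
    for t in range(n_trials):
        onsets[t] = pos * q
        pos += trial_512 + int(rng.integers(isi_lo, isi_hi + 1))
    n_samples = (pos + 2 * TARGET_FS) * q  # 2 s tail

    lookaway = rng.random(n_trials) < config.lookaway_rate
    hits = rng.random((n_trials, config.n_channels)) < config.artifact_rate
    artifacts = []
    for t, ch in zip(*np.nonzero(hits)):
        kind = config.artifact_kinds[int(rng.integers(len(config.artifact_kinds)))]
        artifacts.append((int(t), int(ch), kind))
    return TrialPlan(
        onsets, np.array(conds, dtype=object), np.array(blocks, dtype=int),
        lookaway, artifacts, n_samples,
    )


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f-power noise per channel, synthesized in the
    frequency domain (random phase, 1/sqrt(f) amplitudes) at an FFT-friendly
    length and truncated."""
    from scipy.fft import irfft, next_fast_len

    n_fft = next_fast_len(n_samples, real=True)
    n_freq = n_fft // 2 + 1
    f = np.fft.rfftfreq(n_fft)
    scale = np.zeros(n_freq, dtype=np.float32)
    scale[1:] = 1.0 / np.sqrt(f[1:], dtype=np.float32)
    spec = (
        rng.standard_normal((n_ch, n_freq), dtype=np.float32)
        + 1j * rng.standard_normal((n_ch, n_freq), dtype=np.float32)
    ) * scale
    pink = irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _render_signal(plan: TrialPlan, amplitudes: dict[str, dict[str, float]],
                   config: CohortConfig) -> np.ndarray:
    """Noise-free trace: per trial, add each component's bump at its electrodes."""
    fs = config.sample_rate
    trace = np.zeros((config.n_channels, plan.n_samples), dtype=np.float32)
    # one support waveform per (component, condition)
    half = {}
    for comp, (center, width) in TEMPLATE_SHAPES.items():
        lo = int((center - 6 * width) * fs / 1000.0)
        hi = int((center + 6 * width) * fs / 1000.0)
        t = np.arange(lo, hi + 1) * 1000.0 / fs
        bump = np.exp(-0.5 * ((t - center) / width) ** 2).astype(np.float32)
        half[comp] = (lo, bump)
    idx = {comp: channel_index(MONTAGE, COMPONENTS[comp].electrodes) for comp in COMPONENTS}
    for t_i, onset in enumerate(plan.onsets):
        cond = plan.conditions[t_i]
        amps = amplitudes[cond]
        for comp, a in amps.items():
            if a == 0.0:
                continue
            lo, bump = half[comp]
            s0 = onset + lo
            trace[np.ix_(idx[comp], range(s0, s0 + bump.size))] += np.float32(a) * bump
    return trace


def _inject_artifacts(trace: np.ndarray, plan: TrialPlan, config: CohortConfig,
                      rng: np.random.Generator) -> None:
    fs = config.sample_rate
    for trial, ch, kind in plan.artifacts:
        onset = int(plan.onsets[trial])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if kind == "spike":
            center_ms = float(rng.uniform(80.0, 520.0))
            sd = SPIKE_SD_MS * fs / 1000.0
            c = onset + int(center_ms * fs / 1000.0)
            lo, hi = c - int(4 * sd), c + int(4 * sd)
            t = np.arange(lo, hi + 1)
            trace[ch, lo:hi + 1] += sign * SPIKE_PEAK_UV * np.exp(-0.5 * ((t - c) / sd) ** 2)
        elif kind == "flatline":
            s0 = onset + int(FLATLINE_START_MS * fs / 1000.0)
            s1 = s0 + int(FLATLINE_DUR_MS * fs / 1000.0)
            trace[ch, s0:s1] = 0.0
        elif kind == "step":
            s0 = onset + int(STEP_SPAN_MS[0] * fs / 1000.0)
            s1 = onset + int(STEP_SPAN_MS[1] * fs / 1000.0)
            trace[ch, s0:s1] += sign * STEP_UV


def simulate_recording(
    subject_params: SubjectParams,
    config: CohortConfig,
    rng: np.random.Generator,
    plan: TrialPlan | None = None,
) -> RawRecording:
    """Render one subject-visit: templates + pink/white noise + artifacts.

    Deterministic given (subject_params, config, rng state): the same seeded
    generator yields a bit-identical recording. If ``plan`` is None it is
    drawn from ``rng`` first, matching the draw order used by
    :func:`generate_cohort` for ground truth.
    """
    if plan is None:
        plan = plan_trials(config, rng)
    amplitudes = {
        cond: solve_amplitudes(subject_params.targets[cond]) for cond in CONDITIONS
    }
    trace = _render_signal(plan, amplitudes, config)
    if config.background_uv > 0:
        # Common-mode ongoing oscillation shared by every channel. It keeps
        # channels from being genuinely flat (so the flatline criterion only
        # fires on injected artifacts even at noise_sd=0) and is cancelled
        # exactly by the common-average reference, leaving windowed means
        # untouched.
        t = np.arange(plan.n_samples, dtype=np.float64) / config.sample_rate
        trace += (config.background_uv
                  * np.sin(2 * np.pi * config.background_hz * t)).astype(np.float32)
    if config.noise_sd > 0:
        frac = config.pink_noise_fraction
        noise = np.zeros_like(trace)
        if frac > 0:
            noise += np.float32(np.sqrt(frac)) * _pink_noise(
                rng, config.n_channels, plan.n_samples)
        if frac < 1:
            noise += np.float32(np.sqrt(1 - frac)) * rng.standard_normal(
                trace.shape, dtype=np.float32)
        trace += np.float32(config.noise_sd) * noise
    _inject_artifacts(trace, plan, config, rng)
    events = pd.DataFrame({
        "onset": plan.onsets,
        "condition": plan.conditions,
        "block": plan.blocks,
        "lookaway": plan.lookaway,
    })
    return RawRecording(
        subject_params.subject, subject_params.visit, config.sample_rate,
        MONTAGE, trace, events,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortGroundTruth:
    """Generator truth enabling recovery tests.

    ``component_means``: one row per subject × visit × condition × component
    with the true (pipeline-scale) windowed mean. ``differences``: one row
    per subject × visit × component with the true face−house difference and
    its state under the ±1.5 μV rule. ``trials``: per-trial look-away and
    artifact-injection bookkeeping.
    """

    component_means: pd.DataFrame
    differences: pd.DataFrame
    trials: pd.DataFrame


class CohortRecordings:
    """Lazy, re-iterable collection of the cohort's raw recordings.

    Recordings are regenerated on demand from per-subject-visit seeds, so an
    80-subject cohort never holds more than one trace in memory. Iteration
    order is subject-major, visit-minor and bit-reproducible.
    """

    def __init__(self, config: CohortConfig, params: list[SubjectParams]):
        self.config = config
        self._params = params

    def __len__(self) -> int:
        return len(self._params)

    def __iter__(self):
        for p in self._params:
            yield self.render(p)

    def __getitem__(self, i: int) -> RawRecording:
        return self.render(self._params[i])

    def render(self, p: SubjectParams) -> RawRecording:
        rng = np.random.default_rng(p.seed)
        return simulate_recording(p, self.config, rng)


def generate_cohort(
    config: CohortConfig,
    effect_spec: EffectSpec | None = None,
    state_threshold: float = 1.5,
) -> tuple[CohortRecordings, CohortGroundTruth]:
    """Draw a two-visit cohort and its ground truth.

    Subject-level face−house differences are bivariate normal across visits
    (mean/SD/correlation per component from ``effect_spec``); a common level
    offset per subject-visit-component shifts both conditions equally. True
    states follow the ±``state_threshold`` μV rule.
    """
    effect_spec = effect_spec if effect_spec is not None else default_effect_spec()
    root = np.random.SeedSequence(config.seed)
    effects_seed, *rec_seeds = root.spawn(1 + 2 * config.n_subjects)
    rng = np.random.default_rng(effects_seed)

    params: list[SubjectParams] = []
    mean_rows, diff_rows = [], []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:03d}"
        targets: dict[int, dict[str, dict[str, float]]] = {
            1: {c: {} for c in CONDITIONS}, 2: {c: {} for c in CONDITIONS},
        }
        for comp, eff in effect_spec.components.items():
            z1, z2 = rng.standard_normal(2)
            d1 = eff.diff_mean[0] + eff.diff_sd[0] * z1
            d2 = eff.diff_mean[1] + eff.diff_sd[1] * (
                eff.corr * z1 + np.sqrt(max(0.0, 1 - eff.corr**2)) * z2
            )
            levels = rng.standard_normal(2) * effect_spec.level_sd
            for visit, diff, level in ((1, d1, levels[0]), (2, d2, levels[1])):
                house = eff.house_mean[visit - 1] + level
                targets[visit]["house"][comp] = house
                targets[visit]["face"][comp] = house + diff
                for cond in CONDITIONS:
                    mean_rows.append({
                        "subject": subject, "visit": visit, "condition": cond,
                        "component": comp,
                        "true_mean": targets[visit][cond][comp],
                    })
                diff_rows.append({
                    "subject": subject, "visit": visit, "component": comp,
                    "true_difference": diff,
                    "true_state": classify_state(diff, state_threshold),
                })
        for visit in (1, 2):
            params.append(SubjectParams(
                subject, visit, targets[visit], rec_seeds[2 * s + visit - 1],
            ))

    trial_rows = []
    for p in params:
        plan_rng = np.random.default_rng(p.seed)
        plan = plan_trials(config, plan_rng)
        n_art = np.zeros(len(plan.onsets), dtype=int)
        for trial, _ch, _kind in plan.artifacts:
            n_art[trial] += 1
        for t in range(len(plan.onsets)):
            trial_rows.append({
                "subject": p.subject, "visit": p.visit, "trial": t,
                "block": int(plan.blocks[t]), "condition": plan.conditions[t],
                "lookaway": bool(plan.lookaway[t]),
                "n_artifact_electrodes": int(n_art[t]),
            })

    truth = CohortGroundTruth(
        pd.DataFrame(mean_rows), pd.DataFrame(diff_rows), pd.DataFrame(trial_rows),
    )
    return CohortRecordings(config, params), truth


def draw_cell_means(
    effect_spec: EffectSpec, component: str, n_subjects: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Subject-level true 2×2 cell means for one component (no EEG rendering).

    Convenience for statistical calibration at the score level; one row per
    subject with columns face_v1, house_v1, face_v2, house_v2.
    """
    eff = effect_spec.components[component]
    rows = []
    for s in range(n_subjects):
        z1, z2 = rng.standard_normal(2)
        d1 = eff.diff_mean[0] + eff.diff_sd[0] * z1
        d2 = eff.diff_mean[1] + eff.diff_sd[1] * (
            eff.corr * z1 + np.sqrt(max(0.0, 1 - eff.corr**2)) * z2
        )
        lv = rng.standard_normal(2) * effect_spec.level_sd
        rows.append({
            "subject": f"S{s + 1:03d}",
            "house_v1": eff.house_mean[0] + lv[0],
            "face_v1": eff.house_mean[0] + lv[0] + d1,
            "house_v2": eff.house_mean[1] + lv[1],
            "face_v2": eff.house_mean[1] + lv[1] + d2,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV persistence (documented columnar layout)


def write_recording_tsv(rec: RawRecording, data_path, events_path) -> None:
    """Write a recording as two TSVs.

    ``data_path``: two comment header lines (``# subject=… visit=…
    sample_rate=…`` and ``# channels=<tab-free comma list>``) followed by a
    header row ``sample<TAB><label>…`` and one row per sample with voltages
    in μV. ``events_path``: columns onset, condition, block, lookaway.
    """
    with open(data_path, "w") as fh:
        fh.write(f"# subject={rec.subject}\tvisit={rec.visit}\tsample_rate={rec.sample_rate}\n")
        fh.write("# channels=" + ",".join(rec.channels) + "\n")
        df = pd.DataFrame(rec.data.T, columns=list(rec.channels))
        df.insert(0, "sample", np.arange(rec.data.shape[1]))
        df.to_csv(fh, sep="\t", index=False)
    rec.events.to_csv(events_path, sep="\t", index=False)


def read_recording_tsv(data_path, events_path) -> RawRecording:
    """Inverse of :func:`write_recording_tsv`."""
    with open(data_path) as fh:
        meta = dict(item.split("=", 1) for item in fh.readline()[1:].strip().split("\t"))
        channels = tuple(fh.readline().strip()[len("# channels="):].split(","))
        df = pd.read_csv(fh, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    events["lookaway"] = events["lookaway"].astype(bool)
    data = df[list(channels)].to_numpy().T
    return RawRecording(
        meta["subject"], int(meta["visit"]), int(meta["sample_rate"]),
        channels, data, events,
    )


def write_ground_truth_tsv(truth: CohortGroundTruth, means_path, diffs_path, trials_path) -> None:
    truth.component_means.to_csv(means_path, sep="\t", index=False)
    truth.differences.to_csv(diffs_path, sep="\t", index=False)
    truth.trials.to_csv(trials_path, sep="\t", index=False)
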