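"""Filtering, epoching, artifact flagging, rejection, referencing, averaging."""

import numpy as np
import pandas as pd
import pytest

from conftest import EPOCH_FIRST, N_EPOCH_SAMPLES, epoch_times_ms, make_epochs
from erptrack.components import MONTAGE
from erptrack.preprocess import (
    STATUS_FRACTION, STATUS_INCLUDED, STATUS_LOOKAWAY, TARGET_FS,
    RawRecording, apply_average_reference, apply_rejection, average_by_condition,
    filter_and_downsample, flag_artifacts, preprocess_recording,
    segment_and_baseline,
)


def _raw(data, fs=2048, events=None):
    if events is None:
        events = pd.DataFrame(columns=["onset", "condition", "block", "lookaway"])
    return RawRecording("T001", 1, fs, MONTAGE, data, events)


def _tone(freq, amp, fs=2048, seconds=20.0):
    t = np.arange(int(seconds * fs)) / fs
    data = np.zeros((32, t.size))
    data[:] = amp * np.sin(2 * np.pi * freq * t)
    return data


class TestFilterAndDownsample:
    def test_dc_offset_removed(self):
        out = filter_and_downsample(_raw(np.full((32, 2048 * 20), 100.0)))
        mid = out.data[:, out.data.shape[1] // 4 : -out.data.shape[1] // 4]
        assert np.abs(mid).max() < 1.0
        assert out.sample_rate == TARGET_FS

    @staticmethod
    def _amplitude_at(x, freq, fs=TARGET_FS):
        """Quadrature-demodulated amplitude at one frequency (mid region)."""
        mid = x[x.size // 4 : -x.size // 4]
        t = np.arange(mid.size) / fs
        z = mid * np.exp(-2j * np.pi * freq * t)
        return 2.0 * np.abs(z.mean())

    def test_notch_suppresses_50hz(self):
        out = filter_and_downsample(_raw(_tone(50.0, 20.0)))
        assert self._amplitude_at(out.data[0], 50.0) < 0.05 * 20.0

    def test_passband_preserves_5hz(self):
        out = filter_and_downsample(_raw(_tone(5.0, 10.0)))
        assert self._amplitude_at(out.data[0], 5.0) == pytest.approx(10.0, rel=0.05)

    def test_event_onsets_rescaled(self):
        ev = pd.DataFrame({"onset": [4096], "condition": ["face"], "block": [1], "lookaway": [False]})
        out = filter_and_downsample(_raw(np.zeros((32, 2048 * 4)), events=ev))
        assert out.events["onset"].iloc[0] == 1024

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            filter_and_downsample(_raw(np.zeros((32, 1000)), fs=1000))


class TestSegmentAndBaseline:
    def _events(self, onsets, conds):
        return pd.DataFrame({
            "onset": onsets, "condition": conds,
            "block": [1] * len(onsets), "lookaway": [False] * len(onsets),
        })

    def test_constant_trace_zeroed(self):
        raw = _raw(np.full((32, 2048), 5.0), fs=512, events=self._events([600], ["face"]))
        ep = segment_and_baseline(raw)
        assert ep.data.shape == (1, 32, N_EPOCH_SAMPLES)
        assert np.abs(ep.data).max() < 1e-9

    def test_step_offset_arithmetic(self):
        data = np.full((32, 2048), 2.0)
        onset = 800
        data[:, onset + 1:] = 7.0  # stimulus response starts after the onset sample
        ep = segment_and_baseline(_raw(data, fs=512, events=self._events([onset], ["face"])))
        post = ep.data[0][:, ep.sample_window(10, 900)]
        assert np.allclose(post, 5.0, atol=1e-9)
        base = ep.data[0][:, ep.sample_window(-150, 0)]
        assert np.abs(base.mean(axis=1)).max() < 1e-9

    def test_out_of_bounds_event_skipped(self):
        raw = _raw(np.zeros((32, 1000)), fs=512, events=self._events([50, 400], ["face", "house"]))
        ep = segment_and_baseline(raw)
        assert ep.data.shape[0] == 1
        assert any("skipped" in line for line in ep.log)

    def test_96_events_yield_96_epochs(self):
        onsets = 600 + np.arange(96) * 900
        conds = ["face", "house"] * 48
        raw = _raw(np.zeros((32, int(onsets[-1] + 1200))), fs=512,
                   events=self._events(list(onsets), conds))
        ep = segment_and_baseline(raw)
        assert ep.n_trials == 96
        assert (ep.conditions == "face").sum() == 48


def _busy(n_ch=4, amp=5.0):
    """Trials x channels x samples baseline-corrected data that trips no criterion:
    a square wave of range 2*amp (>=3 μV), 10 μV jumps (<50), peaks < 200."""
    n = N_EPOCH_SAMPLES
    sq = amp * (1 - 2 * ((np.arange(n) // 51) % 2))
    return np.tile(sq, (1, n_ch, 1)).astype(float)


class TestFlagArtifacts:
    channels = ("Oz", "O1", "O2", "PO3")

    def test_amplitude_criterion(self):
        data = _busy()
        s = 0 - EPOCH_FIRST + int(0.3 * TARGET_FS)  # ~300 ms post-stimulus
        data[0, 0, s] = 250.0
        ep = flag_artifacts(make_epochs(data, ["face"], self.channels))
        assert ep.flags[0, 0] and ep.flag_reasons[0, 0] == "amplitude"
        assert not ep.flags[0, 1:].any()

    def test_exact_200_passes(self):
        # triangular excursion peaking at exactly 200 μV, 40 μV/sample slopes
        data = _busy()
        s = -EPOCH_FIRST + 150
        ramp = 200.0 - 40.0 * np.abs(np.arange(-5, 6))
        data[0, 0, s - 5 : s + 6] = ramp
        ep = flag_artifacts(make_epochs(data, ["face"], self.channels))
        assert not ep.flags[0, 0]

    def test_flatline_criterion(self):
        data = _busy()
        data[0, 2, :] = 0.0
        ep = flag_artifacts(make_epochs(data, ["face"], self.channels))
        assert ep.flags[0, 2] and ep.flag_reasons[0, 2] == "flatline"

    def test_gradient_criterion(self):
        data = _busy()
        s = -EPOCH_FIRST + int(0.4 * TARGET_FS)
        data[0, 3, s:] += 60.0
        ep = flag_artifacts(make_epochs(data, ["face"], self.channels))
        assert ep.flags[0, 3] and ep.flag_reasons[0, 3] == "gradient"

    def test_50uv_sinusoid_unflagged(self):
        t = epoch_times_ms() / 1000.0
        wave = 50.0 * np.sin(2 * np.pi * 10.0 * t)
        data = np.tile(wave, (1, 4, 1))
        ep = flag_artifacts(make_epochs(data, ["face"], self.channels))
        assert not ep.flags.any()

    def test_artifact_outside_scan_region_ignored(self):
        data = _busy()
        data[0, 0, -EPOCH_FIRST + int(0.7 * TARGET_FS)] = 500.0  # 700 ms > 600 ms
        data[0, 1, 5] = 500.0                                     # pre-stimulus
        ep = flag_artifacts(make_epochs(data, ["face"], self.channels))
        assert not ep.flags.any()

    def test_lookaway_excludes_whole_trial(self):
        data = _busy()
        ep = flag_artifacts(make_epochs(data, ["face"], self.channels, lookaway=[True]))
        assert ep.trial_status[0] == STATUS_LOOKAWAY
        assert not ep.flags.any()


class TestRejection:
    def test_trial_removed_above_16_percent(self):
        data = np.tile(_busy(n_ch=32), (2, 1, 1))
        ep = flag_artifacts(make_epochs(data, ["face", "house"], MONTAGE))
        ep.flags[0, :6] = True   # 6/32 = 18.75 % > 16 %
        ep.flags[1, :5] = True   # 5/32 = 15.625 % <= 16 %
        ep = apply_rejection(ep)
        assert ep.trial_status[0] == STATUS_FRACTION
        assert ep.trial_status[1] == STATUS_INCLUDED

    def test_electrode_rejected_below_5_clean_trials(self):
        data = np.tile(_busy(n_ch=8), (6, 1, 1))
        ep = flag_artifacts(make_epochs(data, ["face"] * 6, MONTAGE[:8]))
        ep.flags[:2, 0] = True   # channel 0 clean on only 4 of 6 trials
        ep = apply_rejection(ep)
        assert ep.electrode_rejected[0]
        assert not ep.electrode_rejected[1:].any()

    def test_five_clean_trials_keep_electrode(self):
        data = np.tile(_busy(n_ch=8), (6, 1, 1))
        ep = flag_artifacts(make_epochs(data, ["face"] * 6, MONTAGE[:8]))
        ep.flags[0, 0] = True    # 5 clean trials: boundary, kept
        ep = apply_rejection(ep)
        assert not ep.electrode_rejected[0]

    def test_removed_trials_do_not_count_against_electrodes(self):
        # a globally bad trial is removed first, so its flags cannot doom electrodes
        data = np.tile(_busy(n_ch=32), (6, 1, 1))
        ep = flag_artifacts(make_epochs(data, ["face"] * 6, MONTAGE))
        ep.flags[0, :] = True    # whole trial bad -> removed by the 16 % rule
        ep = apply_rejection(ep)
        assert ep.trial_status[0] == STATUS_FRACTION
        assert not ep.electrode_rejected.any()


class TestAverageReference:
    def _ready(self, data, conds, channels, flags=None):
        ep = flag_artifacts(make_epochs(data, conds, channels))
        if flags is not None:
            ep.flags = flags
        ep = apply_rejection(ep)
        return ep

    def test_two_electrode_arithmetic(self):
        data = _busy(n_ch=2)
        data[0, 0] += 4.0
        data[0, 1] += -2.0
        ep = self._ready(np.tile(data, (6, 1, 1)), ["face"] * 6, MONTAGE[:2])
        ep = apply_average_reference(ep)
        # square wave is common-mode, so referenced offsets are (3, -3)
        assert np.allclose(ep.data[0, 0], 3.0, atol=1e-9)
        assert np.allclose(ep.data[0, 1], -3.0, atol=1e-9)

    def test_reference_residual_zero(self):
        rng = np.random.default_rng(5)
        data = _busy(n_ch=8) + rng.normal(0, 5, size=(1, 8, N_EPOCH_SAMPLES))
        ep = self._ready(np.tile(data, (6, 1, 1)), ["face"] * 6, MONTAGE[:8])
        ep = apply_average_reference(ep)
        usable = ~ep.flags[0] & ~ep.electrode_rejected
        assert np.abs(ep.data[0, usable].mean(axis=0)).max() < 1e-9

    def test_flagged_electrode_excluded_from_reference(self):
        # one spiked channel of 32 (3 % < 16 %, trial survives) must not
        # perturb the reference of the remaining channels
        base = np.tile(_busy(n_ch=32), (6, 1, 1))
        spiked = base.copy()
        s = -EPOCH_FIRST + int(0.3 * TARGET_FS)
        spiked[0, 31, s] = 10000.0
        ep_clean = self._ready(base.copy(), ["face"] * 6, MONTAGE)
        ep_clean.flags[0, 31] = True  # mimic the spike's flag without its voltage
        ep_clean = apply_average_reference(ep_clean)
        ep_spiked = self._ready(spiked, ["face"] * 6, MONTAGE)
        assert ep_spiked.flags[0, 31]
        assert ep_spiked.trial_status[0] == STATUS_INCLUDED
        ep_spiked = apply_average_reference(ep_spiked)
        assert np.allclose(ep_spiked.data[0, :31], ep_clean.data[0, :31], atol=1e-9)


class TestAveraging:
    def test_two_trial_mean(self):
        data = np.tile(_busy(n_ch=4), (6, 1, 1))
        data[0:3, 0] += 1.0
        data[3:6, 0] += 3.0
        conds = ["face"] * 6
        ep = flag_artifacts(make_epochs(data, conds, ("PO3", "O1", "Oz", "O2")))
        ep = apply_rejection(ep)
        ep.reference_applied = True  # averaging semantics only
        erp = average_by_condition(ep, families={"P1": ("Oz",)})
        # channel 0 averages (sq+1)*3 and (sq+3)*3 -> sq+2
        sq = data[0, 1]  # untouched square wave
        assert np.allclose(erp.waveforms["face"][0], sq + 2.0, atol=1e-9)

    def test_inclusion_boundary_10_trials(self):
        n_face, n_house = 10, 10
        data = np.tile(_busy(n_ch=4), (n_face + n_house, 1, 1))
        conds = ["face"] * n_face + ["house"] * n_house
        ep = flag_artifacts(make_epochs(data, conds, ("PO3", "O1", "Oz", "O2")))
        ep = apply_rejection(ep)
        ep.reference_applied = True
        erp = average_by_condition(ep, families={"fam": ("Oz", "O1")})
        assert erp.family_included["fam"]

    def test_9_trials_excludes_family(self):
        oz = MONTAGE.index("Oz")
        data = np.tile(_busy(n_ch=32), (20, 1, 1))
        conds = ["face"] * 10 + ["house"] * 10
        ep = flag_artifacts(make_epochs(data, conds, MONTAGE))
        ep.flags[0, oz] = True  # Oz clean on only 9 face trials (1/32 < 16 %)
        ep = apply_rejection(ep)
        ep.reference_applied = True
        erp = average_by_condition(ep, families={"fam": ("Oz", "O1"), "other": ("O2",)})
        assert not erp.family_included["fam"]
        assert erp.family_included["other"]
        assert erp.n_trials["face"][oz] == 9


class TestFullChainOracle:
    """Hand-computed chain on a 3-electrode, 8-trial fixture.

    Offsets ride on a common square wave; flagging removes one spike trial
    (any flag exceeds 16 % of a 3-channel montage) and one look-away trial;
    the remaining six are re-referenced, where the square wave cancels and
    only offset deviations from the per-trial offset mean survive.
    """

    def test_matches_hand_computation(self):
        channels = ("Oz", "O1", "O2")
        offsets = [
            ("face", (4.0, -2.0, 1.0), None),
            ("face", (2.0, 0.0, -2.0), None),
            ("face", (6.0, 0.0, 0.0), None),
            ("house", (2.0, 2.0, 2.0), None),
            ("house", (1.0, 4.0, 1.0), None),
            ("house", (0.0, 0.0, 3.0), None),
            ("face", (9.0, 9.0, 9.0), "lookaway"),
            ("house", (1.0, 1.0, 1.0), "spike"),
        ]
        data = np.concatenate([_busy(n_ch=3) for _ in offsets])
        for t, (_c, off, kind) in enumerate(offsets):
            data[t] += np.asarray(off)[:, None]
            if kind == "spike":
                data[t, 0, -EPOCH_FIRST + int(0.25 * TARGET_FS)] = 300.0
        ep = make_epochs(data, [o[0] for o in offsets], channels,
                         lookaway=[o[2] == "lookaway" for o in offsets])
        ep = flag_artifacts(ep)
        ep = apply_rejection(ep)
        ep = apply_average_reference(ep)
        erp = average_by_condition(ep, families={"fam": channels})

        assert ep.trial_status[6] == STATUS_LOOKAWAY
        assert ep.trial_status[7] == STATUS_FRACTION  # 1/3 flagged > 16 %
        assert list(ep.trial_status[:6]) == [STATUS_INCLUDED] * 6
        # hand computation: referenced offsets per face trial are
        # (3,-3,0), (2,0,-2), (4,-2,-2) -> mean (3, -5/3, -4/3)
        face = erp.waveforms["face"]
        assert np.allclose(face[0], 3.0, atol=1e-9)
        assert np.allclose(face[1], -5.0 / 3.0, atol=1e-9)
        assert np.allclose(face[2], -4.0 / 3.0, atol=1e-9)
        # house: (0,0,0), (-1,2,-1), (-1,-1,2) -> mean (-2/3, 1/3, 1/3)
        house = erp.waveforms["house"]
        assert np.allclose(house[0], -2.0 / 3.0, atol=1e-9)
        assert np.allclose(house[1], 1.0 / 3.0, atol=1e-9)
        assert np.allclose(house[2], 1.0 / 3.0, atol=1e-9)
        assert erp.n_trials["face"].tolist() == [3, 3, 3]

    def test_trial_conservation(self):
        channels = ("Oz", "O1", "O2")
        data = np.concatenate([_busy(n_ch=3) for _ in range(8)])
        ep = make_epochs(data, ["face"] * 4 + ["house"] * 4, channels,
                         lookaway=[True, False, False, False] * 2)
        ep = flag_artifacts(ep)
        ep = apply_rejection(ep)
        ep = apply_average_reference(ep)
        status = ep.trial_status.astype(str)
        assert (status == STATUS_INCLUDED).sum() + (status != STATUS_INCLUDED).sum() == 8
        assert set(status) <= {STATUS_INCLUDED, STATUS_LOOKAWAY, STATUS_FRACTION}


def test_clean_generator_output_has_zero_rejections(clean_config):
    from erptrack.synthetic import SubjectParams, simulate_recording

    targets = {"face": {"P1": 7.65, "N290": 7.31}, "house": {"P1": 10.5, "N290": 16.6}}
    p = SubjectParams("S001", 1, targets, np.random.SeedSequence(1))
    rec = simulate_recording(p, clean_config, np.random.default_rng(p.seed))
    epochs, erp = preprocess_recording(rec)
    assert (epochs.trial_status == STATUS_INCLUDED).all()
    assert not epochs.flags.any()
    assert not epochs.electrode_rejected.any()
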