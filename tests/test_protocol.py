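"""Protocol schedules and stimulus-locked window derivation."""

import pytest

from swimmetrics.errors import ConfigError
from swimmetrics.protocol import (
    asr,
    build_protocol,
    larval_light_dark,
    preset,
    ptz_challenge,
    vmr_dark_to_light,
    vmr_light_to_dark,
    windows_for,
)


class TestPresets:
    def test_asr_noise_onsets(self):
        # 60 min adaptation + 3 x (5 min ambient + 15 s noise)
        prot = asr()
        assert prot.onsets("noise_onset") == [3900.0, 4215.0, 4530.0]
        assert prot.length == pytest.approx(3600 + 3 * 315)

    def test_larval_phase_labels(self):
        prot = larval_light_dark()
        labels = [p.label for p in prot.phases]
        assert labels == ["habituation", "L0", "D1", "L1"]
        assert prot.phase("D1").illumination == "off"
        assert prot.phase_window("D1") == (3000.0, 3300.0)
        assert prot.length == pytest.approx(3600.0)

    def test_vmr_light_onsets_in_light_phases(self):
        prot = vmr_dark_to_light()
        for onset in prot.onsets("light_onset"):
            assert prot.phase_at(onset).illumination == "on"

    def test_vmr_light_to_dark_onsets(self):
        prot = vmr_light_to_dark(adaptation=600, light=300, dark=300, cycles=2)
        assert prot.onsets("dark_onset") == [900.0, 1500.0]

    def test_ptz_schedule_is_one_hour(self):
        prot = ptz_challenge(concentration_mm=7.5)
        assert prot.length == pytest.approx(3600.0)
        assert prot.phase("dark").drug == "PTZ@7.5mM"
        assert prot.onsets("dark_onset") == [3300.0]

    def test_unknown_preset(self):
        with pytest.raises(ConfigError, match="unknown protocol preset"):
            preset("nope")

    def test_phase_durations_sum_to_length(self):
        for name in ("asr_13dpf", "vmr_dark_to_light", "vmr_light_to_dark",
                     "larval_ld_7dpf", "ptz_challenge_9dpf"):
            prot = preset(name)
            assert sum(p.duration for p in prot.phases) == pytest.approx(prot.length)


class TestBuildProtocol:
    def test_explicit_phases(self):
        prot = build_protocol(
            {
                "phases": [
                    {"label": "a", "duration": 10, "illumination": "off"},
                    {"label": "b", "duration": 5},
                ],
                "stimuli": [{"type": "light_onset", "time": 10}],
            }
        )
        assert prot.phase("b").start == 10.0
        assert prot.onsets("light_onset") == [10.0]

    def test_zero_duration_phase_rejected(self):
        with pytest.raises(ConfigError, match="duration must be positive"):
            build_protocol({"phases": [{"label": "a", "duration": 0}]})

    def test_stimulus_off_phase_boundary_rejected(self):
        with pytest.raises(ConfigError, match="does not coincide"):
            build_protocol(
                {
                    "phases": [{"label": "a", "duration": 10}],
                    "stimuli": [{"type": "dark_onset", "time": 3.0}],
                }
            )

    def test_preset_passthrough(self):
        prot = build_protocol({"preset": "asr_13dpf", "adaptation": 120.0})
        assert prot.onsets("noise_onset")[0] == pytest.approx(420.0)


class TestWindows:
    def test_default_pre_post(self):
        prot = asr()
        pairs = windows_for(prot, "noise_onset")
        assert [wp.pre for wp in pairs] == [
            (3840.0, 3900.0), (4155.0, 4215.0), (4470.0, 4530.0)
        ]
        assert pairs[0].post == (3900.0, 3915.0)
        assert not any(wp.shortened for wp in pairs)

    def test_no_onsets_gives_empty_list(self):
        prot = larval_light_dark()
        assert windows_for(prot, "noise_onset") == []

    def test_ptz_symmetric_windows(self):
        prot = ptz_challenge()
        (wp,) = windows_for(prot, "dark_onset", pre=60, post=60)
        assert wp.pre == (3240.0, 3300.0)
        assert wp.post == (3300.0, 3360.0)

    def test_early_onset_clips_and_flags(self):
        prot = build_protocol(
            {
                "phases": [
                    {"label": "a", "duration": 30, "illumination": "off"},
                    {"label": "b", "duration": 30},
                ],
                "stimuli": [{"type": "light_onset", "time": 30}],
            }
        )
        (wp,) = windows_for(prot, "light_onset")
        assert wp.shortened
        assert wp.pre == (0.0, 30.0)

    def test_window_pairs_never_overlap(self):
        for name in ("asr_13dpf", "vmr_dark_to_light", "vmr_light_to_dark"):
            prot = preset(name)
            stim = prot.stimuli[0].type
            pairs = windows_for(prot, stim)
            for a, b in zip(pairs, pairs[1:]):
                assert a.post_stop <= b.pre_start
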