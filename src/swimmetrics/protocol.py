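"""Experiment schedules and stimulus-locked analysis windows.

A :class:`Protocol` is an ordered list of contiguous phases (each with an
illumination state, a sound state and an optional drug) plus the stimulus
onsets implied by the schedule. Stimulus-locked analysis compares a 60 s
pre-onset baseline with a 15 s post-onset window by default (the acoustic
startle and visuomotor conventions); the PTZ light-to-dark challenge uses
symmetric 60 s windows on both sides of the transition.

Named presets reproduce the assay schedules used for shank2b phenotyping:

========================  ===========================================================
``larval_ld_7dpf``        45 min habituation, then 5 min light (L0), 5 min dark (D1),
                          5 min light (L1); 60 min total.
``asr_13dpf``             60 min adaptation (dark, ambient sound), then 3 cycles of
                          5 min ambient + 15 s broad-band noise.
``vmr_dark_to_light``     60 min dark adaptation, then 3 cycles of 5 min dark + 15 s
                          light.
``vmr_light_to_dark``     60 min light adaptation, then 3 cycles of 5 min light +
                          5 min dark.
``ptz_challenge_9dpf``    5 min acclimation + 45 min spontaneous (lit), then 5 min
                          light + 5 min dark; 60 min total.
========================  ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

#: default analysis windows (seconds) around a stimulus onset
PRE_WINDOW = 60.0
POST_WINDOW = 15.0

STIMULUS_TYPES = ("noise_onset", "light_onset", "dark_onset")


@dataclass(frozen=True)
class Phase:
    label: str
    start: float
    duration: float
    illumination: str = "on"   # on | off
    sound: str = "ambient"     # ambient | noise
    drug: str = "none"         # none | PTZ@<conc>mM

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigError(f"phase {self.label!r}: duration must be positive")
        if self.illumination not in ("on", "off"):
            raise ConfigError(f"phase {self.label!r}: illumination must be on/off")
        if self.sound not in ("ambient", "noise"):
            raise ConfigError(f"phase {self.label!r}: sound must be ambient/noise")

    @property
    def stop(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Stimulus:
    type: str
    time: float

    def __post_init__(self):
        if self.type not in STIMULUS_TYPES:
            raise ConfigError(f"unknown stimulus type {self.type!r}")


@dataclass(frozen=True)
class StimulusWindowPair:
    """Pre/post analysis windows around one stimulus onset.

    ``pre`` covers ``[onset - pre_duration, onset)`` and ``post`` covers
    ``[onset, onset + post_duration)``. If the onset sits closer than
    ``pre_duration`` to the recording start, the pre window is clipped at 0
    and ``shortened`` is flagged.
    """

    onset: float
    pre_start: float
    post_stop: float
    shortened: bool = False

    @property
    def pre(self) -> tuple[float, float]:
        return (self.pre_start, self.onset)

    @property
    def post(self) -> tuple[float, float]:
        return (self.onset, self.post_stop)


@dataclass(frozen=True)
class Protocol:
    """Contiguous, non-overlapping phases plus stimulus onsets."""

    phases: tuple[Phase, ...]
    stimuli: tuple[Stimulus, ...] = ()
    name: str = "protocol"

    def __post_init__(self):
        if not self.phases:
            raise ConfigError("protocol needs at least one phase")
        for prev, cur in zip(self.phases, self.phases[1:]):
            if abs(cur.start - prev.stop) > 1e-9:
                raise ConfigError(
                    f"phases {prev.label!r} and {cur.label!r} are not contiguous "
                    f"({prev.stop:g} vs {cur.start:g})"
                )
        starts = {round(p.start, 9) for p in self.phases}
        for s in self.stimuli:
            if round(s.time, 9) not in starts:
                raise ConfigError(
                    f"stimulus {s.type} at t={s.time:g} does not coincide with a phase start"
                )

    @property
    def start(self) -> float:
        return self.phases[0].start

    @property
    def stop(self) -> float:
        return self.phases[-1].stop

    @property
    def length(self) -> float:
        return self.stop - self.start

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise ConfigError(f"no phase labelled {label!r}")

    def phase_window(self, label: str) -> tuple[float, float]:
        p = self.phase(label)
        return (p.start, p.stop)

    def phase_at(self, t: float) -> Phase:
        for p in self.phases:
            if p.start <= t < p.stop:
                return p
        if t == self.stop:
            return self.phases[-1]
        raise ConfigError(f"time {t:g} outside protocol [{self.start:g}, {self.stop:g}]")

    def onsets(self, stimulus_type: str) -> list[float]:
        return [s.time for s in self.stimuli if s.type == stimulus_type]


def windows_for(protocol: Protocol, stimulus_type: str,
                pre: float = PRE_WINDOW, post: float = POST_WINDOW,
                ) -> list[StimulusWindowPair]:
    """One pre/post window pair per onset of ``stimulus_type``, in time order.

    Pre windows are clipped never to precede the recording start; a clipped
    pair carries ``shortened=True``.
    """
    if pre <= 0 or post <= 0:
        raise ConfigError("window durations must be positive")
    pairs = []
    for onset in sorted(protocol.onsets(stimulus_type)):
        pre_start = onset - pre
        shortened = pre_start < protocol.start
        if shortened:
            pre_start = protocol.start
        pairs.append(
            StimulusWindowPair(
                onset=onset,
                pre_start=pre_start,
                post_stop=min(onset + post, protocol.stop),
                shortened=shortened,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# builders


def build_protocol(spec: dict) -> Protocol:
    """Build a Protocol from a config mapping.

    ``spec["phases"]`` is an ordered list of ``{label, duration,
    illumination, sound, drug}`` entries (starts are accumulated);
    ``spec["stimuli"]`` is an optional list of ``{type, time}`` entries.
    Alternatively ``spec["preset"]`` names a preset, with remaining keys
    passed through as overrides.
    """
    if "preset" in spec:
        kwargs = {k: v for k, v in spec.items() if k != "preset"}
        return preset(spec["preset"], **kwargs)
    if "phases" not in spec:
        raise ConfigError("protocol spec needs 'phases' or 'preset'")
    phases = []
    t = float(spec.get("start", 0.0))
    for entry in spec["phases"]:
        p = Phase(
            label=entry["label"],
            start=t,
            duration=float(entry["duration"]),
            illumination=entry.get("illumination", "on"),
            sound=entry.get("sound", "ambient"),
            drug=entry.get("drug", "none"),
        )
        phases.append(p)
        t = p.stop
    stimuli = tuple(
        Stimulus(type=e["type"], time=float(e["time"])) for e in spec.get("stimuli", ())
    )
    return Protocol(phases=tuple(phases), stimuli=stimuli, name=spec.get("name", "protocol"))


def larval_light_dark(habituation: float = 2700.0, phase_duration: float = 300.0) -> Protocol:
    """Larval light/dark assay: habituation, then L0 (light), D1 (dark), L1 (light)."""
    phases = []
    t = 0.0
    for label, dur, illum in [
        ("habituation", habituation, "on"),
        ("L0", phase_duration, "on"),
        ("D1", phase_duration, "off"),
        ("L1", phase_duration, "on"),
    ]:
        phases.append(Phase(label=label, start=t, duration=dur, illumination=illum))
        t += dur
    stimuli = (
        Stimulus("dark_onset", phases[2].start),
        Stimulus("light_onset", phases[3].start),
    )
    return Protocol(tuple(phases), stimuli, name="larval_ld_7dpf")


def asr(adaptation: float = 3600.0, conditioning: float = 300.0,
        noise_duration: float = 15.0, cycles: int = 3,
        trailing: float = 0.0) -> Protocol:
    """Acoustic startle: dark adaptation, then cycles of ambient conditioning + noise."""
    phases = [Phase("adaptation", 0.0, adaptation, illumination="off")]
    stimuli = []
    t = adaptation
    for k in range(1, cycles + 1):
        phases.append(Phase(f"ambient{k}", t, conditioning, illumination="off"))
        t += conditioning
        phases.append(Phase(f"noise{k}", t, noise_duration, illumination="off", sound="noise"))
        stimuli.append(Stimulus("noise_onset", t))
        t += noise_duration
    if trailing > 0:
        phases.append(Phase("trailing", t, trailing, illumination="off"))
    return Protocol(tuple(phases), tuple(stimuli), name="asr_13dpf")


def vmr_dark_to_light(adaptation: float = 3600.0, dark: float = 300.0,
                      light: float = 15.0, cycles: int = 3,
                      trailing: float = 0.0) -> Protocol:
    """Visuomotor response, dark-to-light: dark adaptation, then dark + brief light cycles."""
    phases = [Phase("adaptation", 0.0, adaptation, illumination="off")]
    stimuli = []
    t = adaptation
    for k in range(1, cycles + 1):
        phases.append(Phase(f"dark{k}", t, dark, illumination="off"))
        t += dark
        phases.append(Phase(f"light{k}", t, light, illumination="on"))
        stimuli.append(Stimulus("light_onset", t))
        t += light
    if trailing > 0:
        phases.append(Phase("trailing", t, trailing, illumination="off"))
    return Protocol(tuple(phases), tuple(stimuli), name="vmr_dark_to_light")


def vmr_light_to_dark(adaptation: float = 3600.0, light: float = 300.0,
                      dark: float = 300.0, cycles: int = 3) -> Protocol:
    """Visuomotor response, light-to-dark: light adaptation, then light + dark cycles."""
    phases = [Phase("adaptation", 0.0, adaptation, illumination="on")]
    stimuli = []
    t = adaptation
    for k in range(1, cycles + 1):
        phases.append(Phase(f"light{k}", t, light, illumination="on"))
        t += light
        phases.append(Phase(f"dark{k}", t, dark, illumination="off"))
        stimuli.append(Stimulus("dark_onset", t))
        t += dark
    return Protocol(tuple(phases), tuple(stimuli), name="vmr_light_to_dark")


def ptz_challenge(acclimation: float = 300.0, spontaneous: float = 2700.0,
                  light: float = 300.0, dark: float = 300.0,
                  concentration_mm: float = 0.0) -> Protocol:
    """PTZ light-to-dark challenge: acclimation + spontaneous (lit), then one
    5 min light / 5 min dark cycle. ``concentration_mm`` > 0 marks all phases
    as drug-exposed (the drug is in the bath throughout the recording)."""
    drug = f"PTZ@{concentration_mm:g}mM" if concentration_mm > 0 else "none"
    phases = []
    t = 0.0
    for label, dur, illum in [
        ("acclimation", acclimation, "on"),
        ("spontaneous", spontaneous, "on"),
        ("light", light, "on"),
        ("dark", dark, "off"),
    ]:
        phases.append(Phase(label, t, dur, illumination=illum, drug=drug))
        t += dur
    stimuli = (Stimulus("dark_onset", phases[-1].start),)
    return Protocol(tuple(phases), stimuli, name="ptz_challenge_9dpf")


def open_field(duration: float = 1800.0, habituation: float = 300.0) -> Protocol:
    """Adult open-field recording: brief habituation, then the scored test period."""
    phases = (
        Phase("habituation", 0.0, habituation, illumination="on"),
        Phase("test", habituation, duration, illumination="on"),
    )
    return Protocol(phases, (), name="open_field")


def social_preference(duration: float = 1800.0, acclimation: float = 300.0) -> Protocol:
    """Three-chamber test: free-access acclimation, then the scored recording."""
    phases = (
        Phase("acclimation", 0.0, acclimation, illumination="on"),
        Phase("test", acclimation, duration, illumination="on"),
    )
    return Protocol(phases, (), name="social_preference")


_PRESETS = {
    "larval_ld_7dpf": larval_light_dark,
    "asr_13dpf": asr,
    "vmr_dark_to_light": vmr_dark_to_light,
    "vmr_light_to_dark": vmr_light_to_dark,
    "ptz_challenge_9dpf": ptz_challenge,
    "open_field": open_field,
    "social_preference": social_preference,
}


def preset(name: str, **overrides) -> Protocol:
    """Named protocol preset; keyword overrides pass through to the builder."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown protocol preset {name!r} (known: {sorted(_PRESETS)})"
        ) from None
    return builder(**overrides)
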