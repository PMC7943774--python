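"""Core domain containers: stimulation trains and recording sessions.

A vagus nerve stimulation (VNS) experiment delivers 10-s trains of biphasic
pulses, each train defined by pulse amplitude (mA), pulse width (ms) and
pulse rate (Hz).  A session bundles the continuously sampled physiological
channels (pupil area, exposed-eye/eyelid area, eye position, treadmill
velocity, optionally an axonal fluorescence trace) together with the ordered
event table of trains and session-level metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NERVE_CONDITIONS = ("intact", "single_cut", "double_cut")
EXPERIMENT_KINDS = (
    "parameter_exploration",
    "baseline_dependence",
    "axon_imaging",
    "light_control",
)
LUMINANCE_CLASSES = ("standard", "imaging")


@dataclass(frozen=True)
class StimTrain:
    """One VNS pulse train.

    Parameters
    ----------
    onset
        Train onset, seconds from session start.
    amplitude
        Pulse amplitude in mA.
    width
        Pulse width in ms.
    rate
        Pulse rate in Hz.
    duration
        Train duration in seconds (10 s in all experiments).

    The charge delivered per pulse, ``amplitude * width`` (μC), is the
    empirical collapse of the amplitude-width plane into one dose axis.
    """

    onset: float
    amplitude: float
    width: float
    rate: float
    duration: float = 10.0

    def __post_init__(self) -> None:
        for name in ("amplitude", "width", "rate", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"StimTrain.{name} must be > 0, got {getattr(self, name)!r}")

    @property
    def charge_per_pulse(self) -> float:
        """Charge per pulse in μC (mA × ms)."""
        return self.amplitude * self.width


@dataclass
class Channel:
    """A raw sampled signal with its own timestamp vector."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have identical shape")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("channel timestamps must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class SessionMeta:
    grounded: bool = False
    nerve_condition: str = "intact"
    experiment_kind: str = "parameter_exploration"
    luminance_class: str = "standard"
    session_id: str = "session"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nerve_condition not in NERVE_CONDITIONS:
            raise ValueError(f"nerve_condition must be one of {NERVE_CONDITIONS}")
        if self.experiment_kind not in EXPERIMENT_KINDS:
            raise ValueError(f"experiment_kind must be one of {EXPERIMENT_KINDS}")
        if self.luminance_class not in LUMINANCE_CLASSES:
            raise ValueError(f"luminance_class must be one of {LUMINANCE_CLASSES}")


@dataclass
class SessionRecord:
    """Multichannel time series + VNS event table + metadata for one session."""

    channels: dict[str, Channel]
    events: list[StimTrain]
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        if self.channels and self.events:
            lo = min(ch.span[0] for ch in self.channels.values())
            hi = max(ch.span[1] for ch in self.channels.values())
            for ev in self.events:
                if not (lo <= ev.onset <= hi):
                    raise ValueError(
                        f"event onset {ev.onset} s outside recorded span [{lo}, {hi}] s"
                    )

    @property
    def n_events(self) -> int:
        return len(self.events)

    def event_frame(self):
        """Events as a pandas DataFrame (onset_s, amplitude_ma, width_ms, rate_hz, duration_s, charge_uc)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_s": [e.onset for e in self.events],
                "amplitude_ma": [e.amplitude for e in self.events],
                "width_ms": [e.width for e in self.events],
                "rate_hz": [e.rate for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "charge_uc": [e.charge_per_pulse for e in self.events],
            }
        )
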