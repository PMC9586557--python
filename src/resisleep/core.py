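"""Core containers for recordings, hypnograms and frequency bands.

Conventions used throughout the package:

* Vigilance states are scored in fixed-length epochs (10 s by default) as
  ``WAKE``, ``NREM``, ``REM`` or ``ARTIFACT``.
* Time is expressed in zeitgeber time (ZT): seconds since light onset.
  ZT0 = lights on, ZT12 = lights off in a 12:12 light:dark cycle.
* Epochs are half-open, 0-based intervals ``[k*epoch_s, (k+1)*epoch_s)``
  anchored at the recording start.
* Signal samples are in microvolts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
ARTIFACT = "ARTIFACT"
STATES = (WAKE, NREM, REM, ARTIFACT)

EEG_FRONTAL = "EEG_FRONTAL"
EEG_PARIETAL = "EEG_PARIETAL"
LFP_PRL = "LFP_PRL"
LFP_IL = "LFP_IL"
EMG = "EMG"
ROLES = (EEG_FRONTAL, EEG_PARIETAL, LFP_PRL, LFP_IL, EMG)

LIGHT_ONSET_ZT = 0.0
DARK_ONSET_ZT = 12.0

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, inclusive of its edge bins on integration."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r} requires 0 < f_lo < f_hi, "
                f"got ({self.f_lo}, {self.f_hi})"
            )


#: Slow-wave activity / delta band.
DELTA = BandDefinition("delta", 0.5, 4.0)
#: Theta band, dominant in REM sleep.
THETA = BandDefinition("theta", 6.0, 10.0)
#: Total power band used for percentage normalization.
TOTAL = BandDefinition("total", 0.5, 30.0)
#: Band of waking low-frequency waves (incidence statistic I_2-6).
WAKE_WAVE_BAND = BandDefinition("wake_waves", 2.0, 6.0)


@dataclass
class Hypnogram:
    """Sequence of scored vigilance-state epochs aligned to a recording.

    Parameters
    ----------
    labels
        One state label per epoch, each in :data:`STATES`.
    epoch_s
        Epoch duration in seconds (10 s scoring convention).
    zt_start_s
        ZT time, in seconds after light onset, of the first epoch's start.
    """

    labels: np.ndarray
    epoch_s: float = 10.0
    zt_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U8")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels {sorted(bad)}; expected {STATES}")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def epoch_zt_start_s(self) -> np.ndarray:
        """ZT start time (s) of every epoch."""
        return self.zt_start_s + np.arange(self.n_epochs) * self.epoch_s

    def state_mask(self, state: str) -> np.ndarray:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
        return self.labels == state

    def artifact_fraction(self) -> float:
        if self.n_epochs == 0:
            return 0.0
        return float(np.mean(self.labels == ARTIFACT))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_s == other.epoch_s
            and self.zt_start_s == other.zt_start_s
            and np.array_equal(self.labels, other.labels)
        )


@dataclass(frozen=True)
class ChannelMeta:
    """Role and acquisition metadata for one recorded channel.

    ``hardware_lowpass`` reflects the acquisition chain: 30 Hz for
    EEG-only recordings, 1000 Hz for LFP (and the EEG collected with it).
    """

    role: str
    sampling_rate: float
    hardware_lowpass: float = 30.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"unknown channel role {self.role!r}; accepted roles: {ROLES}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.hardware_lowpass not in (30.0, 1000.0):
            raise ValueError("hardware_lowpass must be 30 or 1000 Hz")


@dataclass
class Channel:
    meta: ChannelMeta
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)

    @property
    def duration_s(self) -> float:
        return self.data.size / self.meta.sampling_rate


@dataclass
class Recording:
    """Multichannel electrophysiology recording with a ZT-anchored start."""

    channels: list[Channel] = field(default_factory=list)
    zt_start_s: float = 0.0

    def __post_init__(self) -> None:
        durs = {round(ch.duration_s, 6) for ch in self.channels}
        if len(durs) > 1:
            raise ValueError(f"channels have mismatched durations: {sorted(durs)} s")

    @property
    def duration_s(self) -> float:
        if not self.channels:
            return 0.0
        return self.channels[0].duration_s

    @property
    def roles(self) -> list[str]:
        return [ch.meta.role for ch in self.channels]

    def get(self, role: str) -> Channel:
        for ch in self.channels:
            if ch.meta.role == role:
                return ch
        raise KeyError(f"no channel with role {role!r}; present: {self.roles}")

    def __contains__(self, role: str) -> bool:
        return any(ch.meta.role == role for ch in self.channels)


def epoch_sample_bounds(n_epochs: int, epoch_s: float, sampling_rate: float) -> np.ndarray:
    """Start/stop sample indices of each epoch for one channel.

    Returns an ``(n_epochs, 2)`` integer array of half-open [start, stop)
    sample intervals. Every sample of ``n_epochs * epoch_s`` seconds of
    signal belongs to exactly one epoch.
    """
    edges = np.round(np.arange(n_epochs + 1) * epoch_s * sampling_rate).astype(np.int64)
    return np.stack([edges[:-1], edges[1:]], axis=1)


def zt_is_light(zt_s: np.ndarray | float, light_onset_zt: float = 0.0,
                dark_onset_zt: float = 12.0) -> np.ndarray | bool:
    """True where a ZT time (seconds) falls in the light period."""
    hours = (np.asarray(zt_s) / 3600.0) % 24.0
    return (hours >= light_onset_zt) & (hours < dark_onset_zt)
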