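"""Core domain types for intracochlear electrocochleography (ECochG).

An ECochG recording consists of stimulus-locked epochs acquired separately
for the two acoustic polarities (condensation, CON; rarefaction, RAR) of a
pure-tone stimulus.  The cochlear microphonic (CM) follows the stimulus
waveform and inverts with polarity, so the difference of the two polarity
averages (DIF) emphasizes the CM while their sum (SUM) cancels it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Polarity",
    "ThresholdCategory",
    "StimulusSpec",
    "EpochMatrix",
    "Recording",
    "LabelRecord",
    "STIMULUS_TABLE",
    "VALID_FREQUENCIES",
    "VALID_ELECTRODES",
]


class Polarity(str, Enum):
    """Acoustic stimulus polarity of an epoch ensemble."""

    CON = "CON"
    RAR = "RAR"
    DIF = "DIF"


class ThresholdCategory(str, Enum):
    """Stimulation level relative to the behavioural hearing threshold.

    supra: 5 dB below the discomfort level; near: 10 dB above the hearing
    threshold; sub: 10 dB below the hearing threshold.
    """

    SUPRA = "supra"
    NEAR = "near"
    SUB = "sub"


#: Acoustic stimulation settings per stimulus frequency:
#: (stimulus_duration ms, recording_delay ms, measurement_window ms,
#:  max_amplitude dB HL).
STIMULUS_TABLE: dict[int, tuple[float, float, float, float]] = {
    250: (12.0, 1.0, 19.1, 109.0),
    500: (8.0, 1.0, 9.6, 115.0),
    750: (6.67, 1.0, 9.6, 123.0),
    1000: (5.0, 1.0, 8.0, 122.0),
    1500: (4.0, 1.0, 8.0, 122.0),
    2000: (3.0, 1.0, 6.5, 122.0),
}

VALID_FREQUENCIES = tuple(sorted(STIMULUS_TABLE))
VALID_ELECTRODES = (1, 4, 7, 10)


@dataclass(frozen=True)
class StimulusSpec:
    """Pure-tone stimulation settings for one recording.

    Parameters
    ----------
    frequency : int
        Stimulus frequency in Hz; one of 250, 500, 750, 1000, 1500, 2000.
    stimulus_duration : float
        Tone-burst duration in ms.
    recording_delay : float
        Delay between recording onset and stimulus onset in ms.
    measurement_window : float
        Length of the recorded epoch in ms.
    level_dB_HL : float
        Stimulation level in dB hearing level.
    threshold_category : ThresholdCategory
        Level relative to the individual hearing threshold.
    max_amplitude_dB_HL : float
        Maximum permissible stimulation level in dB HL.
    """

    frequency: int
    stimulus_duration: float = None  # type: ignore[assignment]
    recording_delay: float = None  # type: ignore[assignment]
    measurement_window: float = None  # type: ignore[assignment]
    level_dB_HL: float = 100.0
    threshold_category: ThresholdCategory = ThresholdCategory.SUPRA
    max_amplitude_dB_HL: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frequency not in STIMULUS_TABLE:
            raise ValueError(
                f"frequency must be one of {VALID_FREQUENCIES}, got {self.frequency}"
            )
        dur, delay, window, max_amp = STIMULUS_TABLE[self.frequency]
        if self.stimulus_duration is None:
            object.__setattr__(self, "stimulus_duration", dur)
        if self.recording_delay is None:
            object.__setattr__(self, "recording_delay", delay)
        if self.measurement_window is None:
            object.__setattr__(self, "measurement_window", window)
        if self.max_amplitude_dB_HL is None:
            object.__setattr__(self, "max_amplitude_dB_HL", max_amp)
        if not isinstance(self.threshold_category, ThresholdCategory):
            object.__setattr__(
                self, "threshold_category", ThresholdCategory(self.threshold_category)
            )
        if self.measurement_window < self.stimulus_duration:
            raise ValueError(
                "measurement_window must be at least the stimulus_duration "
                f"({self.measurement_window} < {self.stimulus_duration} ms)"
            )
        if self.level_dB_HL > self.max_amplitude_dB_HL:
            raise ValueError(
                f"level_dB_HL {self.level_dB_HL} exceeds the maximum amplitude "
                f"{self.max_amplitude_dB_HL} dB HL for {self.frequency} Hz"
            )

    def n_samples(self, sampling_rate: float) -> int:
        """Number of samples in one epoch at the given sampling rate."""
        return int(round(self.measurement_window * 1e-3 * sampling_rate))

    def to_attrs(self) -> dict:
        d = dataclasses.asdict(self)
        d["threshold_category"] = self.threshold_category.value
        return d

    @classmethod
    def from_attrs(cls, attrs: dict) -> "StimulusSpec":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in attrs.items() if k in names})


@dataclass
class EpochMatrix:
    """A stack of stimulus-locked epochs of one polarity.

    ``samples`` is a 2-D float array of shape (n_epochs, n_samples) in µV.
    """

    samples: np.ndarray
    sampling_rate: float
    polarity: Polarity = Polarity.CON

    #: Upper band-pass cutoff the Nyquist check is made against (Hz).
    _BAND_UPPER = 5000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not isinstance(self.polarity, Polarity):
            self.polarity = Polarity(self.polarity)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be 2-D (epochs x samples), got ndim={self.samples.ndim}"
            )
        if self.n_epochs < 4:
            raise ValueError(f"need at least 4 epochs, got {self.n_epochs}")
        if self.sampling_rate <= 2 * self._BAND_UPPER:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the "
                f"upper band-pass cutoff ({self._BAND_UPPER} Hz)"
            )

    @property
    def n_epochs(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def replace(self, samples: np.ndarray, polarity: Polarity | None = None) -> "EpochMatrix":
        """A copy of this matrix with new sample data (metadata preserved)."""
        return EpochMatrix(
            samples=samples,
            sampling_rate=self.sampling_rate,
            polarity=self.polarity if polarity is None else polarity,
        )


@dataclass
class Recording:
    """One ECochG measurement: paired CON/RAR epoch ensembles plus metadata.

    ``ground_truth`` is only meaningful for synthetic recordings, where the
    generator knows whether a CM component was injected.
    """

    con: EpochMatrix
    rar: EpochMatrix
    stimulus: StimulusSpec
    recording_id: str = ""
    electrode: int = 1
    timing: str = "intraoperative"
    ground_truth: bool | None = None
    extra_attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.con.samples.shape != self.rar.samples.shape:
            raise ValueError(
                f"CON and RAR shapes differ: {self.con.samples.shape} vs "
                f"{self.rar.samples.shape}"
            )
        if self.con.sampling_rate != self.rar.sampling_rate:
            raise ValueError("CON and RAR sampling rates differ")
        if self.electrode not in VALID_ELECTRODES:
            raise ValueError(
                f"electrode must be one of {VALID_ELECTRODES}, got {self.electrode}"
            )
        if self.timing not in ("intraoperative", "postoperative"):
            raise ValueError(f"timing must be intra- or postoperative, got {self.timing!r}")
        self.con.polarity = Polarity.CON
        self.rar.polarity = Polarity.RAR

    @property
    def sampling_rate(self) -> float:
        return self.con.sampling_rate

    @property
    def n_epochs(self) -> int:
        return self.con.n_epochs

    def time_axis(self) -> np.ndarray:
        """Time of each sample in ms, starting at recording onset."""
        return np.arange(self.con.n_samples) / self.sampling_rate * 1e3


@dataclass(frozen=True)
class LabelRecord:
    """A single rater's judgement on one recording in one labelling round."""

    recording_id: str
    rater_id: str
    round: int
    response_present: bool

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise ValueError(f"round must be 1 or 2, got {self.round}")
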