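"""Core data containers: EEG traces, stage annotations and detected AD segments.

A recording session is a single-channel voltage trace (microvolts) sampled
uniformly, plus a table of annotated intervals carrying the behavioural
Racine stage observed during each electrographic afterdischarge (AD).
Stages are grouped into three seizure phases:

* ISS — initial seizure stages (Racine 1 and 2)
* LSS — localized seizure stage (Racine 3)
* GSS — generalized seizure stages (Racine 4 and 5)
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError

PHASES = ("ISS", "LSS", "GSS")

_STAGE_TO_PHASE = {1: "ISS", 2: "ISS", 3: "LSS", 4: "GSS", 5: "GSS"}


def phase_of_stage(stage: int) -> str:
    """Map a Racine stage (1-5) to its seizure phase (ISS/LSS/GSS)."""
    try:
        return _STAGE_TO_PHASE[int(stage)]
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"Racine stage must be 1-5, got {stage!r}") from exc


@dataclass
class EEGRecord:
    """Uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : array of float
        Voltage in microvolts.
    sampling_rate : float
        Samples per second (Hz), > 0.
    start_time : float
        Time of the first sample, seconds.
    label : str
        Free-text channel / session label.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigurationError("EEGRecord expects a one-dimensional trace")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("EEGRecord contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def slice_seconds(self, onset: float, duration: float) -> "EEGRecord":
        """Cut the half-open interval [onset, onset + duration) into a new record."""
        i0 = int(round((onset - self.start_time) * self.sampling_rate))
        i1 = i0 + int(round(duration * self.sampling_rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ConfigurationError("requested slice is empty or outside the record")
        return replace(self, samples=self.samples[i0:i1], start_time=onset)


@dataclass
class StageEvent:
    """Annotated AD interval with behavioural context.

    ``phase`` is derived from ``racine_stage`` if not given explicitly.
    """

    onset_s: float
    duration_s: float
    racine_stage: int
    animal_id: str
    group: str
    day: int = 1
    phase: str = field(default="")

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("annotation duration must be positive")
        expected = phase_of_stage(self.racine_stage)
        if not self.phase:
            self.phase = expected
        elif self.phase != expected:
            raise ConfigurationError(
                f"phase {self.phase!r} inconsistent with stage {self.racine_stage}"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class ADSegment:
    """A detected afterdischarge matched to a stage annotation.

    ``add`` is the afterdischarge duration (ADD) measured by the detector,
    not the annotated duration; stage/phase/animal/group come from the
    matched annotation. ``matched`` is False for detections with no
    overlapping annotation, which downstream analyses exclude.
    """

    onset: float
    add: float
    racine_stage: int
    phase: str
    animal_id: str
    group: str
    matched: bool = True

    @property
    def end(self) -> float:
        return self.onset + self.add
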