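"""Shared data containers for multimodal EEG recordings.

Every analysis in this package runs over the same small set of carriers: a
:class:`HeadLayout` of named contacts on a spherical head model, a
:class:`Recording` holding a channels x samples matrix in microvolts, a
:class:`Hypnogram` of fixed-length sleep-stage epochs, and an
:class:`EventSet` of annotated spikes, seizures and stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SLEEP_STAGES",
    "DEFAULT_BANDS",
    "Contact",
    "HeadLayout",
    "Hypnogram",
    "Event",
    "EventSet",
    "Recording",
]

#: The five AASM sleep-wake stage labels.
SLEEP_STAGES = ("W", "N1", "N2", "N3", "REM")

#: Conventional clinical band edges in Hz.  The stage-specific oscillations
#: under comparison are posterior alpha (quiet wake, eyes closed), central
#: sigma/spindles (N2), frontal delta/slow waves (N3) and frontal beta (REM).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (11.0, 16.0),
    "beta": (16.0, 30.0),
}

MODALITIES = ("subscalp", "scalp", "intracranial")


@dataclass(frozen=True)
class Contact:
    """A single electrode contact on the spherical head model."""

    name: str
    position: np.ndarray  # 3-vector, mm
    modality: str  # subscalp | scalp | intracranial

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass
class HeadLayout:
    """Named contacts with 3D positions (mm) on a spherical head model.

    Scalp contacts lie on the sphere of radius ``head_radius_mm``; subscalp
    contacts lie on the concentric sphere ``head_radius_mm - scalp_thickness_mm``
    (implanted between scalp and cranium); intracranial contacts lie strictly
    inside.
    """

    contacts: list[Contact]
    head_radius_mm: float = 92.0
    scalp_thickness_mm: float = 7.0

    def __post_init__(self) -> None:
        names = [c.name for c in self.contacts]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate contact names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contacts]

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.contacts])

    @property
    def modalities(self) -> list[str]:
        return [c.modality for c in self.contacts]

    def by_modality(self, modality: str) -> list[Contact]:
        return [c for c in self.contacts if c.modality == modality]

    def index(self, name: str) -> int:
        for i, c in enumerate(self.contacts):
            if c.name == name:
                return i
        raise KeyError(f"no contact named {name!r}")

    def position_of(self, name: str) -> np.ndarray:
        return self.contacts[self.index(name)].position

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class Hypnogram:
    """Fixed-length-epoch sleep stage labels (AASM 30-s epochs by default)."""

    stages: list[str]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        bad = sorted({s for s in self.stages if s not in SLEEP_STAGES})
        if bad:
            raise ValueError(f"unknown stage labels {bad}; allowed: {SLEEP_STAGES}")

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_length

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_length == other.epoch_length and self.stages == other.stages
        )

    def stage_mask(self, stage: str, fs: float, n_samples: int) -> np.ndarray:
        """Boolean sample mask selecting all epochs of ``stage``."""
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_length * fs))
        for i, s in enumerate(self.stages):
            if s == stage:
                mask[i * spe : min((i + 1) * spe, n_samples)] = True
        return mask


@dataclass
class Event:
    """A single annotated event.

    ``kind`` is one of ``spike``, ``seizure`` or ``stimulus``; ``attributes``
    carries kind-specific ground truth (dipole position/moment for spikes, SOZ
    and PZ positions plus the frequency trajectory for seizures, the stimulus
    modality for stimuli).
    """

    kind: str
    onset: float
    duration: float
    attributes: dict = field(default_factory=dict)

    KINDS = ("spike", "seizure", "stimulus")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventSet:
    events: list[Event] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class Recording:
    """Channels x samples EEG matrix in microvolts with its layout and labels."""

    data: np.ndarray
    sampling_rate: float
    layout: HeadLayout
    annotations: EventSet = field(default_factory=EventSet)
    hypnogram: Optional[Hypnogram] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D channels x samples array")
        if self.data.shape[0] != len(self.layout):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but layout has "
                f"{len(self.layout)} contacts"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.layout.index(name)]

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            sampling_rate=self.sampling_rate,
            layout=self.layout,
            annotations=EventSet(list(self.annotations.events)),
            hypnogram=None
            if self.hypnogram is None
            else replace(self.hypnogram, stages=list(self.hypnogram.stages)),
        )
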