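"""The in-memory container for one subject's multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ChannelError, ValidationError

__all__ = ["Recording", "GROUP_PATIENT", "GROUP_CONTROL"]

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"


@dataclass
class Recording:
    """One subject's EEG: a (channels x time) array plus identity metadata.

    Amplitude units are arbitrary; every downstream feature is either
    scale-invariant or standardised before classification.
    """

    subject_id: str
    group: str
    channel_names: list
    fs: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.group not in (GROUP_PATIENT, GROUP_CONTROL):
            raise ValidationError(
                f"group must be '{GROUP_PATIENT}' or '{GROUP_CONTROL}', "
                f"got {self.group!r}"
            )
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{len(self.channel_names)} channel names but data has "
                f"{self.data.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"recording {self.subject_id} has non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Samples of one channel, matched case-insensitively."""
        lowered = [c.lower() for c in self.channel_names]
        try:
            idx = lowered.index(name.lower())
        except ValueError:
            raise ChannelError([name], self.channel_names) from None
        return self.data[idx]

    def select_channels(self, names) -> "Recording":
        """Sub-recording restricted to ``names``, in the requested order."""
        lowered = {c.lower(): i for i, c in enumerate(self.channel_names)}
        missing = [n for n in names if n.lower() not in lowered]
        if missing:
            raise ChannelError(missing, self.channel_names)
        rows = [lowered[n.lower()] for n in names]
        return Recording(
            subject_id=self.subject_id,
            group=self.group,
            channel_names=list(names),
            fs=self.fs,
            data=self.data[rows],
        )
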