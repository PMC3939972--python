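"""Reading recordings from disk and segmenting them into overlapping windows.

Two on-disk encodings are supported: European Data Format (EDF, read through
``mne``) and a plain delimited-text layout (first row channel names, one
column per channel) which is what the synthetic-cohort writer produces.
Channel names are matched case-insensitively against 10-20 system labels,
optionally mapping the older temporal names onto their modern aliases
(T3=T7, T4=T8).

Windowing follows the analysis protocol: 2-second frames with 50 % overlap,
half-open sample intervals, trailing partial frames discarded so every
window has the same length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import APEN_MIN_SAMPLES
from .exceptions import (
    ChannelError,
    EmptyOutputError,
    FormatError,
    ValidationError,
)
from .recording import Recording

__all__ = [
    "ANALYSIS_CHANNELS",
    "TEMPORAL_ALIASES",
    "WindowingParams",
    "Window",
    "read_recording",
    "read_manifest",
    "read_cohort",
    "segment",
    "windows_to_frame",
]

#: The five central/temporal channels entering the analysis.
ANALYSIS_CHANNELS = ("Cz", "C3", "C4", "T3", "T4")

#: Old-nomenclature temporal electrodes and their modern equivalents.
TEMPORAL_ALIASES = {"t3": "t7", "t4": "t8"}


@dataclass(frozen=True)
class WindowingParams:
    """Frame length, overlap and analysis-channel selection.

    The 50-sample floor keeps every window long enough for a meaningful
    ApEn estimate.
    """

    window_seconds: float = 2.0
    overlap_fraction: float = 0.5
    channels: tuple = ANALYSIS_CHANNELS

    def __post_init__(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ValidationError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )
        if not self.window_seconds > 0:
            raise ValidationError(
                f"window_seconds must be positive, got {self.window_seconds}"
            )

    def n_samples(self, fs: float) -> int:
        n = round(self.window_seconds * fs)
        if n < APEN_MIN_SAMPLES:
            raise ValidationError(
                f"{self.window_seconds} s at {fs} Hz gives {n} samples; "
                f"windows need >= {APEN_MIN_SAMPLES}"
            )
        return n

    def step(self, fs: float) -> int:
        n = self.n_samples(fs)
        step = round(n * (1.0 - self.overlap_fraction))
        return max(step, 1)


@dataclass(frozen=True)
class Window:
    """One single-channel frame with full provenance."""

    subject_id: str
    group: str
    channel: str
    index: int
    samples: np.ndarray = field(repr=False)
    fs: float = 0.0


def _read_delimited(path: Path) -> tuple[list, np.ndarray]:
    """Delimited text: header row of channel names, one column per channel."""
    frame = pd.read_csv(path, sep=None, engine="python")
    names = [str(c).strip() for c in frame.columns]
    data = frame.to_numpy(dtype=float).T
    return names, data


def _read_edf(path: Path) -> tuple[list, np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # keep the file's physical-unit values (mne defaults to volts)
    return list(raw.ch_names), raw.get_data(units="uV"), float(raw.info["sfreq"])


def read_recording(
    path,
    subject_id: str | None = None,
    group: str | None = None,
    fs: float | None = None,
    channels=None,
    use_temporal_aliases: bool = False,
) -> Recording:
    """Read one subject's recording from an EDF or delimited-text file.

    Parameters
    ----------
    path
        File path; ``.edf`` extension selects the EDF reader, anything else
        is parsed as delimited text.
    subject_id, group
        Identity metadata, typically taken from a manifest row.
    fs
        Sampling rate in Hz.  Required for text files (the format carries
        none); ignored for EDF, which stores its own.
    channels
        If given, restrict (and order) the output to these channels,
        matched case-insensitively.  A missing channel raises
        :class:`ChannelError` naming the missing labels.
    use_temporal_aliases
        Accept T7/T8 in the file where T3/T4 are requested (and vice versa).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        try:
            names, data, fs = _read_edf(path)
        except Exception as exc:  # mne raises various concrete types
            raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    else:
        if fs is None:
            raise ValidationError("fs is required when reading delimited text")
        try:
            names, data = _read_delimited(path)
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"cannot parse {path} as delimited text: {exc}") from exc

    rec = Recording(
        subject_id=subject_id if subject_id is not None else path.stem,
        group=group if group is not None else "control",
        channel_names=names,
        fs=float(fs),
        data=data,
    )
    if channels is not None:
        if use_temporal_aliases:
            present = {c.lower() for c in rec.channel_names}
            resolved = []
            for name in channels:
                low = name.lower()
                if low not in present and TEMPORAL_ALIASES.get(low) in present:
                    resolved.append(TEMPORAL_ALIASES[low])
                else:
                    resolved.append(name)
            channels = resolved
        rec = rec.select_channels(channels)
    return rec


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest CSV with columns subject_id, group, filename."""
    manifest = pd.read_csv(path, dtype=str)
    required = {"subject_id", "group", "filename"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks column(s) {sorted(missing)}")
    return manifest


def read_cohort(directory, fs: float | None = None, channels=None) -> list:
    """Read every subject listed in ``directory/manifest.csv``."""
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    recordings = []
    for row in manifest.itertuples(index=False):
        recordings.append(
            read_recording(
                directory / row.filename,
                subject_id=row.subject_id,
                group=row.group,
                fs=fs,
                channels=channels,
            )
        )
    return recordings


def segment(recording: Recording, params: WindowingParams = WindowingParams()) -> list:
    """Cut each analysis channel into overlapping fixed-length windows.

    Window ``i`` of a channel covers the half-open sample interval
    ``[i * step, i * step + N)``; trailing samples that do not fill a whole
    window are discarded, so the count per channel is
    ``floor((L - N) / step) + 1``.
    """
    n = params.n_samples(recording.fs)
    step = params.step(recording.fs)
    length = recording.n_samples
    if length < n:
        raise EmptyOutputError(
            f"recording {recording.subject_id} has {length} samples, "
            f"shorter than one {n}-sample window"
        )
    n_windows = (length - n) // step + 1
    windows = []
    for name in params.channels:
        x = recording.channel(name)
        for i in range(n_windows):
            start = i * step
            windows.append(
                Window(
                    subject_id=recording.subject_id,
                    group=recording.group,
                    channel=name,
                    index=i,
                    samples=x[start : start + n],
                    fs=recording.fs,
                )
            )
    return windows


def windows_to_frame(windows) -> pd.DataFrame:
    """Long-format table of windows (one row per window) for debugging export."""
    if not windows:
        raise EmptyOutputError("no windows to export")
    n = len(windows[0].samples)
    rows = []
    for w in windows:
        if len(w.samples) != n:
            raise ValidationError("windows have inconsistent lengths")
        rows.append(
            [w.subject_id, w.group, w.channel, w.index, *np.asarray(w.samples)]
        )
    cols = ["subject_id", "group", "channel", "window_index"] + [
        f"s{i}" for i in range(n)
    ]
    return pd.DataFrame(rows, columns=cols)
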