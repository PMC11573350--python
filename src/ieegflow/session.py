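"""Core data containers and on-disk formats.

A :class:`RecordingSession` bundles a multichannel signal with its channel
metadata (name, contact group, region label) and an events table; it is the
unit of I/O for the whole pipeline.  Sessions are stored as an HDF5 file
(``/signal`` channels x samples float32, ``/fs`` scalar) with sibling
tab-separated channel and event tables, so every artifact round-trips
through plain, inspectable formats.  EDF recordings can be read through MNE
when it is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

#: Region labels recognised by the analysis.  AI = anterior insula;
#: PCC = posterior cingulate cortex / precuneus and mPFC = medial prefrontal
#: cortex (default-mode network); dPPC = dorsal posterior parietal cortex and
#: MFG = middle frontal gyrus (frontoparietal network); IFG = inferior
#: frontal gyrus (control region).
REGIONS = ("AI", "PCC", "mPFC", "dPPC", "MFG", "IFG", "other")

#: Default-mode / frontoparietal target nodes used for hub statistics.
TARGET_REGIONS = ("PCC", "mPFC", "dPPC", "MFG")

CHANNEL_COLUMNS = ("name", "group", "region")
EVENT_COLUMNS = ("onset_s", "duration_s", "trial_type", "task", "subject_id", "recalled")

TASKS = ("VFR", "CATVFR", "PALVCR", "WMSM")

#: Encoding epoch length per task, seconds.  Verbal free recall and its
#: categorized variant present words for 1.6 s; paired-associates items are
#: shown for 4 s; the spatial water-maze task uses 5 s drive epochs.
ENCODING_EPOCH_S = {"VFR": 1.6, "CATVFR": 1.6, "PALVCR": 4.0, "WMSM": 5.0}

#: Recall epoch length per task, seconds.  Verbal tasks analyse the 1.6 s
#: preceding vocal onset; the water-maze task uses 5 s navigation epochs.
RECALL_EPOCH_S = {"VFR": 1.6, "CATVFR": 1.6, "PALVCR": 1.6, "WMSM": 5.0}


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError(f"invalid band {self.name}: [{self.low}, {self.high}] Hz")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz >= Nyquist {fs / 2} Hz"
            )


#: The analysis bands.  Directed-connectivity analyses use the broadband
#: spectrum; power analyses use high-gamma.
BANDS = {
    "broadband": BandSpec("broadband", 0.5, 80.0),
    "delta_theta": BandSpec("delta_theta", 0.5, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 80.0),
    "high_gamma": BandSpec("high_gamma", 80.0, 160.0),
}


@dataclass
class RecordingSession:
    """Multichannel recording plus channel metadata and events.

    Parameters
    ----------
    signal
        Array of shape (n_channels, n_samples).
    fs
        Sampling rate in Hz.
    channels
        DataFrame with columns ``name``, ``group``, ``region``; one row per
        signal row, in order.
    events
        DataFrame with columns ``onset_s``, ``duration_s``, ``trial_type``,
        ``task``, ``subject_id``, ``recalled``.
    subject_id
        Convenience label; events carry their own subject column.
    """

    signal: np.ndarray
    fs: float
    channels: pd.DataFrame
    events: pd.DataFrame
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel rows for {self.signal.shape[0]} signal rows"
            )
        missing = set(CHANNEL_COLUMNS) - set(self.channels.columns)
        if missing:
            raise ValueError(f"channel table missing columns: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray, fs: float | None = None) -> "RecordingSession":
        """Copy of the session with a new signal array (and optionally fs)."""
        return replace(self, signal=signal, fs=self.fs if fs is None else fs)

    def channel_index(self, name: str) -> int:
        idx = np.flatnonzero(self.channels["name"].to_numpy() == name)
        if idx.size == 0:
            raise KeyError(f"no channel named {name!r}")
        return int(idx[0])


@dataclass
class EpochSet:
    """Trials cut around events: (n_trials, n_channels, n_samples).

    ``window`` is (start, end) in seconds relative to the event anchor
    (stimulus onset for encoding, vocal onset for recall).
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    condition: str
    task: str
    channels: pd.DataFrame
    subject_id: str = ""
    recalled: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=data)


# ---------------------------------------------------------------------------
# Writers / readers


def _sibling(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def save_session(session: RecordingSession, path: str | Path) -> Path:
    """Write a session as HDF5 + channel/event TSVs next to it.

    ``path`` should end in ``.h5``; ``<stem>_channels.tsv`` and
    ``<stem>_events.tsv`` are written alongside.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=session.signal.astype(np.float32))
        f.create_dataset("fs", data=float(session.fs))
        f.attrs["subject_id"] = session.subject_id
    session.channels.to_csv(_sibling(path, "_channels.tsv"), sep="\t", index=False)
    session.events.to_csv(_sibling(path, "_events.tsv"), sep="\t", index=False)
    return path


def load_session(path: str | Path) -> RecordingSession:
    """Read a session previously written by :func:`save_session`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        signal = f["signal"][()].astype(np.float64)
        fs = float(f["fs"][()])
        subject_id = str(f.attrs.get("subject_id", ""))
    channels = pd.read_csv(_sibling(path, "_channels.tsv"), sep="\t")
    events = pd.read_csv(_sibling(path, "_events.tsv"), sep="\t")
    return RecordingSession(signal, fs, channels, events, subject_id=subject_id)


def read_edf(
    path: str | Path,
    channels: pd.DataFrame | str | Path,
    events: pd.DataFrame | str | Path,
    subject_id: str = "",
) -> RecordingSession:
    """Read an EDF recording into a :class:`RecordingSession`.

    Channel metadata and events are supplied as TSVs (or DataFrames) in the
    same schema the HDF5 writer uses; the EDF header only provides channel
    names.  Requires MNE (``pip install ieegflow[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data()
    fs = float(raw.info["sfreq"])
    if not isinstance(channels, pd.DataFrame):
        channels = pd.read_csv(channels, sep="\t")
    if not isinstance(events, pd.DataFrame):
        events = pd.read_csv(events, sep="\t")
    return RecordingSession(signal, fs, channels, events, subject_id=subject_id)


def save_ground_truth(edges: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(list(edges), indent=2) + "\n")
    return path


def load_ground_truth(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
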