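"""Signal conditioning for intracranial EEG.

The canonical order, enforced by the pipeline driver, is

    resample (500 Hz) -> bipolar montage -> line-noise band-stops ->
    per-channel z-normalisation -> band filtering -> epoching

All filters are fourth-order Butterworth designs applied forward and
backward (two-way) so the net phase response is zero; the two passes double
the effective attenuation.  A unit-root check on an autoregressive fit
(:func:`ar_spectral_radius`) is provided to verify the near-nonstationarity
that motivates phase-based rather than Granger-style directed measures.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import (
    ENCODING_EPOCH_S,
    RECALL_EPOCH_S,
    BandSpec,
    EpochSet,
    RecordingSession,
)

logger = logging.getLogger(__name__)

#: 60 Hz line noise and harmonics, removed with band-stops.
LINE_NOISE_STOPS = ((57.0, 63.0), (117.0, 123.0), (177.0, 183.0))

#: One-pass Butterworth order; the forward-backward application doubles it.
FILTER_ORDER = 4


def _butter_sos(btype: str, low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(FILTER_ORDER, (low, high), btype=btype, fs=fs, output="sos")


def _filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, x, axis=-1)


def resample_session(session: RecordingSession, target_fs: float = 500.0) -> RecordingSession:
    """Anti-aliased downsampling to ``target_fs`` (pass-through if equal).

    Event onsets are in seconds and therefore unchanged.  Upsampling is
    refused: the pipeline only ever reduces the rate.
    """
    if target_fs > session.fs:
        raise ValueError(f"refusing to upsample from {session.fs} to {target_fs} Hz")
    if target_fs == session.fs:
        return session
    frac = Fraction(target_fs / session.fs).limit_denominator(10000)
    out = sps.resample_poly(session.signal, frac.numerator, frac.denominator, axis=-1)
    return session.with_signal(out, fs=target_fs)


def bipolar_montage(session: RecordingSession) -> RecordingSession:
    """Re-reference to adjacent-contact differences within each contact group.

    For a group with contacts c1..ck (table order) the output holds k-1
    virtual channels c_i - c_{i+1}, named ``"ci-ci+1"``, carrying the region
    label of the first contact.  Groups of a single contact emit nothing.
    Differencing cancels any signal common to both contacts (volume-conducted
    or reference artifacts).
    """
    if "group" not in session.channels.columns:
        raise ValueError("channel table has no 'group' column")
    rows = []
    out = []
    chans = session.channels.reset_index(drop=True)
    for group, sub in chans.groupby("group", sort=False):
        if len(sub) < 2:
            logger.info("group %s has a single contact; no bipolar channel emitted", group)
            continue
        pos = sub.index.to_numpy()
        for a, b in zip(pos[:-1], pos[1:]):
            out.append(session.signal[a] - session.signal[b])
            rows.append(
                {
                    "name": f"{chans.at[a, 'name']}-{chans.at[b, 'name']}",
                    "group": group,
                    "region": chans.at[a, "region"],
                }
            )
    if not rows:
        raise ValueError("no contact group has >= 2 contacts; bipolar montage is empty")
    channels = pd.DataFrame(rows, columns=["name", "group", "region"])
    return RecordingSession(
        np.asarray(out), session.fs, channels, session.events, subject_id=session.subject_id
    )


def remove_line_noise(session: RecordingSession) -> RecordingSession:
    """Zero-phase band-stops at 57-63, 117-123 and 177-183 Hz.

    Stops above the Nyquist frequency are skipped.
    """
    x = session.signal
    for low, high in LINE_NOISE_STOPS:
        if high >= session.fs / 2:
            continue
        x = _filtfilt(_butter_sos("bandstop", low, high, session.fs), x)
    return session.with_signal(x)


def zscore_channels(session: RecordingSession) -> RecordingSession:
    """Remove each channel's mean and scale by its standard deviation."""
    mu = session.signal.mean(axis=-1, keepdims=True)
    sd = session.signal.std(axis=-1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = session.channels["name"].to_numpy()[flat]
        raise ValueError(f"zero-variance channel(s): {', '.join(map(str, names))}")
    return session.with_signal((session.signal - mu) / sd)


def bandpass(obj: RecordingSession | EpochSet | np.ndarray, band: BandSpec, fs: float | None = None):
    """Zero-phase fourth-order Butterworth band-pass.

    Accepts a session, an epoch set, or a bare array (with ``fs``); returns
    the same type with the last axis filtered.
    """
    if isinstance(obj, RecordingSession):
        band.validate_for(obj.fs)
        return obj.with_signal(_filtfilt(_butter_sos("bandpass", band.low, band.high, obj.fs), obj.signal))
    if isinstance(obj, EpochSet):
        band.validate_for(obj.fs)
        return obj.with_data(_filtfilt(_butter_sos("bandpass", band.low, band.high, obj.fs), obj.data))
    if fs is None:
        raise ValueError("fs is required when filtering a bare array")
    band.validate_for(fs)
    return _filtfilt(_butter_sos("bandpass", band.low, band.high, fs), np.asarray(obj))


def _rest_windows(events: pd.DataFrame, epoch_s: float, n_wanted: int) -> list[float]:
    rest = events[events["trial_type"] == "rest"]
    if rest.empty:
        raise ValueError("no rest span in events table")
    onsets: list[float] = []
    for _, row in rest.iterrows():
        start, dur = float(row["onset_s"]), float(row["duration_s"])
        k = int(np.floor(dur / epoch_s))
        onsets.extend(start + i * epoch_s for i in range(k))
    if len(onsets) < n_wanted:
        warnings.warn(
            f"rest span yields only {len(onsets)} epochs of {epoch_s} s "
            f"({n_wanted} wanted)",
            stacklevel=2,
        )
    return onsets[:n_wanted]


def epoch(
    session: RecordingSession,
    condition: str,
    task: str | None = None,
    pad_pre_s: float = 0.0,
    pad_post_s: float = 0.0,
) -> EpochSet:
    """Cut trials of the given condition into an :class:`EpochSet`.

    Conventions (half-open sample windows, onset sample = floor(onset * fs)):

    - ``encoding``: [onset, onset + L) with L the task's stimulus duration
      (1.6 s verbal free recall, 4 s paired associates, 5 s water maze).
    - ``recall``: [vocal_onset - 1.6 s, vocal_onset) for verbal tasks;
      [onset, onset + 5 s) for the water-maze task.
    - ``rest``: consecutive non-overlapping windows of the task's encoding
      length cut from the pre-task rest span, matched in count to the
      encoding trials.

    ``pad_pre_s``/``pad_post_s`` extend each cut (e.g. to retain a
    pre-stimulus baseline); the ``window`` attribute records the resulting
    times relative to the anchor.  Trials extending outside the recording
    are dropped with a warning.
    """
    events = session.events
    if task is None:
        tasks = events.loc[events["trial_type"] != "rest", "task"].unique()
        if len(tasks) != 1:
            raise ValueError(f"task is ambiguous ({list(tasks)}); pass task explicitly")
        task = str(tasks[0])
    epoch_len = ENCODING_EPOCH_S[task]

    if condition == "encoding":
        sel = events[(events["trial_type"] == "encoding") & (events["task"] == task)]
        anchors = sel["onset_s"].to_numpy(float)
        rel_start, rel_end = 0.0, epoch_len
        recalled = sel["recalled"].to_numpy()
    elif condition == "recall":
        sel = events[(events["trial_type"] == "recall_vocal_onset") & (events["task"] == task)]
        anchors = sel["onset_s"].to_numpy(float)
        if task == "WMSM":
            rel_start, rel_end = 0.0, RECALL_EPOCH_S[task]
        else:
            rel_start, rel_end = -RECALL_EPOCH_S[task], 0.0
        recalled = sel["recalled"].to_numpy()
    elif condition == "rest":
        n_task = int((events["trial_type"] == "encoding").sum())
        anchors = np.asarray(_rest_windows(events, epoch_len, n_task), float)
        rel_start, rel_end = 0.0, epoch_len
        recalled = np.full(len(anchors), np.nan)
    else:
        raise ValueError(f"unknown condition {condition!r}")

    if anchors.size == 0:
        raise ValueError(f"no events match condition={condition!r}, task={task!r}")

    fs = session.fs
    start_rel = rel_start - pad_pre_s
    end_rel = rel_end + pad_post_s
    n_samp = int(round((end_rel - start_rel) * fs))
    cut, kept_recalled = [], []
    n_dropped = 0
    for anchor, rec in zip(anchors, recalled):
        i0 = int(np.floor((anchor + start_rel) * fs))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > session.n_samples:
            n_dropped += 1
            continue
        cut.append(session.signal[:, i0:i1])
        kept_recalled.append(rec)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped}/{len(anchors)} {condition} trials outside the recording",
            stacklevel=2,
        )
    if not cut:
        raise ValueError("all matching trials fall outside the recording")
    return EpochSet(
        data=np.stack(cut),
        fs=fs,
        window=(start_rel, end_rel),
        condition=condition,
        task=task,
        channels=session.channels,
        subject_id=session.subject_id,
        recalled=np.asarray(kept_recalled),
        n_dropped=n_dropped,
    )


def ar_spectral_radius(x: np.ndarray, order: int = 10) -> float:
    """Largest eigenvalue modulus of an AR(order) fit's companion matrix.

    A radius near one indicates a (near) unit root, i.e. a nonstationary
    series for which autoregressive directed measures are unreliable.  The
    AR coefficients are estimated by ordinary least squares with an
    intercept.
    """
    x = np.asarray(x, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if x.size <= 10 * order:
        raise ValueError(f"need more than {10 * order} samples for order {order}")
    from statsmodels.tsa.ar_model import AutoReg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = AutoReg(x, lags=order, trend="c").fit()
    coefs = res.params[1:]  # drop intercept
    companion = np.zeros((order, order))
    companion[0, :] = coefs
    if order > 1:
        companion[1:, :-1] = np.eye(order - 1)
    return float(np.abs(np.linalg.eigvals(companion)).max())
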