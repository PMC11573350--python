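"""High-gamma (80-160 Hz) envelope analysis.

The band is decomposed into eight 10 Hz sub-bands (80-90, ..., 150-160 Hz)
to counteract the 1/f fall-off of spectral power; each sub-band is
band-passed (zero-phase Butterworth), its Hilbert envelope is normalised to
that sub-band's own mean amplitude (expressed in % of the mean, so the
across-time mean is exactly 100 before baseline correction and the measure
is invariant to signal scale), and the eight normalised envelopes are
averaged.  The resulting trace is smoothed with 0.2 s windows at 90%
overlap and baseline-corrected against the 0.2 s pre-stimulus period (or a
matched rest series when no pre-stimulus exists, as for pre-vocal recall
windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from . import preprocess
from .session import BandSpec, EpochSet
from .stats import condition_contrast, fdr_bh

__all__ = [
    "PowerTimeSeries",
    "highgamma_bands",
    "highgamma_envelope",
    "smooth_windows",
    "baseline_correct",
    "windowwise_contrast",
]

#: Seconds trimmed at each epoch edge before statistics (Hilbert edge effects).
EDGE_TRIM_S = 0.05


@dataclass
class PowerTimeSeries:
    """Windowed normalized envelope: (trials, channels, windows).

    Values are percent of each sub-band's own mean amplitude; after
    :func:`baseline_correct` they are percentage-point deviations from the
    pre-stimulus (or rest) baseline.  ``window_times`` are window centres in
    seconds relative to the event anchor.
    """

    values: np.ndarray
    window_times: np.ndarray
    fs_effective: float
    condition: str = ""
    task: str = ""
    subject_id: str = ""
    channels: pd.DataFrame | None = None
    baseline: str = "none"  # none | prestimulus | rest
    win_s: float = 0.2

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]


def highgamma_bands(fs: float) -> list[BandSpec]:
    """The 10 Hz sub-bands of 80-160 Hz representable at sampling rate fs."""
    bands = [
        BandSpec(f"hg_{lo:.0f}_{lo + 10:.0f}", float(lo), float(lo + 10))
        for lo in range(80, 160, 10)
    ]
    usable = [b for b in bands if b.high < fs / 2]
    if not usable:
        raise ValueError(f"fs={fs} Hz cannot resolve any high-gamma sub-band")
    if len(usable) < len(bands):
        warnings.warn(
            f"fs={fs} Hz: only {len(usable)}/{len(bands)} high-gamma sub-bands "
            "below Nyquist; top bands skipped",
            stacklevel=2,
        )
    return usable


def highgamma_envelope(epochs: EpochSet) -> np.ndarray:
    """Across-band mean of own-mean-normalised sub-band envelopes.

    Returns (trials, channels, samples) in percent (mean 100 per band
    before averaging).  Normalisation is per epoch and per channel: each
    trial is an independent analysis unit.  Sub-bands whose mean envelope
    is negligible relative to the signal (< 1e-12 x RMS) are excluded from
    the across-band mean to avoid 0/0 on band-free synthetic inputs.
    """
    bands = highgamma_bands(epochs.fs)
    x = epochs.data
    acc = np.zeros(x.shape)
    cnt = np.zeros(x.shape[:2])
    rms = np.sqrt(np.mean(x**2, axis=-1))
    for band in bands:
        filtered = preprocess.bandpass(x, band, fs=epochs.fs)
        env = np.abs(hilbert(filtered, axis=-1))
        mean_env = env.mean(axis=-1)
        ok = mean_env > 1e-12 * np.maximum(rms, 1e-300)
        if not ok.all():
            warnings.warn(
                f"band {band.name}: negligible power in {int((~ok).sum())} "
                "trial-channel(s); excluded from the across-band mean",
                stacklevel=2,
            )
        norm = np.where(
            ok[..., None], env / np.where(mean_env[..., None] == 0, 1, mean_env[..., None]) * 100, 0.0
        )
        acc += norm
        cnt += ok
    if (cnt == 0).any():
        raise ValueError("no high-gamma sub-band has usable power for some trial-channel")
    return acc / cnt[..., None]


def smooth_windows(
    x: np.ndarray,
    fs: float,
    win_s: float = 0.2,
    overlap: float = 0.9,
    t0: float = 0.0,
    **meta,
) -> PowerTimeSeries:
    """Sliding-window means: 0.2 s windows, 90% overlap by default.

    ``x`` is (trials, channels, samples); ``t0`` is the time of the first
    sample relative to the event anchor.  The number of windows is
    floor((n - win) / step) + 1 with win = round(win_s * fs) samples and
    step = round(win * (1 - overlap)); timestamps are window centres.
    """
    x = np.asarray(x, float)
    win = int(round(win_s * fs))
    if win < 1:
        raise ValueError("window shorter than one sample")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(win * (1 - overlap))))
    n = x.shape[-1]
    if n < win:
        raise ValueError(f"epoch of {n} samples shorter than one {win}-sample window")
    n_win = (n - win) // step + 1
    starts = np.arange(n_win) * step
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    vals = (csum[..., starts + win] - csum[..., starts]) / win
    centers = t0 + (starts + win / 2) / fs
    return PowerTimeSeries(
        values=vals,
        window_times=centers,
        fs_effective=fs / step,
        win_s=win / fs,
        **meta,
    )


def epochs_to_power(epochs: EpochSet, win_s: float = 0.2, overlap: float = 0.9) -> PowerTimeSeries:
    """Envelope extraction + smoothing with epoch metadata carried along.

    The first and last 50 ms of each epoch are excluded (set to the nearest
    interior value) before smoothing to suppress Hilbert edge artifacts.
    """
    env = highgamma_envelope(epochs)
    trim = int(round(EDGE_TRIM_S * epochs.fs))
    if trim > 0 and env.shape[-1] > 2 * trim:
        env[..., :trim] = env[..., trim : trim + 1]
        env[..., -trim:] = env[..., -trim - 1 : -trim]
    return smooth_windows(
        env,
        epochs.fs,
        win_s=win_s,
        overlap=overlap,
        t0=epochs.window[0],
        condition=epochs.condition,
        task=epochs.task,
        subject_id=epochs.subject_id,
        channels=epochs.channels,
    )


def baseline_correct(
    p: PowerTimeSeries,
    baseline_s: float = 0.2,
    rest: PowerTimeSeries | None = None,
) -> PowerTimeSeries:
    """Subtract the pre-stimulus (or matched-rest) baseline per trial/channel.

    With ``rest=None`` the baseline is the mean over windows lying entirely
    within the ``baseline_s`` seconds before the anchor (requires the epochs
    to have been cut with pre-anchor padding).  For conditions with no
    pre-stimulus period (pre-vocal recall, rest-matched contrasts) pass a
    matched rest ``PowerTimeSeries``: its per-channel grand mean is used and
    the output is flagged ``baseline="rest"``.
    """
    if rest is not None:
        base = rest.values.mean(axis=(0, 2))  # per channel
        vals = p.values - base[None, :, None]
        return replace(p, values=vals, baseline="rest")
    # windows lying entirely inside [-baseline_s, 0]
    half = p.win_s / 2
    mask = (p.window_times + half <= 1e-9) & (
        p.window_times - half >= -baseline_s - 1e-9
    )
    if not mask.any():
        raise ValueError(
            "no complete baseline window before the anchor; cut epochs with "
            f"pad_pre_s >= {baseline_s}"
        )
    base = p.values[..., mask].mean(axis=-1)
    return replace(p, values=p.values - base[..., None], baseline="prestimulus")


def windowwise_contrast(
    pa: PowerTimeSeries,
    pb: PowerTimeSeries,
    subjects_a: np.ndarray,
    subjects_b: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mixed-model condition contrast in every time window, FDR-corrected.

    ``pa``/``pb`` hold the two conditions on identical window grids;
    ``subjects_*`` label each trial's subject.  Per window, trials are
    averaged per (subject, channel), the two conditions are contrasted with
    a mixed model (subject random intercept), and the per-window p-values
    are Benjamini-Hochberg corrected across windows.  Returns one row per
    window: window_time, F, p, p_fdr, significant.
    """
    if pa.values.shape[2] != pb.values.shape[2] or not np.allclose(
        pa.window_times, pb.window_times
    ):
        raise ValueError("the two series are not on the same window grid")
    subjects_a = np.asarray(subjects_a)
    subjects_b = np.asarray(subjects_b)
    rows = []
    for w in range(pa.n_windows):
        recs = []
        for cond, p, subj in (("A", pa, subjects_a), ("B", pb, subjects_b)):
            vals = p.values[:, :, w]  # trials x channels
            for s in np.unique(subj):
                m = vals[subj == s].mean(axis=0)  # per channel, trial-averaged
                for c, v in enumerate(m):
                    recs.append({"value": v, "condition": cond, "subject": s, "unit": c})
        report = condition_contrast(pd.DataFrame(recs))
        rows.append(
            {"window_time": pa.window_times[w], "F": report.F, "p": report.p}
        )
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_bh(out["p"].to_numpy(), alpha=alpha)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out


def power_long_table(p: PowerTimeSeries, trial_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format export: one row per (channel, trial, window)."""
    n_tr, n_ch, n_w = p.values.shape
    ch_names = (
        p.channels["name"].tolist() if p.channels is not None else list(range(n_ch))
    )
    regions = (
        p.channels["region"].tolist() if p.channels is not None else [""] * n_ch
    )
    tr_idx, ch_idx, w_idx = np.meshgrid(
        np.arange(n_tr), np.arange(n_ch), np.arange(n_w), indexing="ij"
    )
    return pd.DataFrame(
        {
            "subject_id": p.subject_id,
            "task": p.task,
            "condition": p.condition,
            "region": np.asarray(regions)[ch_idx.ravel()],
            "channel": np.asarray(ch_names)[ch_idx.ravel()],
            "trial": tr_idx.ravel(),
            "window_center_s": p.window_times[w_idx.ravel()],
            "value": p.values.ravel(),
        }
    )
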