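"""Ground-truth-known synthetic multi-electrode sessions.

The generator emulates the statistical structure the analysis assumes —
region-labelled electrode groups, trial-locked task events with a pre-task
rest baseline, broadband 1/f background activity, band-limited oscillations
with configurable *directed* coupling (a delayed-mixture model with a known
lag in samples), and task-locked high-gamma amplitude responses — without
claiming biophysical realism.  Every random draw comes from a single seeded
generator, so identical configurations give bit-identical sessions.

Directed coupling between regions follows a delayed signal mixture: the
target's oscillatory component is ``(1 - s) * own + s * source(t - lag)``.
This gives an unambiguous ground-truth direction and lag against which the
phase-transfer-entropy pipeline can be validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import ENCODING_EPOCH_S, RECALL_EPOCH_S, RecordingSession

__all__ = [
    "CouplingSpec",
    "GammaResponseSpec",
    "SessionConfig",
    "make_session",
    "coupled_phase_pair",
    "add_task_locked_gamma",
    "ground_truth",
]

#: Inter-stimulus interval range per task, seconds.
ISI_RANGES = {
    "VFR": (0.8, 1.2),
    "CATVFR": (0.75, 1.0),
    "PALVCR": (1.75, 2.0),
    "WMSM": (5.0, 5.0),
}

#: Fraction of encoding items later recalled, per task (typical performance).
RECALL_FRACTION = {"VFR": 0.25, "CATVFR": 0.30, "PALVCR": 0.34, "WMSM": 0.48}

HIGH_GAMMA_BAND = (80.0, 160.0)


@dataclass(frozen=True)
class CouplingSpec:
    """A directed influence between two regions.

    ``strength`` in [0, 1] is the mixture weight of the delayed source
    component in the target's oscillation; ``lag`` is the delay in samples;
    ``band`` (Hz) is the oscillation band the coupling lives in.
    """

    source_region: str
    target_region: str
    strength: float
    lag: int
    band: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self) -> None:
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must be in [0, 1]")
        if self.lag < 1:
            raise ValueError("lag must be >= 1 sample")
        if not self.band[0] < self.band[1]:
            raise ValueError("band low must be < high")
        if self.source_region == self.target_region:
            raise ValueError("source and target region must differ")


@dataclass(frozen=True)
class GammaResponseSpec:
    """Task-locked high-gamma amplitude change for one region.

    ``magnitude`` is a fraction of the baseline envelope (0.5 = +-50%);
    ``onset``/``offset`` are seconds relative to the matched event anchor.
    """

    region: str
    condition: str  # encoding | recall | rest
    direction: str  # increase | suppress | none
    magnitude: float
    onset: float = 0.0
    offset: float = 1.6

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if not self.onset < self.offset:
            raise ValueError("onset must be < offset")
        if self.direction not in ("increase", "suppress", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class SessionConfig:
    """Everything needed to synthesise one subject's session."""

    task: str = "VFR"
    n_trials: int = 12
    fs: float = 500.0
    regions: tuple[str, ...] = ("AI", "PCC", "mPFC", "dPPC", "MFG")
    probes_per_region: int = 1
    contacts_per_probe: int = 3
    couplings: tuple[CouplingSpec, ...] = ()
    gamma_responses: tuple[GammaResponseSpec, ...] = ()
    noise_exponent: float = 1.0  # 1/f^alpha background
    noise_amplitude: float = 1.0
    osc_amplitude: float = 1.0
    osc_band: tuple[float, float] = (8.0, 12.0)
    hg_amplitude: float = 0.5
    rest_factor: float = 0.5  # coupling strength multiplier during rest
    delay_period_s: float = 20.0  # post-encoding distractor period
    subject_id: str = "S01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ENCODING_EPOCH_S:
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        top = max(
            [self.osc_band[1], HIGH_GAMMA_BAND[1]]
            + [c.band[1] for c in self.couplings]
        )
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} cannot represent synthesized content up to {top} Hz"
            )


def pink_noise(rng: np.random.Generator, n: int, alpha: float = 1.0) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^alpha power spectrum."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-alpha / 2)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    low, high = band
    if high >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist {fs / 2}")
    sos = sps.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _delayed(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    out[lag:] = x[:-lag]
    return out


def coupled_phase_pair(
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    strength: float,
    lag: int,
    seed: int | np.random.Generator = 0,
    noise: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """A driver/target pair with known directed coupling.

    ``x`` is band-limited noise; ``y = (1 - strength) * independent
    band-limited noise + strength * x(t - lag) + noise * white``.  With
    ``strength=1`` and ``noise=0``, y is an exact delayed copy of x beyond
    the first ``lag`` samples.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must be in [0, 1]")
    if not 1 <= lag < n_samples:
        raise ValueError("need 1 <= lag < n_samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = bandlimited_noise(rng, n_samples, fs, band)
    indep = bandlimited_noise(rng, n_samples, fs, band)
    y = (1 - strength) * indep + strength * _delayed(x, lag)
    if noise:
        y = y + noise * rng.standard_normal(n_samples)
    return x, y


def add_task_locked_gamma(
    signal: np.ndarray,
    events: pd.DataFrame,
    spec: GammaResponseSpec,
    fs: float,
) -> np.ndarray:
    """Scale the 80-160 Hz component's amplitude in event-locked windows.

    The high-gamma component is isolated with a zero-phase band-pass,
    multiplied by (1 + magnitude) or (1 - magnitude) inside each matched
    event's [onset, offset] window, and recombined with the residual.
    Events whose window exceeds the recording are skipped with a warning.
    """
    signal = np.asarray(signal, float)
    if spec.direction == "none" or spec.magnitude == 0:
        return signal.copy()
    trial_type = {"encoding": "encoding", "recall": "recall_vocal_onset", "rest": "rest"}[
        spec.condition
    ]
    matched = events[events["trial_type"] == trial_type]
    n = signal.shape[-1]
    mod = np.ones(n)
    factor = 1 + spec.magnitude if spec.direction == "increase" else 1 - spec.magnitude
    any_window = False
    for onset in matched["onset_s"].to_numpy(float):
        i0 = int(np.floor((onset + spec.onset) * fs))
        i1 = int(np.floor((onset + spec.offset) * fs))
        if i0 < 0 or i1 > n:
            warnings.warn(
                f"gamma-response window [{onset + spec.onset:.2f}, "
                f"{onset + spec.offset:.2f}] s exceeds the recording; event skipped",
                stacklevel=2,
            )
            continue
        mod[i0:i1] = factor
        any_window = True
    if not any_window:
        return signal.copy()
    sos = sps.butter(4, HIGH_GAMMA_BAND, btype="bandpass", fs=fs, output="sos")
    hg = sps.sosfiltfilt(sos, signal, axis=-1)
    return signal - hg + hg * mod


def _build_events(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Timeline: [rest span][encoding trials][delay][recall events]."""
    task = config.task
    enc_len = ENCODING_EPOCH_S[task]
    rec_len = RECALL_EPOCH_S[task]
    isi_lo, isi_hi = ISI_RANGES[task]
    rows = []
    t = 1.0  # edge pad
    rest_dur = config.n_trials * enc_len + 2.0
    rows.append(("rest", t, rest_dur, np.nan))
    t += rest_dur + 1.0

    n_recalled = max(1, int(round(RECALL_FRACTION[task] * config.n_trials)))
    recalled_idx = set(rng.choice(config.n_trials, size=n_recalled, replace=False).tolist())
    for i in range(config.n_trials):
        rows.append(("encoding", t, enc_len, int(i in recalled_idx)))
        t += enc_len + rng.uniform(isi_lo, isi_hi)

    t += config.delay_period_s

    if task == "WMSM":
        # navigation recall epochs start at the event onset
        t += 1.0
        for _ in range(n_recalled):
            rows.append(("recall_vocal_onset", t, rec_len, 1))
            t += rec_len + rng.uniform(1.0, 2.0)
    else:
        # vocal onsets; the analysed window precedes each onset by 1.6 s
        t += rec_len + 1.0
        for _ in range(n_recalled):
            rows.append(("recall_vocal_onset", t, 0.0, 1))
            t += rec_len + rng.uniform(0.5, 1.5)

    df = pd.DataFrame(rows, columns=["trial_type", "onset_s", "duration_s", "recalled"])
    df["task"] = task
    df["subject_id"] = config.subject_id
    return df[["onset_s", "duration_s", "trial_type", "task", "subject_id", "recalled"]]


def _region_band(config: SessionConfig, region: str) -> tuple[float, float]:
    for c in config.couplings:
        if region in (c.source_region, c.target_region):
            return c.band
    return config.osc_band


def make_session(config: SessionConfig) -> RecordingSession:
    """Synthesise a full session for one subject.

    Each region has one latent oscillatory component (band-limited noise)
    and one latent high-gamma component; directed couplings mix a delayed
    copy of the source region's oscillation into the target's, with the
    mixture weight scaled by ``rest_factor`` during the pre-task rest span.
    Contacts on a probe pick up the region's latent components with
    alternating gains (emulating distance to a local source) plus private
    1/f background noise, so adjacent-contact differences retain the latent
    signal.
    """
    rng = np.random.default_rng(config.seed)
    events = _build_events(config, rng)
    last = events.iloc[-1]
    total_s = float(last["onset_s"]) + max(float(last["duration_s"]), 5.0) + 1.0
    n = int(np.ceil(total_s * config.fs))
    fs = config.fs

    # latent oscillation per region (draw in fixed region order for determinism)
    own = {r: bandlimited_noise(rng, n, fs, _region_band(config, r)) for r in config.regions}
    osc = dict(own)
    rest = events[events["trial_type"] == "rest"].iloc[0]
    r0 = int(np.floor(rest["onset_s"] * fs))
    r1 = int(np.floor((rest["onset_s"] + rest["duration_s"]) * fs))
    for c in config.couplings:
        if c.source_region not in own or c.target_region not in own:
            raise ValueError(f"coupling references unknown region: {c}")
        s_eff = np.full(n, c.strength)
        s_eff[r0:r1] = c.strength * config.rest_factor
        osc[c.target_region] = (1 - s_eff) * own[c.target_region] + s_eff * _delayed(
            own[c.source_region], c.lag
        )

    # latent high-gamma per region, with task-locked amplitude responses
    hg = {}
    for r in config.regions:
        h = bandlimited_noise(rng, n, fs, HIGH_GAMMA_BAND)
        mod = np.ones(n)
        for spec in config.gamma_responses:
            if spec.region != r or spec.direction == "none" or spec.magnitude == 0:
                continue
            trial_type = {
                "encoding": "encoding",
                "recall": "recall_vocal_onset",
                "rest": "rest",
            }[spec.condition]
            factor = (
                1 + spec.magnitude if spec.direction == "increase" else 1 - spec.magnitude
            )
            for onset in events.loc[
                events["trial_type"] == trial_type, "onset_s"
            ].to_numpy(float):
                i0 = max(0, int(np.floor((onset + spec.onset) * fs)))
                i1 = min(n, int(np.floor((onset + spec.offset) * fs)))
                mod[i0:i1] = factor
        hg[r] = h * mod

    # contacts: alternating gains + private 1/f noise
    gains = [1.0, 0.4]
    chan_rows = []
    chan_sig = []
    for r in config.regions:
        for p in range(config.probes_per_region):
            group = f"{r}_p{p + 1}"
            for ci in range(config.contacts_per_probe):
                g = gains[ci % 2]
                background = config.noise_amplitude * pink_noise(
                    rng, n, config.noise_exponent
                )
                chan_sig.append(
                    g * (config.osc_amplitude * osc[r] + config.hg_amplitude * hg[r])
                    + background
                )
                chan_rows.append(
                    {"name": f"{r}{p + 1}c{ci + 1}", "group": group, "region": r}
                )
    channels = pd.DataFrame(chan_rows, columns=["name", "group", "region"])
    return RecordingSession(
        signal=np.asarray(chan_sig),
        fs=fs,
        channels=channels,
        events=events,
        subject_id=config.subject_id,
    )


def ground_truth(config: SessionConfig) -> list[dict]:
    """The directed coupling graph as an adjacency list (for validation)."""
    return [
        {
            "source": c.source_region,
            "target": c.target_region,
            "strength": c.strength,
            "lag": c.lag,
        }
        for c in config.couplings
    ]
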