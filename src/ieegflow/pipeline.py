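"""End-to-end orchestration: simulate/load -> preprocess -> power ->
connectivity -> stats -> report.

The stage order mirrors the signal-conditioning chain the analysis assumes
(resample to 500 Hz, bipolar montage, line-noise band-stops, z-scoring,
band filtering, epoching) and is enforced here rather than left to
callers.  A run is fully determined by its config (including the seed):
re-running writes byte-identical CSVs, and the manifest records content
checksums for every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, power, preprocess, stats, synth
from .session import (
    BANDS,
    CHANNEL_COLUMNS,
    EVENT_COLUMNS,
    TARGET_REGIONS,
    RecordingSession,
    load_session,
    save_ground_truth,
    save_session,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; defaults mirror the analysis' printed parameters."""

    input: str = "simulate"  # "simulate" or a directory of .h5 sessions
    output_dir: str = "ieegflow_out"
    seed: int = 0
    n_subjects: int = 4
    task: str = "VFR"
    n_trials: int = 12
    coupling_strength: float = 0.7
    coupling_lag: int = 25
    coupling_band: tuple[float, float] = (8.0, 12.0)
    gamma_suppression_region: str = "PCC"
    gamma_suppression_magnitude: float = 0.3
    target_fs: float = 500.0
    connectivity_band: str = "broadband"
    conditions: tuple[str, ...] = ("encoding", "recall", "rest")
    alpha: float = 0.05
    bf_replicated: float = 3.0
    bf_decisive: float = 100.0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("coupling_band", "conditions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def ai_hub_config(
    seed: int,
    subject_id: str = "S01",
    task: str = "VFR",
    n_trials: int = 12,
    strength: float = 0.7,
    lag: int = 25,
    band: tuple[float, float] = (8.0, 12.0),
    gamma_suppression_region: str | None = "PCC",
    gamma_suppression_magnitude: float = 0.3,
    probes_per_region: int = 1,
) -> synth.SessionConfig:
    """A session where the anterior insula drives all four target nodes."""
    couplings = tuple(
        synth.CouplingSpec("AI", region, strength, lag, band) for region in TARGET_REGIONS
    )
    gamma = ()
    if gamma_suppression_region and gamma_suppression_magnitude > 0:
        from .session import ENCODING_EPOCH_S

        gamma = (
            synth.GammaResponseSpec(
                region=gamma_suppression_region,
                condition="encoding",
                direction="suppress",
                magnitude=gamma_suppression_magnitude,
                onset=0.1,
                offset=ENCODING_EPOCH_S[task],
            ),
        )
    return synth.SessionConfig(
        task=task,
        n_trials=n_trials,
        couplings=couplings,
        gamma_responses=gamma,
        probes_per_region=probes_per_region,
        subject_id=subject_id,
        seed=seed,
    )


def simulate_sessions(config: PipelineConfig) -> list[RecordingSession]:
    """One synthetic session per subject, independently seeded from the run seed."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_subjects)
    sessions = []
    for i, s in enumerate(seeds):
        cfg = ai_hub_config(
            seed=int(s % (2**31)),
            subject_id=f"S{i + 1:02d}",
            task=config.task,
            n_trials=config.n_trials,
            strength=config.coupling_strength,
            lag=config.coupling_lag,
            band=config.coupling_band,
            gamma_suppression_region=config.gamma_suppression_region,
            gamma_suppression_magnitude=config.gamma_suppression_magnitude,
        )
        sessions.append(synth.make_session(cfg))
    return sessions


def preprocess_session(
    session: RecordingSession, target_fs: float = 500.0
) -> RecordingSession:
    """The conditioning chain: resample -> bipolar -> notch -> z-score."""
    s = preprocess.resample_session(session, target_fs=target_fs)
    s = preprocess.bipolar_montage(s)
    s = preprocess.remove_line_noise(s)
    s = preprocess.zscore_channels(s)
    return s


def session_connectivity(
    session: RecordingSession,
    conditions: tuple[str, ...] = ("encoding", "recall", "rest"),
    band_name: str = "broadband",
) -> dict[str, connectivity.PTEResult]:
    """Broadband-filtered PTE between AI and every target-region channel.

    The session must already be preprocessed.  Returns one PTEResult per
    condition (both directions of every AI-target pair).
    """
    filtered = preprocess.bandpass(session, BANDS[band_name])
    pairs = connectivity.region_pairs(filtered.channels, "AI", TARGET_REGIONS)
    out = {}
    for condition in conditions:
        epochs = preprocess.epoch(filtered, condition)
        out[condition] = connectivity.pte_epochs(epochs, pairs)
    return out


def session_power(
    session: RecordingSession,
    conditions: tuple[str, ...] = ("encoding", "rest"),
) -> dict[str, power.PowerTimeSeries]:
    """Baseline-corrected high-gamma power per condition.

    Encoding epochs are padded 0.2 s before stimulus onset and corrected
    against that pre-stimulus baseline; recall (no pre-stimulus exists
    before vocal onset) and rest are corrected against the matched rest
    mean, flagged in the output.
    """
    out: dict[str, power.PowerTimeSeries] = {}
    rest_p = None
    if any(c in conditions for c in ("recall", "rest")):
        rest_epochs = preprocess.epoch(session, "rest")
        rest_p = power.epochs_to_power(rest_epochs)
    for condition in conditions:
        if condition == "encoding":
            ep = preprocess.epoch(session, "encoding", pad_pre_s=0.2)
            out[condition] = power.baseline_correct(power.epochs_to_power(ep))
        elif condition == "recall":
            ep = preprocess.epoch(session, "recall")
            out[condition] = power.baseline_correct(
                power.epochs_to_power(ep), rest=rest_p
            )
        elif condition == "rest":
            out[condition] = power.baseline_correct(rest_p, rest=rest_p)
        else:
            raise ValueError(f"unknown condition {condition!r}")
    return out


def direction_table(
    results: list[connectivity.PTEResult], target_region: str
) -> pd.DataFrame:
    """Observation table contrasting AI->X vs X->AI across subjects.

    One row per (subject, channel pair, direction) with the trial-averaged
    PTE; values are ordered-quantile normalised over the pooled table.
    """
    rows = []
    for res in results:
        t = res.table
        fwd = t[(t["source_region"] == "AI") & (t["target_region"] == target_region)]
        rev = t[(t["source_region"] == target_region) & (t["target_region"] == "AI")]
        for _, r in fwd.iterrows():
            rows.append(
                {
                    "value": r["pte_mean"],
                    "condition": f"AI->{target_region}",
                    "subject": res.subject_id,
                    "pair": f"{r['source_channel']}|{r['target_channel']}",
                    "task": res.task,
                }
            )
        for _, r in rev.iterrows():
            rows.append(
                {
                    "value": r["pte_mean"],
                    "condition": f"{target_region}->AI",
                    "subject": res.subject_id,
                    "pair": f"{r['target_channel']}|{r['source_channel']}",
                    "task": res.task,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["value"] = stats.normalize_orq(table["value"].to_numpy())
    return table


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle.

    Outputs under ``config.output_dir``: per-pair PTE CSV, net-outflow CSV,
    high-gamma power CSV, direction-contrast stats CSV, a JSON manifest
    (seed, config, checksums) and a plain-text summary of the directed-flow
    findings.  Returns a dict of output paths plus in-memory summaries.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.input == "simulate":
            sessions = simulate_sessions(config)
        else:
            paths = sorted(Path(config.input).glob("*.h5"))
            if not paths:
                raise FileNotFoundError(f"no .h5 sessions in {config.input!r}")
            sessions = [load_session(p) for p in paths]

        stage = "preprocess"
        sessions = [preprocess_session(s, config.target_fs) for s in sessions]

        stage = "connectivity"
        per_condition: dict[str, list[connectivity.PTEResult]] = {
            c: [] for c in config.conditions
        }
        pte_frames = []
        outflow_frames = []
        for s in sessions:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = session_connectivity(s, config.conditions, config.connectivity_band)
            for condition, r in res.items():
                per_condition[condition].append(r)
                frame = r.table.copy()
                frame.insert(0, "condition", condition)
                frame.insert(0, "task", r.task)
                frame.insert(0, "subject_id", r.subject_id)
                pte_frames.append(frame)
                flow = connectivity.net_outflow(r, by="region", mode="mean").table
                flow.insert(0, "condition", condition)
                flow.insert(0, "subject_id", r.subject_id)
                outflow_frames.append(flow)

        stage = "power"
        power_frames = []
        for s in sessions:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pw = session_power(s, conditions=("encoding", "rest"))
            for condition, p in pw.items():
                power_frames.append(power.power_long_table(p))

        stage = "stats"
        stat_rows = []
        for condition in config.conditions:
            for region in TARGET_REGIONS:
                table = direction_table(per_condition[condition], region)
                if table.empty:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = stats.condition_contrast(table)
                stat_rows.append(
                    {
                        "condition": condition,
                        "contrast": f"AI->{region} vs {region}->AI",
                        "F": rep.F,
                        "df1": rep.df1,
                        "df2": rep.df2,
                        "p": rep.p,
                        "cohens_d": rep.cohens_d,
                        "direction": rep.direction,
                    }
                )
        stat_table = pd.DataFrame(stat_rows)
        if not stat_table.empty:
            reject, p_adj = stats.fdr_bh(stat_table["p"].to_numpy(), config.alpha)
            stat_table["p_fdr"] = p_adj
            stat_table["significant"] = reject

        stage = "report"
        outputs = {
            "pte": _write_csv(pd.concat(pte_frames, ignore_index=True), out_dir / "pte_pairs.csv"),
            "net_outflow": _write_csv(
                pd.concat(outflow_frames, ignore_index=True), out_dir / "net_outflow.csv"
            ),
            "power": _write_csv(
                pd.concat(power_frames, ignore_index=True), out_dir / "highgamma_power.csv"
            ),
            "stats": _write_csv(stat_table, out_dir / "direction_contrasts.csv"),
        }
        summary = _summary_text(stat_table, outflow_frames)
        (out_dir / "summary.txt").write_text(summary)
        manifest = {
            "seed": config.seed,
            "n_subjects": len(sessions),
            "task": config.task,
            "checksums": {k: _sha256(p) for k, p in outputs.items()},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "outputs": {k: str(p) for k, p in outputs.items()},
        "stats": stat_table,
        "summary": summary,
        "manifest": manifest,
    }


def _summary_text(stat_table: pd.DataFrame, outflow_frames: list[pd.DataFrame]) -> str:
    lines = ["Directed information flow summary", "=" * 34, ""]
    if not stat_table.empty:
        lines.append("Direction-of-flow contrasts (higher direction listed):")
        for _, r in stat_table.iterrows():
            star = " *" if r.get("significant", False) else ""
            lines.append(
                f"  [{r['condition']:>8}] {r['contrast']}: higher = {r['direction']}, "
                f"F(1, {r['df2']}) = {r['F']:.2f}, p = {r['p']:.2g}, "
                f"d = {r['cohens_d']:.2f}{star}"
            )
        lines.append("")
    if outflow_frames:
        flow = pd.concat(outflow_frames, ignore_index=True)
        ranking = (
            flow.groupby("node")["net"].mean().sort_values(ascending=False)
        )
        lines.append("Net outflow ranking (mean across subjects/conditions):")
        for node, val in ranking.items():
            lines.append(f"  {node:>6}: {val:+.4f}")
        lines.append("")
    return "\n".join(lines) + "\n"


def write_simulated_inputs(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Simulate and persist sessions (HDF5 + TSVs + ground-truth JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    sessions = simulate_sessions(config)
    for s in sessions:
        p = save_session(s, out_dir / f"{s.subject_id}.h5")
        paths.append(p)
    gt = ai_hub_config(
        seed=0,
        task=config.task,
        strength=config.coupling_strength,
        lag=config.coupling_lag,
        band=config.coupling_band,
    )
    save_ground_truth(synth.ground_truth(gt), out_dir / "ground_truth.json")
    return paths


def validate_inputs(path: str | Path) -> list[dict]:
    """Check readability, TSV schemas and event/channel integrity.

    Returns a list of findings (empty = all good); never raises on bad
    content, only reports it.
    """
    path = Path(path)
    findings = []
    h5s = sorted(path.glob("*.h5")) if path.is_dir() else [path]
    if not h5s:
        findings.append({"file": str(path), "kind": "missing", "detail": "no .h5 sessions found"})
    for p in h5s:
        try:
            s = load_session(p)
        except Exception as exc:
            findings.append({"file": str(p), "kind": "unreadable", "detail": str(exc)})
            continue
        missing = set(CHANNEL_COLUMNS) - set(s.channels.columns)
        if missing:
            findings.append(
                {"file": str(p), "kind": "schema", "detail": f"channels missing {sorted(missing)}"}
            )
        missing = set(EVENT_COLUMNS) - set(s.events.columns)
        if missing:
            findings.append(
                {"file": str(p), "kind": "schema", "detail": f"events missing {sorted(missing)}"}
            )
            continue
        bad = s.events[
            (s.events["onset_s"] < 0)
            | (s.events["onset_s"] + s.events["duration_s"].fillna(0) > s.duration_s + 1e-9)
        ]
        for _, row in bad.iterrows():
            findings.append(
                {
                    "file": str(p),
                    "kind": "integrity",
                    "detail": f"event at {row['onset_s']} s exceeds recording "
                    f"({s.duration_s:.1f} s)",
                }
            )
    return findings
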