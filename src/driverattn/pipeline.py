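"""End-to-end orchestration: streams → per-trial features → model report.

A run is described by one declarative YAML config; every tolerance and seed
lives there. Sessions are either synthesized (``simulate`` section) or
loaded from CSV files (``sessions`` list). For each unreliable arrow one
:class:`TrialRecord` row is produced — trial count always equals the number
of unreliable events, with per-feature validity flags instead of silent
drops — and the trial table feeds the mixed-model sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior, ecg, eeg, gaze, lme
from .ecg import FeatureMissing
from .simulate import GeneratorConfig, Session, generate_study
from .streams import (
    Window,
    extract_window,
    read_events_csv,
    read_gaze_csv,
    read_responses_csv,
    read_stream_csv,
)

ECG_WINDOW_S = 10.0
EEG_WINDOW_S = 1.0
GAZE_WINDOW_S = 3.0


@dataclass
class FeatureParams:
    """Per-modality extraction settings (windows are fixed by the design)."""

    ecg_fs: float = 250.0
    eeg_fs: float = 500.0
    gaze_fps: float = 120.0
    rt_cap_ms: float = behavior.RT_CAP_MS
    confidence_min: float = 0.8
    min_gaze_samples: int = 10
    amp_limit_uv: float = 100.0
    power_floor: float = 1e-12
    wavelet: str = "sym4"


def extract_features(session: Session, params: Optional[FeatureParams] = None) -> pd.DataFrame:
    """Per-trial feature rows for one session.

    A missing stream leaves that modality's columns NaN for every trial; a
    per-trial extraction failure (too few confident samples, invalid epoch,
    too few beats) leaves NaN for that trial only. ``*_valid`` flags record
    which features were obtained.
    """
    p = params or FeatureParams()
    unrel = [e for e in session.events if e.arrow_type == "unreliable"]

    trials, _counts = behavior.extract_rt(session.events, session.responses, cap=p.rt_cap_ms)
    rt_by_onset = {tr.event.onset: tr for tr in trials}

    peaks = None
    if session.ecg is not None:
        peaks = ecg.detect_r_peaks(session.ecg, wavelet=p.wavelet)
    eeg_filt = None
    if session.eeg is not None:
        eeg_filt = eeg.filter_eeg(session.eeg)

    rows = []
    for e in unrel:
        row: Dict = dict(
            participant=session.participant,
            period=e.period,
            trial=e.trial_index,
            onset=e.onset,
            outcome=e.outcome,
            alpha_db=np.nan, mean_rr=np.nan, rmssd=np.nan,
            ln_x=np.nan, ln_y=np.nan, rt=np.nan,
        )
        if peaks is not None:
            try:
                m = ecg.hrv_metrics(peaks, Window(e.onset - ECG_WINDOW_S, e.onset))
                row["mean_rr"], row["rmssd"] = m.mean_rr, m.rmssd
            except FeatureMissing:
                pass
        if eeg_filt is not None:
            epochs = eeg.epoch_prestimulus(eeg_filt, [e.onset], duration=EEG_WINDOW_S)
            eeg.screen_artifacts(epochs, amp_limit_uv=p.amp_limit_uv)
            try:
                row["alpha_db"] = eeg.alpha_power_db(epochs[0], power_floor=p.power_floor)
            except FeatureMissing:
                pass
        if session.gaze_x is not None and session.gaze_y is not None:
            try:
                win = Window(e.onset - GAZE_WINDOW_S, e.onset)
                d = gaze.gaze_dispersion(
                    extract_window(session.gaze_x, win),
                    extract_window(session.gaze_y, win),
                    confidence_min=p.confidence_min,
                    min_samples=p.min_gaze_samples,
                )
                row["ln_x"], row["ln_y"] = d.ln_x, d.ln_y
            except (FeatureMissing, ValueError):
                pass
        tr = rt_by_onset.get(e.onset)
        if tr is not None and tr.rt_ms is not None:
            row["rt"] = tr.rt_ms
        for name in ("alpha_db", "mean_rr", "rmssd", "ln_x", "rt"):
            row[f"{name}_valid"] = bool(np.isfinite(row[name]))
        rows.append(row)
    return pd.DataFrame(rows)


def build_trial_table(
    sessions: Sequence[Session], params: Optional[FeatureParams] = None
) -> pd.DataFrame:
    frames = [extract_features(s, params) for s in sessions]
    return pd.concat(frames, ignore_index=True)


def behavioral_report(sessions: Sequence[Session], cap: float = behavior.RT_CAP_MS) -> dict:
    """Per-participant, per-period detection performance (H, F, A, accuracy)."""
    out = {}
    a_vals, mean_rts = [], []
    for s in sessions:
        trials, counts = behavior.extract_rt(s.events, s.responses, cap=cap)
        perf = behavior.period_performance(trials, counts)
        out[s.participant] = perf
        rts = [tr.rt_ms for tr in trials if tr.rt_ms is not None]
        h = sum(c.hits for c in counts)
        m = sum(c.misses for c in counts)
        fa = sum(c.false_alarms for c in counts)
        cr = sum(c.correct_rejections for c in counts)
        if h + m and fa + cr and rts:
            a_vals.append(behavior.a_sensitivity(h / (h + m), fa / (fa + cr)).a_value)
            mean_rts.append(float(np.mean(rts)))
    report = dict(per_participant=out)
    if len(a_vals) >= 3:
        report["speed_accuracy_r"] = behavior.speed_accuracy_correlation(a_vals, mean_rts)
    return report


# ---------------------------------------------------------------------------
# config handling

def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def sessions_from_config(cfg: dict):
    """Build sessions either synthetically or from the listed CSV files."""
    params = FeatureParams(**cfg.get("features", {}))
    if "simulate" in cfg:
        gen_kwargs = dict(cfg["simulate"] or {})
        if "seed" not in gen_kwargs and "seed" in cfg:
            gen_kwargs["seed"] = int(cfg["seed"])
        if "outcome_split" in gen_kwargs:
            gen_kwargs["outcome_split"] = tuple(gen_kwargs["outcome_split"])
        gcfg = GeneratorConfig(**gen_kwargs)
        sessions, gt = generate_study(gcfg)
        return sessions, gt, params
    if "sessions" not in cfg:
        raise ValueError("config needs a 'simulate' section or a 'sessions' list")
    sessions = []
    for entry in cfg["sessions"]:
        sessions.append(load_session(entry, params))
    return sessions, None, params


def load_session(entry: dict, params: FeatureParams) -> Session:
    """One session from CSV files; missing stream files leave the modality out."""
    events = read_events_csv(entry["events"])
    responses = read_responses_csv(entry["responses"])
    s = Session(str(entry.get("participant", "P01")), events, responses)
    if entry.get("ecg"):
        s.ecg = read_stream_csv(entry["ecg"], "ecg", params.ecg_fs, units="mV")
    if entry.get("eeg"):
        s.eeg = read_stream_csv(entry["eeg"], "Pz", params.eeg_fs, units="uV")
    if entry.get("gaze"):
        s.gaze_x, s.gaze_y = read_gaze_csv(entry["gaze"], params.gaze_fps)
    return s


def run_pipeline(config, out_dir: Optional[Path] = None):
    """Full run: build sessions, extract features, fit the model sequence.

    Returns (trial table, report dict); when ``out_dir`` is given, writes
    ``trials.csv`` and ``model_report.json``. Identical config + seed gives
    identical outputs.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    sessions, _gt, params = sessions_from_config(cfg)
    table = build_trial_table(sessions, params)
    report = dict(behavior=behavioral_report(sessions, cap=params.rt_cap_ms))
    model_cfg = cfg.get("model", {})
    if model_cfg.get("enabled", True):
        try:
            report["model_search"] = lme.model_search(
                table, drop_ln_x=model_cfg.get("drop_ln_x")
            )
        except ValueError as exc:
            report["model_search"] = dict(error=str(exc))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "trials.csv", index=False)
        with open(out_dir / "model_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return table, report
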