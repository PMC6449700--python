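"""Synthetic multimodal driving-session generator with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: arrow schedules (50 arrows per 10-min period, 20% unreliable with a
6/2/2 failure-outcome split, ~13 s mean spacing with ±2 s jitter rescaled to
the period), an RR-interval series with configurable mean and RMSSD, EEG as
1/f background plus a 10-Hz alpha burst of per-trial latent amplitude in each
1-s pre-stimulus window, 2-D gaze scatter with confidence dropout, and
reaction times drawn from a linear model with crossed participant/trial
random intercepts coupled to the latent features.

Every latent quantity is recorded in :class:`GroundTruth` so that feature
extraction and model fitting can be validated by recovery rather than by
reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .streams import Event, ResponseLog, SignalStream, validate_events

#: latent feature names usable in ``beta_vector`` terms (":"-joined for
#: interactions); "period" is the centered time-period covariate.
LATENT_NAMES = ("alpha", "mean_rr", "rmssd", "ln_x", "period")

OUTCOME_KEYS = {"no_change": "N", "incorrect_change": "I", "correct_change": "C"}


@dataclass
class GeneratorConfig:
    """Study-condition parameters for synthetic sessions.

    RT fixed effects (``beta_vector``) are in ms per standard deviation of
    the (standardized) latent feature; the time-period covariate enters
    centered, in ms per period step. Interaction terms are written as
    ":"-joined latent names, e.g. ``"alpha:rmssd"``.
    """

    n_participants: int = 25
    n_periods: int = 5
    period_duration: float = 600.0  # s
    arrows_per_period: int = 50
    mean_iei: float = 13.0  # s
    iei_jitter: float = 2.0  # s
    p_unreliable: float = 0.2
    outcome_split: Tuple[int, int, int] = (6, 2, 2)  # no / incorrect / correct

    # cardiac
    rr_mean: float = 800.0  # ms
    rr_rmssd_target: float = 35.0  # ms
    rr_mean_latent_scale: float = 0.04  # relative meanRR shift per SD of latent
    rr_rmssd_latent_scale: float = 0.3  # log-RMSSD shift per SD of latent
    ecg_fs: float = 250.0  # Hz
    r_amplitude: float = 1.0  # mV
    t_amplitude_frac: float = 0.3
    ecg_noise_sd: float = 0.05  # mV

    # EEG
    eeg_fs: float = 500.0  # Hz
    alpha_mean_uv: float = 8.0  # µV, geometric-mean 10-Hz burst amplitude
    alpha_log_sd: float = 0.5  # log-amplitude spread per SD of latent
    eeg_noise_sd: float = 10.0  # µV broadband background
    eeg_noise_exponent: float = 1.0  # 1/f slope

    # gaze
    gaze_fps: float = 120.0
    gaze_sigma_x: float = 50.0  # px
    gaze_sigma_y: float = 40.0  # px
    gaze_lnx_latent_scale: float = 0.3  # log-sigma shift per SD of latent
    p_low_confidence: float = 0.1
    screen_center: Tuple[float, float] = (960.0, 600.0)

    # reaction-time model
    beta_vector: Dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 900.0,
            "alpha": 40.0,
            "rmssd": -30.0,
            "period": 60.0,
            "alpha:rmssd": -40.0,
        }
    )
    sd_participant: float = 100.0  # ms
    sd_trial: float = 30.0  # ms
    sd_resid: float = 150.0  # ms
    rt_floor: float = 150.0  # ms
    miss_rate: float = 0.02
    false_alarm_rate: float = 0.01
    p_second_correct: float = 0.95

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_unreliable", "p_low_confidence", "miss_rate",
                     "false_alarm_rate", "p_second_correct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("period_duration", "mean_iei", "rr_mean", "ecg_fs",
                     "eeg_fs", "gaze_fps", "sd_resid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("iei_jitter", "rr_rmssd_target", "sd_participant",
                     "sd_trial", "gaze_sigma_x", "gaze_sigma_y",
                     "ecg_noise_sd", "eeg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_unreliable_per_period != sum(self.outcome_split):
            raise ValueError(
                "outcome_split must sum to round(p_unreliable * arrows_per_period) "
                f"= {self.n_unreliable_per_period}, got {sum(self.outcome_split)}"
            )
        for term in self.beta_vector:
            if term == "intercept":
                continue
            for part in term.split(":"):
                if part not in LATENT_NAMES:
                    raise ValueError(f"unknown latent {part!r} in beta term {term!r}")

    @property
    def n_unreliable_per_period(self) -> int:
        return int(round(self.p_unreliable * self.arrows_per_period))

    @property
    def session_duration(self) -> float:
        return self.n_periods * self.period_duration


@dataclass
class GroundTruth:
    """Per-trial latents and random effects behind one generated study."""

    trials: "object"  # pandas.DataFrame, one row per unreliable event
    participant_intercepts: Dict[str, float]
    trial_intercepts: np.ndarray  # indexed by trial_index - 1
    r_peak_times: Dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Session:
    """One participant's streams plus event and response logs."""

    participant: str
    events: List[Event]
    responses: ResponseLog
    ecg: Optional[SignalStream] = None
    eeg: Optional[SignalStream] = None
    gaze_x: Optional[SignalStream] = None
    gaze_y: Optional[SignalStream] = None


# ---------------------------------------------------------------------------
# event schedule

def generate_event_schedule(config: GeneratorConfig, rng: np.random.Generator) -> List[Event]:
    """Arrow schedule for one full session (all periods, session clock).

    Per period exactly ``arrows_per_period`` arrows are placed; the arrow
    *count* takes precedence over the nominal 13-s spacing, so jittered
    inter-event intervals are rescaled to fit the period duration.
    """
    end_margin = 3.0  # s kept free after the last arrow for responses
    if config.period_duration - end_margin < config.arrows_per_period * 1.0:
        raise ValueError(
            f"period_duration {config.period_duration} s too short for "
            f"{config.arrows_per_period} arrows"
        )
    n_unrel = config.n_unreliable_per_period
    events: List[Event] = []
    for period in range(1, config.n_periods + 1):
        t0 = (period - 1) * config.period_duration
        ieis = rng.uniform(
            config.mean_iei - config.iei_jitter,
            config.mean_iei + config.iei_jitter,
            size=config.arrows_per_period,
        )
        onsets = np.cumsum(ieis)
        onsets *= (config.period_duration - end_margin) / onsets[-1]
        unrel_pos = np.sort(
            rng.choice(config.arrows_per_period, size=n_unrel, replace=False)
        )
        outcomes = np.repeat(
            ["no_change", "incorrect_change", "correct_change"], config.outcome_split
        )
        rng.shuffle(outcomes)
        trial_counter = 0
        unrel_set = set(int(i) for i in unrel_pos)
        for i, onset in enumerate(onsets):
            if i in unrel_set:
                trial_counter += 1
                events.append(
                    Event(
                        onset=t0 + float(onset),
                        arrow_type="unreliable",
                        outcome=str(outcomes[trial_counter - 1]),
                        period=period,
                        trial_index=trial_counter,
                    )
                )
            else:
                events.append(
                    Event(
                        onset=t0 + float(onset),
                        arrow_type="reliable",
                        outcome="normal",
                        period=period,
                    )
                )
    validate_events(events)
    return events


# ---------------------------------------------------------------------------
# cardiac

def generate_rr_series(
    mean_rr: float,
    rmssd_target: float,
    n_beats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """I.i.d. Gaussian RR intervals (ms) whose expected RMSSD is the target.

    Successive differences of i.i.d. intervals with standard deviation σ have
    variance 2σ², so σ = rmssd_target/√2. Non-positive draws are resampled;
    a configuration where more than 1% of draws would be non-positive is
    rejected as physiologically meaningless.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if rmssd_target < 0:
        raise ValueError("rmssd_target must be non-negative")
    if n_beats < 2:
        raise ValueError("need at least 2 beats for one interval")
    n_intervals = n_beats - 1
    sigma = rmssd_target / np.sqrt(2.0)
    if sigma > 0 and stats.norm.cdf(0.0, loc=mean_rr, scale=sigma) > 0.01:
        raise ValueError(
            f"rmssd_target {rmssd_target} ms is unrealistically large for "
            f"mean_rr {mean_rr} ms (>1% non-positive intervals)"
        )
    intervals = mean_rr + sigma * rng.standard_normal(n_intervals)
    bad = intervals <= 0
    while np.any(bad):
        intervals[bad] = mean_rr + sigma * rng.standard_normal(int(bad.sum()))
        bad = intervals <= 0
    return intervals


def _qrs_template(fs: float, width_s: float = 0.08) -> Tuple[np.ndarray, int]:
    """Stereotyped biphasic QRS pulse (Mexican-hat), unit peak at its center."""
    a = width_s / 5.0  # characteristic scale; support ~ ±2.5 a
    half = int(round(2.5 * a * fs)) + 1
    t = np.arange(-half, half + 1) / fs
    tpl = (1.0 - (t / a) ** 2) * np.exp(-(t ** 2) / (2 * a ** 2))
    return tpl, half


def synthesize_ecg(
    rr_intervals_ms: Sequence[float],
    fs: float,
    rng: np.random.Generator,
    r_amplitude: float = 1.0,
    t_amplitude_frac: float = 0.3,
    noise_sd: float = 0.0,
    start_time: float = 0.0,
    first_beat_offset: float = 0.5,
    tail: float = 1.0,
) -> Tuple[SignalStream, np.ndarray]:
    """ECG waveform (mV) from an RR series; returns (stream, true R times)."""
    if fs < 100:
        raise ValueError("ECG sampling rate must be at least 100 Hz")
    rr = np.asarray(rr_intervals_ms, dtype=float) / 1000.0
    beat_times = start_time + first_beat_offset + np.concatenate([[0.0], np.cumsum(rr)])
    duration = (beat_times[-1] - start_time) + tail
    n = int(round(duration * fs))
    x = np.zeros(n)
    qrs, half = _qrs_template(fs)
    t_half = int(round(0.125 * fs))
    tt = np.arange(-t_half, t_half + 1) / fs
    t_wave = np.exp(-(tt ** 2) / (2 * 0.05 ** 2))
    for bt in beat_times:
        idx = int(round((bt - start_time) * fs))
        _add_at(x, r_amplitude * qrs, idx - half)
        _add_at(x, r_amplitude * t_amplitude_frac * t_wave, idx + int(round(0.30 * fs)) - t_half)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    stream = SignalStream("ecg", fs, start_time, x, units="mV")
    return stream, beat_times


def _add_at(x: np.ndarray, tpl: np.ndarray, start: int) -> None:
    lo = max(start, 0)
    hi = min(start + tpl.size, x.size)
    if hi > lo:
        x[lo:hi] += tpl[lo - start: hi - start]


# ---------------------------------------------------------------------------
# EEG

def one_over_f_noise(
    n: int, fs: float, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian background with ~1/f^exponent power spectrum, given total SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def synthesize_eeg(
    events: Sequence[Event],
    alpha_amp_uv: Sequence[float],
    fs: float,
    duration: float,
    rng: np.random.Generator,
    noise_sd: float = 10.0,
    noise_exponent: float = 1.0,
    alpha_freq: float = 10.0,
    ramp: float = 0.1,
    start_time: float = 0.0,
    channel_id: str = "Pz",
) -> SignalStream:
    """Single-channel EEG: 1/f background plus per-trial pre-stimulus alpha.

    Within each unreliable event's ``[onset-1 s, onset)`` window a 10-Hz
    sinusoid of that trial's latent amplitude is added, with raised-cosine
    on/off ramps of ``ramp`` seconds lying *outside* the window.
    """
    unrel = [e for e in events if e.arrow_type == "unreliable"]
    if len(unrel) != len(alpha_amp_uv):
        raise ValueError("need one alpha amplitude per unreliable event")
    n = int(round(duration * fs))
    x = one_over_f_noise(n, fs, noise_exponent, noise_sd, rng)
    t = start_time + np.arange(n) / fs
    envelope = np.zeros(n)
    for e, amp in zip(unrel, alpha_amp_uv):
        rise0, rise1 = e.onset - 1.0 - ramp, e.onset - 1.0
        fall0, fall1 = e.onset, e.onset + ramp
        seg = (t >= rise0) & (t < fall1)
        ts = t[seg]
        env = np.ones_like(ts)
        rising = ts < rise1
        env[rising] = 0.5 * (1 - np.cos(np.pi * (ts[rising] - rise0) / ramp))
        falling = ts >= fall0
        env[falling] = 0.5 * (1 + np.cos(np.pi * (ts[falling] - fall0) / ramp))
        envelope[seg] = np.maximum(envelope[seg], amp * env)
    phase = rng.uniform(0, 2 * np.pi)
    x = x + envelope * np.sin(2 * np.pi * alpha_freq * (t - start_time) + phase)
    return SignalStream(channel_id, fs, start_time, x, units="uV")


# ---------------------------------------------------------------------------
# gaze

def synthesize_gaze(
    duration: float,
    sigma_x: float,
    sigma_y: float,
    rng: np.random.Generator,
    fps: float = 120.0,
    p_low_confidence: float = 0.0,
    center: Tuple[float, float] = (960.0, 600.0),
    start_time: float = 0.0,
    sigma_x_t: Optional[np.ndarray] = None,
    sigma_y_t: Optional[np.ndarray] = None,
) -> Tuple[SignalStream, SignalStream]:
    """I.i.d. Gaussian gaze scatter about screen center with dropout.

    ``sigma_x_t``/``sigma_y_t`` optionally give per-sample dispersions
    (used to plant trial-specific gaze narrowing); otherwise the scalar
    sigmas apply throughout. A fraction ``p_low_confidence`` of samples
    receives confidence below 0.8, the rest in [0.8, 1].
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    n = int(round(duration * fps))
    sx = sigma_x_t if sigma_x_t is not None else np.full(n, sigma_x)
    sy = sigma_y_t if sigma_y_t is not None else np.full(n, sigma_y)
    x = center[0] + sx * rng.standard_normal(n)
    y = center[1] + sy * rng.standard_normal(n)
    low = rng.random(n) < p_low_confidence
    conf = rng.uniform(0.8, 1.0, size=n)
    conf[low] = rng.uniform(0.0, 0.8, size=int(low.sum()))
    gx = SignalStream("gaze_x", fps, start_time, x, units="px", confidence=conf)
    gy = SignalStream("gaze_y", fps, start_time, y, units="px", confidence=conf.copy())
    return gx, gy


# ---------------------------------------------------------------------------
# reaction times and responses

def period_centered(period: np.ndarray, n_periods: int) -> np.ndarray:
    return np.asarray(period, dtype=float) - (n_periods + 1) / 2.0


def linear_predictor(
    beta: Dict[str, float], latents: Dict[str, np.ndarray]
) -> np.ndarray:
    """Fixed-effect RT predictor: intercept + Σ β_term · Π latent components."""
    n = len(next(iter(latents.values())))
    lp = np.full(n, float(beta.get("intercept", 0.0)))
    for term, coef in beta.items():
        if term == "intercept" or coef == 0.0:
            continue
        prod = np.ones(n)
        for part in term.split(":"):
            prod = prod * latents[part]
        lp += coef * prod
    return lp


def generate_responses(
    events: Sequence[Event],
    rts_ms: Sequence[Optional[float]],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> ResponseLog:
    """Button presses implied by per-trial RTs (None = miss).

    Each detected unreliable arrow gets a `U` press at onset + RT and a
    second press reporting the lane-change outcome with configured accuracy;
    reliable arrows draw false-alarm `U` presses at the configured rate.
    """
    unrel = [e for e in events if e.arrow_type == "unreliable"]
    if len(unrel) != len(rts_ms):
        raise ValueError("need one RT entry per unreliable event")
    presses = []
    for e, rt in zip(unrel, rts_ms):
        if rt is None:
            continue
        t_u = e.onset + rt / 1000.0
        presses.append((t_u, "U"))
        correct_key = OUTCOME_KEYS[e.outcome]
        if rng.random() < config.p_second_correct:
            key = correct_key
        else:
            key = rng.choice([k for k in "NIC" if k != correct_key])
        presses.append((t_u + 0.4 + 0.2 * rng.random(), str(key)))
    for e in events:
        if e.arrow_type == "reliable" and rng.random() < config.false_alarm_rate:
            presses.append((e.onset + rng.uniform(0.3, 1.0), "U"))
    presses.sort(key=lambda p: p[0])
    return ResponseLog(presses)


# ---------------------------------------------------------------------------
# study-level generation

def _draw_latents(n: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    return {name: rng.standard_normal(n) for name in ("alpha", "mean_rr", "rmssd", "ln_x")}


def generate_trial_table(config: GeneratorConfig, rng: Optional[np.random.Generator] = None):
    """Latent-level study: per-trial features and RTs without signal synthesis.

    Returns (DataFrame, GroundTruth). The feature columns carry the latent
    standardized values directly (the model stage re-standardizes, so only
    their ordering and correlation structure matter); RT is in ms. This is
    the path used for model-recovery and calibration simulations, where
    thousands of mixed-model fits would make waveform synthesis pointless.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_unrel = config.n_unreliable_per_period
    v_trial = config.sd_trial * rng.standard_normal(n_unrel)
    rows = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        u = config.sd_participant * rng.standard_normal()
        n_tr = config.n_periods * n_unrel
        lat = _draw_latents(n_tr, rng)
        period = np.repeat(np.arange(1, config.n_periods + 1), n_unrel)
        trial = np.tile(np.arange(1, n_unrel + 1), config.n_periods)
        lat["period"] = period_centered(period, config.n_periods)
        lp = linear_predictor(config.beta_vector, lat)
        rt = lp + u + v_trial[trial - 1] + config.sd_resid * rng.standard_normal(n_tr)
        rt = np.maximum(rt, config.rt_floor)
        missed = rng.random(n_tr) < config.miss_rate
        for i in range(n_tr):
            rows.append(
                dict(
                    participant=pid,
                    period=int(period[i]),
                    trial=int(trial[i]),
                    alpha_db=lat["alpha"][i],
                    mean_rr=lat["mean_rr"][i],
                    rmssd=lat["rmssd"][i],
                    ln_x=lat["ln_x"][i],
                    ln_y=np.nan,
                    rt=(np.nan if missed[i] else rt[i]),
                    linpred=lp[i],
                    u_participant=u,
                )
            )
    df = pd.DataFrame(rows)
    gt = GroundTruth(
        trials=df.copy(),
        participant_intercepts={},
        trial_intercepts=v_trial,
    )
    return df, gt


def generate_study(config: GeneratorConfig):
    """Full signal-level study: one :class:`Session` per participant.

    Returns (sessions, GroundTruth). All randomness flows from a single
    generator seeded by ``config.seed``, so a fixed config is reproducible.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    n_unrel = config.n_unreliable_per_period
    v_trial = config.sd_trial * rng.standard_normal(n_unrel)
    sessions: List[Session] = []
    rows = []
    peak_times: Dict[str, np.ndarray] = {}
    u_by_pid: Dict[str, float] = {}
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        u = config.sd_participant * rng.standard_normal()
        u_by_pid[pid] = u
        events = generate_event_schedule(config, rng)
        unrel = [e for e in events if e.arrow_type == "unreliable"]
        n_tr = len(unrel)
        lat = _draw_latents(n_tr, rng)
        period = np.array([e.period for e in unrel])
        trial = np.array([e.trial_index for e in unrel])
        lat["period"] = period_centered(period, config.n_periods)
        lp = linear_predictor(config.beta_vector, lat)
        rt = lp + u + v_trial[trial - 1] + config.sd_resid * rng.standard_normal(n_tr)
        rt = np.maximum(rt, config.rt_floor)
        missed = rng.random(n_tr) < config.miss_rate

        # physical per-trial parameters tied to the latents
        alpha_amp = config.alpha_mean_uv * np.exp(config.alpha_log_sd * lat["alpha"])
        trial_mean_rr = config.rr_mean * (1.0 + config.rr_mean_latent_scale * lat["mean_rr"])
        trial_rmssd = config.rr_rmssd_target * np.exp(
            config.rr_rmssd_latent_scale * lat["rmssd"]
        )
        sig_x = config.gaze_sigma_x * np.exp(config.gaze_lnx_latent_scale * lat["ln_x"])
        sig_y = np.full(n_tr, config.gaze_sigma_y)

        duration = config.session_duration
        ecg, peaks = _session_ecg(config, unrel, trial_mean_rr, trial_rmssd, duration, rng)
        peak_times[pid] = peaks
        eeg = synthesize_eeg(
            events, alpha_amp, config.eeg_fs, duration, rng,
            noise_sd=config.eeg_noise_sd, noise_exponent=config.eeg_noise_exponent,
        )
        gx, gy = _session_gaze(config, unrel, sig_x, sig_y, duration, rng)
        responses = generate_responses(
            events, [None if m else r for m, r in zip(missed, rt)], config, rng
        )
        sessions.append(Session(pid, events, responses, ecg=ecg, eeg=eeg, gaze_x=gx, gaze_y=gy))
        for i in range(n_tr):
            rows.append(
                dict(
                    participant=pid,
                    period=int(period[i]),
                    trial=int(trial[i]),
                    z_alpha=lat["alpha"][i],
                    z_mean_rr=lat["mean_rr"][i],
                    z_rmssd=lat["rmssd"][i],
                    z_ln_x=lat["ln_x"][i],
                    alpha_amp_uv=alpha_amp[i],
                    trial_mean_rr=trial_mean_rr[i],
                    trial_rmssd=trial_rmssd[i],
                    sigma_x=sig_x[i],
                    sigma_y=sig_y[i],
                    linpred=lp[i],
                    rt=(np.nan if missed[i] else rt[i]),
                    missed=bool(missed[i]),
                )
            )
    gt = GroundTruth(
        trials=pd.DataFrame(rows),
        participant_intercepts=u_by_pid,
        trial_intercepts=v_trial,
        r_peak_times=peak_times,
    )
    return sessions, gt


def _session_ecg(config, unrel_events, trial_mean_rr, trial_rmssd, duration, rng):
    """Session-long ECG whose RR statistics inside each 10-s pre-stimulus
    window follow that trial's latent meanRR/RMSSD; baseline elsewhere."""
    windows = [
        (e.onset - 10.0, e.onset, i) for i, e in enumerate(unrel_events)
    ]
    windows.sort()
    rr_list = []
    t = 0.0
    wi = 0
    while t < duration - 1.0:
        while wi < len(windows) and t >= windows[wi][1]:
            wi += 1
        if wi < len(windows) and windows[wi][0] <= t < windows[wi][1]:
            k = windows[wi][2]
            mean, rmssd = trial_mean_rr[k], trial_rmssd[k]
        else:
            mean, rmssd = config.rr_mean, config.rr_rmssd_target
        sigma = rmssd / np.sqrt(2.0)
        iv = mean + sigma * rng.standard_normal()
        while iv <= 0:
            iv = mean + sigma * rng.standard_normal()
        rr_list.append(iv)
        t += iv / 1000.0
    return synthesize_ecg(
        np.array(rr_list), config.ecg_fs, rng,
        r_amplitude=config.r_amplitude,
        t_amplitude_frac=config.t_amplitude_frac,
        noise_sd=config.ecg_noise_sd,
        first_beat_offset=0.3,
        tail=0.5,
    )


def _session_gaze(config, unrel_events, sig_x, sig_y, duration, rng):
    n = int(round(duration * config.gaze_fps))
    t = np.arange(n) / config.gaze_fps
    sx = np.full(n, config.gaze_sigma_x)
    sy = np.full(n, config.gaze_sigma_y)
    for i, e in enumerate(unrel_events):
        seg = (t >= e.onset - 3.0) & (t < e.onset)
        sx[seg] = sig_x[i]
        sy[seg] = sig_y[i]
    return synthesize_gaze(
        duration, config.gaze_sigma_x, config.gaze_sigma_y, rng,
        fps=config.gaze_fps, p_low_confidence=config.p_low_confidence,
        center=config.screen_center, sigma_x_t=sx, sigma_y_t=sy,
    )
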