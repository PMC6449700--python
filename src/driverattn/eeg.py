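"""EEG preprocessing and pre-stimulus alpha power.

The continuous record is band-limited with zero-phase FIR filters (1 Hz
high-pass with 2 Hz transition band, 40 Hz low-pass with 10 Hz transition
band), optionally re-referenced to the mastoid average, epoched to 1-s
pre-stimulus windows, artifact-screened (±100 µV samples; channels beyond
±2 SD of the across-channel amplitude distribution are flagged), and each
valid epoch is linearly detrended and transformed with a Hamming-windowed
periodogram. Alpha power is 10·log10(power) at the frequency bin nearest
10 Hz — with a 1-s epoch at 500 Hz and nfft = 512 that bin sits at
5000/512 = 9.7656… Hz, i.e. the 9.76-Hz bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal

from .ecg import FeatureMissing
from .streams import SignalStream, Window, extract_window


@dataclass
class Epoch:
    """One 1-s pre-stimulus EEG segment with a validity flag."""

    channel_id: str
    samples: np.ndarray
    sampling_rate: float
    window: Window
    valid: bool = True
    reason: str = ""


@dataclass
class Spectrum:
    frequencies: np.ndarray
    power_db: np.ndarray
    nfft: int


def design_fir(
    fs: float,
    cutoff: float,
    transition: float,
    kind: str,
    window: str = "hamming",
) -> np.ndarray:
    """Windowed-sinc FIR with −6 dB point at ``cutoff``.

    Filter length follows the usual Hamming-window rule of thumb
    (≈3.3 / transition bandwidth), forced odd so the filter has integer
    group delay and can be applied with zero phase.
    """
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd
    return signal.firwin(numtaps, cutoff, window=window, pass_zero=(kind == "lowpass"), fs=fs)


def filter_eeg(
    stream: SignalStream,
    highpass: Tuple[float, float] = (1.0, 2.0),
    lowpass: Tuple[float, float] = (40.0, 10.0),
) -> SignalStream:
    """Zero-phase band-limiting of the continuous record before epoching.

    Each (cutoff, transition) pair designs a linear-phase FIR applied by
    centered convolution, so pre-stimulus timing is not shifted. Output
    length equals input length.
    """
    if stream.sampling_rate < 100:
        raise ValueError("EEG sampling rate must be at least 100 Hz")
    x = stream.samples
    for (cutoff, transition), kind in ((highpass, "highpass"), (lowpass, "lowpass")):
        h = design_fir(stream.sampling_rate, cutoff, transition, kind)
        if h.size > x.size:
            raise ValueError(
                f"record of {x.size} samples shorter than {kind} filter ({h.size} taps)"
            )
        x = _zero_phase(x, h)
    from dataclasses import replace

    return replace(stream, samples=x)


def _zero_phase(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Centered convolution with an odd, symmetric FIR: zero net delay."""
    half = h.size // 2
    padded = np.pad(x, half, mode="reflect")
    return signal.fftconvolve(padded, h, mode="same")[half:-half]


def rereference(
    channels: Dict[str, SignalStream], ref_ids: Tuple[str, str] = ("A1", "A2")
) -> Dict[str, SignalStream]:
    """Subtract the mastoid-average reference from every data channel."""
    from dataclasses import replace

    for r in ref_ids:
        if r not in channels:
            raise KeyError(f"reference channel {r!r} missing")
    ref = 0.5 * (channels[ref_ids[0]].samples + channels[ref_ids[1]].samples)
    out = {}
    for cid, ch in channels.items():
        if cid in ref_ids:
            continue
        if ch.samples.shape != ref.shape:
            raise ValueError(f"channel {cid!r} length differs from references")
        out[cid] = replace(ch, samples=ch.samples - ref)
    return out


def epoch_prestimulus(
    stream: SignalStream, onsets: Sequence[float], duration: float = 1.0
) -> List[Epoch]:
    """Cut ``[onset - duration, onset)`` epochs from a continuous stream."""
    epochs = []
    for onset in onsets:
        win = Window(onset - duration, onset)
        try:
            seg = extract_window(stream, win)
        except ValueError:
            epochs.append(
                Epoch(stream.channel_id, np.array([]), stream.sampling_rate, win,
                      valid=False, reason="no samples in window")
            )
            continue
        epochs.append(Epoch(stream.channel_id, seg.samples, seg.sampling_rate, win))
    return epochs


def screen_artifacts(
    epochs: List[Epoch],
    channel_amplitudes: Dict[str, float] | None = None,
    amp_limit_uv: float = 100.0,
    channel_sd_limit: float = 2.0,
) -> Tuple[List[Epoch], List[str]]:
    """Apply the ±100 µV sample rule and the ±2 SD bad-channel rule.

    Epochs containing any sample beyond ``±amp_limit_uv`` are marked
    invalid. ``channel_amplitudes`` maps channel id to a record-level
    amplitude summary (e.g. the channel's standard deviation over the
    record); channels whose summary lies beyond ``channel_sd_limit``
    standard deviations of the across-channel distribution are returned as
    flagged (flagging only — interpolation is out of scope here).
    """
    for ep in epochs:
        if ep.valid and ep.samples.size and np.max(np.abs(ep.samples)) > amp_limit_uv:
            ep.valid = False
            ep.reason = f"sample exceeds +/-{amp_limit_uv} uV"
    bad_channels: List[str] = []
    if channel_amplitudes and len(channel_amplitudes) >= 3:
        ids = list(channel_amplitudes)
        vals = np.array([channel_amplitudes[c] for c in ids], dtype=float)
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd > 0:
            z = (vals - mu) / sd
            bad_channels = [c for c, zz in zip(ids, z) if abs(zz) > channel_sd_limit]
    for ep in epochs:
        if ep.valid and ep.channel_id in bad_channels:
            ep.valid = False
            ep.reason = "channel flagged artifactual (+/-2 SD rule)"
    return epochs, bad_channels


def power_spectrum(
    samples: np.ndarray,
    fs: float,
    nfft: int | None = None,
    power_floor: float = 1e-12,
) -> Spectrum:
    """Hamming-windowed PSD of one detrended epoch, in dB.

    ``nfft`` defaults to the next power of two at or above the epoch length
    (512 for a 1-s epoch at 500 Hz). With a single segment equal to the
    epoch this Welch call reduces to one windowed periodogram.
    """
    n = samples.size
    if nfft is None:
        nfft = 1 << int(np.ceil(np.log2(max(n, 2))))
    freqs, pxx = signal.welch(
        samples,
        fs=fs,
        window="hamming",
        nperseg=n,
        noverlap=0,
        nfft=nfft,
        detrend="linear",
    )
    power_db = 10.0 * np.log10(np.maximum(pxx, power_floor))
    return Spectrum(frequencies=freqs, power_db=power_db, nfft=nfft)


def alpha_bin(frequencies: np.ndarray, target_hz: float = 10.0) -> int:
    return int(np.argmin(np.abs(np.asarray(frequencies) - target_hz)))


def alpha_power_db(
    epoch: Epoch,
    target_hz: float = 10.0,
    nfft: int | None = None,
    power_floor: float = 1e-12,
) -> float:
    """Pre-stimulus alpha power: dB value at the bin nearest ``target_hz``."""
    if not epoch.valid:
        raise FeatureMissing(f"invalid epoch: {epoch.reason}")
    spec = power_spectrum(epoch.samples, epoch.sampling_rate, nfft=nfft,
                          power_floor=power_floor)
    return float(spec.power_db[alpha_bin(spec.frequencies, target_hz)])
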