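"""Log-transformed gaze dispersion from confidence-filtered windows.

Horizontal and vertical dispersion are the sample standard deviations of
gaze position (px) over the 3-s pre-stimulus window, computed on raw
samples whose tracker confidence is at least 0.8, then natural-log
transformed (lnX, lnY) to approximate normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg import FeatureMissing
from .streams import SignalStream


@dataclass
class Dispersion:
    sd_x: float
    sd_y: float
    ln_x: float
    ln_y: float
    n_used: int


def gaze_dispersion(
    x: SignalStream,
    y: SignalStream,
    confidence_min: float = 0.8,
    min_samples: int = 10,
) -> Dispersion:
    """Dispersion of one pre-stimulus gaze window.

    Samples with confidence below ``confidence_min`` are discarded; the
    standard deviations use the n−1 denominator. Fewer than ``min_samples``
    retained samples, or a zero dispersion (no log defined), flag the
    feature missing for the trial.
    """
    if x.confidence is None or y.confidence is None:
        raise ValueError("gaze streams must carry confidence values")
    if x.n_samples != y.n_samples:
        raise ValueError("gaze x and y windows differ in length")
    keep = (x.confidence >= confidence_min) & (y.confidence >= confidence_min)
    n_used = int(keep.sum())
    if n_used < max(min_samples, 2):
        raise FeatureMissing(
            f"only {n_used} confident gaze samples (need >= {max(min_samples, 2)})"
        )
    sd_x = float(np.std(x.samples[keep], ddof=1))
    sd_y = float(np.std(y.samples[keep], ddof=1))
    if sd_x <= 0.0 or sd_y <= 0.0:
        raise FeatureMissing("zero gaze dispersion; log-transform undefined")
    return Dispersion(
        sd_x=sd_x, sd_y=sd_y, ln_x=float(np.log(sd_x)), ln_y=float(np.log(sd_y)),
        n_used=n_used,
    )
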