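"""Detection behavior: reaction times, the RT ceiling, and sensitivity A.

Reaction time to each unreliable arrow is the latency of the first `U`
press in the response window after its onset; RTs above 2,600 ms are set
equal to 2,600 ms (winsorized, not discarded). Discrimination sensitivity
uses the non-parametric A statistic of Zhang & Mueller — the average of the
areas of the minimum-area and maximum-area proper ROC curves through the
observed (false-alarm, hit) pair — which remains defined at hit or
false-alarm rates of 0 and 1, where d′ does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .streams import Event, ResponseLog

RT_CAP_MS = 2600.0

OUTCOME_KEYS = {"no_change": "N", "incorrect_change": "I", "correct_change": "C"}


@dataclass
class TrialResponse:
    """Scored response to one unreliable arrow."""

    event: Event
    rt_ms: Optional[float]  # capped; None on a miss
    hit: bool
    second_key: Optional[str]
    second_correct: Optional[bool]


@dataclass
class DetectionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    period: Optional[int] = None

    @property
    def hit_rate(self) -> float:
        n = self.hits + self.misses
        return self.hits / n if n else float("nan")

    @property
    def fa_rate(self) -> float:
        n = self.false_alarms + self.correct_rejections
        return self.false_alarms / n if n else float("nan")


@dataclass
class SensitivityA:
    a_value: float


def cap_rt(rt_ms: float, cap: float = RT_CAP_MS) -> float:
    """Winsorize a reaction time at the ceiling (idempotent)."""
    return min(float(rt_ms), float(cap))


def extract_rt(
    events: Sequence[Event],
    responses: ResponseLog,
    cap: float = RT_CAP_MS,
    last_window_s: float = 10.0,
):
    """Score `U` presses against arrows and extract capped RTs.

    The response window for an arrow is ``(onset, next onset]`` (arrows
    arrive every ~13 s, far above the longest credible RT); the final
    arrow's window extends ``last_window_s``. The first `U` press in an
    unreliable arrow's window is its hit; `U` presses in a reliable arrow's
    window count as false alarms against that (nearest preceding) arrow.
    The first N/I/C press after a hit, within the same window, is matched
    against the true outcome for lane-change accuracy.

    Returns (list of TrialResponse, list of per-period DetectionCounts).
    """
    events = sorted(events, key=lambda e: e.onset)
    onsets = np.array([e.onset for e in events])
    ends = np.append(onsets[1:], onsets[-1] + last_window_s) if len(events) else np.array([])

    n_before = sum(1 for t, _ in responses.presses if len(events) and t <= onsets[0])
    if n_before:
        warnings.warn(f"{n_before} presses before the first event ignored")

    # assign each press to the event whose (onset, next onset] window holds it
    per_event_presses: List[List] = [[] for _ in events]
    for t, key in responses.presses:
        i = int(np.searchsorted(onsets, t, side="left")) - 1
        if i < 0 or t > ends[i]:
            continue
        per_event_presses[i].append((t, key))

    trials: List[TrialResponse] = []
    fa_by_period: Dict[int, int] = {}
    cr_by_period: Dict[int, int] = {}
    for e, presses in zip(events, per_event_presses):
        u_times = [t for t, k in presses if k == "U"]
        if e.arrow_type == "reliable":
            if u_times:
                fa_by_period[e.period] = fa_by_period.get(e.period, 0) + 1
            else:
                cr_by_period[e.period] = cr_by_period.get(e.period, 0) + 1
            continue
        if not u_times:
            trials.append(TrialResponse(e, None, False, None, None))
            continue
        t_u = u_times[0]
        rt = cap_rt((t_u - e.onset) * 1000.0, cap)
        second = next((k for t, k in presses if k in "NIC" and t > t_u), None)
        correct = None if second is None else (second == OUTCOME_KEYS[e.outcome])
        trials.append(TrialResponse(e, rt, True, second, correct))

    periods = sorted({e.period for e in events})
    counts = []
    for p in periods:
        hits = sum(1 for tr in trials if tr.event.period == p and tr.hit)
        misses = sum(1 for tr in trials if tr.event.period == p and not tr.hit)
        counts.append(
            DetectionCounts(
                hits=hits,
                misses=misses,
                false_alarms=fa_by_period.get(p, 0),
                correct_rejections=cr_by_period.get(p, 0),
                period=p,
            )
        )
    return trials, counts


# ---------------------------------------------------------------------------
# sensitivity A

def a_sensitivity(H: float, F: float) -> SensitivityA:
    """Zhang–Mueller A via its closed-form piecewise expression.

    For H ≥ F:
        A = 3/4 + (H−F)/4 − F(1−H)          if F ≤ 1/2 ≤ H
        A = 3/4 + (H−F)/4 − F/(4H)          if F ≤ H < 1/2
        A = 3/4 + (H−F)/4 − (1−H)/(4(1−F))  if 1/2 < F ≤ H
    Below-chance pairs use the ROC symmetry A(H, F) = 1 − A(F, H).
    """
    if not (0.0 <= H <= 1.0 and 0.0 <= F <= 1.0):
        raise ValueError("H and F must lie in [0, 1]")
    if H == F:
        return SensitivityA(0.5)
    if H < F:
        return SensitivityA(1.0 - a_sensitivity(F, H).a_value)
    if F <= 0.5 <= H:
        a = 0.75 + (H - F) / 4.0 - F * (1.0 - H)
    elif H < 0.5:
        a = 0.75 + (H - F) / 4.0 - F / (4.0 * H)
    else:
        a = 0.75 + (H - F) / 4.0 - (1.0 - H) / (4.0 * (1.0 - F))
    return SensitivityA(float(a))


def a_sensitivity_numeric(H: float, F: float, grid: int = 401) -> float:
    """A by explicit construction of the extremal proper ROC curves.

    Independent check of the closed form: the minimum-area and maximum-area
    proper ROC curves through (F, H) are found by linear programming over
    non-decreasing concave curves pinned at the observed point (a vertical
    rise from the origin is admissible, so only the minimum-area curve is
    additionally pinned at (0, 0)); A is the average of their two areas.
    """
    if H < F:
        return 1.0 - a_sensitivity_numeric(F, H, grid)
    if H == F:
        return 0.5
    return 0.5 * (
        _proper_roc_area(H, F, maximize=False, grid=grid)
        + _proper_roc_area(H, F, maximize=True, grid=grid)
    )


def _proper_roc_area(H: float, F: float, maximize: bool, grid: int) -> float:
    # grid includes the kink locations of the extremal polylines so the LP
    # attains the exact optimum rather than an O(h^2) approximation
    knots = [0.0, 1.0, F]
    if H > 0:
        knots += [min(1.0, F / H)]
    knots += [min(1.0, 2.0 * F)]
    if H < 1:
        knots += [max(0.0, F - H * (1.0 - F) / (1.0 - H))]
    knots = np.unique(np.clip(knots, 0.0, 1.0))
    uniform = np.linspace(0.0, 1.0, grid)
    # uniform points colliding with a knot would create ill-scaled
    # concavity rows; the knots win
    clear = np.all(np.abs(uniform[:, None] - knots[None, :]) > 1e-6, axis=1)
    x = np.unique(np.concatenate([uniform[clear], knots]))
    iF = int(np.argmin(np.abs(x - F)))
    x[iF] = F
    n = x.size

    w = np.zeros(n)  # trapezoid quadrature weights = area objective
    w[1:] += np.diff(x) / 2.0
    w[:-1] += np.diff(x) / 2.0
    c = -w if maximize else w

    rows, rhs = [], []
    for i in range(n - 1):  # non-decreasing
        r = np.zeros(n)
        r[i], r[i + 1] = 1.0, -1.0
        rows.append(r)
        rhs.append(0.0)
    for i in range(1, n - 1):  # concave: slope after i must not exceed slope before
        h1, h2 = x[i] - x[i - 1], x[i + 1] - x[i]
        r = np.zeros(n)
        # (f[i+1]-f[i])/h2 - (f[i]-f[i-1])/h1 <= 0; O(1) row scaling keeps
        # the solver's feasibility tolerance meaningful on fine grids
        r[i - 1], r[i], r[i + 1] = 1.0 / h1, -(1.0 / h1 + 1.0 / h2), 1.0 / h2
        rows.append(r)
        rhs.append(0.0)
    a_eq, b_eq = [], []
    r = np.zeros(n)
    r[iF] = 1.0
    a_eq.append(r)
    b_eq.append(H)
    r = np.zeros(n)
    r[-1] = 1.0
    a_eq.append(r)
    b_eq.append(1.0)
    if not maximize:
        r = np.zeros(n)
        r[0] = 1.0
        a_eq.append(r)
        b_eq.append(0.0)
    res = linprog(
        c,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        A_eq=np.array(a_eq),
        b_eq=np.array(b_eq),
        bounds=[(0.0, 1.0)] * n,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"ROC-area LP failed for H={H}, F={F}: {res.message}")
    return float(w @ res.x)


# ---------------------------------------------------------------------------
# per-period aggregation

def period_performance(
    trials: Sequence[TrialResponse], counts: Sequence[DetectionCounts]
) -> List[dict]:
    """Per-period H, F, A and second-press (lane-change) accuracy."""
    out = []
    for dc in counts:
        n_unrel = dc.hits + dc.misses
        row = dict(
            period=dc.period,
            hits=dc.hits,
            misses=dc.misses,
            false_alarms=dc.false_alarms,
            correct_rejections=dc.correct_rejections,
        )
        if n_unrel == 0:
            row.update(hit_rate=None, fa_rate=None, a_value=None, second_press_accuracy=None)
            out.append(row)
            continue
        H, F = dc.hit_rate, dc.fa_rate
        row["hit_rate"] = H
        row["fa_rate"] = F
        row["a_value"] = a_sensitivity(H, F).a_value if np.isfinite(F) else None
        judged = [
            tr.second_correct
            for tr in trials
            if tr.event.period == dc.period and tr.second_correct is not None
        ]
        row["second_press_accuracy"] = float(np.mean(judged)) if judged else None
        out.append(row)
    return out


def speed_accuracy_correlation(a_values: Sequence[float], mean_rts: Sequence[float]) -> float:
    """Product-moment correlation of per-participant A and mean RT."""
    a = np.asarray(a_values, dtype=float)
    r = np.asarray(mean_rts, dtype=float)
    if a.size != r.size or a.size < 3:
        raise ValueError("need >=3 paired participant summaries")
    return float(np.corrcoef(a, r)[0, 1])
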