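"""Behavioural accuracy scoring for the S-R-K task battery.

Each cognitive-control level has its own accuracy metric, expressed as a
percentage in [0, 100]:

* **Skill** (tracking): the cursor trajectory is compared with the ideal
  track in terms of excess path length and lateral error,
  ``Skill% = [1 - (L - Lopt)/L] * [errMAX / (errMAX + err)] * 100``.
* **Rule** (obstacle rules): fraction of the 14 rule slots (7 turn +
  7 altitude) applied correctly, the altitude slots weighted by ``w``,
  ``Rule% = (sum turn_i + sum w_i * alt_i) / 14 * 100``.
* **Knowledge 1** (windy-sector recovery): ideal circuit time over actual
  circuit + event time, ``K1% = Topt / (Tcir + Tev) * 100``.
* **Knowledge 2** (button-sequence emergency): equal weight on inverse
  attempt count and unused fraction of the 20-min budget,
  ``K2% = (1/natt) * 50 + ((Tav - T)/Tav) * 50``.

Level scores aggregate the two repetitions of each condition by
arithmetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Total number of rule slots per Rule condition (7 turn + 7 altitude).
N_RULE_SLOTS = 14

#: Available time to solve the K2 emergency, seconds (20 min).
T_AVAILABLE_K2 = 1200.0


class MalformedLogError(ValueError):
    """A behavioural log violates its structural invariants."""


@dataclass(frozen=True)
class TrackLog:
    """Cursor trajectory evidence for a Skill condition.

    ``cursor_samples`` are (t, x, y) rows with strictly increasing t;
    ``ideal_track`` is the ideal polyline as (x, y) vertices.
    """

    cursor_samples: np.ndarray  # (n, 3): t, x, y
    ideal_track: np.ndarray     # (m, 2): x, y
    completion_time: float

    def __post_init__(self):
        cs = np.asarray(self.cursor_samples, dtype=float)
        it = np.asarray(self.ideal_track, dtype=float)
        object.__setattr__(self, "cursor_samples", cs)
        object.__setattr__(self, "ideal_track", it)
        if cs.ndim != 2 or cs.shape[1] != 3 or cs.shape[0] < 2:
            raise MalformedLogError("need >= 2 cursor samples of (t, x, y)")
        if it.ndim != 2 or it.shape[1] != 2 or it.shape[0] < 2:
            raise MalformedLogError("ideal track needs >= 2 (x, y) vertices")
        if np.any(np.diff(cs[:, 0]) <= 0):
            raise MalformedLogError("cursor timestamps must strictly increase")


@dataclass(frozen=True)
class RuleLog:
    """Outcomes of the 7 turn and 7 altitude rule slots of a Rule condition."""

    turn_outcomes: tuple
    alt_outcomes: tuple
    alt_weights: tuple = field(default=(1.0,) * 7)
    completion_time: float = 0.0

    def __post_init__(self):
        if len(self.turn_outcomes) != 7 or len(self.alt_outcomes) != 7:
            raise MalformedLogError("rule log needs exactly 7 turn + 7 altitude slots")
        if len(self.alt_weights) != 7:
            raise MalformedLogError("need exactly 7 altitude weights")
        if not all(o in (0, 1) for o in self.turn_outcomes + self.alt_outcomes):
            raise MalformedLogError("rule outcomes must be 0 or 1")
        if not all(0 < w <= 1 for w in self.alt_weights):
            raise MalformedLogError("altitude weights must lie in (0, 1]")


@dataclass(frozen=True)
class KnowledgeLog:
    """Timing/attempt evidence for a Knowledge condition (variant K1 or K2)."""

    variant: str                 # "K1" | "K2"
    completion_time: float = 0.0
    # K1 fields
    t_opt: float = math.nan      # ideal circuit time, s
    t_cir: float = math.nan      # actual circuit time, s
    t_ev: float = math.nan       # time spent solving the event, s
    # K2 fields
    n_att: int = 0               # attempts to find the button sequence
    t_used: float = math.nan     # time used to solve the failure, s
    t_av: float = T_AVAILABLE_K2

    def __post_init__(self):
        if self.variant == "K1":
            if not (self.t_cir >= self.t_opt > 0) or not self.t_ev >= 0:
                raise MalformedLogError("K1 requires Tcir >= Topt > 0 and Tev >= 0")
        elif self.variant == "K2":
            if self.n_att < 1 or not (0 <= self.t_used <= self.t_av):
                raise MalformedLogError("K2 requires natt >= 1 and 0 <= T <= Tav")
        else:
            raise MalformedLogError(f"unknown knowledge variant {self.variant!r}")


@dataclass(frozen=True)
class ScoreSet:
    """Per-condition accuracies plus per-level (S, R, K) means, in percent."""

    condition_scores: dict
    condition_times: dict
    level_scores: dict
    level_times: dict


# ---------------------------------------------------------------------------
# geometry

def _point_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Euclidean distance of each point to the closest segment of a polyline."""
    p = np.asarray(points, dtype=float)[:, None, :]        # (n, 1, 2)
    a = np.asarray(polyline, dtype=float)[None, :-1, :]    # (1, m-1, 2)
    b = np.asarray(polyline, dtype=float)[None, 1:, :]
    ab = b - a
    denom = np.einsum("...i,...i", ab, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("...i,...i", p - a, ab) / denom
    t = np.nan_to_num(t, nan=0.0)                          # degenerate segment
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[..., None] * ab
    d = np.linalg.norm(p - proj, axis=-1)                  # (n, m-1)
    return d.min(axis=1)


def polyline_length(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


def track_geometry(log: TrackLog) -> tuple[float, float, float, float]:
    """Return (L, Lopt, err, errMAX) from a tracking log.

    L and Lopt are polyline lengths of the cursor path and ideal track;
    err / errMAX are the mean / max point-to-polyline distances of the
    cursor samples from the ideal track over the entire run.
    """
    cursor_xy = log.cursor_samples[:, 1:3]
    L = polyline_length(cursor_xy)
    L_opt = polyline_length(log.ideal_track)
    d = _point_to_polyline(cursor_xy, log.ideal_track)
    # snap floating-point dust so a perfect retrace scores exactly 100
    tol = 1e-9 * max(1.0, L_opt)
    d[d < tol] = 0.0
    if L < L_opt and L_opt - L < tol:
        L = L_opt
    return L, L_opt, float(d.mean()), float(d.max())


# ---------------------------------------------------------------------------
# accuracy formulas

def skill_accuracy(L: float, L_opt: float, err: float, err_max: float) -> float:
    """Skill tracking accuracy in percent.

    ``[1 - (L - Lopt)/L] * [errMAX/(errMAX + err)] * 100`` clipped to
    [0, 100]; the error factor is defined as 1 for a perfect run
    (err = errMAX = 0).
    """
    if L_opt <= 0 or L < L_opt or err < 0 or err_max < err:
        raise ValueError("require L >= Lopt > 0 and errMAX >= err >= 0")
    length_factor = 1.0 - (L - L_opt) / L
    error_factor = 1.0 if err_max == 0 else err_max / (err_max + err)
    return float(np.clip(length_factor * error_factor * 100.0, 0.0, 100.0))


def rule_accuracy(log: RuleLog) -> float:
    """Rule accuracy in percent: correctly applied rule slots out of 14."""
    score = sum(log.turn_outcomes) + sum(
        w * a for w, a in zip(log.alt_weights, log.alt_outcomes)
    )
    return score / N_RULE_SLOTS * 100.0


def knowledge1_accuracy(log: KnowledgeLog) -> float:
    """K1 accuracy in percent: ideal time over (circuit + event) time."""
    if log.variant != "K1":
        raise ValueError("knowledge1_accuracy requires a K1 log")
    denom = log.t_cir + log.t_ev
    if denom <= 0:
        raise ValueError("Tcir + Tev must be positive")
    return log.t_opt / denom * 100.0


def knowledge2_accuracy(log: KnowledgeLog) -> float:
    """K2 accuracy in percent: attempt term plus unused-time term, 50 each."""
    if log.variant != "K2":
        raise ValueError("knowledge2_accuracy requires a K2 log")
    return (1.0 / log.n_att) * 50.0 + (log.t_av - log.t_used) / log.t_av * 50.0


def score_log(log) -> float:
    """Dispatch a behavioural log to its level's accuracy formula."""
    if isinstance(log, TrackLog):
        return skill_accuracy(*track_geometry(log))
    if isinstance(log, RuleLog):
        return rule_accuracy(log)
    if isinstance(log, KnowledgeLog):
        return knowledge1_accuracy(log) if log.variant == "K1" else knowledge2_accuracy(log)
    raise TypeError(f"not a behavioural log: {type(log)!r}")


# ---------------------------------------------------------------------------
# aggregation

_LEVEL_CONDITIONS = {"S": ("S1", "S2"), "R": ("R1", "R2"), "K": ("K1", "K2")}


def aggregate_scores(condition_scores: dict, condition_times: dict) -> ScoreSet:
    """Combine condition accuracies/times into per-level (S, R, K) means."""
    level_scores, level_times = {}, {}
    for level, conds in _LEVEL_CONDITIONS.items():
        missing = [c for c in conds if c not in condition_scores or c not in condition_times]
        if missing:
            raise ValueError(f"missing repetition(s) {missing} for level {level}")
        level_scores[level] = float(np.mean([condition_scores[c] for c in conds]))
        level_times[level] = float(np.mean([condition_times[c] for c in conds]))
    return ScoreSet(
        condition_scores=dict(condition_scores),
        condition_times=dict(condition_times),
        level_scores=level_scores,
        level_times=level_times,
    )


def questionnaire_average(item_scores: dict) -> dict:
    """Per-level mean questionnaire score across items and repetitions.

    ``item_scores`` maps condition -> sequence of item ratings; the same
    items must be rated in every condition.
    """
    lengths = {c: len(v) for c, v in item_scores.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"ragged item sets across conditions: {lengths}")
    out = {}
    for level, conds in _LEVEL_CONDITIONS.items():
        missing = [c for c in conds if c not in item_scores]
        if missing:
            raise ValueError(f"missing condition(s) {missing} for level {level}")
        out[level] = float(np.mean([np.asarray(item_scores[c], float) for c in conds]))
    return out


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled (n-1 denominator) standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))
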