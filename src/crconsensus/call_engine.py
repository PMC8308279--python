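"""Probe-level detection calls, change calls, and signal log ratios.

Implements MAS5-style comparative analysis for Affymetrix probe sets: each
probe set is a small family of perfect-match (PM) / mismatch (MM) probe
pairs, and three quantities are derived per probe set:

* a *detection call* (present / marginal / absent) from a one-sided
  signed-rank test of the discrimination scores (PM-MM)/(PM+MM) against a
  small offset tau;
* a *change call* (increase ... decrease) from a one-sided signed-rank test
  on per-pair log2 background-adjusted intensity differences between an
  experiment chip and its baseline chip;
* a *signal log ratio* (SLR), a one-step Tukey-biweight robust average of
  the same per-pair log2 ratios — the log2 fold-change estimate.

Call thresholds follow the software defaults the source study applied:
present p < 0.04, marginal 0.04 <= p < 0.06, absent p >= 0.06; increase
p <= 0.0025, marginal increase 0.0025 < p <= 0.003, no change
0.003 < p < 0.997, marginal decrease 0.997 <= p < 0.998, decrease
p >= 0.998.  No fold-change cut-off is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from ._wilcoxon import DEFAULT_EXACT_LIMIT, signed_rank_p
from .design import CONTROL_LEVEL

__all__ = [
    "ProbePairSet",
    "DetectionCriteria",
    "ChangeCriteria",
    "DetectionResult",
    "ChangeResult",
    "discrimination_scores",
    "detection_call",
    "change_pvalue",
    "classify_change",
    "signal_log_ratio",
    "compute_call_table",
    "DETECTION_CODES",
    "CHANGE_CODES",
]

#: Floor applied to PM-MM before taking log2 (guards non-positive values).
BACKGROUND_FLOOR = 1.0

DETECTION_CODES = {"present": "P", "marginal": "M", "absent": "A"}
CHANGE_CODES = {
    "increase": "I",
    "marginal_increase": "MI",
    "no_change": "NC",
    "marginal_decrease": "MD",
    "decrease": "D",
}
DETECTION_FROM_CODE = {v: k for k, v in DETECTION_CODES.items()}
CHANGE_FROM_CODE = {v: k for k, v in CHANGE_CODES.items()}


@dataclass(frozen=True)
class ProbePairSet:
    """PM/MM intensities of one probe set on one chip."""

    probe_set_id: str
    pm: np.ndarray
    mm: np.ndarray
    chip_id: str = ""

    def __post_init__(self) -> None:
        pm = np.asarray(self.pm, dtype=float)
        mm = np.asarray(self.mm, dtype=float)
        object.__setattr__(self, "pm", pm)
        object.__setattr__(self, "mm", mm)
        if pm.ndim != 1 or pm.size == 0 or pm.shape != mm.shape:
            raise ValueError(
                f"{self.probe_set_id}: pm and mm must be equal-length, non-empty"
            )
        if np.any(pm <= 0) or np.any(mm <= 0):
            raise ValueError(f"{self.probe_set_id}: intensities must be positive")

    def __len__(self) -> int:
        return int(self.pm.size)


@dataclass(frozen=True)
class DetectionCriteria:
    """Detection-call thresholds and the discrimination-score offset tau."""

    tau: float = 0.015
    p_present: float = 0.04
    p_marginal: float = 0.06

    def __post_init__(self) -> None:
        if not (0.0 < self.p_present < self.p_marginal < 1.0):
            raise ValueError("need 0 < p_present < p_marginal < 1")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class ChangeCriteria:
    """Five-way change-call thresholds on the change p-value."""

    p_increase: float = 0.0025
    p_marginal_increase: float = 0.003
    p_no_change_hi: float = 0.997
    p_decrease: float = 0.998

    def __post_init__(self) -> None:
        if not (
            self.p_increase
            < self.p_marginal_increase
            < self.p_no_change_hi
            < self.p_decrease
        ):
            raise ValueError("change thresholds must be strictly increasing")


@dataclass(frozen=True)
class DetectionResult:
    p_value: float
    call: str  # present | marginal | absent


@dataclass(frozen=True)
class ChangeResult:
    p_value: float
    call: str  # increase | marginal_increase | no_change | marginal_decrease | decrease
    slr: float


def discrimination_scores(probe_pairs: ProbePairSet) -> np.ndarray:
    """Per-pair discrimination scores R = (PM - MM) / (PM + MM), in (-1, 1)."""
    return (probe_pairs.pm - probe_pairs.mm) / (probe_pairs.pm + probe_pairs.mm)


def detection_call(
    scores: np.ndarray,
    criteria: DetectionCriteria = DetectionCriteria(),
    *,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> DetectionResult:
    """Detection p-value and present/marginal/absent call.

    The p-value is the one-sided exact signed-rank p for H1:
    median(score) > tau.  Scores exactly equal to tau are dropped; if all
    are dropped the transcript is undetectable by convention (p = 1,
    absent).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("need at least one discrimination score")
    d = scores - criteria.tau
    d = d[d != 0]
    if d.size == 0:
        p = 1.0
    else:
        p = signed_rank_p(d, mid_p=False, exact_limit=exact_limit)
    if p < criteria.p_present:
        call = "present"
    elif p < criteria.p_marginal:
        call = "marginal"
    else:
        call = "absent"
    return DetectionResult(p_value=p, call=call)


def _log2_background_adjusted(pps: ProbePairSet) -> np.ndarray:
    return np.log2(np.maximum(pps.pm - pps.mm, BACKGROUND_FLOOR))


def _paired_log_ratios(baseline: ProbePairSet, experiment: ProbePairSet) -> np.ndarray:
    if baseline.probe_set_id != experiment.probe_set_id:
        raise ValueError(
            f"probe set mismatch: {baseline.probe_set_id!r} vs "
            f"{experiment.probe_set_id!r}"
        )
    if len(baseline) != len(experiment):
        raise ValueError(
            f"{baseline.probe_set_id}: probe-pair counts differ "
            f"({len(baseline)} vs {len(experiment)})"
        )
    return _log2_background_adjusted(experiment) - _log2_background_adjusted(baseline)


def change_pvalue(
    baseline: ProbePairSet,
    experiment: ProbePairSet,
    *,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> float:
    """One-sided mid-p signed-rank change p-value.

    Tested on per-pair differences of log2 background-adjusted intensities
    (PM - MM floored at 1.0), oriented so p near 0 means increase in the
    experiment chip and p near 1 means decrease.  The mid-p tail makes the
    test exactly anti-symmetric: swapping the chips maps p to 1 - p, and an
    identical pair of chips gives p = 0.5.
    """
    d = _paired_log_ratios(baseline, experiment)
    d = d[d != 0]
    if d.size == 0:
        return 0.5
    return signed_rank_p(d, mid_p=True, exact_limit=exact_limit)


def classify_change(p: float, criteria: ChangeCriteria = ChangeCriteria()) -> str:
    """Five-way change call; boundary values follow the published thresholds."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"change p-value {p!r} outside [0, 1]")
    if p <= criteria.p_increase:
        return "increase"
    if p <= criteria.p_marginal_increase:
        return "marginal_increase"
    if p < criteria.p_no_change_hi:
        return "no_change"
    if p < criteria.p_decrease:
        return "marginal_decrease"
    return "decrease"


def tukey_biweight(x: np.ndarray, c: float = 5.0, epsilon: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate.

    Centred at the median, scaled by the median absolute deviation; points
    further than ``c`` scale units get zero weight, so a single wild probe
    pair cannot dominate the average.  ``epsilon`` keeps the scale positive
    for constant vectors (all weights then equal 1 and the mean is returned).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    t = np.median(x)
    s = np.median(np.abs(x - t))
    u = (x - t) / (c * s + epsilon)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def signal_log_ratio(
    baseline: ProbePairSet,
    experiment: ProbePairSet,
    *,
    c: float = 5.0,
    epsilon: float = 1e-4,
) -> float:
    """Robust log2 fold-change: one-step biweight of the per-pair log2 ratios."""
    return tukey_biweight(_paired_log_ratios(baseline, experiment), c=c, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Bulk table computation


def _chip_probe_arrays(
    intensities: pd.DataFrame,
) -> dict[str, dict[str, ProbePairSet]]:
    """Index a long intensity table into ProbePairSets keyed by chip, probe."""
    required = {"chip_id", "probe_set_id", "probe_index", "pm", "mm"}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns {sorted(missing)}")
    out: dict[str, dict[str, ProbePairSet]] = {}
    ordered = intensities.sort_values(["chip_id", "probe_set_id", "probe_index"])
    for (chip, probe), sub in ordered.groupby(["chip_id", "probe_set_id"], sort=False):
        out.setdefault(chip, {})[probe] = ProbePairSet(
            probe_set_id=probe,
            pm=sub["pm"].to_numpy(),
            mm=sub["mm"].to_numpy(),
            chip_id=chip,
        )
    return out


def compute_call_table(
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    detection_criteria: DetectionCriteria = DetectionCriteria(),
    change_criteria: ChangeCriteria = ChangeCriteria(),
) -> pd.DataFrame:
    """Run detection + comparison analysis for every CR chip against its control.

    ``design`` pairs each CR chip (tissue, duration, cr_level > 0,
    replicate_index) with the control chip of the same tissue, duration and
    replicate.  Returns one row per probe set per CR chip with detection
    p-values/calls for both chips of the pair, the change p-value and call,
    and the signal log ratio; calls are serialized as P/M/A and
    I/MI/NC/MD/D.
    """
    chips = _chip_probe_arrays(intensities)
    detections: dict[str, dict[str, DetectionResult]] = {}

    def detect(chip: str) -> dict[str, DetectionResult]:
        if chip not in detections:
            if chip not in chips:
                raise ValueError(f"design references chip {chip!r} with no intensities")
            detections[chip] = {
                probe: detection_call(discrimination_scores(pps), detection_criteria)
                for probe, pps in chips[chip].items()
            }
        return detections[chip]

    controls = {
        (row.tissue, row.duration, int(row.replicate_index)): row.chip_id
        for row in design.itertuples()
        if int(row.cr_level) == CONTROL_LEVEL
    }

    rows = []
    for row in design.itertuples():
        level = int(row.cr_level)
        if level == CONTROL_LEVEL:
            continue
        rep = int(row.replicate_index)
        key = (row.tissue, row.duration, rep)
        if key not in controls:
            raise ValueError(f"no control chip for {key}")
        base_chip, exp_chip = controls[key], row.chip_id
        det_base, det_exp = detect(base_chip), detect(exp_chip)
        for probe, exp_pps in chips[exp_chip].items():
            base_pps = chips[base_chip].get(probe)
            if base_pps is None:
                raise ValueError(
                    f"probe {probe!r} on chip {exp_chip!r} missing from control "
                    f"{base_chip!r}"
                )
            p_change = change_pvalue(base_pps, exp_pps)
            rows.append(
                {
                    "probe_set_id": probe,
                    "tissue": row.tissue,
                    "duration": row.duration,
                    "cr_level": level,
                    "replicate_index": rep,
                    "detection_p_baseline": det_base[probe].p_value,
                    "detection_call_baseline": DETECTION_CODES[det_base[probe].call],
                    "detection_p_experiment": det_exp[probe].p_value,
                    "detection_call_experiment": DETECTION_CODES[det_exp[probe].call],
                    "change_p": p_change,
                    "change_call": CHANGE_CODES[classify_change(p_change, change_criteria)],
                    "slr": signal_log_ratio(base_pps, exp_pps),
                }
            )
    return pd.DataFrame(rows)
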