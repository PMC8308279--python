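"""Synthetic probe-level microarray data with planted dose-consistent signal.

Emulates the study design end to end so every pipeline stage can be
exercised without the deposited raw data: 5 tissues x {1 week, 1 month}
(intestine 1 month only) x 4 restriction levels against per-duration
controls, pooled RNA (one chip per condition, duplicate chips for adipose).

The intensity model is deliberately minimal — log-normal perfect-match
intensities with a per-probe affinity, mismatch intensities at a fixed
fraction of the realized PM with independent multiplicative jitter — just
enough structure for
discrimination scores, detection calls and signal log ratios to behave as
on real chips.  It is not a physical model of hybridization.

Planted structure: a configurable number of probe sets per tissue are
"responsive" — their log2 expression on CR chips is shifted by
``effect_slr_at_30 * dose_scaling[level]`` with the same sign in every
condition of the tissue, so the consensus filter should recover exactly
those probes.  A further block of "common" probe sets carries the same
shift in all five tissues, feeding the cross-tissue commonality analysis.
Because the effect multiplies both PM and MM, the expected signal log ratio
of a planted probe equals the planted shift exactly in the noiseless limit.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    CONTROL_LEVEL,
    CR_LEVELS,
    TISSUES,
    n_replicates,
    tissue_durations,
)

__all__ = ["SimConfig", "SimResult", "simulate", "write_simulation"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults describe the emulated study conditions."""

    n_probesets: int = 200
    probes_per_set: int = 11
    n_responsive_up: int = 12  # planted per tissue
    n_responsive_down: int = 12
    n_common_up: int = 5  # planted consistently across all tissues
    n_common_down: int = 5
    effect_slr_at_30: float = 1.5  # log2 shift at 30% restriction
    dose_scaling: tuple[float, ...] = (0.25, 0.5, 0.8, 1.0)  # 5/10/20/30%
    noise_sd: float = 0.1  # per-chip log2 intensity noise
    mm_fraction: float = 0.5  # MM mean as a fraction of PM mean
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    affinity_sd: float = 0.8  # per-probe log2 affinity spread within a set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets < 1 or self.probes_per_set < 1:
            raise ValueError("need at least one probe set and one probe pair")
        planted = (
            self.n_common_up
            + self.n_common_down
            + len(TISSUES) * (self.n_responsive_up + self.n_responsive_down)
        )
        if planted > self.n_probesets:
            raise ValueError(
                f"planted probes ({planted}) exceed n_probesets ({self.n_probesets})"
            )
        if len(self.dose_scaling) != len(CR_LEVELS):
            raise ValueError("dose_scaling needs one factor per CR level")
        if any(s <= 0 for s in self.dose_scaling) or any(
            a > b for a, b in zip(self.dose_scaling, self.dose_scaling[1:])
        ):
            raise ValueError("dose_scaling must be positive and non-decreasing")
        if not 0 < self.mm_fraction < 1:
            raise ValueError("mm_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SimResult:
    intensities: pd.DataFrame  # chip_id, probe_set_id, probe_index, pm, mm
    design: pd.DataFrame  # chip_id, tissue, duration, cr_level, role, replicate_index
    truth: pd.DataFrame  # probe_set_id, tissue, duration, cr_level, direction, expected_slr


def _dose_factor(config: SimConfig, level: int) -> float:
    return config.dose_scaling[CR_LEVELS.index(level)]


def simulate(config: SimConfig) -> SimResult:
    """Generate intensities, design and planted ground truth from one seed."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_probesets, config.probes_per_set
    probes = [f"SYN{i:05d}_at" for i in range(n)]

    # Disjoint planted blocks: common first, then per-tissue responsive.
    signed_effect = {t: np.zeros(n) for t in TISSUES}  # log2 shift at 30% CR
    cursor = 0
    for sign, count in ((1.0, config.n_common_up), (-1.0, config.n_common_down)):
        for t in TISSUES:
            signed_effect[t][cursor : cursor + count] = sign * config.effect_slr_at_30
        cursor += count
    for t in TISSUES:
        for sign, count in ((1.0, config.n_responsive_up), (-1.0, config.n_responsive_down)):
            signed_effect[t][cursor : cursor + count] = sign * config.effect_slr_at_30
            cursor += count

    affinity = rng.normal(0.0, config.affinity_sd, size=(n, m))

    intensity_frames = []
    design_rows = []
    truth_rows = []
    for tissue in TISSUES:
        base_mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
        for duration in tissue_durations(tissue):
            for level in (CONTROL_LEVEL,) + CR_LEVELS:
                shift = (
                    signed_effect[tissue] * _dose_factor(config, level)
                    if level != CONTROL_LEVEL
                    else np.zeros(n)
                )
                mean_log2 = base_mu[:, None] + affinity + shift[:, None]
                for rep in range(n_replicates(tissue)):
                    chip_id = f"{tissue}_{duration}_{level:02d}_r{rep}"
                    pm = 2.0 ** (mean_log2 + rng.normal(0.0, config.noise_sd, (n, m)))
                    # MM tracks the realized PM at mm_fraction with its own
                    # multiplicative jitter, so noise_sd keeps its meaning on
                    # the background-adjusted log2 scale.
                    mm = pm * config.mm_fraction * 2.0 ** rng.normal(
                        0.0, config.noise_sd, (n, m)
                    )
                    intensity_frames.append(
                        pd.DataFrame(
                            {
                                "chip_id": chip_id,
                                "probe_set_id": np.repeat(probes, m),
                                "probe_index": np.tile(np.arange(m), n),
                                "pm": pm.ravel(),
                                "mm": mm.ravel(),
                            }
                        )
                    )
                    design_rows.append(
                        {
                            "chip_id": chip_id,
                            "tissue": tissue,
                            "duration": duration,
                            "cr_level": level,
                            "role": "control" if level == CONTROL_LEVEL else "cr",
                            "replicate_index": rep,
                        }
                    )
                if level != CONTROL_LEVEL:
                    planted = np.nonzero(signed_effect[tissue])[0]
                    for i in planted:
                        truth_rows.append(
                            {
                                "probe_set_id": probes[i],
                                "tissue": tissue,
                                "duration": duration,
                                "cr_level": level,
                                "direction": "up" if signed_effect[tissue][i] > 0 else "down",
                                "expected_slr": signed_effect[tissue][i]
                                * _dose_factor(config, level),
                            }
                        )

    return SimResult(
        intensities=pd.concat(intensity_frames, ignore_index=True),
        design=pd.DataFrame(design_rows),
        truth=pd.DataFrame(truth_rows),
    )


def planted_responsive(truth: pd.DataFrame, tissue: str) -> tuple[set[str], set[str]]:
    """Ground-truth (up, down) responsive probe sets for one tissue."""
    sub = truth[truth["tissue"] == tissue]
    up = set(sub[sub["direction"] == "up"]["probe_set_id"])
    down = set(sub[sub["direction"] == "down"]["probe_set_id"])
    return up, down


def write_simulation(result: SimResult, out_dir: str | Path) -> None:
    """Write per-chip intensity TSVs plus design.tsv and ground_truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for chip_id, sub in result.intensities.groupby("chip_id", sort=True):
        sub.to_csv(out / f"chip_{chip_id}.tsv", sep="\t", index=False)
    result.design.to_csv(out / "design.tsv", sep="\t", index=False)
    result.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
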