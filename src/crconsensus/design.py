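"""Study design: tissues, durations, restriction levels, and the 36-condition grid.

The experimental design this package targets is a dose-graded calorie
restriction (CR) study in five rat tissues.  Four tissues (liver, adipose,
muscle, brain) were sampled after both one week (``1w``) and one month
(``1m``) of restriction; intestine was sampled after one month only.  Each
tissue/duration block has four restriction levels (5, 10, 20, 30 percent
below ad-libitum intake) compared against a per-duration control, giving
8 + 8 + 8 + 8 + 4 = 36 CR conditions in total.  RNA was pooled across
animals, so each condition is represented by a single hybridization
(duplicate chips for adipose).
"""

from __future__ import annotations

from dataclasses import dataclass

TISSUES: tuple[str, ...] = ("liver", "adipose", "muscle", "brain", "intestine")
DURATIONS: tuple[str, ...] = ("1w", "1m")
CR_LEVELS: tuple[int, ...] = (5, 10, 20, 30)

#: Tissues hybridized on duplicate chips per pooled sample.
REPLICATED_TISSUES: frozenset[str] = frozenset({"adipose"})

#: Level used in design tables to mark the ad-libitum control chip.
CONTROL_LEVEL: int = 0


def tissue_durations(tissue: str) -> tuple[str, ...]:
    """Durations available for *tissue* (intestine was collected at 1m only)."""
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    return ("1m",) if tissue == "intestine" else DURATIONS


def n_replicates(tissue: str) -> int:
    return 2 if tissue in REPLICATED_TISSUES else 1


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One of the 36 (tissue, duration, CR level) conditions."""

    tissue: str
    duration: str
    cr_level: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.duration not in tissue_durations(self.tissue):
            raise ValueError(
                f"tissue {self.tissue!r} has no duration {self.duration!r}"
            )
        if self.cr_level not in CR_LEVELS:
            raise ValueError(f"unknown CR level {self.cr_level!r}")

    @property
    def column(self) -> str:
        """Canonical column label, e.g. ``liver_1w_5``."""
        return f"{self.tissue}_{self.duration}_{self.cr_level}"

    @classmethod
    def from_column(cls, label: str) -> "ConditionKey":
        try:
            tissue, duration, level = label.rsplit("_", 2)
            return cls(tissue, duration, int(level))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed condition column {label!r}") from exc


def design_conditions() -> tuple[ConditionKey, ...]:
    """All 36 CR conditions in canonical (tissue, duration, level) order."""
    out = []
    for tissue in TISSUES:
        for duration in tissue_durations(tissue):
            for level in CR_LEVELS:
                out.append(ConditionKey(tissue, duration, level))
    return tuple(out)


def condition_columns() -> list[str]:
    return [c.column for c in design_conditions()]


def tissue_conditions(tissue: str) -> tuple[ConditionKey, ...]:
    return tuple(c for c in design_conditions() if c.tissue == tissue)
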