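"""Breeding-stage vocabulary shared by the classifier, simulator and outcomes."""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd


class StageLabel(enum.Enum):
    PRE_BREEDING = "PrB"
    INCUBATION = "I"
    CHICK_GUARDING = "CG"
    POST_BREEDING = "PoB"


#: labels with indistinguishable revisitation profiles; split positionally
NON_BREEDING_LABELS = frozenset({StageLabel.PRE_BREEDING, StageLabel.POST_BREEDING})


class TransitionKind(enum.Enum):
    INCUBATION_START = "incubation_start"
    HATCH = "hatch"
    NEST_FAIL = "nest_fail"
    BROOD_FAIL = "brood_fail"
    TAG_END = "tag_end"


@dataclass
class StageSegment:
    """A labelled breeding-status interval [start, end)."""

    label: StageLabel
    start: pd.Timestamp
    end: pd.Timestamp
    attempt_index: int | None = None
    confidence_notes: str = ""

    @property
    def days(self) -> float:
        return (self.end - self.start).total_seconds() / 86400.0


@dataclass
class TransitionEvent:
    """A typed, timed change of breeding status."""

    kind: TransitionKind
    time: pd.Timestamp
    resolution_s: float  # half-width of the timing uncertainty, seconds
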