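"""Canonical neuropsychological battery metadata.

The default battery mirrors a first-episode-schizophrenia assessment
protocol: CVLT-II, Logical Memory, Digit Span, Digit-Symbol Coding,
Letter-Number Sequencing, D-KEFS Color-Word tasks and verbal fluency.
Fourteen raw measures feed eight theory-based cognitive domains; timed
measures (completion times) are marked ``lower_better`` so that z-scoring
can orient every score as "higher = better".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Direction(str, Enum):
    """Scoring direction of a raw subtest measure."""

    higher_better = "higher_better"
    lower_better = "lower_better"


@dataclass(frozen=True)
class Subtest:
    """A raw battery measure: its canonical name and scoring direction."""

    name: str
    direction: Direction


DEFAULT_SUBTESTS: tuple[Subtest, ...] = (
    Subtest("cvlt_list_a_total", Direction.higher_better),
    Subtest("lm_trial_1", Direction.higher_better),
    Subtest("cvlt_long_delay_recall", Direction.higher_better),
    Subtest("lm_trial_2", Direction.higher_better),
    Subtest("digit_span", Direction.higher_better),
    Subtest("digit_symbol_coding", Direction.higher_better),
    Subtest("cowat_color_naming", Direction.lower_better),
    Subtest("cowat_reading", Direction.lower_better),
    Subtest("letter_number_sequencing", Direction.higher_better),
    Subtest("vf_fas", Direction.higher_better),
    Subtest("vf_categories", Direction.higher_better),
    Subtest("vf_switching", Direction.higher_better),
    Subtest("cowat_interference", Direction.lower_better),
    Subtest("cowat_switching", Direction.lower_better),
)

DEFAULT_DIRECTIONS: dict[str, Direction] = {s.name: s.direction for s in DEFAULT_SUBTESTS}

#: Theory-based domain memberships. Single-measure domains (attention,
#: psychomotor speed, working memory) are intentional: the battery has one
#: indicator for each.
DEFAULT_DOMAINS: dict[str, tuple[str, ...]] = {
    "learning": ("cvlt_list_a_total", "lm_trial_1"),
    "memory": ("cvlt_long_delay_recall", "lm_trial_2"),
    "attention": ("digit_span",),
    "psychomotor_speed": ("digit_symbol_coding",),
    "mental_speed": ("cowat_color_naming", "cowat_reading"),
    "working_memory": ("letter_number_sequencing",),
    "verbal_fluency": ("vf_fas", "vf_categories", "vf_switching"),
    "cognitive_control": ("cowat_interference", "cowat_switching"),
}

COMPOSITE = "composite"

#: Required identifier/demographic columns of the canonical long-format table.
ID_COLUMNS = ("subject_id", "group", "baseline_age", "sex", "time_years")

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"
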