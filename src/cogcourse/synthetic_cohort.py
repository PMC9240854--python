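"""Seeded two-group, two-wave cohort generator.

Emulates a first-episode-schizophrenia follow-up design: patients and
controls assessed at baseline and again about a decade later on a
multi-subtest battery. Scores are generated on the control-baseline z-scale
(group deficit, subject random intercept, baseline-age effect, per-group
practice effect, impaired-subgroup shift, residual noise) and then mapped to
the raw scale of each subtest, respecting its scoring direction. This makes
downstream z-score recovery exactly testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .battery import (
    DEFAULT_SUBTESTS,
    GROUP_CONTROL,
    GROUP_PATIENT,
    ID_COLUMNS,
    Direction,
    Subtest,
)


class SimConfigError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class SubtestSim:
    """Generative parameters for one subtest.

    ``group_deficit_sd_units`` is the patient deficit in control-baseline SD
    units (positive = worse performance). ``practice_effect_sd_units`` maps
    group -> SD-unit gain per year of retest interval. ``age_slope`` is the
    SD-unit change per year of baseline age relative to the reference age.
    """

    name: str
    direction: Direction = Direction.higher_better
    control_baseline_mean: float = 50.0
    control_baseline_sd: float = 10.0
    group_deficit_sd_units: float = 1.0
    practice_effect_sd_units: dict[str, float] = field(
        default_factory=lambda: {GROUP_PATIENT: 0.02, GROUP_CONTROL: 0.03}
    )
    age_slope_sd_units_per_year: float = -0.02


def _default_subtest_defs() -> tuple[SubtestSim, ...]:
    # Plausible raw scales per instrument; timed tasks in seconds.
    raw_scale = {
        "cvlt_list_a_total": (50.0, 10.0),
        "lm_trial_1": (28.0, 7.0),
        "cvlt_long_delay_recall": (11.0, 3.0),
        "lm_trial_2": (17.0, 6.0),
        "digit_span": (17.0, 4.0),
        "digit_symbol_coding": (75.0, 15.0),
        "cowat_color_naming": (30.0, 5.0),
        "cowat_reading": (22.0, 4.0),
        "letter_number_sequencing": (11.0, 2.5),
        "vf_fas": (42.0, 11.0),
        "vf_categories": (43.0, 9.0),
        "vf_switching": (14.0, 3.0),
        "cowat_interference": (55.0, 11.0),
        "cowat_switching": (60.0, 13.0),
    }
    return tuple(
        SubtestSim(
            name=s.name,
            direction=s.direction,
            control_baseline_mean=raw_scale[s.name][0],
            control_baseline_sd=raw_scale[s.name][1],
        )
        for s in DEFAULT_SUBTESTS
    )


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification of a two-wave cohort.

    Defaults emulate the study design the pipeline targets: 75 patients and
    108 controls, patients ~5 years younger, a ~1 SD global patient deficit,
    small practice effects, a 10-year retest interval, and a patient subgroup
    carrying an extra global deficit.
    """

    n_patient: int = 75
    n_control: int = 108
    baseline_age_mean: dict[str, float] = field(
        default_factory=lambda: {GROUP_PATIENT: 26.0, GROUP_CONTROL: 31.0}
    )
    baseline_age_sd: dict[str, float] = field(
        default_factory=lambda: {GROUP_PATIENT: 7.7, GROUP_CONTROL: 7.4}
    )
    subtest_defs: tuple[SubtestSim, ...] = field(default_factory=_default_subtest_defs)
    follow_up_years: float = 10.0
    random_intercept_sd: float = 0.8
    residual_sd: float = 0.5
    impaired_fraction: float = 0.25
    impaired_extra_deficit: float = 1.0
    attrition_rate: dict[str, float] = field(
        default_factory=lambda: {GROUP_PATIENT: 0.0, GROUP_CONTROL: 0.0}
    )
    missing_rate: float = 0.0
    age_reference_years: float = 29.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patient < 2:
            raise SimConfigError("n_patient must be >= 2")
        if self.n_control < 2:
            raise SimConfigError("n_control must be >= 2")
        for grp in (GROUP_PATIENT, GROUP_CONTROL):
            if self.baseline_age_sd[grp] < 0:
                raise SimConfigError(f"baseline_age_sd[{grp}] must be >= 0")
            if not 0.0 <= self.attrition_rate.get(grp, 0.0) <= 1.0:
                raise SimConfigError(f"attrition_rate[{grp}] must be in [0, 1]")
        if self.follow_up_years <= 0:
            raise SimConfigError("follow_up_years must be > 0")
        if self.random_intercept_sd < 0:
            raise SimConfigError("random_intercept_sd must be >= 0")
        if self.residual_sd < 0:
            raise SimConfigError("residual_sd must be >= 0")
        if not 0.0 <= self.impaired_fraction <= 1.0:
            raise SimConfigError("impaired_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SimConfigError("missing_rate must be in [0, 1]")
        if not self.subtest_defs:
            raise SimConfigError("subtest_defs must be non-empty")
        names = [s.name for s in self.subtest_defs]
        if len(set(names)) != len(names):
            raise SimConfigError("subtest_defs contains duplicate names")
        for s in self.subtest_defs:
            if s.control_baseline_sd <= 0:
                raise SimConfigError(f"subtest_defs[{s.name}].control_baseline_sd must be > 0")


@dataclass(frozen=True)
class AssessmentRecord:
    """One subject x wave row of raw subtest scores plus demographics."""

    subject_id: str
    group: str
    baseline_age: float
    sex: str
    time: float
    subtest_scores: dict[str, float]


def generate_cohort(config: SimConfig) -> list[AssessmentRecord]:
    """Generate the full two-wave cohort described by ``config``.

    Deterministic given (config, config.seed): two calls with equal inputs
    return bit-identical record lists. Attrition, if configured, removes
    wave-2 records at random within each group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[AssessmentRecord] = []
    groups = [GROUP_PATIENT] * config.n_patient + [GROUP_CONTROL] * config.n_control
    for idx, group in enumerate(groups):
        sid = f"{'P' if group == GROUP_PATIENT else 'C'}{idx:04d}"
        age = rng.normal(config.baseline_age_mean[group], config.baseline_age_sd[group])
        sex = "M" if rng.random() < 0.5 else "F"
        b_j = rng.normal(0.0, config.random_intercept_sd) if config.random_intercept_sd else 0.0
        impaired = group == GROUP_PATIENT and rng.random() < config.impaired_fraction
        for t in (0.0, config.follow_up_years):
            scores: dict[str, float] = {}
            for st in config.subtest_defs:
                latent = (
                    -st.group_deficit_sd_units * (group == GROUP_PATIENT)
                    - config.impaired_extra_deficit * impaired
                    + b_j
                    + st.age_slope_sd_units_per_year * (age - config.age_reference_years)
                    + t * st.practice_effect_sd_units[group]
                )
                if config.residual_sd:
                    latent += rng.normal(0.0, config.residual_sd)
                sign = 1.0 if st.direction == Direction.higher_better else -1.0
                scores[st.name] = st.control_baseline_mean + sign * latent * st.control_baseline_sd
            if config.missing_rate:
                miss = rng.random(len(scores)) < config.missing_rate
                if miss.all():  # every record keeps at least one observed score
                    miss[rng.integers(len(scores))] = False
                for name, m in zip(list(scores), miss):
                    if m:
                        scores[name] = math.nan
            records.append(AssessmentRecord(sid, group, age, sex, t, scores))
    if any(config.attrition_rate.get(g, 0.0) > 0 for g in (GROUP_PATIENT, GROUP_CONTROL)):
        records = apply_attrition(
            records, config.attrition_rate, mechanism="random", seed=config.seed + 1
        )
    return records


def apply_attrition(
    records: list[AssessmentRecord],
    rate_by_group: dict[str, float],
    mechanism: str = "random",
    seed: int | None = None,
    directions: dict[str, Direction] | None = None,
) -> list[AssessmentRecord]:
    """Remove wave-2 records to emulate loss to follow-up.

    ``random`` drops a uniform sample within each group; ``worst_baseline``
    drops the subjects with the lowest baseline composite first (composite =
    mean of direction-corrected within-sample baseline z-scores), enabling
    attrition-bias experiments. Baseline records are never touched.
    """
    for grp, rate in rate_by_group.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"attrition rate for {grp} must be in [0, 1]")
    if mechanism not in ("random", "worst_baseline"):
        raise ValueError(f"unknown attrition mechanism: {mechanism!r}")
    rng = np.random.default_rng(seed)
    baseline = [r for r in records if r.time == 0.0]
    ranks: dict[str, float] = {}
    if mechanism == "worst_baseline":
        ranks = _baseline_composites(baseline, directions)
    drop: set[str] = set()
    for grp, rate in rate_by_group.items():
        sids = sorted({r.subject_id for r in records if r.group == grp and r.time > 0.0})
        k = int(round(rate * len(sids)))
        if k == 0:
            continue
        if mechanism == "random":
            drop.update(rng.choice(sids, size=k, replace=False))
        else:
            sids.sort(key=lambda s: ranks.get(s, 0.0))
            drop.update(sids[:k])
    return [r for r in records if not (r.time > 0.0 and r.subject_id in drop)]


def _baseline_composites(
    baseline: list[AssessmentRecord], directions: dict[str, Direction] | None
) -> dict[str, float]:
    df = records_to_frame(baseline)
    subtests = [c for c in df.columns if c not in ID_COLUMNS]
    z = pd.DataFrame(index=df.index)
    for st in subtests:
        col = df[st].astype(float)
        sd = col.std(ddof=1)
        if not sd > 0:
            continue
        zz = (col - col.mean()) / sd
        if directions and directions.get(st) == Direction.lower_better:
            zz = -zz
        z[st] = zz
    comp = z.mean(axis=1)
    return dict(zip(df["subject_id"], comp))


def records_to_frame(records: list[AssessmentRecord]) -> pd.DataFrame:
    """Convert records to the canonical long-format table (one row per
    subject x wave; id columns then one column per subtest)."""
    subtests: list[str] = []
    for r in records:
        for name in r.subtest_scores:
            if name not in subtests:
                subtests.append(name)
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "baseline_age": r.baseline_age,
            "sex": r.sex,
            "time_years": r.time,
        }
        for name in subtests:
            row[name] = r.subtest_scores.get(name, math.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ID_COLUMNS) + subtests)


def frame_to_records(df: pd.DataFrame) -> list[AssessmentRecord]:
    """Inverse of :func:`records_to_frame`."""
    subtests = [c for c in df.columns if c not in ID_COLUMNS]
    return [
        AssessmentRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            baseline_age=float(row["baseline_age"]),
            sex=str(row["sex"]),
            time=float(row["time_years"]),
            subtest_scores={s: float(row[s]) for s in subtests},
        )
        for _, row in df.iterrows()
    ]


def write_cohort_csv(records: list[AssessmentRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    return df


def null_config(**overrides) -> SimConfig:
    """A convenience config with every systematic effect and noise source
    zeroed: controls score exactly the configured baseline mean at both
    waves. Useful as a fixture base."""
    defs = tuple(
        replace(
            s,
            group_deficit_sd_units=0.0,
            practice_effect_sd_units={GROUP_PATIENT: 0.0, GROUP_CONTROL: 0.0},
            age_slope_sd_units_per_year=0.0,
        )
        for s in _default_subtest_defs()
    )
    base = SimConfig(
        subtest_defs=defs,
        random_intercept_sd=0.0,
        residual_sd=0.0,
        impaired_fraction=0.0,
        impaired_extra_deficit=0.0,
    )
    return replace(base, **overrides) if overrides else base
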