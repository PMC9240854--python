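"""Impairment classifier: strict cut-off boundary, subject rule, prevalence
arithmetic, transition tracing, monotonicity, and brute-force reconciliation
of domain- and subject-level transitions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogcourse import (
    ClassifierConfig,
    classify_profiles,
    classify_subject,
    flag_impairment,
    prevalence,
    transition_analysis,
)
from cogcourse.battery import DEFAULT_DOMAINS
from cogcourse.impairment_classification import (
    ImpairmentError,
    impairment_percentage_table,
)

DOMAINS = list(DEFAULT_DOMAINS)
CFG = ClassifierConfig()


@pytest.mark.parametrize(
    "z,expected",
    [(-1.5, False), (-1.51, True), (0.0, False), (-3.0, True), (math.nan, None)],
)
def test_flag_is_strictly_below_cutoff(z, expected):
    assert flag_impairment(z, CFG) is expected


def test_subject_rule_requires_two_domains():
    z = {d: 0.0 for d in DOMAINS}
    z["learning"], z["memory"] = -1.6, -1.7
    prof = classify_subject(z, CFG)
    assert prof.clinically_impaired is True
    assert prof.n_impaired == 2

    z2 = {d: 0.0 for d in DOMAINS}
    z2["attention"] = -3.0
    assert classify_subject(z2, CFG).clinically_impaired is False

    z3 = {d: -1.6 for d in DOMAINS}
    prof3 = classify_subject(z3, CFG)
    assert prof3.clinically_impaired is True
    assert prof3.n_impaired == 8


def test_insufficient_observed_domains_gives_missing_status():
    z = {d: math.nan for d in DOMAINS}
    z["learning"] = -2.0
    cfg = ClassifierConfig(min_observed=4)
    prof = classify_subject(z, cfg)
    assert prof.clinically_impaired is None
    assert prof.n_observed == 1
    assert prof.n_impaired == 1  # missing domains excluded, not counted


def profiles_from_flags(flags_by_subject, group="patient", time=0.0):
    rows = []
    for sid, flags in flags_by_subject.items():
        row = {
            "subject_id": sid,
            "group": group,
            "time_years": time,
            "n_impaired": sum(flags),
            "n_observed": len(DOMAINS),
            "clinically_impaired": sum(flags) >= CFG.min_domains,
        }
        for d, f in zip(DOMAINS, flags):
            row[f"imp_{d}"] = bool(f)
        rows.append(row)
    return pd.DataFrame(rows)


def test_prevalence_rounding_and_errors():
    flags = {f"s{i}": [1, 1] + [0] * 6 for i in range(11)}
    flags.update({f"t{i}": [0] * 8 for i in range(5)})
    pct, n = prevalence(profiles_from_flags(flags))
    assert n == 16
    assert round(pct, 1) == 68.8  # 11 of 16
    none_flags = {f"s{i}": [0] * 8 for i in range(4)}
    assert prevalence(profiles_from_flags(none_flags))[0] == 0.0
    with pytest.raises(ImpairmentError):
        prevalence(profiles_from_flags({}))


def test_prevalence_is_order_invariant(small_cohort_df):
    from cogcourse import score_battery

    _, scores = score_battery(small_cohort_df)
    profiles = classify_profiles(scores, CFG)
    shuffled = classify_profiles(
        scores.sample(frac=1.0, random_state=1).reset_index(drop=True), CFG
    )
    assert prevalence(profiles) == prevalence(shuffled)


def test_transition_rule_tracing_two_to_one_domain():
    """Impaired on {learning, memory} at baseline and only {learning} at
    follow-up: counts as improved-on-a-domain AND as no longer clinically
    impaired (1 < 2 domains)."""
    b = profiles_from_flags({"s": [1, 1, 0, 0, 0, 0, 0, 0]})
    f = profiles_from_flags({"s": [1, 0, 0, 0, 0, 0, 0, 0]}, time=10.0)
    ts = transition_analysis(b, f, CFG)
    assert ts.pct_improved_any_domain == 100.0
    assert ts.pct_no_longer_impaired == 100.0
    assert ts.pct_additional_domains == 0.0


def test_identical_flags_give_all_zero_transitions():
    flags = {"a": [1, 1, 0, 0, 0, 0, 0, 0], "b": [0] * 8, "c": [1] * 8}
    b = profiles_from_flags(flags)
    f = profiles_from_flags(flags, time=10.0)
    ts = transition_analysis(b, f, CFG)
    assert ts.pct_improved_any_domain == 0.0
    assert ts.pct_no_longer_impaired == 0.0
    assert ts.pct_additional_domains == 0.0
    assert ts.pct_improved == 0.0
    assert ts.pct_declined == 0.0
    assert ts.pct_became_impaired == 0.0
    # one of the two baseline-impaired subjects is impaired on all domains
    assert ts.pct_all_domains_at_follow_up == 50.0


def test_unimpaired_subject_crossing_two_domains_becomes_impaired():
    b = profiles_from_flags({"s": [0] * 8})
    f = profiles_from_flags({"s": [1, 1, 0, 0, 0, 0, 0, 0]}, time=10.0)
    ts = transition_analysis(b, f, CFG)
    assert ts.pct_became_impaired == 100.0
    assert ts.pct_declined == 100.0


def test_subjects_missing_a_wave_are_excluded_and_counted():
    b = profiles_from_flags({"s": [1, 1, 0, 0, 0, 0, 0, 0], "t": [0] * 8})
    f = profiles_from_flags({"s": [1, 1, 0, 0, 0, 0, 0, 0]}, time=10.0)
    ts = transition_analysis(b, f, CFG)
    assert ts.n_excluded == 1
    assert ts.n_baseline_impaired == 1


@settings(max_examples=50, deadline=None)
@given(
    z=st.lists(
        st.floats(min_value=-4.0, max_value=2.0, allow_nan=False),
        min_size=8,
        max_size=8,
    ),
    cut_shift=st.floats(min_value=0.01, max_value=2.0),
)
def test_more_negative_cutoff_never_increases_impaired_count(z, cut_shift):
    zmap = dict(zip(DOMAINS, z))
    loose = classify_subject(zmap, ClassifierConfig(cutoff=-1.0))
    strict = classify_subject(zmap, ClassifierConfig(cutoff=-1.0 - cut_shift))
    assert strict.n_impaired <= loose.n_impaired


def test_lower_min_domains_never_decreases_prevalence():
    rng = np.random.default_rng(0)
    flags = {f"s{i}": rng.integers(0, 2, 8).tolist() for i in range(60)}
    prev = []
    for k in (4, 3, 2, 1):
        rows = profiles_from_flags(flags)
        rows["clinically_impaired"] = rows["n_impaired"] >= k
        prev.append(prevalence(rows)[0])
    assert prev == sorted(prev)


def test_brute_force_transition_reconciliation():
    """Sampled 8-domain flag pairs: subject-level transitions implied by the
    clinical rule must reconcile with domain-level moves (a direct-counting
    oracle independent of transition_analysis)."""
    rng = np.random.default_rng(7)
    n = 400
    base_flags = rng.integers(0, 2, (n, 8))
    fup_flags = rng.integers(0, 2, (n, 8))
    b = profiles_from_flags({f"s{i}": base_flags[i].tolist() for i in range(n)})
    f = profiles_from_flags(
        {f"s{i}": fup_flags[i].tolist() for i in range(n)}, time=10.0
    )
    ts = transition_analysis(b, f, CFG)

    # oracle: direct counting on the raw flag matrices
    bi = base_flags.sum(axis=1) >= 2
    fi = fup_flags.sum(axis=1) >= 2
    improved = ((base_flags == 1) & (fup_flags == 0)).any(axis=1)
    declined = ((base_flags == 0) & (fup_flags == 1)).any(axis=1)
    n_imp = bi.sum()
    n_unimp = n - n_imp
    assert ts.n_baseline_impaired == n_imp
    assert ts.pct_improved_any_domain == pytest.approx(100 * improved[bi].mean())
    assert ts.pct_no_longer_impaired == pytest.approx(100 * (~fi[bi]).mean())
    assert ts.pct_additional_domains == pytest.approx(100 * declined[bi].mean())
    assert ts.pct_all_domains_at_follow_up == pytest.approx(
        100 * (fup_flags[bi].sum(axis=1) == 8).mean()
    )
    assert ts.pct_improved == pytest.approx(100 * improved[~bi].mean())
    assert ts.pct_declined == pytest.approx(100 * declined[~bi].mean())
    assert ts.pct_became_impaired == pytest.approx(100 * fi[~bi].mean())

    # logical implications of the clinical rule
    assert (~fi[bi] <= improved[bi]).all()  # no-longer-impaired => improved
    assert (fi[~bi] <= declined[~bi]).all()  # became-impaired => declined


def test_percentage_table_shape(small_cohort_df):
    from cogcourse import score_battery

    _, scores = score_battery(small_cohort_df)
    profiles = classify_profiles(scores, CFG)
    tbl = impairment_percentage_table(profiles, CFG)
    assert set(tbl["domain"]) == set(DOMAINS)
    assert len(tbl) == 2 * 2 * len(DOMAINS)  # group x wave x domain
    assert tbl["pct_impaired"].between(0, 100).all()
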