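"""Clinically significant cognitive impairment: flags, prevalence, transitions.

A domain is impaired when its z-score (control-baseline scale) falls strictly
below the cut-off (default -1.5 SD); a subject is clinically impaired when at
least ``min_domains`` (default 2) domains are impaired. The composite is
excluded from the domain count by default — it averages the domains, so
counting it would double-weight them. Follow-up impairment is judged against
the same baseline control norms used at baseline, which is what makes
prevalence comparable across waves.

The transition analysis stratifies subjects by baseline impairment status and
reports, within each stratum, the percentage improving beyond threshold on at
least one domain, no longer (or newly) meeting the clinical criterion,
accruing additional impaired domains, or impaired on every domain at
follow-up. All percentages are of the baseline stratum, complete two-wave
cases only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .battery import DEFAULT_DOMAINS


class ImpairmentError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    cutoff: float = -1.5
    min_domains: int = 2
    domains_considered: tuple[str, ...] = tuple(DEFAULT_DOMAINS)
    #: minimum observed domains required to classify a subject at all
    min_observed: int | None = None

    def __post_init__(self):
        if not self.cutoff < 0:
            raise ImpairmentError("cutoff must be negative (z-units below the norm mean)")
        if not 1 <= self.min_domains <= len(self.domains_considered):
            raise ImpairmentError(
                "min_domains must be between 1 and the number of domains considered"
            )

    @property
    def required_observed(self) -> int:
        return self.min_domains if self.min_observed is None else self.min_observed


@dataclass(frozen=True)
class ImpairmentProfile:
    subject_id: str
    time: float
    impaired_by_domain: dict[str, bool | None]
    n_impaired: int
    n_observed: int
    clinically_impaired: bool | None


def flag_impairment(z: float, config: ClassifierConfig) -> bool | None:
    """Strict threshold: impaired iff z < cutoff; missing z -> None."""
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return None
    return bool(z < config.cutoff)


def classify_subject(
    z_by_domain: dict[str, float],
    config: ClassifierConfig,
    subject_id: str = "",
    time: float = 0.0,
) -> ImpairmentProfile:
    """Flag each considered domain and derive the subject-level status.

    Missing domains are excluded from the impaired count (the exclusion is
    visible via ``n_observed``); a subject with fewer observed domains than
    the completeness rule requires gets status ``None``, never a silent
    "not impaired".
    """
    flags = {d: flag_impairment(z_by_domain.get(d, math.nan), config) for d in config.domains_considered}
    n_obs = sum(f is not None for f in flags.values())
    n_imp = sum(bool(f) for f in flags.values())
    status: bool | None
    if n_obs < config.required_observed:
        status = None
    else:
        status = n_imp >= config.min_domains
    return ImpairmentProfile(subject_id, time, flags, n_imp, n_obs, status)


def classify_profiles(
    domain_scores: pd.DataFrame, config: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Classify every subject x wave row of a domain-score table.

    Returns a table with per-domain impairment flags (``imp_<domain>``),
    the impaired-domain count and the subject-level status.
    """
    config = config or ClassifierConfig()
    rows = []
    for _, r in domain_scores.iterrows():
        prof = classify_subject(
            {d: r[d] for d in config.domains_considered if d in r.index},
            config,
            subject_id=str(r["subject_id"]),
            time=float(r["time_years"]),
        )
        row = {
            "subject_id": prof.subject_id,
            "group": r["group"],
            "time_years": prof.time,
            "n_impaired": prof.n_impaired,
            "n_observed": prof.n_observed,
            "clinically_impaired": prof.clinically_impaired,
        }
        for d, f in prof.impaired_by_domain.items():
            row[f"imp_{d}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def prevalence(profiles: pd.DataFrame) -> tuple[float, int]:
    """Percent of classifiable subjects who are clinically impaired, plus the
    denominator (subjects with a determinate status)."""
    if profiles.empty:
        raise ImpairmentError("no profiles supplied")
    status = profiles["clinically_impaired"].dropna()
    n = len(status)
    if n == 0:
        raise ImpairmentError("no classifiable subjects (all statuses missing)")
    return 100.0 * status.sum() / n, n


@dataclass(frozen=True)
class TransitionSummary:
    """Baseline-stratified follow-up transitions (percent of each stratum)."""

    n_baseline_impaired: int
    n_baseline_unimpaired: int
    n_excluded: int
    # within the baseline-impaired stratum
    pct_improved_any_domain: float = math.nan
    pct_no_longer_impaired: float = math.nan
    pct_additional_domains: float = math.nan
    pct_all_domains_at_follow_up: float = math.nan
    # within the baseline-unimpaired stratum
    pct_improved: float = math.nan
    pct_declined: float = math.nan
    pct_became_impaired: float = math.nan

    def to_frame(self) -> pd.DataFrame:
        recs = [
            ("impaired", "improved_any_domain", self.pct_improved_any_domain),
            ("impaired", "no_longer_impaired", self.pct_no_longer_impaired),
            ("impaired", "additional_domains", self.pct_additional_domains),
            ("impaired", "all_domains_at_follow_up", self.pct_all_domains_at_follow_up),
            ("unimpaired", "improved", self.pct_improved),
            ("unimpaired", "declined", self.pct_declined),
            ("unimpaired", "became_impaired", self.pct_became_impaired),
        ]
        return pd.DataFrame(recs, columns=["baseline_stratum", "transition", "pct"])


def transition_analysis(
    baseline_profiles: pd.DataFrame,
    followup_profiles: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> TransitionSummary:
    """Stratify by baseline status and tabulate domain- and subject-level
    transitions over complete two-wave cases.

    Domain-level: "improved beyond threshold" = impaired at baseline, not at
    follow-up (decline symmetric). Subject-level: "no longer impaired" /
    "became impaired" by the clinical criterion; "all domains at follow-up" =
    every considered domain impaired.
    """
    config = config or ClassifierConfig()
    doms = [f"imp_{d}" for d in config.domains_considered]
    b = baseline_profiles.set_index("subject_id")
    f = followup_profiles.set_index("subject_id")
    common = b.index.intersection(f.index)
    usable = [
        sid
        for sid in common
        if b.loc[sid, "clinically_impaired"] is not None
        and not (isinstance(b.loc[sid, "clinically_impaired"], float) and math.isnan(b.loc[sid, "clinically_impaired"]))
        and f.loc[sid, "clinically_impaired"] is not None
        and not (isinstance(f.loc[sid, "clinically_impaired"], float) and math.isnan(f.loc[sid, "clinically_impaired"]))
    ]
    n_excluded = len(set(b.index) | set(f.index)) - len(usable)
    imp_ids = [s for s in usable if bool(b.loc[s, "clinically_impaired"])]
    unimp_ids = [s for s in usable if not bool(b.loc[s, "clinically_impaired"])]

    def _domain_moves(sid):
        improved = declined = False
        for d in doms:
            fb, ff = b.loc[sid, d], f.loc[sid, d]
            if fb is None or ff is None:
                continue
            if bool(fb) and not bool(ff):
                improved = True
            if not bool(fb) and bool(ff):
                declined = True
        return improved, declined

    def pct(count, denom):
        return 100.0 * count / denom if denom else math.nan

    imp_improved = imp_nolonger = imp_additional = imp_all = 0
    for sid in imp_ids:
        improved, declined = _domain_moves(sid)
        imp_improved += improved
        imp_additional += declined  # reached criteria on >=1 new domain
        imp_nolonger += not bool(f.loc[sid, "clinically_impaired"])
        imp_all += int(f.loc[sid, "n_impaired"]) == len(config.domains_considered)
    un_improved = un_declined = un_became = 0
    for sid in unimp_ids:
        improved, declined = _domain_moves(sid)
        un_improved += improved
        un_declined += declined
        un_became += bool(f.loc[sid, "clinically_impaired"])

    return TransitionSummary(
        n_baseline_impaired=len(imp_ids),
        n_baseline_unimpaired=len(unimp_ids),
        n_excluded=n_excluded,
        pct_improved_any_domain=pct(imp_improved, len(imp_ids)),
        pct_no_longer_impaired=pct(imp_nolonger, len(imp_ids)),
        pct_additional_domains=pct(imp_additional, len(imp_ids)),
        pct_all_domains_at_follow_up=pct(imp_all, len(imp_ids)),
        pct_improved=pct(un_improved, len(unimp_ids)),
        pct_declined=pct(un_declined, len(unimp_ids)),
        pct_became_impaired=pct(un_became, len(unimp_ids)),
    )


def impairment_percentage_table(
    profiles: pd.DataFrame, config: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Per (group, wave, domain) percentage of subjects impaired — the shape
    used for per-domain impairment bar charts."""
    config = config or ClassifierConfig()
    rows = []
    for (grp, t), sub in profiles.groupby(["group", "time_years"], sort=True):
        for d in config.domains_considered:
            col = sub[f"imp_{d}"]
            known = col[col.notna()]
            rows.append(
                {
                    "group": grp,
                    "time_years": t,
                    "domain": d,
                    "pct_impaired": (
                        round(100.0 * known.astype(bool).sum() / len(known), 1)
                        if len(known)
                        else math.nan
                    ),
                    "n": len(known),
                }
            )
    return pd.DataFrame(rows)
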