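"""Control-baseline norms, z-scoring, and domain/composite construction.

Raw subtest scores are standardized against the healthy-control baseline
sample (mean/SD with the n-1 denominator), with timed "lower is better"
measures sign-flipped so that a higher z always means better performance.
Follow-up scores are standardized against the *baseline* control norms, not
refreshed follow-up norms, which keeps long-term change interpretable on a
single scale. Domain scores are means of member-subtest z-scores; the
cognitive composite is the mean of the domain scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import (
    COMPOSITE,
    DEFAULT_DIRECTIONS,
    DEFAULT_DOMAINS,
    GROUP_CONTROL,
    ID_COLUMNS,
    Direction,
)


class NormError(ValueError):
    """Norms cannot be built or applied for a named subtest."""


@dataclass(frozen=True)
class NormReference:
    """Per-subtest normative table: mean, SD, direction and norm-sample n."""

    table: pd.DataFrame  # index: subtest; columns: mean, sd, direction, n_norm

    def __post_init__(self):
        bad_sd = self.table.index[~(self.table["sd"] > 0)].tolist()
        if bad_sd:
            raise NormError(f"non-positive norm SD for subtest(s): {bad_sd}")
        bad_n = self.table.index[self.table["n_norm"] < 2].tolist()
        if bad_n:
            raise NormError(f"norm n < 2 for subtest(s): {bad_n}")

    @property
    def subtests(self) -> list[str]:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        self.table.rename_axis("subtest").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "NormReference":
        t = pd.read_csv(path).set_index("subtest")
        t["direction"] = t["direction"].map(Direction)
        return cls(t)


def build_norms(
    df: pd.DataFrame,
    directions: dict[str, Direction] | None = None,
    norm_group: str = GROUP_CONTROL,
    norm_time: float = 0.0,
) -> NormReference:
    """Compute per-subtest normative mean/SD from the ``norm_group`` rows at
    ``norm_time`` (by default: controls at baseline).

    Raises :class:`NormError`, naming the subtest, when a subtest has fewer
    than two non-missing normative observations or zero variance.
    """
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    subtests = [c for c in df.columns if c not in ID_COLUMNS]
    ref = df[(df["group"] == norm_group) & (df["time_years"] == norm_time)]
    if ref.empty:
        raise NormError(f"no rows for norm group {norm_group!r} at time {norm_time}")
    rows = {}
    for st in subtests:
        vals = ref[st].astype(float).dropna()
        if len(vals) < 2:
            raise NormError(f"subtest {st!r} has {len(vals)} normative observations (< 2)")
        sd = vals.std(ddof=1)
        if not sd > 0:
            raise NormError(f"subtest {st!r} has zero variance in the norm sample")
        rows[st] = {
            "mean": vals.mean(),
            "sd": sd,
            "direction": directions.get(st, Direction.higher_better),
            "n_norm": len(vals),
        }
    return NormReference(pd.DataFrame.from_dict(rows, orient="index"))


def zscore(df: pd.DataFrame, norms: NormReference) -> pd.DataFrame:
    """Replace raw subtest columns with z-scores on the norm scale.

    ``higher_better``: z = (raw - mean) / sd. ``lower_better`` (timed):
    z = (mean - raw) / sd, so higher z is always better. Missing values stay
    missing. Every non-missing subtest column must be covered by the norms.
    """
    subtests = [c for c in df.columns if c not in ID_COLUMNS]
    uncovered = [s for s in subtests if s not in norms.table.index and df[s].notna().any()]
    if uncovered:
        raise NormError(f"subtest(s) absent from norms: {uncovered}")
    out = df.copy()
    for st in subtests:
        if st not in norms.table.index:
            continue
        mean, sd, direction = norms.table.loc[st, ["mean", "sd", "direction"]]
        raw = out[st].astype(float)
        z = (raw - mean) / sd
        if direction == Direction.lower_better:
            z = -z
        out[st] = z
    return out


def compute_domain_scores(
    zdf: pd.DataFrame,
    domain_defs: dict[str, tuple[str, ...]] | None = None,
    min_domains_for_composite: int | None = None,
) -> pd.DataFrame:
    """Aggregate z-scored subtests into domain scores and the composite.

    Each domain score is the mean of its member subtests' z-scores that are
    present; a domain with all members missing stays missing. The composite
    is the mean of the available domain scores, but is set missing when
    fewer than ``min_domains_for_composite`` domains are observed (default:
    all domains required — the strict composite used for impairment and
    reliable-change analyses).
    """
    domain_defs = DEFAULT_DOMAINS if domain_defs is None else domain_defs
    if min_domains_for_composite is None:
        min_domains_for_composite = len(domain_defs)
    out = zdf[list(ID_COLUMNS)].copy()
    for domain, members in domain_defs.items():
        if not members:
            raise ValueError(f"domain {domain!r} has an empty member list")
        missing_members = [m for m in members if m not in zdf.columns]
        if missing_members:
            raise ValueError(f"domain {domain!r} members absent from battery: {missing_members}")
        out[domain] = zdf[list(members)].astype(float).mean(axis=1)
    dom_block = out[list(domain_defs)]
    out["n_domains_observed"] = dom_block.notna().sum(axis=1)
    composite = dom_block.mean(axis=1)
    composite[out["n_domains_observed"] < min_domains_for_composite] = np.nan
    out[COMPOSITE] = composite
    return out


def score_battery(
    df: pd.DataFrame,
    directions: dict[str, Direction] | None = None,
    domain_defs: dict[str, tuple[str, ...]] | None = None,
    norms: NormReference | None = None,
    min_domains_for_composite: int | None = None,
) -> tuple[NormReference, pd.DataFrame]:
    """Convenience wrapper: build norms (unless supplied), z-score, and
    compute domain scores. Returns ``(norms, domain_score_table)``."""
    if norms is None:
        norms = build_norms(df, directions=directions)
    zdf = zscore(df, norms)
    return norms, compute_domain_scores(
        zdf, domain_defs=domain_defs, min_domains_for_composite=min_domains_for_composite
    )
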