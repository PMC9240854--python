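"""Regression-based reliable change index (RCI) with practice-effect and
regression-to-the-mean correction.

Within each group and measure, observed change (follow-up minus baseline)
is regressed on the baseline score by ordinary least squares. Writing the
fitted line in centered form,

    predicted_change(x) = Ybar + B * (x - Xbar),

where Ybar is the group mean change (absorbing the practice effect), Xbar
the group baseline mean, and B the slope (capturing regression toward the
mean), the RCI limits for a subject with baseline x are

    predicted_change(x) -/+ z_crit * SEE,

with SEE the residual standard error of the change regression and z_crit
the two-sided standard-normal quantile for the confidence level (1.645 at
90 %). Change below the lower limit is a reliable decrease, above the upper
a reliable increase, otherwise stable; boundary ties count as stable.

A leverage-adjusted variant (prediction standard error inflated by
sqrt(1 + 1/n + (x - Xbar)^2 / Sxx)) is available via ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .battery import COMPOSITE, DEFAULT_DOMAINS

CATEGORIES = ("decrease", "stable", "increase")


class RCIError(ValueError):
    pass


@dataclass(frozen=True)
class RCIModel:
    """Parameters of one group x measure change-on-baseline regression."""

    group: str
    measure: str
    mean_change: float  # Ybar
    baseline_mean: float  # Xbar
    slope: float  # B
    see: float  # residual standard error
    n: int
    ci_level: float = 0.90
    z_crit: float = field(default=None)  # type: ignore[assignment]
    sxx: float = field(default=np.nan)  # centered baseline sum of squares

    def __post_init__(self):
        if not 0.0 < self.ci_level < 1.0:
            raise RCIError("ci_level must be in (0, 1)")
        if self.see < 0:
            raise RCIError("see must be >= 0")
        if self.z_crit is None:
            object.__setattr__(
                self, "z_crit", float(stats.norm.ppf(0.5 + self.ci_level / 2.0))
            )

    @property
    def degenerate(self) -> bool:
        """True when the regression fits perfectly (SEE = 0 up to floating
        roundoff); the RCI limits then collapse onto the prediction and
        every nonzero deviation flags."""
        return self.see <= 1e-12


def fit_rci_model(
    baseline: np.ndarray,
    followup: np.ndarray,
    group: str = "",
    measure: str = "",
    ci_level: float = 0.90,
) -> RCIModel:
    """OLS of change on baseline for one group's complete-case pairs."""
    baseline = np.asarray(baseline, float)
    followup = np.asarray(followup, float)
    if baseline.shape != followup.shape:
        raise RCIError("baseline and follow-up arrays differ in length")
    ok = ~(np.isnan(baseline) | np.isnan(followup))
    x = baseline[ok]
    change = followup[ok] - x
    n = len(x)
    if n < 3:
        raise RCIError(f"need >= 3 complete pairs, got {n}")
    xbar = float(x.mean())
    ybar = float(change.mean())
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise RCIError("baseline scores have zero variance")
    slope = float(np.sum((x - xbar) * (change - ybar)) / sxx)
    resid = change - (ybar + slope * (x - xbar))
    see = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return RCIModel(
        group=group,
        measure=measure,
        mean_change=ybar,
        baseline_mean=xbar,
        slope=slope,
        see=see,
        n=n,
        ci_level=ci_level,
        sxx=sxx,
    )


def rci_limits(
    model: RCIModel, baseline_i: float, method: str = "see"
) -> tuple[float, float, float]:
    """Individual predicted change and (lower, upper) RCI limits.

    ``method='see'`` uses the residual standard error as the half-width
    scale (the default construction); ``method='prediction'`` uses the
    leverage-adjusted standard error of a new observation's prediction.
    """
    predicted = model.mean_change + model.slope * (baseline_i - model.baseline_mean)
    if method == "see":
        scale = model.see
    elif method == "prediction":
        lev = 1.0 + 1.0 / model.n + (baseline_i - model.baseline_mean) ** 2 / model.sxx
        scale = model.see * float(np.sqrt(lev))
    else:
        raise RCIError(f"unknown RCI limit method: {method!r}")
    half = model.z_crit * scale
    return float(predicted), float(predicted - half), float(predicted + half)


def classify_change(observed_change: float, lower: float, upper: float) -> str:
    """Strict-inequality classification; boundary equality is stable."""
    if np.isnan(observed_change):
        raise RCIError("observed change is missing; exclude before classifying")
    if observed_change < lower:
        return "decrease"
    if observed_change > upper:
        return "increase"
    return "stable"


def rci_analysis(
    domain_scores: pd.DataFrame,
    measures: list[str] | None = None,
    baseline_time: float = 0.0,
    ci_level: float = 0.90,
    method: str = "see",
) -> tuple[list[RCIModel], pd.DataFrame, pd.DataFrame]:
    """Fit per-group, per-measure RCI models and classify every complete case.

    Returns ``(models, classifications, exclusions)``. ``classifications``
    has one row per subject x measure with baseline, observed and predicted
    change, limits, and category. ``exclusions`` counts subjects dropped per
    group x measure for missing either wave (never silently).
    """
    if measures is None:
        measures = list(DEFAULT_DOMAINS) + [COMPOSITE]
    models: list[RCIModel] = []
    rows = []
    excl = []
    for grp, gdf in domain_scores.groupby("group", sort=True):
        base = gdf[gdf["time_years"] == baseline_time].set_index("subject_id")
        fup = gdf[gdf["time_years"] != baseline_time].set_index("subject_id")
        for measure in measures:
            pair = pd.DataFrame(
                {"baseline": base[measure], "followup": fup[measure]}
            )
            complete = pair.dropna()
            excl.append(
                {
                    "group": grp,
                    "measure": measure,
                    "n_complete": len(complete),
                    "n_excluded": len(pair) - len(complete),
                }
            )
            model = fit_rci_model(
                complete["baseline"].to_numpy(),
                complete["followup"].to_numpy(),
                group=grp,
                measure=measure,
                ci_level=ci_level,
            )
            models.append(model)
            for sid, r in complete.iterrows():
                pred, lo, hi = rci_limits(model, r["baseline"], method=method)
                obs = r["followup"] - r["baseline"]
                rows.append(
                    {
                        "subject_id": sid,
                        "group": grp,
                        "measure": measure,
                        "baseline": r["baseline"],
                        "observed_change": obs,
                        "predicted_change": pred,
                        "lower": lo,
                        "upper": hi,
                        "category": classify_change(obs, lo, hi),
                    }
                )
    return models, pd.DataFrame(rows), pd.DataFrame(excl)


def summarize_rci(
    classifications: pd.DataFrame, models: list[RCIModel] | None = None
) -> pd.DataFrame:
    """Per group x measure summary: mean change, slope, and the percentage
    of complete cases with reliable decrease / increase (1-decimal), with
    stability as the exact complement before rounding."""
    by_model = {(m.group, m.measure): m for m in models} if models else {}
    rows = []
    for (grp, measure), sub in classifications.groupby(["group", "measure"], sort=True):
        n = len(sub)
        dec = 100.0 * (sub["category"] == "decrease").sum() / n
        inc = 100.0 * (sub["category"] == "increase").sum() / n
        model = by_model.get((grp, measure))
        rows.append(
            {
                "group": grp,
                "measure": measure,
                "n": n,
                "mean_change": round(
                    model.mean_change if model else sub["observed_change"].mean(), 3
                ),
                "slope": round(model.slope, 3) if model else np.nan,
                "pct_decrease": round(dec, 1),
                "pct_increase": round(inc, 1),
                "pct_stable": round(100.0 - dec - inc, 1),
            }
        )
    return pd.DataFrame(rows)
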