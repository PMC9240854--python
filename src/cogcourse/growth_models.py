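"""Random-intercept linear mixed growth models for two-wave cognitive data.

For each domain (or the composite) the group model is

    Y_ij = b1 + u_j + b2*time + b3*group + b4*age + b5*time:group
           + b6*time:age + e_ij

with a subject random intercept u_j (single variance component, i.e. a
scaled-identity G matrix), maximum-likelihood estimation, group coded
0 = control / 1 = patient, time in years since baseline, and baseline age
mean-centered on the analysis sample. Per-group growth curves drop the
group terms and are fitted within each group separately.

Fixed-effect p-values use a residual-df Wald t approximation
(df = n_obs - n_fixed_effects); Kenward-Roger/Satterthwaite df are not
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .battery import GROUP_CONTROL, GROUP_PATIENT

GROUP_TERMS = ("group", "time:group")
ALL_TERMS = ("intercept", "time", "group", "age", "time:group", "time:age")


class GrowthModelError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthModelSpec:
    """Which response to model and whether group terms are included."""

    response: str = "composite"
    include_group_terms: bool = True

    @property
    def terms(self) -> tuple[str, ...]:
        if self.include_group_terms:
            return ALL_TERMS
        return tuple(t for t in ALL_TERMS if t not in GROUP_TERMS)


@dataclass(frozen=True)
class GrowthFit:
    """Fixed effects, variance components and Wald tests from one fit."""

    response: str
    beta: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    random_intercept_var: float
    residual_var: float
    n_subjects: int
    n_obs: int
    df_resid: int
    converged: bool
    age_center: float
    time_range: tuple[float, float]
    group_label: str | None = field(default=None)  # set for per-group curves

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.beta),
                "estimate": list(self.beta.values()),
                "se": [self.se[k] for k in self.beta],
                "t": [self.t[k] for k in self.beta],
                "p": [self.p[k] for k in self.beta],
            }
        )


def _design(df: pd.DataFrame, terms: tuple[str, ...], age_center: float) -> np.ndarray:
    cols = {
        "intercept": np.ones(len(df)),
        "time": df["time_years"].to_numpy(float),
        "group": (df["group"] == GROUP_PATIENT).to_numpy(float),
        "age": df["baseline_age"].to_numpy(float) - age_center,
    }
    cols["time:group"] = cols["time"] * cols["group"]
    cols["time:age"] = cols["time"] * cols["age"]
    return np.column_stack([cols[t] for t in terms])


def fit_growth_model(
    domain_scores: pd.DataFrame,
    spec: GrowthModelSpec,
    age_center: float | None = None,
) -> GrowthFit:
    """ML fit of the growth model for ``spec.response``.

    Rows with a missing response are dropped. ``age_center`` defaults to the
    mean baseline age over the analysis rows; per-group curves fitted through
    :func:`fit_group_growth_curves` share the full-sample center so their
    intercepts are comparable.
    """
    if spec.response not in domain_scores.columns:
        raise GrowthModelError(f"response column {spec.response!r} not found")
    data = domain_scores.dropna(subset=[spec.response]).copy()
    if data.empty:
        raise GrowthModelError(f"no non-missing rows for response {spec.response!r}")
    groups_present = set(data["group"])
    if spec.include_group_terms and len(groups_present) < 2:
        raise GrowthModelError(
            "group terms requested but data contain a single group: "
            f"{sorted(groups_present)}"
        )
    if age_center is None:
        age_center = float(data["baseline_age"].mean())
    terms = spec.terms
    X = _design(data, terms, age_center)
    y = data[spec.response].to_numpy(float)
    subj = data["subject_id"].to_numpy()
    k = len(terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, X, groups=subj)
            res = model.fit(reml=False)
            fe = np.asarray(res.fe_params, float)
            bse = np.asarray(res.bse_fe, float)
            re_var = float(np.asarray(res.cov_re)[0, 0])
            resid_var = float(res.scale)
            converged = bool(res.converged)
    except np.linalg.LinAlgError:
        # Variance components unidentifiable (e.g. an exact linear fit):
        # the ML fixed effects coincide with least squares on the design.
        fe, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ fe
        resid_var = float(resid @ resid) / max(len(y) - k, 1)
        xtx_inv = np.linalg.pinv(X.T @ X)
        bse = np.sqrt(np.maximum(resid_var * np.diag(xtx_inv), 0.0))
        re_var = 0.0
        converged = False
    beta = dict(zip(terms, fe))
    se = dict(zip(terms, bse))
    tvals = {t: beta[t] / se[t] if se[t] > 0 else np.nan for t in terms}
    df_resid = max(len(y) - k, 1)
    pvals = {t: float(2 * stats.t.sf(abs(tvals[t]), df_resid)) for t in terms}
    return GrowthFit(
        response=spec.response,
        beta=beta,
        se=se,
        t=tvals,
        p=pvals,
        random_intercept_var=re_var,
        residual_var=resid_var,
        n_subjects=int(pd.unique(subj).size),
        n_obs=len(y),
        df_resid=df_resid,
        converged=converged,
        age_center=age_center,
        time_range=(float(data["time_years"].min()), float(data["time_years"].max())),
    )


def fit_group_growth_curves(
    domain_scores: pd.DataFrame, response: str = "composite"
) -> dict[str, GrowthFit]:
    """Fit the no-group-terms growth curve within each group separately.

    Age is centered on the full analysis sample (both groups), not within
    group, so group curves share the covariate reference point.
    """
    data = domain_scores.dropna(subset=[response])
    if data.empty:
        raise GrowthModelError(f"no non-missing rows for response {response!r}")
    age_center = float(data["baseline_age"].mean())
    spec = GrowthModelSpec(response=response, include_group_terms=False)
    fits: dict[str, GrowthFit] = {}
    for grp in (GROUP_PATIENT, GROUP_CONTROL):
        sub = data[data["group"] == grp]
        if sub.empty:
            continue
        fit = fit_growth_model(sub, spec, age_center=age_center)
        fits[grp] = GrowthFit(**{**fit.__dict__, "group_label": grp})
    return fits


def estimated_marginal_means(
    fit: GrowthFit, group: str, time: float, at_age: float | None = None
) -> float:
    """Model-predicted mean score for a group at a time point.

    Evaluated at ``at_age`` (default: the sample mean age used for
    centering). At the reference group (controls), time 0 and mean age this
    is the model intercept. Extrapolating beyond the observed time range
    emits a warning rather than an error.
    """
    lo, hi = fit.time_range
    if not lo <= time <= hi:
        warnings.warn(
            f"EMM requested at time {time} outside observed range [{lo}, {hi}]",
            stacklevel=2,
        )
    age_c = 0.0 if at_age is None else at_age - fit.age_center
    g = 1.0 if group == GROUP_PATIENT else 0.0
    value = fit.beta["intercept"] + fit.beta["time"] * time + fit.beta["age"] * age_c
    if "group" in fit.beta:
        value += fit.beta["group"] * g + fit.beta["time:group"] * time * g
    value += fit.beta["time:age"] * time * age_c
    return float(value)


def growth_summary_table(fits: dict[str, GrowthFit]) -> pd.DataFrame:
    """Tidy (measure, term, estimate, se, t, p) table over several fits."""
    frames = []
    for measure, fit in fits.items():
        f = fit.summary_frame()
        f.insert(0, "measure", measure)
        if fit.group_label is not None:
            f.insert(1, "group", fit.group_label)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
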