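"""Group, longitudinal and survival inference on pipeline metrics.

Cross-sectional contrasts use OLS with age, sex and education as
covariates; longitudinal change in the patient group uses a linear mixed
model with months from baseline as the continuous variable of interest and
a random intercept per subject (REML, maximum-likelihood fallback on
non-convergence); phenoconversion risk uses Cox proportional hazards on
the z-scored baseline metric (Breslow ties), with one model for conversion
to any synucleinopathy and one for conversion to DLB only (PD conversions
censored at conversion).  Multiple testing is controlled per declared
family with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import CohortTable, ValidationError

__all__ = [
    "CohortDesign",
    "ModelResult",
    "cross_sectional_glm",
    "longitudinal_lmm",
    "cox_conversion",
    "fdr_adjust",
]

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass
class CohortDesign:
    outcome: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    group_col: str = "group"
    time_col: str = "months_from_baseline"
    subject_col: str = "subject_id"
    family_id: str = "default"


@dataclass
class ModelResult:
    model_family: str
    term: str
    estimate: float
    standard_error: float
    statistic: float
    p_value: float
    conf_int: tuple[float, float]
    n_observations: int
    converged: bool = True
    hazard_ratio: float | None = None
    hazard_ratio_ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.conf_int
        if self.converged and not (lo - 1e-9 <= self.estimate <= hi + 1e-9):
            raise ValidationError("confidence interval does not bracket estimate")


def _design_matrix(df: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.unique())
            if len(levels) < 2:
                cols[cov] = np.zeros(len(df))
            else:
                # binary indicator for the second level (e.g. sex M vs F)
                cols[f"{cov}[{levels[1]}]"] = (col == levels[1]).astype(float)
        else:
            cols[cov] = col.astype(float)
    return pd.DataFrame(cols, index=df.index)


def cross_sectional_glm(
    metric: pd.Series,
    cohort: pd.DataFrame,
    design: CohortDesign,
) -> ModelResult:
    """OLS of a per-subject metric on group + covariates; reports the group term.

    ``metric`` is indexed by subject id and joined against the baseline rows
    of the cohort frame.  Excluded rows are never dropped silently: subjects
    missing either metric or covariates raise.
    """
    df = cohort.set_index(design.subject_col)
    missing = set(metric.index) - set(df.index)
    if missing:
        raise ValidationError(f"metric subjects absent from cohort: {sorted(missing)[:5]}")
    df = df.loc[metric.index].copy()
    df["_metric"] = metric
    if df[list(design.covariates)].isna().any().any():
        raise ValidationError("missing covariate values (no silent row dropping)")
    counts = df[design.group_col].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValidationError(f"need >= 2 subjects per group, got {counts.to_dict()}")
    x = _design_matrix(df, design.covariates)
    x.insert(0, "group_case", (df[design.group_col] == "case").astype(float))
    x = sm.add_constant(x)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    fit = sm.OLS(df["_metric"].astype(float), x).fit()
    ci = fit.conf_int().loc["group_case"]
    return ModelResult(
        model_family="ols_glm",
        term="group_case",
        estimate=float(fit.params["group_case"]),
        standard_error=float(fit.bse["group_case"]),
        statistic=float(fit.tvalues["group_case"]),
        p_value=float(fit.pvalues["group_case"]),
        conf_int=(float(ci[0]), float(ci[1])),
        n_observations=int(fit.nobs),
    )


def permutation_p(
    metric: pd.Series,
    cohort: pd.DataFrame,
    design: CohortDesign,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Label-permutation p value for the group term of the cross-sectional GLM."""
    observed = cross_sectional_glm(metric, cohort, design).statistic
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    hits = 0
    for _ in range(n_permutations):
        shuffled = df.copy()
        shuffled[design.group_col] = rng.permutation(
            df[design.group_col].to_numpy()
        )
        t = cross_sectional_glm(metric, shuffled, design).statistic
        if abs(t) >= abs(observed):
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def longitudinal_lmm(
    metric: pd.Series,
    cohort: pd.DataFrame,
    design: CohortDesign,
) -> ModelResult:
    """Random-intercept mixed model for change over months.

    ``metric`` is indexed like the cohort frame's rows (one value per
    subject-visit).  Fixed effects: months + covariates; random intercept
    per subject.  REML, with a maximum-likelihood refit if REML does not
    converge; a still-unconverged fit is returned flagged.
    """
    df = cohort.copy()
    df["_metric"] = np.asarray(metric, dtype=float)
    visit_counts = df.groupby(design.subject_col)[design.time_col].nunique()
    if (visit_counts < 2).all():
        raise ValidationError(
            "every subject has a single visit: time slope not identifiable"
        )
    x = _design_matrix(df, design.covariates)
    x.insert(0, "months", df[design.time_col].astype(float))
    x = sm.add_constant(x)
    model = sm.MixedLM(
        df["_metric"].astype(float), x, groups=df[design.subject_col]
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
        if not fit.converged:
            fit = model.fit(reml=False)
            converged = bool(fit.converged)
    ci = fit.conf_int().loc["months"]
    return ModelResult(
        model_family="lmm_random_intercept",
        term="months",
        estimate=float(fit.params["months"]),
        standard_error=float(fit.bse["months"]),
        statistic=float(fit.tvalues["months"]),
        p_value=float(fit.pvalues["months"]),
        conf_int=(float(ci[0]), float(ci[1])),
        n_observations=int(len(df)),
        converged=converged,
        extra={"reml": converged},
    )


def cox_conversion(
    metric: pd.Series,
    cohort: CohortTable | pd.DataFrame,
    endpoint: str = "any_synucleinopathy",
) -> ModelResult:
    """Cox proportional hazards of phenoconversion on a z-scored metric.

    ``endpoint='any_synucleinopathy'`` counts PD and DLB conversions as
    events; ``'dlb_only'`` counts DLB conversions, censoring PD converters
    at their conversion time.  The metric is z-scored across included
    subjects so the hazard ratio is per SD.
    """
    from lifelines import CoxPHFitter

    if endpoint not in ("any_synucleinopathy", "dlb_only"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    frame = cohort.frame if isinstance(cohort, CohortTable) else cohort
    base = frame[frame["group"] == "case"]
    base = base[base["months_from_baseline"] == 0].set_index("subject_id")
    missing = set(metric.index) - set(base.index)
    if missing:
        raise ValidationError(f"metric subjects absent from cohort: {sorted(missing)[:5]}")
    base = base.loc[metric.index]
    times = base["months_to_event_or_censor"].astype(float)
    if (times <= 0).any():
        raise ValidationError("non-positive event/censor times")
    if endpoint == "any_synucleinopathy":
        events = base["conversion_event"].isin(["PD", "DLB"])
    else:
        events = base["conversion_event"] == "DLB"
    if events.sum() == 0:
        raise ValidationError(f"no events for endpoint {endpoint!r}")
    m = np.asarray(metric, dtype=float)
    if m.std() == 0:
        raise ValidationError("zero-variance metric: z-scoring undefined")
    z = (m - m.mean()) / m.std()
    data = pd.DataFrame(
        {"duration": times.to_numpy(), "event": events.to_numpy().astype(int), "z": z}
    )
    cph = CoxPHFitter()
    cph.fit(data, duration_col="duration", event_col="event")
    beta = float(cph.params_["z"])
    se = float(cph.standard_errors_["z"])
    ci_low, ci_high = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return ModelResult(
        model_family=f"cox_{endpoint}",
        term="z_metric",
        estimate=beta,
        standard_error=se,
        statistic=beta / se,
        p_value=float(cph.summary.loc["z", "p"]),
        conf_int=(ci_low, ci_high),
        n_observations=int(len(data)),
        hazard_ratio=float(np.exp(beta)),
        hazard_ratio_ci=(float(np.exp(ci_low)), float(np.exp(ci_high))),
        extra={"n_events": int(events.sum())},
    )


def fdr_adjust(p_values, family_id: str = "default") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values within one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError(f"empty p-value family {family_id!r}")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
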