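"""Survival modelling: Cox screening, risk score, KM/log-rank, 5-year ROC.

Candidate lncRNAs are first screened one at a time with a proportional-
hazards model on median-dichotomized expression (high vs low, low as
reference).  Survivors enter a multivariate Cox fit on continuous
expression whose coefficients define the risk score

    RS = sum_i Exp_i * Coe_i,

with the training-set median RS as the cut-off between high- and low-risk
groups.  Groups are compared by Kaplan-Meier curves and the log-rank test,
and the score's discrimination at the 5-year horizon (1825 days) is
measured with a cumulative-case / dynamic-control ROC using inverse-
probability-of-censoring weights.  Follow-up is administratively truncated
at the horizon before every fit.

Cox models are fitted by lifelines (Newton-type maximization of the Efron
partial likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

HIGH = "high"
LOW = "low"
FIVE_YEARS_DAYS = 1825


@dataclass
class CoxModel:
    """Per-covariate estimates from a proportional-hazards fit."""

    covariate_names: list[str]
    beta: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # (n, 2): lower, upper on the HR scale
    pvalue: np.ndarray
    converged: bool

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "hr": self.hr,
                "hr_ci_low": self.ci95[:, 0],
                "hr_ci_high": self.ci95[:, 1],
                "pvalue": self.pvalue,
            },
            index=pd.Index(self.covariate_names, name="covariate"),
        )


@dataclass
class RiskModel:
    """Ordered lncRNA ids, their Cox coefficients, and the training cutoff."""

    lnc_ids: list[str]
    coefficients: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.lnc_ids) != len(self.coefficients):
            raise ValueError("lnc_ids and coefficients must have equal length")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


@dataclass
class RocCurve:
    """Time-dependent ROC curve at a fixed horizon."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    horizon: float


# -- cohort handling -------------------------------------------------------


def truncate_follow_up(
    clinical: pd.DataFrame, horizon: float = FIVE_YEARS_DAYS
) -> pd.DataFrame:
    """Administratively censor follow-up beyond ``horizon`` days."""
    out = clinical.copy()
    over = out["os_days"] > horizon
    out.loc[over, "os_days"] = horizon
    out.loc[over, "event"] = 0
    return out


def split_cohort(clinical: pd.DataFrame, seed: int) -> tuple[list[str], list[str]]:
    """Seeded random half split: ceil(n/2) training, floor(n/2) testing."""
    ids = np.asarray(clinical.index)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = -(-n // 2)
    train = ids[perm[:n_train]]
    test = ids[perm[n_train:]]
    return list(train), list(test)


def dichotomize_by_median(values: pd.Series) -> pd.Series:
    """Label samples high (value >= median) or low."""
    if len(values) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if values.nunique() == 1:
        raise ValueError("all values equal; median split is degenerate")
    med = values.median()
    return pd.Series(
        np.where(values >= med, HIGH, LOW), index=values.index, name=values.name
    )


# -- Cox fitting -----------------------------------------------------------


def fit_multivariate_cox(
    covariates: pd.DataFrame,
    durations: pd.Series,
    events: pd.Series,
) -> CoxModel:
    """Cox proportional-hazards fit (Efron ties) of ``covariates`` on survival.

    Raises on a constant covariate; a monotone partial likelihood (perfect
    separation) yields ``converged=False`` with NaN estimates.
    """
    constant = [c for c in covariates.columns if covariates[c].nunique() == 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    n_events = int(events.sum())
    if n_events < covariates.shape[1]:
        raise ValueError(
            f"{n_events} events cannot support {covariates.shape[1]} covariates"
        )
    df = covariates.copy()
    df["_duration"] = durations.loc[covariates.index]
    df["_event"] = events.loc[covariates.index]
    cph = CoxPHFitter()
    names = list(covariates.columns)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_duration", event_col="_event")
    except ConvergenceError:
        k = len(names)
        nan = np.full(k, np.nan)
        return CoxModel(names, nan, nan, np.full((k, 2), np.nan), nan, False)
    s = cph.summary.loc[names]
    return CoxModel(
        covariate_names=names,
        beta=s["coef"].to_numpy(),
        hr=s["exp(coef)"].to_numpy(),
        ci95=s[["exp(coef) lower 95%", "exp(coef) upper 95%"]].to_numpy(),
        pvalue=s["p"].to_numpy(),
        converged=True,
    )


def univariate_cox_screen(
    expr_values: pd.DataFrame,
    clinical: pd.DataFrame,
    candidates,
    alpha: float = 0.05,
    horizon: float = FIVE_YEARS_DAYS,
) -> tuple[list[str], dict[str, CoxModel]]:
    """Screen candidates one at a time on median-dichotomized expression.

    ``expr_values`` is lncRNAs x samples (normalized); only samples present
    in ``clinical`` are used.  Follow-up is truncated at ``horizon`` first.
    Returns the candidates with Wald p < ``alpha`` and every fitted model.
    A candidate whose fit does not converge is excluded with a warning.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate lncRNAs to screen")
    clin = truncate_follow_up(clinical, horizon)
    samples = [s for s in expr_values.columns if s in clin.index]
    clin = clin.loc[samples]
    selected: list[str] = []
    models: dict[str, CoxModel] = {}
    for lnc in candidates:
        groups = dichotomize_by_median(expr_values.loc[lnc, samples])
        x = pd.DataFrame({f"{lnc}_high": (groups == HIGH).astype(float)})
        model = fit_multivariate_cox(x, clin["os_days"], clin["event"])
        models[lnc] = model
        if not model.converged:
            warnings.warn(f"Cox fit for {lnc} did not converge; excluded",
                          stacklevel=2)
            continue
        if model.pvalue[0] < alpha:
            selected.append(lnc)
    return selected, models


# -- risk score ------------------------------------------------------------


def build_risk_model(
    expr_values: pd.DataFrame,
    clinical: pd.DataFrame,
    lnc_ids,
    horizon: float = FIVE_YEARS_DAYS,
) -> RiskModel:
    """Multivariate Cox on continuous expression; cutoff = median training RS.

    ``clinical`` defines the (training) samples used both for the fit and
    for the median cut-off.
    """
    lnc_ids = list(lnc_ids)
    clin = truncate_follow_up(clinical, horizon)
    samples = [s for s in expr_values.columns if s in clin.index]
    clin = clin.loc[samples]
    x = expr_values.loc[lnc_ids, samples].T.astype(float)
    model = fit_multivariate_cox(x, clin["os_days"], clin["event"])
    if not model.converged:
        raise RuntimeError("multivariate Cox fit for the risk model did not converge")
    rm = RiskModel(lnc_ids=lnc_ids, coefficients=model.beta, cutoff=0.0)
    scores = risk_score(rm, expr_values[samples])
    rm.cutoff = float(scores.median())
    return rm


def risk_score(model: RiskModel, expr_values: pd.DataFrame) -> pd.Series:
    """RS = sum_i Exp_i * Coe_i per sample (columns of ``expr_values``)."""
    missing = [g for g in model.lnc_ids if g not in expr_values.index]
    if missing:
        raise ValueError(f"expression matrix missing model lncRNAs: {missing}")
    x = expr_values.loc[model.lnc_ids].to_numpy(dtype=float)
    return pd.Series(
        model.coefficients @ x, index=expr_values.columns, name="risk_score"
    )


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """High risk when score >= cutoff, else low."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return pd.Series(
        np.where(scores >= cutoff, HIGH, LOW), index=scores.index, name="risk_group"
    )


# -- nonparametric comparison ---------------------------------------------


def kaplan_meier(
    durations: pd.Series, events: pd.Series, groups: pd.Series
) -> dict[str, tuple[pd.DataFrame, float]]:
    """Product-limit curve and median survival per group.

    The median is the smallest time at which S(t) <= 0.5; if the curve
    never reaches 0.5 the median is ``inf`` (not reached).
    """
    if groups.empty:
        raise ValueError("no group labels")
    out: dict[str, tuple[pd.DataFrame, float]] = {}
    for label in pd.unique(groups):
        idx = groups.index[groups == label]
        kmf = KaplanMeierFitter()
        kmf.fit(durations.loc[idx], events.loc[idx], label=str(label))
        sf = kmf.survival_function_
        sf.columns = ["survival"]
        out[str(label)] = (sf, float(kmf.median_survival_time_))
    return out


def logrank_test(
    durations: pd.Series, events: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and p-value."""
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    a = groups.index[groups == labels[0]]
    b = groups.index[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        durations.loc[a], durations.loc[b], events.loc[a], events.loc[b]
    )
    return float(res.test_statistic), float(res.p_value)


# -- time-dependent ROC ----------------------------------------------------


def _censoring_survival(durations: np.ndarray, events: np.ndarray) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, 1 - events)
    return kmf


def time_dependent_roc(
    scores: pd.Series,
    durations: pd.Series,
    events: pd.Series,
    horizon: float = FIVE_YEARS_DAYS,
) -> RocCurve:
    """Cumulative-case / dynamic-control ROC at ``horizon`` with IPCW.

    Cases are subjects with an observed event by the horizon, weighted by
    1/G(T-); controls are subjects still at risk beyond the horizon,
    weighted by 1/G(horizon), where G is the Kaplan-Meier estimate of the
    censoring survival function.  Tied scores contribute 1/2.  With no
    censoring the AUC reduces to the Mann-Whitney statistic of cases vs
    controls.
    """
    s = scores.to_numpy(dtype=float)
    t = durations.loc[scores.index].to_numpy(dtype=float)
    e = events.loc[scores.index].to_numpy(dtype=int)
    if horizon <= 0 or horizon > t.max():
        raise ValueError("horizon must be positive and within the follow-up range")
    case = (t <= horizon) & (e == 1)
    # a subject censored exactly at the horizon (administrative truncation)
    # is known event-free through the horizon and counts as a control
    control = (t > horizon) | ((t == horizon) & (e == 0))
    if not case.any() or not control.any():
        raise ValueError("need at least one case and one control at the horizon")

    G = _censoring_survival(t, e)
    eps = 1e-9
    g_case = G.survival_function_at_times(t[case] * (1 - eps)).to_numpy()
    # left limit at the horizon: with administrative censoring exactly at the
    # horizon G(horizon) can hit 0 even though controls were observed there
    g_ctrl = float(G.survival_function_at_times(horizon * (1 - eps)).iloc[0])
    w_case = np.where(g_case > 0, 1.0 / np.where(g_case > 0, g_case, 1.0), 0.0)
    w_ctrl = np.full(control.sum(), 1.0 / g_ctrl if g_ctrl > 0 else 0.0)

    sc, wc = s[case], w_case
    sn, wn = s[control], w_ctrl
    # weighted Mann-Whitney with 1/2 for ties
    diff = sc[:, None] - sn[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    wmat = wc[:, None] * wn[None, :]
    total = wmat.sum()
    auc = float((conc * wmat).sum() / total) if total > 0 else 0.5

    thresholds = np.unique(s)[::-1]
    tpr = np.array([(wc * (sc >= c)).sum() / wc.sum() for c in thresholds])
    fpr = np.array([(wn * (sn >= c)).sum() / wn.sum() for c in thresholds])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    thresholds = np.concatenate([[np.inf], thresholds])
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc, horizon=horizon)


# -- independence analysis -------------------------------------------------

INDEPENDENCE_VARIABLES = [
    "risk_score_high_vs_low",
    "age",
    "sex_male_vs_female",
    "weight",
    "grade_I+II_vs_III+IV",
    "stage_I+III_vs_II+IV",
]


def _independence_covariates(
    clinical: pd.DataFrame, risk_groups: pd.Series
) -> pd.DataFrame:
    clin = clinical.loc[risk_groups.index]
    return pd.DataFrame(
        {
            "risk_score_high_vs_low": (risk_groups == HIGH).astype(float),
            "age": clin["age"].astype(float),
            "sex_male_vs_female": (clin["sex"] == "male").astype(float),
            "weight": clin["weight"].astype(float),
            "grade_I+II_vs_III+IV": clin["grade"].isin([1, 2]).astype(float),
            "stage_I+III_vs_II+IV": clin["stage"].isin([1, 3]).astype(float),
        },
        index=risk_groups.index,
    )


def independence_analysis(
    clinical: pd.DataFrame,
    risk_groups: pd.Series,
    horizon: float = FIVE_YEARS_DAYS,
) -> pd.DataFrame:
    """Univariate and multivariate Cox fits of risk group plus clinical covariates.

    Covariate contrasts: risk high vs low, sex male vs female, grade I+II
    vs III+IV, stage I+III vs II+IV; age and weight continuous.  One row
    per explanatory variable, with hazard ratio, 95% CI and p-value from
    both the univariate and the joint fit.
    """
    clin = truncate_follow_up(clinical.loc[risk_groups.index], horizon)
    x = _independence_covariates(clin, risk_groups)
    durations, events = clin["os_days"], clin["event"]

    rows = {}
    for name in x.columns:
        uni = fit_multivariate_cox(x[[name]], durations, events)
        rows[name] = {
            "uni_hr": uni.hr[0],
            "uni_ci_low": uni.ci95[0, 0],
            "uni_ci_high": uni.ci95[0, 1],
            "uni_p": uni.pvalue[0],
        }
    multi = fit_multivariate_cox(x, durations, events)
    for i, name in enumerate(multi.covariate_names):
        rows[name].update(
            {
                "multi_beta": multi.beta[i],
                "multi_hr": multi.hr[i],
                "multi_ci_low": multi.ci95[i, 0],
                "multi_ci_high": multi.ci95[i, 1],
                "multi_p": multi.pvalue[i],
            }
        )
    report = pd.DataFrame.from_dict(rows, orient="index").loc[INDEPENDENCE_VARIABLES]
    report.index.name = "variable"
    return report
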