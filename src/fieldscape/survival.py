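"""Defect integration and survival analysis.

A patient carries "any defect" when at least one DNA platform meets its
trigger: moderate/high exome mutation burden, occult-tumor methylation,
or copy-number evidence ('evidence_of_tumor' from triplets or
'likely_evidence' from pairs). Field effects, small copy-number
evidence, low burden and RNA-only positivity do not trigger the flag.
Survival is summarized by Kaplan-Meier curves with a log-rank test and
by Cox proportional-hazards models with the stated covariates;
follow-up is administratively censored at 10 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from fieldscape.io_formats import (
    AGE_DECADES,
    ClinicalRecord,
    FieldscapeValidationError,
    NODE_LEVELS,
    STAGES,
    T_SIZES,
    TUMOR_SUBTYPES,
    clinical_to_frame,
)

DEFECT_EXOME = {"moderate", "high"}
DEFECT_METHYLATION = {"occult_tumor"}
DEFECT_CN = {"evidence_of_tumor", "likely_evidence"}

# reference level first; categorical covariates expand against these
REFERENCE_LEVELS = {
    "subtype": ["inactive", "active"],
    "node_status": ["negative", "positive"],
    "tumor_subtype": ["LumA", "LumB", "HER2", "Basal"],
    "stage": list(STAGES),
    "t_size": list(T_SIZES),
    "age_decade": list(AGE_DECADES),
    "any_defect": [False, True],
}

_AGE_MIDPOINTS = {"<40": 35.0, "40-49": 44.5, "50-59": 54.5, "60-69": 64.5, "70+": 75.0}


@dataclass(frozen=True)
class DefectProfile:
    patient_id: str
    methylation_category: str | None
    cn_category: str | None
    exome_category: str | None
    rna_mutation_positive: bool | None
    any_defect: bool | None
    contributing_platforms: tuple[str, ...] = ()


def integrate_defects(
    patient_id: str,
    methylation_category: str | None = None,
    cn_category: str | None = None,
    exome_category: str | None = None,
    rna_mutation_positive: bool | None = None,
) -> DefectProfile:
    """Combine per-platform calls into the any-defect flag.

    Missing platforms do not contribute; with no DNA platform at all the
    flag is undefined and the patient is excluded downstream.
    """
    platforms = []
    triggers = []
    if exome_category is not None:
        platforms.append("exome")
        triggers.append(exome_category in DEFECT_EXOME)
    if methylation_category is not None:
        platforms.append("methylation")
        triggers.append(methylation_category in DEFECT_METHYLATION)
    if cn_category is not None:
        platforms.append("cnv")
        triggers.append(cn_category in DEFECT_CN)
    any_defect = any(triggers) if platforms else None
    return DefectProfile(
        patient_id=patient_id,
        methylation_category=methylation_category,
        cn_category=cn_category,
        exome_category=exome_category,
        rna_mutation_positive=rna_mutation_positive,
        any_defect=any_defect,
        contributing_platforms=tuple(platforms),
    )


def defect_table(
    patients: list[str],
    methylation: pd.Series | None = None,
    cn: pd.Series | None = None,
    exome: pd.Series | None = None,
    rna: pd.Series | None = None,
) -> pd.DataFrame:
    def get(series: pd.Series | None, pid: str):
        if series is None or pid not in series.index:
            return None
        v = series[pid]
        return None if pd.isna(v) else v

    rows = []
    for pid in patients:
        prof = integrate_defects(
            pid,
            methylation_category=get(methylation, pid),
            cn_category=get(cn, pid),
            exome_category=get(exome, pid),
            rna_mutation_positive=get(rna, pid),
        )
        rows.append(
            {
                "patient_id": pid,
                "methylation": prof.methylation_category,
                "cnv": prof.cn_category,
                "exome": prof.exome_category,
                "rna_positive": prof.rna_mutation_positive,
                "any_defect": prof.any_defect,
                "platforms": ",".join(prof.contributing_platforms),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# survival


def _censor(df: pd.DataFrame, censor_at: float | None) -> pd.DataFrame:
    df = df.copy()
    if censor_at is not None:
        over = df["time_years"] > censor_at
        df.loc[over, "event"] = False
        df.loc[over, "time_years"] = censor_at
    return df


@dataclass
class SurvivalResult:
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_p: float | None = None
    logrank_stat: float | None = None
    cox_terms: pd.DataFrame | None = None
    n: int = 0
    n_events: int = 0


def km_fit(
    records: list[ClinicalRecord] | pd.DataFrame,
    groups: pd.Series,
    censor_at: float | None = 10.0,
) -> SurvivalResult:
    """Kaplan-Meier product-limit curves per group plus the log-rank test."""
    df = records if isinstance(records, pd.DataFrame) else clinical_to_frame(records)
    df = df.join(groups.rename("group"), how="inner").dropna(subset=["group"])
    df = _censor(df, censor_at)
    if df["event"].sum() == 0:
        raise FieldscapeValidationError("no events after censoring")
    result = SurvivalResult(n=len(df), n_events=int(df["event"].sum()))
    for g, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            raise FieldscapeValidationError(f"group {g!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], event_observed=sub["event"].astype(int), label=str(g))
        curve = kmf.survival_function_.rename(columns={str(g): "survival"})
        curve["at_risk"] = kmf.event_table["at_risk"].reindex(curve.index)
        result.km_curves[str(g)] = curve
    if df["group"].nunique() >= 2:
        lr = multivariate_logrank_test(
            df["time_years"], df["group"], df["event"].astype(int)
        )
        result.logrank_p = float(lr.p_value)
        result.logrank_stat = float(lr.test_statistic)
    return result


def _encode_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov not in df.columns:
            raise FieldscapeValidationError(f"missing covariate {cov!r}")
        col = df[cov]
        levels = REFERENCE_LEVELS.get(cov)
        if levels is None or col.dtype.kind in "fi":
            X[cov] = col.astype(float)
            continue
        if col.dtype.kind == "b" or set(col.dropna().unique()) <= {True, False}:
            X[cov] = col.astype(float)
            continue
        present = [l for l in levels if l in set(col.dropna())]
        for level in present[1:]:  # first present level is the reference
            X[f"{cov}[{level}]"] = (col == level).astype(float).mask(col.isna())
    return X


def cox_fit(
    records: list[ClinicalRecord] | pd.DataFrame,
    covariates: list[str],
    extra: pd.DataFrame | None = None,
    er_filter: bool = False,
    ties: str = "efron",
    censor_at: float | None = 10.0,
) -> SurvivalResult:
    """Cox proportional-hazards fit with Wald 95% CIs per term.

    Categorical covariates expand against fixed reference levels
    (inactive subtype, node-negative, LumA, stage I, T1, age <40, no
    defect). Patients missing any covariate are complete-case excluded.
    """
    df = records if isinstance(records, pd.DataFrame) else clinical_to_frame(records)
    if extra is not None:
        df = df.join(extra, how="left")
    if er_filter:
        df = df[df["er_status"] == "positive"]
    df = _censor(df, censor_at)
    X = _encode_covariates(df, covariates)
    data = pd.concat([df[["time_years", "event"]], X], axis=1).dropna()
    n_events = int(data["event"].sum())
    if n_events == 0:
        raise FieldscapeValidationError("zero events; Cox model undefined")
    if n_events < X.shape[1]:
        raise FieldscapeValidationError(
            f"{n_events} events for {X.shape[1]} parameters; reduce the covariate set"
        )
    data = data.astype(float)
    if ties == "efron":
        cph = CoxPHFitter()
        try:
            cph.fit(data, duration_col="time_years", event_col="event")
        except Exception as exc:  # lifelines raises ConvergenceError subclasses
            raise FieldscapeValidationError(f"Cox fit failed: {exc}") from exc
        summary = cph.summary
        terms = pd.DataFrame(
            {
                "coef": summary["coef"],
                "hazard_ratio": summary["exp(coef)"],
                "ci_low": summary["exp(coef) lower 95%"],
                "ci_high": summary["exp(coef) upper 95%"],
                "p": summary["p"],
            }
        )
    elif ties == "breslow":
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        y = np.array(
            [(bool(e), t) for e, t in zip(data["event"], data["time_years"])],
            dtype=[("event", bool), ("time", float)],
        )
        Xmat = data.drop(columns=["time_years", "event"])
        est = CoxPHSurvivalAnalysis(ties="breslow")
        est.fit(Xmat.to_numpy(), y)
        coef = est.coef_
        # Wald CIs from the inverse information matrix
        from numpy.linalg import inv

        se = np.sqrt(np.diag(inv(_breslow_information(est, Xmat.to_numpy(), y))))
        z = coef / se
        terms = pd.DataFrame(
            {
                "coef": coef,
                "hazard_ratio": np.exp(coef),
                "ci_low": np.exp(coef - 1.959963984540054 * se),
                "ci_high": np.exp(coef + 1.959963984540054 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=Xmat.columns,
        )
    else:
        raise FieldscapeValidationError(f"unknown tie method {ties!r}")
    result = SurvivalResult(cox_terms=terms, n=len(data), n_events=n_events)
    return result


def _breslow_information(est, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Observed information of the Breslow partial likelihood at the fit."""
    beta = est.coef_
    times = y["time"]
    events = y["event"]
    order = np.argsort(times)
    X, times, events = X[order], times[order], events[order]
    eta = X @ beta
    w = np.exp(eta)
    info = np.zeros((X.shape[1], X.shape[1]))
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        wr = w[risk]
        xr = X[risk]
        s0 = wr.sum()
        s1 = xr.T @ wr
        s2 = (xr * wr[:, None]).T @ xr
        xbar = s1 / s0
        info += s2 / s0 - np.outer(xbar, xbar)
    return info


def sensitivity_exclude_stage(
    records: pd.DataFrame,
    covariates: list[str],
    exclude_stages: set[str] = frozenset({"IV"}),
    raw_stage_col: str = "raw_stage",
    **cox_kwargs,
) -> tuple[SurvivalResult, SurvivalResult]:
    """Primary Cox fit and a refit excluding the named raw stages."""
    primary = cox_fit(records, covariates, **cox_kwargs)
    if raw_stage_col in records.columns:
        kept = records[~records[raw_stage_col].isin(exclude_stages)]
    else:
        kept = records
    if len(kept) == len(records):
        return primary, primary
    return primary, cox_fit(kept, covariates, **cox_kwargs)


# ---------------------------------------------------------------------------
# association battery


def association_tests(df: pd.DataFrame, subtype_col: str = "subtype") -> pd.DataFrame:
    """Subtype vs clinical factors: chi-square when expected counts allow,
    Fisher exact for sparse 2x2 tables, pooled t-test for age."""
    rows = []
    for factor in ("node_status", "tumor_subtype", "stage", "t_size", "any_defect"):
        if factor not in df.columns:
            continue
        sub = df[[subtype_col, factor]].dropna()
        table = pd.crosstab(sub[subtype_col], sub[factor])
        if table.size == 0 or min(table.shape) < 2:
            continue
        expected = stats.contingency.expected_freq(table)
        if (expected >= 5).all():
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            test = "chi_square"
        elif table.shape == (2, 2):
            stat, p = stats.fisher_exact(table)
            test = "fisher_exact"
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            test = "chi_square_low_expected"
        rows.append({"factor": factor, "test": test, "statistic": float(stat), "p": float(p)})
    if "age_decade" in df.columns:
        sub = df[[subtype_col, "age_decade"]].dropna()
        age = sub["age_decade"].map(_AGE_MIDPOINTS)
        groups = [age[sub[subtype_col] == g] for g in sorted(sub[subtype_col].unique())]
        if len(groups) == 2 and all(len(g) >= 2 for g in groups):
            stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
            rows.append(
                {"factor": "age", "test": "pooled_t", "statistic": float(stat), "p": float(p)}
            )
    return pd.DataFrame(rows).set_index("factor")
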