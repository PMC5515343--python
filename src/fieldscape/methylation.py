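"""Occult-tumor and field-effect detection from adjacent-normal methylation.

Per sample, adjacent beta values are regressed on the matched tumor beta
values across probes hyper-methylated in tumors. A steep slope (>0.4)
indicates tumor-like methylation; among those, a low residual standard
error marks occult tumor cells while a noisy fit is read as a field
(cancerization) effect. Samples are ranked by (slope desc, residual s.e.
asc) to order them from high to low occult-tumor probability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fieldscape.io_formats import FieldscapeValidationError, MatrixTable

MIN_REGRESSION_PROBES = 10


@dataclass(frozen=True)
class ProbeSet:
    """Tumor-vs-normal differential probes: hyper and hypo lists with scores."""

    hyper_probes: tuple[str, ...]
    hypo_probes: tuple[str, ...]
    diff_scores: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.hyper_probes) & set(self.hypo_probes):
            raise FieldscapeValidationError("hyper and hypo probe lists overlap")
        for p in self.hyper_probes:
            if self.diff_scores[p] <= 0:
                raise FieldscapeValidationError(f"hyper probe {p} has non-positive diff")
        for p in self.hypo_probes:
            if self.diff_scores[p] >= 0:
                raise FieldscapeValidationError(f"hypo probe {p} has non-negative diff")


@dataclass(frozen=True)
class OccultRegressionResult:
    sample_id: str
    slope: float
    intercept: float
    residual_se: float
    n_probes: int
    category: str | None = None  # occult_tumor | field_effect | normal


def select_differential_probes(
    tumor_matrix: MatrixTable,
    normal_matrix: MatrixTable,
    n_hyper: int = 500,
    n_hypo: int = 500,
) -> ProbeSet:
    """Rank probes by mean(tumor) - mean(normal); take the extremes.

    Ties are broken lexicographically by probe id; zero-difference probes
    never qualify for either list.
    """
    shared = tumor_matrix.values.index.intersection(normal_matrix.values.index)
    if len(shared) < n_hyper + n_hypo:
        raise FieldscapeValidationError(
            f"only {len(shared)} shared probes; need {n_hyper + n_hypo}"
        )
    diff = (
        tumor_matrix.values.loc[shared].mean(axis=1)
        - normal_matrix.values.loc[shared].mean(axis=1)
    )
    diff = diff.sort_index()  # lexicographic tie-break baseline
    pos = diff[diff > 0].sort_values(ascending=False, kind="stable")
    neg = diff[diff < 0].sort_values(ascending=True, kind="stable")
    if len(pos) < n_hyper or len(neg) < n_hypo:
        raise FieldscapeValidationError(
            f"insufficient signed differences: {len(pos)} positive (need {n_hyper}), "
            f"{len(neg)} negative (need {n_hypo})"
        )
    hyper = tuple(pos.index[:n_hyper])
    hypo = tuple(neg.index[:n_hypo])
    scores = {p: float(diff[p]) for p in hyper + hypo}
    return ProbeSet(hyper_probes=hyper, hypo_probes=hypo, diff_scores=scores)


def fit_occult_regression(
    adjacent_betas: pd.Series,
    tumor_betas: pd.Series,
    probes: ProbeSet,
    sample_id: str = "",
) -> OccultRegressionResult:
    """OLS of adjacent on tumor betas over the hyper-methylated probes."""
    idx = pd.Index(probes.hyper_probes)
    y = adjacent_betas.reindex(idx).to_numpy(dtype=float)
    x = tumor_betas.reindex(idx).to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < MIN_REGRESSION_PROBES:
        raise FieldscapeValidationError(
            f"{sample_id}: only {n} usable probes (need >= {MIN_REGRESSION_PROBES})"
        )
    if np.ptp(x) == 0:
        raise FieldscapeValidationError(
            f"{sample_id}: tumor betas have zero variance; slope undefined"
        )
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rse = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return OccultRegressionResult(
        sample_id=sample_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_se=rse,
        n_probes=n,
    )


def classify_methylation(
    result: OccultRegressionResult,
    slope_threshold: float = 0.4,
    rse_threshold: float = 1.0,
) -> OccultRegressionResult:
    """Apply the slope/residual-s.e. thresholds (strict inequalities).

    slope > threshold with residual s.e. below the cutoff -> occult_tumor;
    slope > threshold with a noisy fit -> field_effect; otherwise normal.
    """
    if not (np.isfinite(result.slope) and np.isfinite(result.residual_se)):
        raise FieldscapeValidationError(f"{result.sample_id}: non-finite fit")
    if result.slope > slope_threshold:
        category = "occult_tumor" if result.residual_se < rse_threshold else "field_effect"
    else:
        category = "normal"
    return replace(result, category=category)


def rank_samples(results: Sequence[OccultRegressionResult]) -> list[OccultRegressionResult]:
    """Order from high to low occult-tumor probability."""
    return sorted(results, key=lambda r: (-r.slope, r.residual_se, r.sample_id))


def analyze_cohort(
    tumor_matrix: MatrixTable,
    adjacent_matrix: MatrixTable,
    normal_matrix: MatrixTable | None = None,
    n_hyper: int = 500,
    n_hypo: int = 500,
    slope_threshold: float = 0.4,
    rse_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-sample occult regression and classification for a cohort.

    The reference normal panel defaults to the adjacent cohort itself
    (the tumor-vs-normal contrast used for probe selection).
    """
    if normal_matrix is None:
        normal_matrix = adjacent_matrix
    probes = select_differential_probes(tumor_matrix, normal_matrix, n_hyper, n_hypo)
    shared_samples = [
        s for s in adjacent_matrix.sample_ids if s in set(tumor_matrix.sample_ids)
    ]
    results = []
    for s in shared_samples:
        res = fit_occult_regression(
            adjacent_matrix.values[s], tumor_matrix.values[s], probes, sample_id=s
        )
        results.append(classify_methylation(res, slope_threshold, rse_threshold))
    ordered = rank_samples(results)
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "slope": r.slope,
                "intercept": r.intercept,
                "residual_se": r.residual_se,
                "n_probes": r.n_probes,
                "category": r.category,
            }
            for r in ordered
        ]
    ).set_index("sample_id")


def cellularity_confound_check(
    adjacent_matrix: MatrixTable,
    probes: ProbeSet,
    cellularity: pd.Series,
) -> tuple[float, float]:
    """Pearson correlation of per-sample median hyper-probe beta vs cellularity.

    A near-zero correlation argues the occult call is not a cellularity
    artifact.
    """
    med = adjacent_matrix.values.loc[list(probes.hyper_probes)].median(axis=0)
    joined = pd.concat([med.rename("median_beta"), cellularity.rename("cellularity")], axis=1).dropna()
    if len(joined) < 3:
        raise FieldscapeValidationError("need >=3 samples with cellularity")
    if joined["median_beta"].nunique() == 1 or joined["cellularity"].nunique() == 1:
        raise FieldscapeValidationError("constant vector; correlation undefined")
    r, p = stats.pearsonr(joined["median_beta"], joined["cellularity"])
    return float(r), float(p)
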