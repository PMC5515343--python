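"""Somatic SNV filter cascade and adjacent-normal mutation burden.

A tumor-derived SNV survives the cascade when all three compartments
(tumor, blood, adjacent normal) reach >= 20x coverage, the tumor VAF
exceeds 10%, the tumor-vs-blood contrast is significant by a two-sided
Fisher exact test (p < 0.05), and the variant is absent from blood
(VAF < 5%). Burden in the adjacent normal is then tiered from the
fraction of detected variants with VAF > 1%, and RNA-level expression of
tumor mutations is scored from read support at the same loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd

from fieldscape.io_formats import FieldscapeValidationError

_REL_TIE_TOL = 1.0 + 1e-7  # standard relative gate for two-sided mass inclusion


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    # P(X = a) for X ~ Hypergeom(N = row1+row2, K = row1, n = col1)
    n_total = row1 + row2
    return (
        lgamma(row1 + 1) - lgamma(a + 1) - lgamma(row1 - a + 1)
        + lgamma(row2 + 1) - lgamma(col1 - a + 1) - lgamma(row2 - col1 + a + 1)
        - (lgamma(n_total + 1) - lgamma(col1 + 1) - lgamma(n_total - col1 + 1))
    )


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums the hypergeometric probabilities of all tables (with the same
    margins) no more probable than the observed one, using the standard
    1+1e-7 relative tolerance for ties.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise FieldscapeValidationError("negative cell in 2x2 table")
    row1, row2, col1 = a + b, c + d, a + c
    if row1 == 0 or row2 == 0 or col1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, col1 - row2), min(col1, row1)
    logp = np.array([_log_hypergeom_pmf(x, row1, row2, col1) for x in range(lo, hi + 1)])
    p = np.exp(logp - logp.max())
    obs = p[a - lo]
    total = p.sum()
    return float(min(1.0, p[p <= obs * _REL_TIE_TOL].sum() / total))


@dataclass(frozen=True)
class BurdenCall:
    patient_id: str
    n_detected: int
    frac_vaf_gt_1pct: float
    category: str  # high | moderate | low | none


def _vaf(alt: pd.Series, depth: pd.Series) -> pd.Series:
    return alt.where(depth > 0, 0) / depth.where(depth > 0, 1)


def annotate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Add per-compartment depths and VAFs to a pileup table."""
    df = variants.copy()
    for comp in ("t", "b", "n", "rna"):
        df[f"{comp}_depth"] = df[f"{comp}_ref"] + df[f"{comp}_alt"]
        df[f"{comp}_vaf"] = _vaf(df[f"{comp}_alt"], df[f"{comp}_depth"])
    return df


def filter_somatic_snvs(
    variants: pd.DataFrame,
    min_cov: int = 20,
    min_tumor_vaf: float = 0.10,
    max_p: float = 0.05,
    max_blood_vaf: float = 0.05,
) -> pd.DataFrame:
    """Apply the somatic filter cascade; returns the annotated table.

    Adds ``fisher_p``, ``passes_somatic_filter`` and ``fail_reason``.
    Insufficient coverage is a failure reason, never an exception.
    """
    df = annotate_variants(variants)
    cov_ok = (
        (df["t_depth"] >= min_cov)
        & (df["b_depth"] >= min_cov)
        & (df["n_depth"] >= min_cov)
    )
    df["fisher_p"] = [
        fisher_exact_two_sided([[row.t_alt, row.t_ref], [row.b_alt, row.b_ref]])
        for row in df.itertuples(index=False)
    ]
    vaf_ok = df["t_vaf"] > min_tumor_vaf
    p_ok = df["fisher_p"] < max_p
    blood_ok = df["b_vaf"] < max_blood_vaf
    df["passes_somatic_filter"] = cov_ok & vaf_ok & p_ok & blood_ok
    reason = np.select(
        [~cov_ok, ~vaf_ok, ~p_ok, ~blood_ok],
        ["insufficient_coverage", "low_tumor_vaf", "fisher_not_significant",
         "present_in_blood"],
        default="",
    )
    df["fail_reason"] = reason
    return df


def classify_exome_burden(
    passing: pd.DataFrame,
    patient_id: str = "",
    adjacent_detection_floor_alt_reads: int = 2,
    vaf_threshold: float = 0.01,
    denominator: str = "detected",
) -> BurdenCall:
    """Tier adjacent-normal mutation burden from detected-variant VAFs.

    A variant is detected when its adjacent alt-read count reaches the
    floor (default 2). Precedence over the fraction of variants with VAF
    above 1% (denominator: detected-in-adjacent by default, or "all"
    filter-passing tumor mutations): fewer than 2 detected -> none;
    fraction >= 0.5 -> high; fraction <= 0.1 -> low; otherwise moderate.
    """
    if denominator not in ("detected", "all"):
        raise FieldscapeValidationError(f"unknown denominator {denominator!r}")
    if len(passing) and "n_vaf" not in passing.columns:
        passing = annotate_variants(passing)
    detected = passing[passing["n_alt"] >= adjacent_detection_floor_alt_reads] if len(passing) else passing
    n_detected = int(len(detected))
    if n_detected < 2:
        return BurdenCall(patient_id, n_detected, 0.0, "none")
    pool = detected if denominator == "detected" else passing
    frac = float((pool["n_vaf"] > vaf_threshold).mean())
    if frac >= 0.5:
        category = "high"
    elif frac <= 0.1:
        category = "low"
    else:
        category = "moderate"
    return BurdenCall(patient_id, n_detected, frac, category)


@dataclass(frozen=True)
class RnaMutationScore:
    expressed_fraction: float | None
    mutant_expressed_fraction: float | None
    n_present: int
    positive: bool


def rna_mutation_score(
    variants: pd.DataFrame,
    min_rna_depth: int = 10,
    min_var_reads: int = 2,
) -> RnaMutationScore:
    """Score RNA expression of tumor mutations in the adjacent tissue.

    A locus is expressed at >= 10x RNA depth; it is "present" with >= 2
    variant-supporting reads; a sample with >= 2 present loci is positive.
    """
    df = annotate_variants(variants) if "rna_depth" not in variants.columns else variants
    if len(df) == 0:
        return RnaMutationScore(None, None, 0, False)
    expressed = df["rna_depth"] >= min_rna_depth
    present = expressed & (df["rna_alt"] >= min_var_reads)
    n_present = int(present.sum())
    if expressed.sum() == 0:
        return RnaMutationScore(None, None, n_present, n_present >= 2)
    return RnaMutationScore(
        expressed_fraction=float(expressed.mean()),
        mutant_expressed_fraction=float(present.sum() / expressed.sum()),
        n_present=n_present,
        positive=n_present >= 2,
    )


def tumor_gene_recurrence_report(
    variants: pd.DataFrame,
    gene_annotations: pd.DataFrame,
    adjacent_detection_floor_alt_reads: int = 2,
) -> pd.DataFrame:
    """Per-gene counts of tumor mutations detected in the adjacent normal.

    ``gene_annotations`` maps (chrom, pos) to gene symbols; unannotated
    variants are dropped. Columns: n_tumor, n_detected_in_adjacent,
    max_adjacent_vaf, n_below_1pct (detected with VAF < 1%).
    """
    df = annotate_variants(variants)
    df = df.merge(gene_annotations[["chrom", "pos", "gene"]], on=["chrom", "pos"])
    if df.empty:
        return pd.DataFrame(
            columns=["n_tumor", "n_detected_in_adjacent", "max_adjacent_vaf", "n_below_1pct"]
        )
    df["detected"] = df["n_alt"] >= adjacent_detection_floor_alt_reads

    def summarize(g: pd.DataFrame) -> pd.Series:
        det = g[g["detected"]]
        return pd.Series(
            {
                "n_tumor": len(g),
                "n_detected_in_adjacent": len(det),
                "max_adjacent_vaf": float(det["n_vaf"].max()) if len(det) else 0.0,
                "n_below_1pct": int((det["n_vaf"] < 0.01).sum()),
            }
        )

    out = df.groupby("gene").apply(summarize, include_groups=False)
    out[["n_tumor", "n_detected_in_adjacent", "n_below_1pct"]] = out[
        ["n_tumor", "n_detected_in_adjacent", "n_below_1pct"]
    ].astype(int)
    return out.sort_index()


def burden_table(variants: pd.DataFrame, **filter_kwargs) -> pd.DataFrame:
    """Filter cascade + burden call + RNA score for every patient."""
    rows = []
    for patient, group in variants.groupby("patient", sort=True):
        filtered = filter_somatic_snvs(group, **filter_kwargs)
        passing = filtered[filtered["passes_somatic_filter"]]
        call = classify_exome_burden(passing, patient_id=str(patient))
        rna = rna_mutation_score(passing)
        rows.append(
            {
                "patient_id": patient,
                "n_somatic": len(group),
                "n_passing": len(passing),
                "n_detected": call.n_detected,
                "frac_vaf_gt_1pct": call.frac_vaf_gt_1pct,
                "category": call.category,
                "rna_n_present": rna.n_present,
                "rna_positive": rna.positive,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
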