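"""Expression subtyping of cancer-adjacent tissue.

Pipeline: library-size (RPM) or upper-quartile normalization, an
expression floor for miR mature strands, variance-based feature
selection, NMF consensus clustering (Brunet multiplicative updates under
a KL objective, repeated over random restarts; co-clustering frequencies
form the consensus matrix), silhouette widths computed on 1 - consensus,
permutation (SAM-style) Wilcoxon differential abundance with a plug-in
FDR, fold-change/abundance filters, nearest-centroid active/inactive
assignment, and mRNA-miR cluster concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr

from fieldscape.io_formats import FieldscapeValidationError, MatrixTable

# ---------------------------------------------------------------------------
# normalization and feature selection


def upper_quartile_normalize(matrix: MatrixTable) -> MatrixTable:
    """Divide each sample by its 75th percentile over nonzero features,
    then rescale by the median of those upper quartiles so magnitudes stay
    comparable across samples."""
    df = matrix.values
    uqs = {}
    for s in df.columns:
        col = df[s].to_numpy(dtype=float)
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise FieldscapeValidationError(f"sample {s!r} has no nonzero features")
        uqs[s] = np.percentile(nonzero, 75)
    uq = pd.Series(uqs)
    scaled = df.div(uq, axis=1) * float(uq.median())
    return MatrixTable(values=scaled, value_kind="uq_normalized")


def rpm_normalize(matrix: MatrixTable) -> MatrixTable:
    """Scale each sample to one million total reads."""
    sums = matrix.values.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise FieldscapeValidationError(f"sample {bad!r} has zero total count")
    return MatrixTable(values=matrix.values.div(sums, axis=1) * 1e6, value_kind="rpm")


def filter_expressed_mirs(
    matrix: MatrixTable, min_mean_rpm: float = 1.0, min_libraries: int = 10
) -> MatrixTable:
    """Keep mature strands with RPM >= threshold in enough libraries."""
    keep = (matrix.values >= min_mean_rpm).sum(axis=1) >= min_libraries
    if not keep.any():
        raise FieldscapeValidationError("no features pass the expression floor")
    return MatrixTable(values=matrix.values.loc[keep], value_kind=matrix.value_kind)


def select_variable_features(
    matrix: MatrixTable, fraction: float | None = None, n: int | None = None
) -> list[str]:
    """Top features by cross-sample variance (ties by feature id)."""
    if (fraction is None) == (n is None):
        raise FieldscapeValidationError("specify exactly one of fraction or n")
    var = matrix.values.var(axis=1, ddof=1)
    k = n if n is not None else int(round(fraction * len(var)))
    ranked = var.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])


# ---------------------------------------------------------------------------
# NMF (Brunet multiplicative updates, KL objective)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    eps = 1e-12
    mask = V > 0
    return float(
        np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], eps))) - V.sum() + WH.sum()
    )


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Brunet multiplicative-update NMF minimizing KL divergence.

    Returns (W, H, objective trace); the objective is non-increasing.
    Sample cluster labels are argmax over the rows of H.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise FieldscapeValidationError("NMF input must be non-negative")
    n_feat, n_samp = V.shape
    if k < 1 or k > min(n_feat, n_samp):
        raise FieldscapeValidationError(f"k={k} out of range for shape {V.shape}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, size=(n_feat, k))
    H = rng.uniform(0.1, 1.0, size=(k, n_samp))
    eps = 1e-12
    trace = [_kl_divergence(V, W @ H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, eps)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = np.maximum(W @ H, eps)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(V, W @ H)
        trace.append(obj)
        prev = trace[-2]
        if prev - obj <= tol * max(abs(prev), 1.0):
            break
    return W, H, trace


def nmf_labels(H: np.ndarray) -> np.ndarray:
    """Cluster label per sample: the dominant metagene (1-based)."""
    return np.argmax(H, axis=0) + 1


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ConsensusResult:
    k: int
    assignments: pd.Series  # sample -> 1..k
    consensus_matrix: pd.DataFrame
    silhouette_widths: pd.Series
    n_runs: int

    @property
    def mean_silhouette(self) -> float:
        return float(self.silhouette_widths.mean())


def consensus_cluster(
    matrix: MatrixTable,
    k: int,
    n_runs: int = 500,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Repeated NMF restarts; co-clustering frequencies form the consensus.

    Final assignments come from an average-linkage cut of 1 - consensus
    into k groups, relabeled so cluster 1 is the largest.
    """
    samples = matrix.sample_ids
    n = len(samples)
    if n < k:
        raise FieldscapeValidationError(f"{n} samples cannot form {k} clusters")
    V = matrix.values.to_numpy(dtype=float)
    co = np.zeros((n, n))
    seeds = np.random.SeedSequence([seed, k]).generate_state(n_runs)
    for run_seed in seeds:
        _, H, _ = nmf_factorize(V, k, int(run_seed) % (2**31), max_iter=max_iter, tol=tol)
        labels = nmf_labels(H)
        co += labels[:, None] == labels[None, :]
    consensus = co / len(seeds)
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    order = pd.Series(raw).value_counts().index  # largest cluster first
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = np.array([remap[v] for v in raw])
    consensus_df = pd.DataFrame(consensus, index=samples, columns=samples)
    assignments = pd.Series(labels, index=samples, name="cluster")
    sil = silhouette_from_consensus(consensus_df, assignments)
    return ConsensusResult(
        k=k,
        assignments=assignments,
        consensus_matrix=consensus_df,
        silhouette_widths=sil,
        n_runs=len(seeds),
    )


def rank_survey(
    matrix: MatrixTable,
    k_range: range = range(2, 16),
    n_runs: int = 30,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Survey candidate cluster numbers with a lighter restart count."""
    rows = []
    for k in k_range:
        if k > len(matrix.sample_ids):
            continue
        res = consensus_cluster(matrix, k, n_runs=n_runs, seed=seed, **kwargs)
        off_diag = res.consensus_matrix.to_numpy()[
            ~np.eye(len(res.consensus_matrix), dtype=bool)
        ]
        rows.append(
            {
                "k": k,
                "mean_silhouette": res.mean_silhouette,
                "consensus_dispersion": float(np.mean((off_diag - 0.5) ** 2) * 4),
            }
        )
    return pd.DataFrame(rows).set_index("k")


def silhouette_from_consensus(
    consensus_matrix: pd.DataFrame, assignments: pd.Series
) -> pd.Series:
    """Per-sample silhouette widths on dissimilarity 1 - consensus.

    Singleton clusters get width 0 by convention.
    """
    d = 1.0 - consensus_matrix.to_numpy(dtype=float)
    labels = assignments.reindex(consensus_matrix.index).to_numpy()
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            widths[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        widths[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return pd.Series(widths, index=consensus_matrix.index, name="silhouette")


# ---------------------------------------------------------------------------
# SAM-style permutation differential abundance (Wilcoxon statistic)


@dataclass
class DifferentialFeature:
    feature_id: str
    fold_change: float  # signed: <1 ratios reported as negative reciprocal
    mean_rpm_c1: float
    mean_rpm_c2: float
    statistic: float
    q_value: float
    passes_filters: bool = False


def _standardized_wilcoxon(ranks: np.ndarray, group2: np.ndarray) -> np.ndarray:
    """Standardized rank-sum of group 2, per feature (rows of ``ranks``)."""
    n = ranks.shape[1]
    n2 = int(group2.sum())
    n1 = n - n2
    w = ranks[:, group2].sum(axis=1)
    mean = n2 * (n + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n + 1) / 12.0)
    return (w - mean) / sd


def sam_wilcoxon(
    matrix: MatrixTable,
    labels: pd.Series,
    n_perms: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class unpaired permutation test on a standardized Wilcoxon statistic.

    The null distribution comes from label permutations (all distinct
    permutations when fewer than ``n_perms`` exist). q-values use the
    plug-in estimator: at each observed |statistic| threshold, the median
    permutation count of null exceedances over the observed count,
    monotonized so q never decreases with decreasing significance.
    """
    labels = labels.reindex(matrix.sample_ids)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise FieldscapeValidationError(f"need exactly 2 classes, got {classes}")
    group2 = (labels == classes[1]).to_numpy()
    n1, n2 = int((~group2).sum()), int(group2.sum())
    if min(n1, n2) < 2:
        raise FieldscapeValidationError("each class needs >= 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, X)
    d_obs = _standardized_wilcoxon(ranks, group2)

    from math import comb

    n = n1 + n2
    n_distinct = comb(n, n2)
    rng = np.random.default_rng(seed)
    if n_distinct <= n_perms:
        from itertools import combinations

        perm_masks = []
        for subset in combinations(range(n), n2):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            perm_masks.append(mask)
    else:
        perm_masks = []
        for _ in range(n_perms):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n2, replace=False)] = True
            perm_masks.append(mask)
    null = np.column_stack([_standardized_wilcoxon(ranks, m) for m in perm_masks])

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    # exceedance counts per permutation at every observed threshold
    null_abs = np.abs(null)
    raw = np.empty(len(order))
    for rank_i, t in enumerate(thresholds):
        observed = rank_i + 1
        med_null = np.median((null_abs >= t).sum(axis=0))
        raw[rank_i] = min(1.0, med_null / observed)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    rpm = matrix.values
    mean1 = rpm.iloc[:, np.where(~group2)[0]].mean(axis=1).to_numpy()
    mean2 = rpm.iloc[:, np.where(group2)[0]].mean(axis=1).to_numpy()
    ratio = (mean2 + 0.5) / (mean1 + 0.5)
    fold = np.where(ratio >= 1, ratio, -1.0 / ratio)
    return pd.DataFrame(
        {
            "statistic": d_obs,
            "q_value": q,
            "mean_rpm_c1": mean1,
            "mean_rpm_c2": mean2,
            "fold_change": fold,
        },
        index=matrix.values.index,
    )


def filter_differential(
    features: pd.DataFrame,
    fdr: float = 0.05,
    min_abs_fc: float = 1.5,
    min_rpm: float = 25.0,
    top_n_per_direction: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the q/FC/abundance filters; also return the top fold changes.

    A feature passes with q below the FDR target, |fold change| >= 1.5,
    and mean RPM >= 25 in at least one of the two clusters.
    """
    df = features.copy()
    df["passes_filters"] = (
        (df["q_value"] < fdr)
        & (df["fold_change"].abs() >= min_abs_fc)
        & (df[["mean_rpm_c1", "mean_rpm_c2"]].max(axis=1) >= min_rpm)
    )
    passed = df[df["passes_filters"]]
    up = passed.nlargest(top_n_per_direction, "fold_change")
    down = passed.nsmallest(top_n_per_direction, "fold_change")
    top = pd.concat([up, down.iloc[::-1]])
    return df, top


# ---------------------------------------------------------------------------
# subtype assignment and concordance


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str
    distances: dict[str, float]
    tied: bool = False


def derive_centroids(matrix: MatrixTable, assignments: pd.Series,
                     labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-cluster mean profiles as centroid columns."""
    cols = {}
    for cl in sorted(assignments.unique()):
        name = labels.get(cl, str(cl)) if labels else str(cl)
        cols[name] = matrix.values.loc[:, assignments[assignments == cl].index].mean(axis=1)
    return pd.DataFrame(cols)


def assign_subtype(
    sample_profile: pd.Series,
    centroids: pd.DataFrame,
    distance: str = "spearman",
) -> SubtypeCall:
    """Nearest-centroid call; spearman distance is 1 - rank correlation.

    Ties break deterministically to the lexicographically first label
    and are flagged.
    """
    shared = centroids.index.intersection(sample_profile.index)
    if len(shared) < 0.5 * len(centroids.index):
        raise FieldscapeValidationError(
            f"only {len(shared)}/{len(centroids.index)} centroid features present"
        )
    x = sample_profile.reindex(shared).to_numpy(dtype=float)
    dists = {}
    for label in sorted(centroids.columns):
        c = centroids.loc[shared, label].to_numpy(dtype=float)
        if distance == "euclidean":
            dists[label] = float(np.sqrt(np.sum((x - c) ** 2)))
        elif distance == "spearman":
            rho = spearmanr(x, c).statistic
            dists[label] = float(1.0 - rho)
        else:
            raise FieldscapeValidationError(f"unknown distance {distance!r}")
    best = min(dists, key=lambda l: (dists[l], l))
    tied = sum(1 for v in dists.values() if v == dists[best]) > 1
    return SubtypeCall(
        sample_id=str(sample_profile.name), subtype=best, distances=dists, tied=tied
    )


def assign_subtypes(
    matrix: MatrixTable, centroids: pd.DataFrame, distance: str = "spearman"
) -> pd.DataFrame:
    calls = [
        assign_subtype(matrix.values[s], centroids, distance)
        for s in matrix.sample_ids
    ]
    return pd.DataFrame(
        [
            {"sample_id": c.sample_id, "subtype": c.subtype, "tied": c.tied,
             **{f"dist_{k}": v for k, v in sorted(c.distances.items())}}
            for c in calls
        ]
    ).set_index("sample_id")


def cluster_concordance(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Fraction of samples agreeing, maximized over the two-cluster label swap."""
    joined = pd.concat([labels_a.rename("a"), labels_b.rename("b")], axis=1).dropna()
    if joined.empty:
        raise FieldscapeValidationError("no shared samples")
    a_levels = sorted(joined["a"].unique())
    b_levels = sorted(joined["b"].unique())
    if len(a_levels) > 2 or len(b_levels) > 2:
        raise FieldscapeValidationError("concordance is defined for two-cluster labelings")
    direct = float((joined["a"].astype(str) == joined["b"].astype(str)).mean())
    if len(b_levels) == 2:
        swap = {b_levels[0]: b_levels[1], b_levels[1]: b_levels[0]}
        swapped = float((joined["a"].astype(str) == joined["b"].map(swap).astype(str)).mean())
    else:
        swapped = 0.0
    return max(direct, swapped)


def row_scaled_log_rpm(matrix: MatrixTable) -> pd.DataFrame:
    """log10(RPM+1), row-standardized — the export used for ordered heatmaps."""
    logged = np.log10(matrix.values + 1.0)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=1).replace(0, 1.0)
    return centered.div(sd, axis=0)
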