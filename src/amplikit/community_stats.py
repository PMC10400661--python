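"""Community statistics: alpha/beta diversity and differential abundance.

Alpha indices (observed richness, Chao1, Shannon, Simpson), rarefaction,
Jaccard-distance PCoA ordination, a permutation PERMANOVA, per-genus
Wilcoxon rank-sum tests with DESeq-style baseMean / log2FoldChange axes,
and Pearson reproducibility of matched community profiles.

Count tables are pandas DataFrames with features (ASVs or genera) as rows
and samples as columns; all statistics operate on unflagged counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "alpha_diversity",
    "rarefaction_curve",
    "jaccard_distances",
    "jaccard_pcoa",
    "permanova",
    "diff_abundance",
    "pearson_reproducibility",
]


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity indices.

    observed = number of nonzero features; Chao1 = S + F1(F1-1)/(2(F2+1))
    with F1/F2 the singleton/doubleton counts; Shannon = -sum p ln p;
    Simpson = 1 - sum p^2 (plus inverse Simpson).  Empty samples get all
    indices 0.
    """
    rows = []
    for sample in table.columns:
        x = table[sample].to_numpy(dtype=float)
        x = x[x > 0]
        if x.size == 0:
            rows.append(
                {"sample": sample, "observed": 0, "chao1": 0.0,
                 "shannon": 0.0, "simpson": 0.0, "inv_simpson": 0.0}
            )
            continue
        s = x.size
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = x / x.sum()
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        inv_simpson = float(1.0 / (p**2).sum())
        rows.append(
            {"sample": sample, "observed": s, "chao1": chao1,
             "shannon": shannon, "simpson": simpson,
             "inv_simpson": inv_simpson}
        )
    return pd.DataFrame(rows).set_index("sample")


def rarefaction_curve(
    counts: pd.Series | np.ndarray,
    depths: list[int],
    n_rep: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean observed richness under subsampling without replacement.

    For each depth, reads are subsampled without replacement ``n_rep``
    times and the mean number of features observed is reported.  Depths
    exceeding the sample total are skipped with a warning column.
    """
    x = np.asarray(counts, dtype=int)
    total = int(x.sum())
    pool = np.repeat(np.arange(x.size), x)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            continue
        if depth == total:
            rows.append({"depth": depth, "richness": float((x > 0).sum())})
            continue
        richness = np.empty(n_rep)
        for r in range(n_rep):
            sub = rng.choice(pool, size=depth, replace=False)
            richness[r] = np.unique(sub).size
        rows.append({"depth": depth, "richness": float(richness.mean())})
    return pd.DataFrame(rows)


def expected_rarefied_richness(
    counts: pd.Series | np.ndarray, depth: int
) -> float:
    """Closed-form hypergeometric expectation of rarefied richness:
    ``E[S] = sum_i (1 - C(N - N_i, d) / C(N, d))``."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    n = x.sum()
    terms = []
    for ni in x:
        # C(N-Ni, d)/C(N, d) via log-gammas for numerical safety
        if n - ni < depth:
            terms.append(1.0)
            continue
        log_ratio = (
            _log_comb(n - ni, depth) - _log_comb(n, depth)
        )
        terms.append(1.0 - np.exp(log_ratio))
    return float(np.sum(terms))


def _log_comb(n: float, k: float) -> float:
    from scipy.special import gammaln

    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def jaccard_distances(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between samples (presence/absence)."""
    presence = (table.to_numpy() > 0)
    n = presence.shape[1]
    if n < 2:
        raise ValueError("at least 2 samples required")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = presence[:, i], presence[:, j]
            union = np.logical_or(a, b).sum()
            inter = np.logical_and(a, b).sum()
            d[i, j] = d[j, i] = 0.0 if union == 0 else 1.0 - inter / union
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def jaccard_pcoa(table: pd.DataFrame):
    """Jaccard distance matrix + PCoA ordination of the samples.

    Returns ``(distances, coordinates, eigenvalues)``; coordinates are a
    DataFrame (samples x axes) from the eigendecomposition of the
    double-centred squared-distance matrix.
    """
    dist = jaccard_distances(table)
    ord_res = _skbio_pcoa(dist.to_numpy(), number_of_dimensions=0)
    coords = pd.DataFrame(
        ord_res.samples.to_numpy(),
        index=dist.index,
        columns=[f"PC{i + 1}" for i in range(ord_res.samples.shape[1])],
    )
    eigvals = np.asarray(ord_res.eigvals)
    return dist, coords, eigvals


def permanova(
    distances: pd.DataFrame | np.ndarray,
    labels: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational MANOVA on a distance matrix.

    Partitions the total sum of squared distances into among- and
    within-group components; the pseudo-F statistic is compared against
    ``n_perm`` random label permutations and
    ``p = (1 + #{F* >= F}) / (1 + n_perm)``.  Every group needs >= 2
    members.
    """
    d = np.asarray(distances, dtype=float)
    labels_arr = np.asarray(labels)
    n = d.shape[0]
    if len(labels_arr) != n:
        raise ValueError("labels length must match the distance matrix")
    groups, counts = np.unique(labels_arr, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    a = len(groups)
    d2 = d**2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n

    def pseudo_f(lab: np.ndarray) -> float:
        ss_within = 0.0
        for g in groups:
            idx = np.nonzero(lab == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        if ss_within == 0.0:
            # degenerate case: identical samples within every group
            return float("inf") if ss_among > 1e-12 else 0.0
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels_arr)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels_arr)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(f_obs), float(p)


def _size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features with any zero excluded)."""
    x = table.to_numpy(dtype=float)
    nonzero = (x > 0).all(axis=1)
    if not nonzero.any():
        # degenerate table: fall back to library-size scaling
        totals = x.sum(axis=0)
        return pd.Series(totals / np.exp(np.mean(np.log(totals))),
                         index=table.columns)
    ref = np.exp(np.mean(np.log(x[nonzero]), axis=1))
    ratios = x[nonzero] / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=table.columns)


def diff_abundance(
    table: pd.DataFrame,
    groups_a: list[str],
    groups_b: list[str],
    pseudocount: float = 0.5,
    min_mean_rel_abundance: float = 0.005,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature (genus) differential abundance between two groups.

    Counts are normalized by median-of-ratios size factors; per feature:
    baseMean = mean normalized count over all samples, log2FoldChange =
    log2((meanA + pc) / (meanB + pc)), two-sided Wilcoxon rank-sum p
    (exact for group sizes <= 10 without ties, tie-corrected normal
    approximation otherwise).  A feature is flagged significant when
    p < ``alpha`` and its mean relative abundance exceeds
    ``min_mean_rel_abundance`` (default 0.5%).  All-zero features are
    excluded.
    """
    if not groups_a or not groups_b:
        raise ValueError("both groups must be non-empty")
    table = table.loc[table.sum(axis=1) > 0]
    sf = _size_factors(table[list(groups_a) + list(groups_b)])
    norm = table[list(groups_a) + list(groups_b)] / sf
    rel = table.div(table.sum(axis=0), axis=1)
    rows = []
    for feature in table.index:
        xa = norm.loc[feature, groups_a].to_numpy(dtype=float)
        xb = norm.loc[feature, groups_b].to_numpy(dtype=float)
        base_mean = float(np.concatenate([xa, xb]).mean())
        log2fc = float(
            np.log2((xa.mean() + pseudocount) / (xb.mean() + pseudocount))
        )
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            p = 1.0
        else:
            method = (
                "exact"
                if max(len(xa), len(xb)) <= 10
                and len(np.unique(np.concatenate([xa, xb])))
                == len(xa) + len(xb)
                else "asymptotic"
            )
            p = float(
                sps.mannwhitneyu(
                    xa, xb, alternative="two-sided", method=method
                ).pvalue
            )
        mean_rel = float(rel.loc[feature].mean())
        rows.append(
            {
                "feature": feature,
                "baseMean": base_mean,
                "log2FoldChange": log2fc,
                "pvalue": p,
                "mean_rel_abundance": mean_rel,
                "significant": bool(
                    p < alpha and mean_rel > min_mean_rel_abundance
                ),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def pearson_reproducibility(
    profile_x: pd.Series | dict, profile_y: pd.Series | dict
) -> float:
    """Pearson r between two matched relative-abundance profiles.

    Profiles are aligned on the union of their features (absent features
    filled with zero) and converted to relative abundances.  Returns NaN
    when either aligned vector has zero variance.
    """
    sx = pd.Series(profile_x, dtype=float)
    sy = pd.Series(profile_y, dtype=float)
    taxa = sorted(set(sx.index) | set(sy.index))
    x = sx.reindex(taxa).fillna(0.0).to_numpy()
    y = sy.reindex(taxa).fillna(0.0).to_numpy()
    if x.sum() > 0:
        x = x / x.sum()
    if y.sum() > 0:
        y = y / y.sum()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)
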