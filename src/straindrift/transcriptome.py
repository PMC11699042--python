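"""Expression-layer drift metrics: count filtering, median-of-ratios
normalization, a negative-binomial Wald differential-expression test, CV
profiles per chromosome, PCA variance, and paired log2 fold-change
distributions between culture timepoints.

The DEG rule throughout is p_adj <= 0.01 and |log2FC| > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import RankTestResult, bh_adjust, wilcoxon_signed_rank

__all__ = [
    "CountMatrix",
    "DEResult",
    "CVProfile",
    "PCAResult",
    "filter_counts",
    "size_factors",
    "strain_mean_expression",
    "de_test",
    "cv_profile",
    "pca_variance",
    "paired_lfc",
    "compare_lfc_magnitudes",
]

DEG_PADJ = 0.01
DEG_LFC = 1.0
PSEUDO_MEAN = 0.5
MIN_DISPERSION = 1e-8


@dataclass
class CountMatrix:
    """Integer counts (genes x samples) with gene and sample metadata.

    ``gene_map`` is indexed by gene id with a ``chromosome`` column;
    ``samples`` is indexed by sample id with columns such as cell_line,
    strain, timepoint, replicate, batch.
    """

    counts: pd.DataFrame
    gene_map: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_map.index)
        if missing:
            raise ValueError(f"{len(missing)} genes lack metadata")
        missing_s = set(self.counts.columns) - set(self.samples.index)
        if missing_s:
            raise ValueError(f"{len(missing_s)} samples lack metadata")

    def subset_genes(self, genes) -> "CountMatrix":
        genes = list(genes)
        return CountMatrix(self.counts.loc[genes], self.gene_map.loc[genes], self.samples)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.gene_map, self.samples.loc[ids])


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    Columns: log2fc, p, p_adj, deg (p_adj <= 0.01 and |log2fc| > 1),
    direction ('up'/'down' by the sign of log2fc).
    """

    table: pd.DataFrame

    @property
    def n_deg(self) -> int:
        return int(self.table["deg"].sum())

    @property
    def n_up(self) -> int:
        t = self.table
        return int((t["deg"] & (t["direction"] == "up")).sum())

    @property
    def n_down(self) -> int:
        t = self.table
        return int((t["deg"] & (t["direction"] == "down")).sum())


@dataclass
class CVProfile:
    per_gene: pd.Series  # CV across strains, top-expressed genes only
    per_chromosome: pd.Series  # median CV of expressed genes per chromosome


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    percent_variance: np.ndarray

    def within_group_spread(self, groups: pd.Series, n_components: int = 2) -> float:
        """Mean pairwise distance within groups in the leading components."""
        coords = self.coordinates.iloc[:, :n_components]
        dists = []
        for _, idx in coords.groupby(groups.reindex(coords.index)).groups.items():
            sub = coords.loc[idx].to_numpy()
            if len(sub) < 2:
                continue
            diff = sub[:, None, :] - sub[None, :, :]
            d = np.sqrt((diff**2).sum(axis=2))
            dists.append(d[np.triu_indices(len(sub), k=1)])
        return float(np.concatenate(dists).mean()) if dists else 0.0


def size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    Over genes with nonzero counts in every sample, each sample's factor is
    the median ratio of its counts to the per-gene geometric mean.  When no
    gene is positive everywhere, falls back to upper-quartile scaling
    (factors normalized to geometric mean 1).
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        lx = np.log(x[all_pos])
        log_gm = lx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(lx - log_gm, axis=0))
    else:
        warnings.warn("no gene positive in all samples: upper-quartile fallback", UserWarning)
        uq = np.array([np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0 for col in x.T])
        sf = uq / np.exp(np.mean(np.log(uq)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts / size_factors(cm)


def filter_counts(
    cm: CountMatrix, min_total: int = 10, low_expr_quantile: float = 0.40
) -> CountMatrix:
    """Two-step expression filter in the stated order.

    First drop genes whose total count over all samples is below
    ``min_total``; then drop the lowest ``low_expr_quantile`` fraction of
    the remaining genes ranked by mean normalized expression.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = cm.counts.sum(axis=1)
    kept = cm.counts.index[totals >= min_total]
    if len(kept) == 0:
        raise ValueError("all genes removed by the total-count filter")
    cm1 = cm.subset_genes(kept)
    mean_norm = normalized_counts(cm1).mean(axis=1)
    n_drop = int(np.floor(low_expr_quantile * len(kept)))
    if n_drop >= len(kept):
        raise ValueError("quantile filter removes every gene")
    order = mean_norm.sort_values(kind="mergesort", ascending=True)
    keep2 = order.index[n_drop:]
    # preserve original gene order
    keep2 = [g for g in cm1.counts.index if g in set(keep2)]
    return cm1.subset_genes(keep2)


def de_test(cm: CountMatrix, group_a, group_b) -> DEResult:
    """Negative-binomial Wald test for differential expression.

    Counts are normalized by median-of-ratios factors; a per-gene
    dispersion is estimated by method of moments pooled within groups
    (floored at 1e-8).  The Wald statistic tests the log2 ratio of group
    means (a 0.5 pseudo-mean protects zero means); BH adjustment and the
    DEG rule (p_adj <= 0.01, |log2FC| > 1) give the calls.  ``group_b``
    is contrasted against the ``group_a`` reference.
    """
    group_a, group_b = list(group_a), list(group_b)
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = cm.subset_samples(group_a + group_b)
    norm = (sub.counts / size_factors(sub)).to_numpy(dtype=float)
    na, nb = len(group_a), len(group_b)
    a, b = norm[:, :na], norm[:, na:]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    # pooled within-group method-of-moments NB dispersion on normalized counts
    d = max(na + nb - 2, 1)
    pooled_var = (a.var(axis=1, ddof=0) * na + b.var(axis=1, ddof=0) * nb) / d
    mu_pool = (mu_a * na + mu_b * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu_pool) / mu_pool**2
    alpha = np.where(np.isfinite(alpha), alpha, MIN_DISPERSION)
    alpha = np.maximum(alpha, MIN_DISPERSION)
    # with few replicates the method-of-moments dispersion is noisy; floor it
    # at the global median so lucky-low-variance genes cannot inflate the Wald
    # statistic (a crude stand-in for full dispersion shrinkage)
    if alpha.size >= 10:
        alpha = np.maximum(alpha, np.median(alpha))
    zero = (mu_a == 0) | (mu_b == 0)
    mu_a_s = np.where(zero, mu_a + PSEUDO_MEAN, mu_a)
    mu_b_s = np.where(zero, mu_b + PSEUDO_MEAN, mu_b)
    lfc = np.log2(mu_b_s / mu_a_s)
    ln2_sq = np.log(2.0) ** 2
    var_lfc = (
        (mu_a_s + alpha * mu_a_s**2) / (na * mu_a_s**2)
        + (mu_b_s + alpha * mu_b_s**2) / (nb * mu_b_s**2)
    ) / ln2_sq
    se = np.sqrt(np.maximum(var_lfc, 1e-12))
    z = lfc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(mu_a == mu_b, 1.0, p)  # identical group means carry no signal
    adj = bh_adjust(p).p_adj
    deg = (adj <= DEG_PADJ) & (np.abs(lfc) > DEG_LFC)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "p_adj": adj,
            "deg": deg,
            "direction": np.where(lfc > 0, "up", "down"),
        },
        index=sub.counts.index,
    )
    return DEResult(table=table)


def cv_profile(
    strain_means: pd.DataFrame,
    gene_map: pd.DataFrame,
    top_quantile: float = 0.60,
    population_sd: bool = False,
) -> CVProfile:
    """Coefficient of variation of expression across strains.

    ``strain_means`` is genes x strains (normalized expression averaged
    over replicates).  Only the top ``top_quantile`` expressed genes (by
    mean across strains) are profiled; the per-chromosome summary is the
    median CV of those genes.  Sample (n-1) standard deviation by default.
    """
    if strain_means.shape[1] < 3:
        raise ValueError("need >= 3 strains")
    mean = strain_means.mean(axis=1)
    n_keep = int(np.ceil(top_quantile * len(mean)))
    top = mean.sort_values(kind="mergesort", ascending=False).index[:n_keep]
    sub = strain_means.loc[top]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0 if population_sd else 1)
    cv = (sd / mu.replace(0, np.nan)).fillna(0.0)
    chrom = gene_map.loc[cv.index, "chromosome"].astype(str)
    per_chrom = cv.groupby(chrom.to_numpy()).median()
    return CVProfile(per_gene=cv, per_chromosome=per_chrom)


def pca_variance(
    cm: CountMatrix, n_top_genes: int = 500, n_components: int | None = None
) -> PCAResult:
    """PCA of log2(normalized count + 1) on the top-variance genes.

    Returns sample coordinates (scores) and the percent variance captured
    by each component.
    """
    if cm.counts.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    log_expr = np.log2(normalized_counts(cm) + 1.0)
    gene_var = log_expr.var(axis=1, ddof=1)
    top = gene_var.sort_values(kind="mergesort", ascending=False).index[
        : min(n_top_genes, len(gene_var))
    ]
    x = log_expr.loc[top].to_numpy().T  # samples x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if n_components is None:
        n_components = s.size
    coords = u[:, :n_components] * s[:n_components]
    total = (s**2).sum()
    pct = 100.0 * (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=cm.counts.columns),
        percent_variance=pct,
    )


def strain_mean_expression(cm: CountMatrix, strain_col: str = "strain") -> pd.DataFrame:
    """Normalized expression averaged over each strain's replicates
    (genes x strains) — the input to :func:`cv_profile`."""
    norm = normalized_counts(cm)
    strains = cm.samples.loc[norm.columns, strain_col]
    return norm.T.groupby(strains.to_numpy()).mean().T


def paired_lfc(cm_ref: CountMatrix, cm_alt: CountMatrix) -> tuple[pd.Series, dict]:
    """Per-gene log2 fold change of a later timepoint against a reference.

    Both matrices are normalized independently (median-of-ratios); the
    fold change is log2((mean_alt + 0.5) / (mean_ref + 0.5)) per gene.
    Returns the vector and a summary (median, min, max).
    """
    if list(cm_ref.counts.index) != list(cm_alt.counts.index):
        raise ValueError("gene sets differ between timepoints")
    mu_ref = normalized_counts(cm_ref).mean(axis=1)
    mu_alt = normalized_counts(cm_alt).mean(axis=1)
    lfc = np.log2((mu_alt + PSEUDO_MEAN) / (mu_ref + PSEUDO_MEAN))
    summary = {
        "median": float(lfc.median()),
        "min": float(lfc.min()),
        "max": float(lfc.max()),
    }
    return lfc, summary


def compare_lfc_magnitudes(lfc_a, lfc_b, sidedness: str = "two-sided") -> RankTestResult:
    """Wilcoxon signed-rank comparison of |log2FC| between two entities.

    The vectors are paired by gene (same index/order required): does one
    cell line's expression drift more than another's over the same genes?
    """
    a = np.abs(np.asarray(lfc_a, dtype=float))
    b = np.abs(np.asarray(lfc_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("fold-change vectors must be paired by gene")
    return wilcoxon_signed_rank(a, b, sidedness=sidedness)
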