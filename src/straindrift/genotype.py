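"""SNP-layer QC and strain-concordance metrics.

Genotype calls are coded 0 (hom-ref), 1 (het), 2 (hom-alt) with NaN for
missing.  The module provides array-style QC filtering (call rate,
Hardy-Weinberg exact test, Y-chromosome exclusion), shared-SNP fractions
across strains, genotype transition counts between two strains, and the
Euclidean distance between timepoints in PCA eigenvector space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "EigenDistance",
    "hwe_exact_p",
    "qc_filter",
    "shared_snp_fraction",
    "transition_counts",
    "eigen_distance",
    "read_genotype_csv",
    "read_minimal_vcf",
]

CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y")


@dataclass
class GenotypeMatrix:
    """Samples x loci genotype calls with per-locus annotations.

    ``calls`` is a DataFrame (rows = samples, columns = locus ids) of
    floats in {0, 1, 2, NaN}; ``annotations`` is indexed by locus id with
    columns ``chromosome`` (str), ``in_exon`` and ``non_synonymous`` (bool).
    """

    calls: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        missing_ann = set(self.calls.columns) - set(self.annotations.index)
        if missing_ann:
            raise ValueError(f"{len(missing_ann)} loci lack annotations")
        bad = set(self.annotations.loc[list(self.calls.columns), "chromosome"].astype(str)) - set(
            CHROMOSOMES
        )
        if bad:
            raise ValueError(f"unknown chromosome labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def subset_loci(self, loci) -> "GenotypeMatrix":
        loci = list(loci)
        return GenotypeMatrix(self.calls[loci], self.annotations.loc[loci])


@dataclass
class QCReport:
    n_input: int
    n_passed: int
    removed_call_rate: int
    removed_hwe: int
    removed_y_chromosome: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class EigenDistance:
    """Sample coordinates in the top-k eigenvector space and pair distances."""

    k: int
    coordinates: pd.DataFrame  # samples x k
    distances: pd.DataFrame = field(init=False)  # samples x samples

    def __post_init__(self) -> None:
        x = self.coordinates.to_numpy()
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        self.distances = pd.DataFrame(
            d, index=self.coordinates.index, columns=self.coordinates.index
        )

    def distance(self, a: str, b: str) -> float:
        return float(self.distances.loc[a, b])


def hwe_exact_p(n_aa_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration (Wigginton-style exact test).
    Monomorphic loci return 1.
    """
    n_aa, n_ab, n_bb = int(n_aa_hom), int(n_het), int(n_alt_hom)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    # feasible het counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    # log conditional probability up to a common constant:
    # P(het) ∝ n! / (n_aa! n_ab! n_bb!) * 2^n_ab  (allele counts fixed)
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(n_ab)
    p_obs = probs[hets == obs]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    return (
        int(np.sum(col == 0)),
        int(np.sum(col == 1)),
        int(np.sum(col == 2)),
    )


def qc_filter(
    gm: GenotypeMatrix, call_rate_min: float = 0.95, hwe_p_min: float = 1e-6
) -> tuple[GenotypeMatrix, QCReport]:
    """Array QC: call rate > ``call_rate_min``, HWE exact p >= ``hwe_p_min``
    (pooled over all samples), and exclusion of Y-chromosome loci.

    Each removed locus is attributed to the first filter (in that order)
    that it fails.  Idempotent: re-filtering the output removes nothing.
    """
    if gm.n_samples < 1 or gm.n_loci < 1:
        raise ValueError("empty genotype matrix")
    calls = gm.calls.to_numpy(dtype=float)
    call_rate = 1.0 - np.isnan(calls).mean(axis=0)
    fail_cr = call_rate <= call_rate_min

    hwe_p = np.ones(gm.n_loci)
    for j in range(gm.n_loci):
        if fail_cr[j]:
            continue
        col = calls[:, j]
        col = col[~np.isnan(col)]
        if col.size:
            hwe_p[j] = hwe_exact_p(*_genotype_counts(col))
    fail_hwe = (hwe_p < hwe_p_min) & ~fail_cr

    chrom = gm.annotations.loc[gm.calls.columns, "chromosome"].astype(str).to_numpy()
    fail_y = (chrom == "Y") & ~fail_cr & ~fail_hwe

    keep = ~(fail_cr | fail_hwe | fail_y)
    report = QCReport(
        n_input=gm.n_loci,
        n_passed=int(keep.sum()),
        removed_call_rate=int(fail_cr.sum()),
        removed_hwe=int(fail_hwe.sum()),
        removed_y_chromosome=int(fail_y.sum()),
    )
    return gm.subset_loci(gm.calls.columns[keep]), report


def shared_snp_fraction(
    gm: GenotypeMatrix, in_exon: bool = False, non_synonymous: bool = False
) -> float:
    """Fraction of annotation-eligible, complete-case loci with the same
    call in every strain (row of ``gm``).

    Loci with any missing call are excluded from numerator and denominator.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 strains")
    mask = np.ones(gm.n_loci, dtype=bool)
    ann = gm.annotations.loc[gm.calls.columns]
    if in_exon:
        mask &= ann["in_exon"].to_numpy(dtype=bool)
    if non_synonymous:
        mask &= ann["non_synonymous"].to_numpy(dtype=bool)
    calls = gm.calls.to_numpy(dtype=float)[:, mask]
    complete = ~np.isnan(calls).any(axis=0)
    calls = calls[:, complete]
    if calls.shape[1] == 0:
        raise ValueError("no eligible loci (after annotation filter and missingness)")
    identical = (calls == calls[0]).all(axis=0)
    return float(identical.mean())


def transition_counts(a, b) -> dict[str, int]:
    """Classify per-locus genotype transitions between two strains.

    Returns counts of ``consistent``, ``hom_to_het`` (0->1 or 2->1),
    ``het_to_hom`` (1->0 or 1->2) and ``hom_to_hom_other`` (0<->2).
    Loci missing in either strain are excluded; category totals sum to the
    number of compared loci.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("strain call vectors must share loci")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    consistent = a == b
    hom_a = (a == 0) | (a == 2)
    hom_b = (b == 0) | (b == 2)
    return {
        "consistent": int(consistent.sum()),
        "hom_to_het": int((hom_a & (b == 1)).sum()),
        "het_to_hom": int(((a == 1) & hom_b).sum()),
        "hom_to_hom_other": int((hom_a & hom_b & ~consistent).sum()),
        "n_compared": int(ok.sum()),
    }


def eigen_distance(gm: GenotypeMatrix, k: int = 10) -> EigenDistance:
    """PCA of the dosage matrix and Euclidean distances between samples.

    Missing calls are mean-imputed per locus, columns are centered, and the
    top-k right singular vectors (scaled by their singular values) give the
    sample coordinates — i.e. classical PCA scores.  At k = rank the
    pairwise distances equal the full-space distances of the centered rows.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = gm.calls.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", UserWarning)
        k = max(rank, 1)
    coords = u[:, :k] * s[:k]
    return EigenDistance(
        k=k, coordinates=pd.DataFrame(coords, index=gm.calls.index)
    )


def read_genotype_csv(calls_path, annotations_path) -> GenotypeMatrix:
    """Read a samples x loci call matrix CSV and a locus annotation CSV."""
    calls = pd.read_csv(calls_path, index_col=0)
    ann = pd.read_csv(annotations_path, index_col=0)
    ann["chromosome"] = ann["chromosome"].astype(str)
    ann["in_exon"] = ann["in_exon"].astype(bool)
    ann["non_synonymous"] = ann["non_synonymous"].astype(bool)
    return GenotypeMatrix(calls=calls, annotations=ann)


def read_minimal_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF 4.2 file carrying only GT in the FORMAT field.

    Returns a samples x loci dosage DataFrame ({0,1,2}, NaN for ./.).
    """
    rows = []
    loci = []
    samples = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if fields[8].split(":")[0] != "GT":
                raise ValueError("only GT-first FORMAT supported")
            loci.append(fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}")
            calls = []
            for sample_field in fields[9:]:
                gt = sample_field.split(":")[0].replace("|", "/")
                if "." in gt:
                    calls.append(np.nan)
                else:
                    calls.append(float(sum(int(a) for a in gt.split("/"))))
            rows.append(calls)
    if samples is None:
        raise ValueError("missing #CHROM header line")
    return pd.DataFrame(np.asarray(rows, dtype=float).T, index=samples, columns=loci)
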