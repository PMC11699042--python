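"""Copy-number segmentation and instability metrics.

Binned log2-ratio tracks (BED-style, 0-based half-open) are segmented per
chromosome with a circular binary segmentation scheme: the arc maximizing
the two-sample t-statistic between inside and outside bins is accepted as
a change if its permutation p-value clears ``alpha``, recursively.  The
module also computes the Genomic Index (squared count of copy-altered
segments over the count of altered chromosomes), cross-platform interval
matching with an 80-120% size criterion, and a trapezoidal area summary of
copy-number ratio profiles.

Coordinate conventions: bin tracks are 0-based half-open (BED); segment
sets are 1-based inclusive (SEG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinnedLogRatio",
    "CNSegmentSet",
    "CNStabilitySummary",
    "IntervalMatch",
    "segment_track",
    "genomic_index",
    "match_intervals",
    "cn_ratio_auc",
    "read_track_tsv",
    "read_seg_tsv",
]


@dataclass
class BinnedLogRatio:
    """Per-bin log2 copy-ratio track; columns chrom/start/end/log2ratio."""

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "log2ratio"}
        if not req.issubset(self.bins.columns):
            raise ValueError(f"track requires columns {sorted(req)}")
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if np.any(e <= s):
                raise ValueError(f"empty/inverted bin on {chrom}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping or unsorted bins on {chrom}")

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


@dataclass
class CNSegmentSet:
    """1-based inclusive segments with mean log2 ratio and/or copy number."""

    segments: pd.DataFrame  # chrom, start, end, value, n_bins

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "value"}
        if not req.issubset(self.segments.columns):
            raise ValueError(f"segments require columns {sorted(req)}")
        sizes = self.segments["end"] - self.segments["start"] + 1
        if (sizes <= 0).any():
            raise ValueError("segment end must be >= start (1-based inclusive)")

    @property
    def sizes(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"] + 1).to_numpy()

    def copy_numbers(self, value_is_log2: bool = True) -> np.ndarray:
        """Segment copy numbers, neutral = 2 (value stored as log2 ratio)."""
        v = self.segments["value"].to_numpy(dtype=float)
        return 2.0 * 2.0**v if value_is_log2 else v

    def to_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)


@dataclass
class CNStabilitySummary:
    GI: float
    n_altered_segments: int
    n_altered_chromosomes: int
    auc_cn_ratio: float | None = None


@dataclass
class IntervalMatch:
    ref_chrom: str
    ref_start: int
    ref_end: int
    matched: pd.DataFrame  # query segments matching this ref
    mean_cn: float  # NaN when unmatched

    @property
    def unmatched(self) -> bool:
        return len(self.matched) == 0


def _max_arc_t(x: np.ndarray) -> tuple[float, int, int]:
    """Maximum squared two-sample t over circular arcs (i, j].

    Returns (t^2, i, j); inside = x[i:j], outside = the rest.  Degenerate
    splits (zero within-group variance with equal means) yield t^2 = inf
    only when the means differ.
    """
    n = x.size
    s = np.concatenate([[0.0], np.cumsum(x)])
    q = np.concatenate([[0.0], np.cumsum(x**2)])
    i_idx, j_idx = np.triu_indices(n + 1, k=1)
    keep = (j_idx - i_idx) < n  # outside must be nonempty
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    n_in = (j_idx - i_idx).astype(float)
    n_out = n - n_in
    sum_in = s[j_idx] - s[i_idx]
    sum_out = s[n] - sum_in
    ss_in = q[j_idx] - q[i_idx] - sum_in**2 / n_in
    ss_out = (q[n] - (q[j_idx] - q[i_idx])) - sum_out**2 / n_out
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss_in + ss_out) / max(n - 2, 1)
        num = (sum_in / n_in - sum_out / n_out) ** 2
        t2 = num / (sp2 * (1.0 / n_in + 1.0 / n_out))
        t2 = np.where(num == 0, 0.0, t2)  # equal means: no evidence
        t2 = np.where((sp2 == 0) & (num > 0), np.inf, t2)
    best = int(np.argmax(t2))
    return float(t2[best]), int(i_idx[best]), int(j_idx[best])


def _perm_max_t(x: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Max arc t^2 for ``n_perm`` random shuffles of x (vectorized)."""
    n = x.size
    i_idx, j_idx = np.triu_indices(n + 1, k=1)
    keep = (j_idx - i_idx) < n
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    n_in = (j_idx - i_idx).astype(float)
    n_out = n - n_in
    out = np.empty(n_perm)
    block = max(1, int(2_000_000 // max(i_idx.size, 1)))
    total_sum = x.sum()
    total_q = (x**2).sum()
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        s = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1)
        q = np.concatenate([np.zeros((b, 1)), np.cumsum(perms**2, axis=1)], axis=1)
        sum_in = s[:, j_idx] - s[:, i_idx]
        q_in = q[:, j_idx] - q[:, i_idx]
        sum_out = total_sum - sum_in
        ss_in = q_in - sum_in**2 / n_in
        ss_out = (total_q - q_in) - sum_out**2 / n_out
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = (ss_in + ss_out) / max(n - 2, 1)
            num = (sum_in / n_in - sum_out / n_out) ** 2
            t2 = num / (sp2 * (1.0 / n_in + 1.0 / n_out))
            t2 = np.where(num == 0, 0.0, t2)
            t2 = np.where((sp2 == 0) & (num > 0), np.inf, t2)
        out[done : done + b] = t2.max(axis=1)
        done += b
    return out


def _segment_recursive(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[int]:
    """Return sorted interior breakpoints (bin offsets) for one array."""
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        return []
    t2_obs, i, j = _max_arc_t(x)
    if t2_obs <= 0:
        return []
    perm_t2 = _perm_max_t(x, n_perm, rng)
    p = (1.0 + np.sum(perm_t2 >= t2_obs)) / (n_perm + 1.0)
    if p >= alpha:
        return []
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    if not cuts:
        return []
    bounds = [0] + cuts + [n]
    out: list[int] = list(cuts)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sub = _segment_recursive(x[lo:hi], alpha, n_perm, rng)
        out.extend(lo + c for c in sub)
    return sorted(set(out))


def segment_track(
    track: BinnedLogRatio,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
) -> CNSegmentSet:
    """Circular binary segmentation of a binned log2-ratio track.

    Per chromosome, the arc (i, j] maximizing the two-sample t-statistic
    between inside and outside bins is accepted as a split when its
    permutation p-value (``n_perm`` shuffles) is below ``alpha``; the
    procedure recurses into the resulting pieces.  Segment values are mean
    log2 ratios; output segments are 1-based inclusive and tile the input
    bins exactly.  Chromosomes with a single bin pass through unsegmented.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in track.bins.groupby("chrom", sort=False):
        x = grp["log2ratio"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cuts = _segment_recursive(x, alpha, n_perm, rng) if x.size >= 2 else []
        bounds = [0] + cuts + [x.size]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[lo]) + 1,  # BED -> SEG coordinates
                    "end": int(ends[hi - 1]),
                    "value": float(np.mean(x[lo:hi])),
                    "n_bins": hi - lo,
                }
            )
    return CNSegmentSet(segments=pd.DataFrame(rows))


def genomic_index(
    segs: CNSegmentSet,
    neutral: float = 2.0,
    tol: float = 0.3,
    value_is_log2: bool = True,
) -> CNStabilitySummary:
    """Genomic Index: (altered segments)^2 / (altered chromosomes).

    A segment is altered when its copy number deviates from ``neutral`` by
    more than ``tol``; each chromosome counts once regardless of how many
    altered segments it carries.  No altered segments gives GI = 0.
    """
    cn = segs.copy_numbers(value_is_log2=value_is_log2)
    altered = np.abs(cn - neutral) > tol
    n_seg = int(altered.sum())
    chroms = segs.segments.loc[altered, "chrom"]
    n_chrom = int(chroms.nunique())
    gi = (n_seg**2) / n_chrom if n_chrom > 0 else 0.0
    return CNStabilitySummary(GI=float(gi), n_altered_segments=n_seg, n_altered_chromosomes=n_chrom)


def match_intervals(
    ref: CNSegmentSet,
    query: CNSegmentSet,
    size_lo: float = 0.8,
    size_hi: float = 1.2,
    value_is_log2: bool = True,
) -> list[IntervalMatch]:
    """Match query segments to reference segments (same 1-based convention).

    A query q matches a reference r iff they share a chromosome, they
    overlap (r.start <= q.end and r.end >= q.start), and size(q) lies in
    [size_lo, size_hi] x size(r).  Per reference the aggregate value is the
    mean copy number of all matched queries; unmatched references carry NaN.
    """
    for ss in (ref, query):
        if ((ss.segments["end"] - ss.segments["start"] + 1) <= 0).any():
            raise ValueError("negative interval sizes: mixed coordinate conventions?")
    qdf = query.segments.copy()
    qdf["cn"] = query.copy_numbers(value_is_log2=value_is_log2)
    qdf["size"] = query.sizes
    out = []
    for _, r in ref.segments.iterrows():
        r_size = r["end"] - r["start"] + 1
        cand = qdf[qdf["chrom"] == r["chrom"]]
        hit = cand[
            (r["start"] <= cand["end"])
            & (r["end"] >= cand["start"])
            & (cand["size"] >= size_lo * r_size)
            & (cand["size"] <= size_hi * r_size)
        ]
        out.append(
            IntervalMatch(
                ref_chrom=str(r["chrom"]),
                ref_start=int(r["start"]),
                ref_end=int(r["end"]),
                matched=hit,
                mean_cn=float(hit["cn"].mean()) if len(hit) else float("nan"),
            )
        )
    return out


def cn_ratio_auc(ref_cn, query_cn, positions) -> float:
    """Area summary of a copy-number ratio profile along the genome.

    Trapezoidal integral of |log2(query/ref)| against genomic position
    (interval midpoints on a cumulative axis), normalized by the total
    span so identical profiles give 0 and a constant 2-fold ratio gives 1.
    """
    ref_cn = np.asarray(ref_cn, dtype=float)
    query_cn = np.asarray(query_cn, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if ref_cn.size < 2 or ref_cn.shape != query_cn.shape or ref_cn.shape != positions.shape:
        raise ValueError("need >= 2 intervals with matching ref/query/position arrays")
    if np.any(ref_cn <= 0) or np.any(query_cn <= 0):
        raise ValueError("copy numbers must be positive")
    order = np.argsort(positions)
    x = positions[order]
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError("degenerate genomic span")
    y = np.abs(np.log2(query_cn[order] / ref_cn[order]))
    return float(np.trapezoid(y, (x - x[0]) / span))


def read_track_tsv(path) -> BinnedLogRatio:
    return BinnedLogRatio(pd.read_csv(path, sep="\t"))


def read_seg_tsv(path) -> CNSegmentSet:
    return CNSegmentSet(pd.read_csv(path, sep="\t"))
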