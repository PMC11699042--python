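"""Methylation-array normalization, beta/M transforms, and differential
methylation between culture timepoints.

Raw methylated/unmethylated intensity pairs are normalized per sample and
per channel: a background shift placing the 5th percentile of the
negative-control probes at 0, followed by a dye-bias scaling that sets the
mean of the normalization-control probes to 10,000.  Beta values use the
conventional offset of 100 in the denominator; M-values are the logit2
transform.  Probe-wise differential methylation uses a moderated two-group
t-test on M-values with BH control at FDR 0.05; promoter-level analysis
averages betas over regions with at least five CpGs and tests the logit of
the region means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, moderate_variances

__all__ = [
    "IntensityMatrix",
    "BetaMatrix",
    "MValueMatrix",
    "DMResult",
    "normalize_intensities",
    "beta_values",
    "m_values",
    "probe_dm",
    "promoter_dm",
    "consistent_regions",
]

NEG_PERCENTILE = 5.0
NORM_TARGET = 10_000.0


@dataclass
class IntensityMatrix:
    """Methylated/unmethylated probe intensities plus per-channel controls.

    All frames are probes x samples; ``meth``/``unmeth`` share an index
    (CpG probe ids), control frames have their own probe indexes but the
    same sample columns.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    neg_ctrl_meth: pd.DataFrame
    neg_ctrl_unmeth: pd.DataFrame
    norm_ctrl_meth: pd.DataFrame
    norm_ctrl_unmeth: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.meth.columns)
        for name in ("unmeth", "neg_ctrl_meth", "neg_ctrl_unmeth", "norm_ctrl_meth", "norm_ctrl_unmeth"):
            frame = getattr(self, name)
            if frame.empty:
                raise ValueError(f"{name} controls/intensities missing")
            if list(frame.columns) != cols:
                raise ValueError(f"{name} sample columns differ from meth")


@dataclass
class BetaMatrix:
    """Beta values in [0, 1) with a probe map and mask flags.

    ``probe_map`` is indexed by probe id with columns ``chromosome`` and
    ``promoter_id`` (NaN/empty when the CpG is not in a promoter).
    ``masked`` flags probes excluded from downstream analysis (user mask
    plus X/Y chromosomes).
    """

    beta: pd.DataFrame
    probe_map: pd.DataFrame
    masked: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.masked is None:
            self.masked = pd.Series(False, index=self.beta.index)

    def unmasked(self) -> pd.DataFrame:
        return self.beta.loc[~self.masked.reindex(self.beta.index, fill_value=False)]


@dataclass
class MValueMatrix:
    m: pd.DataFrame


@dataclass
class DMResult:
    """Per-unit (probe or region) differential-methylation table.

    ``table`` columns: effect (delta M or delta logit-mean-beta, group b
    minus group a), t, p, p_adj, significant, direction ('hypo'/'hyper');
    region results also carry n_cpgs.
    """

    table: pd.DataFrame
    fdr: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_hypo(self) -> int:
        t = self.table
        return int((t["significant"] & (t["direction"] == "hypo")).sum())

    @property
    def n_hyper(self) -> int:
        t = self.table
        return int((t["significant"] & (t["direction"] == "hyper")).sum())


def _normalize_channel(signal: pd.DataFrame, neg: pd.DataFrame, norm: pd.DataFrame):
    """Background-shift then dye-scale one channel; returns all three frames.

    The percentile is the lower order statistic (no interpolation) so that
    after shifting and clipping the 5th percentile of the negative controls
    is exactly 0 and the whole operation is a fixed point of itself.
    """
    shift = pd.Series(
        np.percentile(neg.to_numpy(), NEG_PERCENTILE, axis=0, method="lower"),
        index=neg.columns,
    )
    sig = (signal - shift).clip(lower=0.0)
    neg_s = (neg - shift).clip(lower=0.0)
    norm_s = (norm - shift).clip(lower=0.0)
    scale_mean = norm_s.mean(axis=0)
    if (scale_mean <= 0).any():
        raise ValueError("normalization-control mean is zero after background shift")
    factor = NORM_TARGET / scale_mean
    return sig * factor, neg_s * factor, norm_s * factor


def normalize_intensities(x: IntensityMatrix) -> IntensityMatrix:
    """Background and dye-bias correction, each channel independently.

    Per sample and channel: shift so the 5th percentile of negative
    controls is 0 (clipping at 0), then scale so the normalization-control
    mean is 10,000.  Idempotent on its own output.
    """
    meth, neg_m, norm_m = _normalize_channel(x.meth, x.neg_ctrl_meth, x.norm_ctrl_meth)
    unmeth, neg_u, norm_u = _normalize_channel(x.unmeth, x.neg_ctrl_unmeth, x.norm_ctrl_unmeth)
    return IntensityMatrix(
        meth=meth,
        unmeth=unmeth,
        neg_ctrl_meth=neg_m,
        neg_ctrl_unmeth=neg_u,
        norm_ctrl_meth=norm_m,
        norm_ctrl_unmeth=norm_u,
    )


def beta_values(
    x: IntensityMatrix,
    probe_map: pd.DataFrame,
    offset: float = 100.0,
    mask_ids=None,
) -> BetaMatrix:
    """Beta = M / (M + U + offset); masked and X/Y probes are flagged.

    ``mask_ids`` is an optional iterable of probe ids to exclude from
    downstream analysis (e.g. a published cross-reactive-probe list).
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    beta = x.meth / (x.meth + x.unmeth + offset)
    beta = beta.fillna(0.0)  # 0/0 with offset 0
    masked = pd.Series(False, index=beta.index)
    if mask_ids is not None:
        masked |= beta.index.isin(set(mask_ids))
    pm = probe_map.reindex(beta.index)
    masked |= pm["chromosome"].astype(str).isin(["X", "Y"]).to_numpy()
    return BetaMatrix(beta=beta, probe_map=pm, masked=masked)


def m_values(b: BetaMatrix | pd.DataFrame, eps: float = 1e-6) -> MValueMatrix:
    """M = log2(beta / (1 - beta)) (logit2 transform).

    Betas are bounded into [eps, 1-eps] first so fully background-subtracted
    probes (beta exactly 0) yield finite M-values.
    """
    beta = b.beta if isinstance(b, BetaMatrix) else b
    bounded = beta.clip(lower=eps, upper=1.0 - eps)
    m = np.log2(bounded / (1.0 - bounded))
    return MValueMatrix(m=pd.DataFrame(m, index=beta.index, columns=beta.columns))


def inverse_m(m: pd.DataFrame | np.ndarray):
    """Map M-values back to betas (logistic in base 2)."""
    p = 2.0**np.asarray(m, dtype=float)
    out = p / (1.0 + p)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out


def _two_group_moderated(values: pd.DataFrame, group_a, group_b, moderated: bool = True):
    """Moderated two-group t-test per row; returns effect, t, p, df."""
    a = values[list(group_a)].to_numpy(dtype=float)
    b = values[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if min(na, nb) < 2:
        warnings.warn("a group has a single sample: no within-group variance; "
                      "falling back to pooled cross-group variance", UserWarning)
    effect = b.mean(axis=1) - a.mean(axis=1)
    d = max(na + nb - 2, 1)
    s2 = (a.var(axis=1, ddof=0) * na + b.var(axis=1, ddof=0) * nb) / d
    if moderated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mv = moderate_variances(s2, d)
        s2_use = mv.s2_post
        df = mv.df_total
    else:
        s2_use = s2
        df = d
    se = np.sqrt(s2_use * (1.0 / na + 1.0 / nb))
    se = np.maximum(se, 1e-12)
    t = effect / se
    df_eff = df if np.isfinite(df) else 1e6
    p = 2.0 * sps.t.sf(np.abs(t), df_eff)
    return effect, t, p


def probe_dm(
    mv: MValueMatrix,
    group_a,
    group_b,
    fdr: float = 0.05,
    moderated: bool = True,
) -> DMResult:
    """Probe-wise differential methylation on M-values.

    Two-group comparison (``group_b`` vs ``group_a`` reference) with a
    moderated t statistic and BH control; a probe is significant when its
    adjusted p is below ``fdr``, hypo-methylated when the effect (delta M)
    is negative.
    """
    effect, t, p = _two_group_moderated(mv.m, group_a, group_b, moderated=moderated)
    adj = bh_adjust(p).p_adj
    table = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p": p,
            "p_adj": adj,
            "significant": adj < fdr,
            "direction": np.where(effect < 0, "hypo", "hyper"),
        },
        index=mv.m.index,
    )
    return DMResult(table=table, fdr=fdr)


def promoter_dm(
    bm: BetaMatrix,
    group_a,
    group_b,
    min_cpgs: int = 5,
    fdr: float = 0.05,
    moderated: bool = True,
) -> DMResult:
    """Region-level differential methylation over promoter regions.

    CpGs are aggregated by promoter id (mask-excluded probes dropped);
    regions with fewer than ``min_cpgs`` CpGs are skipped.  Per region the
    mean beta per sample is logit2-transformed and tested with the same
    moderated two-group machinery as the probe-wise analysis.
    """
    pm = bm.probe_map
    keep = (~bm.masked) & pm["promoter_id"].notna()
    beta = bm.beta.loc[keep]
    promoters = pm.loc[keep, "promoter_id"]
    sizes = promoters.value_counts()
    eligible = sizes[sizes >= min_cpgs].index
    if len(eligible) == 0:
        warnings.warn(f"no promoter region has >= {min_cpgs} CpGs", UserWarning)
        empty = pd.DataFrame(
            columns=["effect", "t", "p", "p_adj", "significant", "direction", "n_cpgs"]
        )
        return DMResult(table=empty, fdr=fdr)
    region_mean = beta.groupby(promoters.to_numpy()).mean().loc[eligible]
    eps = 1e-6
    logit = np.log2(region_mean.clip(eps, 1 - eps) / (1 - region_mean.clip(eps, 1 - eps)))
    effect, t, p = _two_group_moderated(logit, group_a, group_b, moderated=moderated)
    adj = bh_adjust(p).p_adj
    table = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p": p,
            "p_adj": adj,
            "significant": adj < fdr,
            "direction": np.where(effect < 0, "hypo", "hyper"),
            "n_cpgs": sizes.loc[eligible].to_numpy(),
        },
        index=eligible,
    )
    return DMResult(table=table, fdr=fdr)


def consistent_regions(results: list[DMResult]) -> list:
    """Region ids called significant in every supplied result.

    The cross-cell-line consistency check: which promoter regions drift in
    all lines (typically very few).
    """
    if not results:
        return []
    common = None
    for res in results:
        sig = set(res.table.index[res.table["significant"]])
        common = sig if common is None else (common & sig)
    return sorted(common)
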