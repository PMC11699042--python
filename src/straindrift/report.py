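"""Per-layer drift metrics, stability rankings, and the pipeline driver.

For each simulated (or supplied) cell line the pipeline computes one
instability value per data layer for the m12-vs-m0 comparison of the
continuously cultured strain:

* genotype — Euclidean distance between the two timepoints in the top-k
  PCA eigenvector space of the QC-filtered call matrix;
* copy_number — area summary of the per-bin copy-number ratio profile
  between the segmented m12 and m0 tracks;
* methylation — number of significantly differentially methylated CpG
  probes (FDR < 0.05);
* transcriptome — number of DEGs (p_adj <= 0.01, |log2FC| > 1);
* drug — relative change of the mean dose-response AUC across compounds.

Each layer's values are ranked across cell lines (1 = most stable) and the
rankings aggregated by mean rank.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import copynumber as cnv
from . import drugresponse as drug
from . import genotype as geno
from . import methylation as meth
from . import transcriptome as rna
from .simulate import (
    PAPER_LIKE_MULTIPLIERS,
    DriftConfig,
    StrainDataset,
    paper_like_dataset,
)

__all__ = [
    "LayerMetric",
    "StabilityRanking",
    "LAYERS",
    "compute_layer_metrics",
    "rank_layer",
    "aggregate_ranking",
    "run_pipeline",
]

LAYERS = ("genotype", "copy_number", "methylation", "transcriptome", "drug")


@dataclass
class LayerMetric:
    layer: str
    cell_line: str
    comparison: str
    value: float
    higher_is_less_stable: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite metric for {self.cell_line}/{self.layer}")


@dataclass
class StabilityRanking:
    per_layer: pd.DataFrame  # lines x layers, rank (1 = most stable)
    mean_rank: pd.Series
    order: list  # most stable first


def _timepoint_samples(ds: StrainDataset, strain: int = 1) -> tuple[str, str]:
    last = max(ds.timepoints)
    return f"s{strain}_m0", f"s{strain}_m{6 * last}"


def genotype_metric(ds: StrainDataset, k: int = 10, call_rate_min: float = 0.95,
                    hwe_p_min: float = 1e-6) -> float:
    """Eigenvector-space distance between m0 and the last timepoint."""
    gm, _ = geno.qc_filter(ds.genotype, call_rate_min=call_rate_min, hwe_p_min=hwe_p_min)
    ed = geno.eigen_distance(gm, k=k)
    a, b = _timepoint_samples(ds)
    return ed.distance(a, b)


def _bin_cn_from_segments(track: cnv.BinnedLogRatio, segs: cnv.CNSegmentSet) -> np.ndarray:
    """Copy number per track bin, read off the covering segment."""
    out = np.empty(len(track.bins))
    sdf = segs.segments
    i = 0
    for chrom, grp in track.bins.groupby("chrom", sort=False):
        ssub = sdf[sdf["chrom"] == chrom]
        starts = ssub["start"].to_numpy()
        ends = ssub["end"].to_numpy()
        vals = 2.0 * 2.0 ** ssub["value"].to_numpy()
        mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2.0 + 0.5
        for m in mids:
            j = np.searchsorted(ends, m)
            j = min(j, len(ends) - 1)
            out[i] = vals[j] if starts[j] <= m <= ends[j] else vals[min(j, len(vals) - 1)]
            i += 1
    return out


def copy_number_metric(ds: StrainDataset, alpha: float = 0.01, n_perm: int = 200,
                       seed: int = 0) -> float:
    """CN-ratio area between segmented m12 and m0 tracks."""
    a, b = _timepoint_samples(ds)
    track_a, track_b = ds.cn_tracks[a], ds.cn_tracks[b]
    segs_a = cnv.segment_track(track_a, alpha=alpha, n_perm=n_perm, seed=seed)
    segs_b = cnv.segment_track(track_b, alpha=alpha, n_perm=n_perm, seed=seed + 1)
    cn_a = _bin_cn_from_segments(track_a, segs_a)
    cn_b = _bin_cn_from_segments(track_b, segs_b)
    # cumulative genome coordinate of bin midpoints
    widths = (track_a.bins["end"] - track_a.bins["start"]).to_numpy(dtype=float)
    pos = np.cumsum(widths) - widths / 2.0
    return cnv.cn_ratio_auc(cn_a, cn_b, pos)


def methylation_metric(ds: StrainDataset, fdr: float = 0.05) -> float:
    """Count of differentially methylated CpG probes, m12 vs m0."""
    norm = meth.normalize_intensities(ds.methylation)
    bm = meth.beta_values(norm, ds.meth_probe_map)
    mv = meth.m_values(bm.unmasked())
    a, b = _timepoint_samples(ds)
    reps = ds.config.n_meth_replicates
    ga = [f"{a}_r{k}" for k in range(1, reps + 1)]
    gb = [f"{b}_r{k}" for k in range(1, reps + 1)]
    return float(meth.probe_dm(mv, ga, gb, fdr=fdr).n_significant)


def transcriptome_metric(ds: StrainDataset) -> float:
    """Number of DEGs between m0 and m12 replicate groups."""
    a, b = _timepoint_samples(ds)
    reps = ds.config.n_replicates
    ga = [f"{a}_r{k}" for k in range(1, reps + 1)]
    gb = [f"{b}_r{k}" for k in range(1, reps + 1)]
    cm = ds.expression.subset_samples(ga + gb)
    cm = rna.filter_counts(cm)
    return float(rna.de_test(cm, ga, gb).n_deg)


def drug_metric(ds: StrainDataset) -> float:
    """Relative change of the mean AUC across compounds, m12 vs m0."""
    a, b = _timepoint_samples(ds)
    norm = drug.normalize_viability(ds.drug_plates)
    norm = norm[norm["strain"] == "s1"]
    table = drug.auc_table(norm, by=("timepoint",))
    rel, _ = drug.delta_auc(table.loc[a.split("_")[1]], table.loc[b.split("_")[1]])
    return rel


_METRIC_FUNCS = {
    "genotype": genotype_metric,
    "copy_number": copy_number_metric,
    "methylation": methylation_metric,
    "transcriptome": transcriptome_metric,
    "drug": drug_metric,
}


def compute_layer_metrics(
    datasets: dict, layers=LAYERS, seed: int = 0
) -> list[LayerMetric]:
    """One instability value per (cell line, layer), m12 vs m0."""
    out = []
    last = None
    for line, ds in datasets.items():
        last = max(ds.timepoints)
        for layer in layers:
            func = _METRIC_FUNCS[layer]
            kwargs = {"seed": seed} if layer == "copy_number" else {}
            out.append(
                LayerMetric(
                    layer=layer,
                    cell_line=line,
                    comparison=f"m{6 * last}-vs-m0",
                    value=float(func(ds, **kwargs)),
                )
            )
    return out


def rank_layer(metrics: list[LayerMetric]) -> pd.Series:
    """Rank cell lines within one layer; 1 = most stable; ties averaged."""
    layers = {m.layer for m in metrics}
    if len(layers) != 1:
        raise ValueError("rank_layer expects metrics from a single layer")
    lines = [m.cell_line for m in metrics]
    if len(set(lines)) != len(lines):
        raise ValueError("duplicate cell line in layer metrics")
    if len(lines) < 2:
        raise ValueError("need >= 2 cell lines to rank")
    vals = np.array([m.value if m.higher_is_less_stable else -m.value for m in metrics])
    ranks = sps.rankdata(vals)  # ascending: small value = stable = rank 1
    return pd.Series(ranks, index=lines, name=layers.pop())


def aggregate_ranking(per_layer_ranks: dict[str, pd.Series]) -> StabilityRanking:
    """Mean-rank aggregation across layers.

    All layers must cover the same cell lines.  Final order is by mean
    rank; ties broken by the genotype-layer rank (when present), then
    lexicographically.
    """
    frames = pd.DataFrame(per_layer_ranks)
    if frames.isna().any().any():
        raise ValueError("layers cover different cell-line sets")
    mean_rank = frames.mean(axis=1)
    tiebreak = frames["genotype"] if "genotype" in frames else pd.Series(0, index=frames.index)
    order = sorted(frames.index, key=lambda ln: (mean_rank[ln], tiebreak[ln], ln))
    return StabilityRanking(per_layer=frames, mean_rank=mean_rank, order=order)


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Simulate the configured cell lines, compute every requested layer's
    metric, rank, and (optionally) write the report bundle.

    Config keys (all optional): ``seed`` (int), ``scale`` (entity-count
    scale of the fixture), ``lines`` (name -> drift multiplier), ``layers``
    (subset of LAYERS), ``drift`` (DriftConfig field overrides).  A failing
    layer is recorded under ``failures`` and skipped in the aggregate.
    """
    seed = int(config.get("seed", 0))
    scale = float(config.get("scale", 0.1))
    layers = tuple(config.get("layers", LAYERS))
    unknown = set(layers) - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layers: {sorted(unknown)}")
    multipliers = dict(config.get("lines", PAPER_LIKE_MULTIPLIERS))
    drift_overrides = dict(config.get("drift", {}))
    base = DriftConfig(n_strains=1, seed=seed, **drift_overrides)

    datasets = {}
    for i, (line, mult) in enumerate(multipliers.items()):
        cfg = dataclasses.replace(base.scaled(float(mult)), seed=seed * 101 + i)
        from .simulate import simulate_dataset

        datasets[line] = simulate_dataset(
            line,
            cfg,
            n_loci=max(10, int(20_000 * scale)),
            n_cpgs=max(10, int(10_000 * scale)),
            n_genes=max(10, int(5_000 * scale)),
            n_compounds=20,  # fixed library size; not a scalable entity count
        )

    metrics: list[LayerMetric] = []
    failures: dict[str, str] = {}
    for layer in layers:
        try:
            layer_metrics = [
                m
                for m in compute_layer_metrics(datasets, layers=(layer,), seed=seed)
            ]
            metrics.extend(layer_metrics)
        except Exception as exc:  # pragma: no cover - defensive
            failures[layer] = repr(exc)

    ok_layers = [l for l in layers if l not in failures]
    ranks = {
        layer: rank_layer([m for m in metrics if m.layer == layer])
        for layer in ok_layers
    }
    ranking = aggregate_ranking(ranks)

    bundle = {
        "config": {
            "seed": seed,
            "scale": scale,
            "layers": list(layers),
            "lines": multipliers,
            "drift": drift_overrides,
            "thresholds": {
                "call_rate_min": 0.95,
                "hwe_p_min": 1e-6,
                "meth_fdr": 0.05,
                "deg_p_adj": 0.01,
                "deg_abs_log2fc": 1.0,
                "promoter_min_cpgs": 5,
                "count_min_total": 10,
                "low_expr_quantile": 0.40,
                "cv_top_quantile": 0.60,
                "fixed_dose_uM": 1.0,
            },
        },
        "metrics": [dataclasses.asdict(m) for m in metrics],
        "ranks": {k: v.to_dict() for k, v in ranks.items()},
        "mean_rank": ranking.mean_rank.to_dict(),
        "order_most_stable_first": ranking.order,
        "failures": failures,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metric_df = pd.DataFrame(bundle["metrics"]).sort_values(["layer", "cell_line"])
        metric_df.to_csv(out / "layer_metrics.csv", index=False)
        ranking.per_layer.sort_index().to_csv(out / "layer_ranks.csv")
        with open(out / "ranking.json", "w") as fh:
            json.dump(
                {
                    "mean_rank": bundle["mean_rank"],
                    "order_most_stable_first": ranking.order,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["config"], fh, indent=2, sort_keys=True)
        lines = ["stability ranking (most stable first):"]
        lines += [
            f"  {i + 1}. {ln} (mean rank {ranking.mean_rank[ln]:.2f})"
            for i, ln in enumerate(ranking.order)
        ]
        if failures:
            lines.append(f"failed layers: {sorted(failures)}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")

    return bundle
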