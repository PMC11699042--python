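"""Synthetic strain-drift simulator.

Generates a parental cell-line state (genotypes, integer copy-number
segments, CpG methylation levels, gene expression parameters, compound
potencies), evolves derived strains and culture timepoints under tunable
per-layer drift, and renders the evolved states as the assay-level inputs
every analysis module consumes: genotype call matrices with missingness,
binned log2 copy-ratio tracks, methylation intensity pairs with negative
and normalization control probes, replicated expression count matrices,
and long-format drug-screen plate tables with DMSO vehicle wells.

The study design emulated is one cell line observed as multiple strains
over three culture timepoints (m0/m6/m12), with three biological
replicates for expression, two technical replicates for methylation, and
four replicates (plates) for drug screens.  Drift intensity is controlled
per layer by :class:`DriftConfig`; every random draw comes from an
independent, deterministically keyed RNG substream so adding strains or
layers never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copynumber import BinnedLogRatio
from .genotype import GenotypeMatrix
from .methylation import IntensityMatrix
from .transcriptome import CountMatrix
from .drugresponse import PlateTable

__all__ = [
    "DriftConfig",
    "ParentalState",
    "StrainDataset",
    "simulate_parental",
    "evolve_strain",
    "render_assays",
    "simulate_dataset",
    "paper_like_dataset",
    "write_fixture_set",
    "default_karyotype",
]

# Allele frequencies of polymorphic array loci are drawn from Beta(0.8, 0.8);
# baseline CpG betas from the bimodal mixture 0.55*Beta(1.5,15) + 0.45*Beta(15,1.5).
ALLELE_FREQ_BETA = (0.8, 0.8)
BETA_MIX_WEIGHT_LOW = 0.55
BETA_MIX_LOW = (1.5, 15.0)
BETA_MIX_HIGH = (15.0, 1.5)

DOSE_SERIES_UM = np.logspace(-5, 1, 10)  # 1e-5 .. 10 uM
N_VEHICLE_WELLS = 8
MEAN_TOTAL_INTENSITY = 10_000.0
BACKGROUND_INTENSITY = 200.0
N_CONTROL_PROBES = 100

_LAYER_IDS = {
    "parental": 1,
    "genotype": 2,
    "cn": 3,
    "meth": 4,
    "expr": 5,
    "drug": 6,
    "evolve": 7,
}


def _tp_label(tp: int) -> str:
    """Timepoint index -> month label (0 -> m0, 1 -> m6, 2 -> m12)."""
    return f"m{6 * tp}"


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic substream keyed by (layer, strain, timepoint, ...)."""
    ints = [int(seed)]
    for k in keys:
        if isinstance(k, str):
            ints.append(_LAYER_IDS.get(k, zlib.crc32(k.encode())))
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class DriftConfig:
    """Per-layer drift intensities and study-design counts.

    Rates/fractions are per culture interval (one interval = six months);
    sd parameters set the magnitude of a single drift event on the scale
    named in the field.
    """

    snp_flip_rate: float = 0.002
    cn_event_rate: float = 1.0
    meth_drift_rate: float = 0.01
    meth_shift_sd: float = 2.0
    expr_de_fraction: float = 0.02
    expr_lfc_sd: float = 1.5
    drug_potency_sd: float = 0.15
    n_strains: int = 3
    n_timepoints: int = 3
    n_replicates: int = 3  # expression biological replicates
    n_meth_replicates: int = 2  # methylation technical replicates
    n_drug_replicates: int = 4  # drug-screen plates
    genotype_missing_rate: float = 0.02
    cn_noise_sd: float = 0.15
    meth_intensity_noise_sd: float = 0.05
    expr_size_factor_sd: float = 0.15
    drug_plate_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "snp_flip_rate",
            "meth_drift_rate",
            "expr_de_fraction",
            "genotype_missing_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "cn_event_rate",
            "meth_shift_sd",
            "expr_lfc_sd",
            "drug_potency_sd",
            "cn_noise_sd",
            "meth_intensity_noise_sd",
            "expr_size_factor_sd",
            "drug_plate_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_strains", "n_timepoints", "n_replicates", "n_meth_replicates", "n_drug_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def scaled(self, factor: float) -> "DriftConfig":
        """A copy with overall drift intensity multiplied by ``factor``.

        Event rates/fractions scale linearly (capped at 1); the IC50
        random-walk sd scales by sqrt(factor), since for a diffusion-like
        process intensity is variance per interval, not sd.  Design counts
        and assay noise levels are unchanged.
        """
        return dataclasses.replace(
            self,
            snp_flip_rate=min(1.0, self.snp_flip_rate * factor),
            cn_event_rate=self.cn_event_rate * factor,
            meth_drift_rate=min(1.0, self.meth_drift_rate * factor),
            expr_de_fraction=min(1.0, self.expr_de_fraction * factor),
            drug_potency_sd=self.drug_potency_sd * float(np.sqrt(factor)),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ParentalState:
    """One genomic/epigenomic/phenotypic state of a cell population."""

    loci: pd.DataFrame  # chromosome, position, in_exon, non_synonymous, genotype
    cn_segments: pd.DataFrame  # chrom, start, end (1-based incl.), cn, n_bins
    cpg_probes: pd.DataFrame  # chromosome, position, promoter_id, beta
    genes: pd.DataFrame  # chromosome, base_mean, dispersion
    compounds: pd.DataFrame  # log10_ic50, hill_slope, floor
    karyotype: dict  # chrom -> (n_bins, bin_size)

    def copy(self) -> "ParentalState":
        return ParentalState(
            loci=self.loci.copy(),
            cn_segments=self.cn_segments.copy(),
            cpg_probes=self.cpg_probes.copy(),
            genes=self.genes.copy(),
            compounds=self.compounds.copy(),
            karyotype=dict(self.karyotype),
        )


@dataclass
class StrainDataset:
    """All rendered assay layers for one cell line.

    Samples are named ``s<strain>_m<month>`` (e.g. ``s1_m0``, ``s1_m6``);
    replicated assays append ``_r<k>``.  ``states`` keeps the underlying true states
    for oracle checks.
    """

    cell_line: str
    config: DriftConfig
    sample_names: list
    strains: list
    timepoints: list
    genotype: GenotypeMatrix
    cn_tracks: dict  # sample -> BinnedLogRatio
    methylation: IntensityMatrix
    meth_probe_map: pd.DataFrame
    expression: CountMatrix
    drug_plates: PlateTable
    states: dict = field(repr=False, default_factory=dict)


def default_karyotype(n_chromosomes: int = 10, bins_per_chromosome: int = 40,
                      bin_size: int = 1_000_000, with_sex: bool = True) -> dict:
    """A compact karyotype: autosomes 1..n plus X and a short Y."""
    kt = {str(c): (bins_per_chromosome, bin_size) for c in range(1, n_chromosomes + 1)}
    if with_sex:
        kt["X"] = (bins_per_chromosome, bin_size)
        kt["Y"] = (max(2, bins_per_chromosome // 4), bin_size)
    return kt


def simulate_parental(
    n_loci: int,
    n_cpgs: int,
    n_genes: int,
    n_compounds: int,
    karyotype: dict | None = None,
    seed: int = 0,
) -> ParentalState:
    """Draw a reproducible parental cell-line state.

    Allele frequencies come from Beta(0.8, 0.8) and genotypes from the
    binomial (Hardy-Weinberg) law at those frequencies; baseline CpG betas
    are bimodal (mixture of a low and a high Beta component); expression
    base means are lognormal with lognormal NB dispersions; compound
    potencies are uniform on the log10 scale.
    """
    if min(n_loci, n_cpgs, n_genes, n_compounds) < 1:
        raise ValueError("all entity counts must be >= 1")
    karyotype = karyotype if karyotype is not None else default_karyotype()
    for chrom, spec_ in karyotype.items():
        if len(spec_) != 2 or spec_[0] < 1 or spec_[1] < 1:
            raise ValueError(f"invalid karyotype entry for {chrom!r}: {spec_!r}")
    rng = _rng(seed, "parental")

    chroms = list(karyotype)
    weights = np.array([karyotype[c][0] for c in chroms], dtype=float)
    weights /= weights.sum()
    chrom_lengths = {c: karyotype[c][0] * karyotype[c][1] for c in chroms}

    # genotype loci
    loc_chrom = rng.choice(chroms, size=n_loci, p=weights)
    loc_pos = np.array([rng.integers(1, chrom_lengths[c] + 1) for c in loc_chrom])
    freq = rng.beta(*ALLELE_FREQ_BETA, size=n_loci)
    genotype = rng.binomial(2, freq)
    in_exon = rng.random(n_loci) < 0.4
    non_syn = in_exon & (rng.random(n_loci) < 0.5)
    loci = pd.DataFrame(
        {
            "chromosome": loc_chrom,
            "position": loc_pos,
            "in_exon": in_exon,
            "non_synonymous": non_syn,
            "allele_freq": freq,
            "genotype": genotype,
        },
        index=[f"rs{i:07d}" for i in range(n_loci)],
    )

    # copy-number segments: mostly neutral, occasional baseline aneuploidy
    seg_rows = []
    for c in chroms:
        n_bins, bin_size = karyotype[c]
        n_segs = int(rng.integers(1, min(3, n_bins) + 1))
        cuts = np.sort(rng.choice(np.arange(1, n_bins), size=n_segs - 1, replace=False)) if n_segs > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [n_bins]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cn = int(rng.choice([1, 2, 2, 2, 2, 3]))
            seg_rows.append(
                {
                    "chrom": c,
                    "start": int(lo) * bin_size + 1,
                    "end": int(hi) * bin_size,
                    "cn": cn,
                    "n_bins": int(hi - lo),
                }
            )
    cn_segments = pd.DataFrame(seg_rows)

    # CpG probes with bimodal baseline betas and promoter grouping
    cpg_chrom = rng.choice(chroms, size=n_cpgs, p=weights)
    cpg_pos = np.array([rng.integers(1, chrom_lengths[c] + 1) for c in cpg_chrom])
    low = rng.random(n_cpgs) < BETA_MIX_WEIGHT_LOW
    beta = np.where(
        low,
        rng.beta(*BETA_MIX_LOW, size=n_cpgs),
        rng.beta(*BETA_MIX_HIGH, size=n_cpgs),
    )
    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    promoter_id = np.full(n_cpgs, None, dtype=object)
    i = 0
    prom = 0
    while i < n_cpgs:
        size = int(rng.integers(2, 9))
        if rng.random() < 0.7:  # ~70% of CpG runs sit in a promoter
            promoter_id[i : i + size] = f"prom{prom:05d}"
            prom += 1
        i += size
    cpg_probes = pd.DataFrame(
        {
            "chromosome": cpg_chrom,
            "position": cpg_pos,
            "promoter_id": promoter_id,
            "beta": beta,
        },
        index=[f"cg{i:07d}" for i in range(n_cpgs)],
    )

    # genes
    gene_chrom = rng.choice(chroms, size=n_genes, p=weights)
    base_mean = np.exp(rng.normal(3.0, 1.5, size=n_genes))
    dispersion = np.exp(rng.normal(np.log(0.05), 0.5, size=n_genes))
    genes = pd.DataFrame(
        {"chromosome": gene_chrom, "base_mean": base_mean, "dispersion": dispersion},
        index=[f"gene{i:05d}" for i in range(n_genes)],
    )

    # compounds
    compounds = pd.DataFrame(
        {
            "log10_ic50": rng.uniform(-3.0, 1.0, size=n_compounds),
            "hill_slope": rng.uniform(0.7, 2.0, size=n_compounds),
            "floor": rng.uniform(0.0, 0.3, size=n_compounds),
        },
        index=[f"drug{i:03d}" for i in range(n_compounds)],
    )

    return ParentalState(
        loci=loci,
        cn_segments=cn_segments,
        cpg_probes=cpg_probes,
        genes=genes,
        compounds=compounds,
        karyotype=dict(karyotype),
    )


def evolve_strain(
    parent: ParentalState,
    cfg: DriftConfig,
    n_intervals: int,
    rng_key: tuple = (),
) -> ParentalState:
    """Apply ``n_intervals`` culture intervals of drift to a state.

    Per interval: genotype calls flip between adjacent dosage states with
    probability ``snp_flip_rate`` per locus (hom<->het only, so over n
    intervals a locus is touched with probability 1-(1-r)^n); a Poisson
    number of whole-segment copy-number events of +/-1 (floored at 0);
    a ``meth_drift_rate`` fraction of CpGs shifted by N(0, meth_shift_sd)
    on the M-value scale and mapped back to beta; an ``expr_de_fraction``
    fraction of genes with means multiplied by 2^N(0, expr_lfc_sd); and
    every compound's log10 IC50 shifted by N(0, drug_potency_sd).

    A zero-rate config is the exact identity for any ``n_intervals``.
    """
    if n_intervals < 0:
        raise ValueError("n_intervals must be >= 0")
    state = parent.copy()
    rng = _rng(cfg.seed, "evolve", *rng_key)
    for _ in range(n_intervals):
        # genotype: adjacent-dosage transitions
        if cfg.snp_flip_rate > 0:
            flip = rng.random(len(state.loci)) < cfg.snp_flip_rate
            g = state.loci["genotype"].to_numpy().copy()
            het = g == 1
            to_hom = rng.choice([0, 2], size=len(g))
            g = np.where(flip & ~het, 1, g)
            g = np.where(flip & het, to_hom, g)
            state.loci["genotype"] = g
        # copy number: whole-segment +/-1 events
        if cfg.cn_event_rate > 0:
            n_events = rng.poisson(cfg.cn_event_rate)
            if n_events:
                idx = rng.integers(0, len(state.cn_segments), size=n_events)
                step = rng.choice([-1, 1], size=n_events)
                cn = state.cn_segments["cn"].to_numpy().copy()
                for k, s in zip(idx, step):
                    cn[k] = max(0, cn[k] + s)
                state.cn_segments["cn"] = cn
        # methylation: shift on M scale, map back to beta
        if cfg.meth_drift_rate > 0 and cfg.meth_shift_sd > 0:
            sel = rng.random(len(state.cpg_probes)) < cfg.meth_drift_rate
            if sel.any():
                b = state.cpg_probes["beta"].to_numpy().copy()
                m = np.log2(b[sel] / (1 - b[sel]))
                m = m + rng.normal(0.0, cfg.meth_shift_sd, size=sel.sum())
                p = 2.0**m
                b[sel] = np.clip(p / (1 + p), 1e-6, 1 - 1e-6)
                state.cpg_probes["beta"] = b
        # expression: multiplicative drift of gene means
        if cfg.expr_de_fraction > 0 and cfg.expr_lfc_sd > 0:
            sel = rng.random(len(state.genes)) < cfg.expr_de_fraction
            if sel.any():
                mean = state.genes["base_mean"].to_numpy().copy()
                mean[sel] *= 2.0 ** rng.normal(0.0, cfg.expr_lfc_sd, size=sel.sum())
                state.genes["base_mean"] = mean
        # drug potency: log10-IC50 random walk
        if cfg.drug_potency_sd > 0:
            state.compounds["log10_ic50"] = state.compounds[
                "log10_ic50"
            ].to_numpy() + rng.normal(0.0, cfg.drug_potency_sd, size=len(state.compounds))
    return state


def _render_genotype(states: dict, cfg: DriftConfig, sample_names: list) -> GenotypeMatrix:
    first = next(iter(states.values()))
    ann = first.loci[["chromosome", "in_exon", "non_synonymous"]].copy()
    calls = {}
    for (strain, tp), state in states.items():
        rng = _rng(cfg.seed, "genotype", strain, tp)
        g = state.loci["genotype"].to_numpy(dtype=float).copy()
        if cfg.genotype_missing_rate > 0:
            miss = rng.random(g.size) < cfg.genotype_missing_rate
            g[miss] = np.nan
        calls[_sample_name(strain, tp)] = g
    frame = pd.DataFrame(calls, index=first.loci.index).T
    frame = frame.loc[sample_names]
    return GenotypeMatrix(calls=frame, annotations=ann)


def _segments_to_track(state: ParentalState, noise_sd: float, rng) -> BinnedLogRatio:
    rows = []
    for _, seg in state.cn_segments.iterrows():
        n_bins = int(seg["n_bins"])
        bin_size = state.karyotype[seg["chrom"]][1]
        start0 = int(seg["start"]) - 1
        log2r = np.log2(max(float(seg["cn"]), 0.25) / 2.0)
        noise = rng.normal(0.0, noise_sd, size=n_bins) if noise_sd > 0 else np.zeros(n_bins)
        for k in range(n_bins):
            rows.append(
                {
                    "chrom": seg["chrom"],
                    "start": start0 + k * bin_size,
                    "end": start0 + (k + 1) * bin_size,
                    "log2ratio": log2r + noise[k],
                }
            )
    return BinnedLogRatio(pd.DataFrame(rows))


def _render_methylation(states: dict, cfg: DriftConfig):
    first = next(iter(states.values()))
    probes = first.cpg_probes.index
    meth, unmeth = {}, {}
    neg_m, neg_u, norm_m, norm_u = {}, {}, {}, {}
    nz = cfg.meth_intensity_noise_sd

    def noise(rng, size):
        return rng.lognormal(0.0, nz, size=size) if nz > 0 else np.ones(size)

    for (strain, tp), state in states.items():
        for rep in range(1, cfg.n_meth_replicates + 1):
            rng = _rng(cfg.seed, "meth", strain, tp, rep)
            col = f"{_sample_name(strain, tp)}_r{rep}"
            beta = state.cpg_probes["beta"].to_numpy()
            total = (
                rng.lognormal(np.log(MEAN_TOTAL_INTENSITY), 0.3, size=beta.size)
                if nz > 0
                else np.full(beta.size, MEAN_TOTAL_INTENSITY)
            )
            gain_m = rng.lognormal(0.0, 0.2) if nz > 0 else 1.0
            gain_u = rng.lognormal(0.0, 0.2) if nz > 0 else 1.0
            bg = BACKGROUND_INTENSITY
            meth[col] = gain_m * (beta * total + bg) * noise(rng, beta.size)
            unmeth[col] = gain_u * ((1 - beta) * total + bg) * noise(rng, beta.size)
            neg_m[col] = gain_m * bg * noise(rng, N_CONTROL_PROBES)
            neg_u[col] = gain_u * bg * noise(rng, N_CONTROL_PROBES)
            norm_m[col] = gain_m * (MEAN_TOTAL_INTENSITY + bg) * noise(rng, N_CONTROL_PROBES)
            norm_u[col] = gain_u * (MEAN_TOTAL_INTENSITY + bg) * noise(rng, N_CONTROL_PROBES)

    ctrl_idx = [f"neg{i:03d}" for i in range(N_CONTROL_PROBES)]
    norm_idx = [f"norm{i:03d}" for i in range(N_CONTROL_PROBES)]
    intensities = IntensityMatrix(
        meth=pd.DataFrame(meth, index=probes),
        unmeth=pd.DataFrame(unmeth, index=probes),
        neg_ctrl_meth=pd.DataFrame(neg_m, index=ctrl_idx),
        neg_ctrl_unmeth=pd.DataFrame(neg_u, index=ctrl_idx),
        norm_ctrl_meth=pd.DataFrame(norm_m, index=norm_idx),
        norm_ctrl_unmeth=pd.DataFrame(norm_u, index=norm_idx),
    )
    probe_map = first.cpg_probes[["chromosome", "promoter_id"]].copy()
    return intensities, probe_map


def _render_expression(states: dict, cfg: DriftConfig) -> CountMatrix:
    first = next(iter(states.values()))
    genes = first.genes.index
    counts = {}
    meta = []
    for (strain, tp), state in states.items():
        mean = state.genes["base_mean"].to_numpy()
        disp = state.genes["dispersion"].to_numpy()
        for rep in range(1, cfg.n_replicates + 1):
            rng = _rng(cfg.seed, "expr", strain, tp, rep)
            sf = (
                rng.lognormal(0.0, cfg.expr_size_factor_sd)
                if cfg.expr_size_factor_sd > 0
                else 1.0
            )
            mu = mean * sf
            lam = rng.gamma(shape=1.0 / disp, scale=disp * mu)
            col = f"{_sample_name(strain, tp)}_r{rep}"
            counts[col] = rng.poisson(lam)
            meta.append(
                {
                    "sample": col,
                    "strain": f"s{strain}",
                    "timepoint": _tp_label(tp),
                    "replicate": rep,
                    "batch": 1,
                }
            )
    gene_map = first.genes[["chromosome"]].copy()
    samples = pd.DataFrame(meta).set_index("sample")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes), gene_map=gene_map, samples=samples
    )


def _render_drug(states: dict, cfg: DriftConfig) -> PlateTable:
    rows = []
    nz = cfg.drug_plate_noise_sd
    for (strain, tp), state in states.items():
        for rep in range(1, cfg.n_drug_replicates + 1):
            rng = _rng(cfg.seed, "drug", strain, tp, rep)
            gain = rng.lognormal(0.0, 0.1) if nz > 0 else 1.0
            plate = f"{_sample_name(strain, tp)}_p{rep}"
            for comp, prm in state.compounds.iterrows():
                ic50 = 10.0 ** prm["log10_ic50"]
                v = prm["floor"] + (1 - prm["floor"]) / (
                    1 + (DOSE_SERIES_UM / ic50) ** prm["hill_slope"]
                )
                noise = rng.lognormal(0.0, nz, size=v.size) if nz > 0 else np.ones(v.size)
                for c, vi, ni in zip(DOSE_SERIES_UM, v, noise):
                    rows.append(
                        {
                            "compound": comp,
                            "conc_uM": c,
                            "replicate": rep,
                            "signal": gain * vi * ni,
                            "is_vehicle": False,
                            "plate": plate,
                            "strain": f"s{strain}",
                            "timepoint": _tp_label(tp),
                        }
                    )
            veh_noise = rng.lognormal(0.0, nz, size=N_VEHICLE_WELLS) if nz > 0 else np.ones(N_VEHICLE_WELLS)
            for ni in veh_noise:
                rows.append(
                    {
                        "compound": "DMSO",
                        "conc_uM": 0.0,
                        "replicate": rep,
                        "signal": gain * ni,
                        "is_vehicle": True,
                        "plate": plate,
                        "strain": f"s{strain}",
                        "timepoint": _tp_label(tp),
                    }
                )
    return PlateTable(pd.DataFrame(rows))


def render_assays(states: dict, cfg: DriftConfig, cell_line: str = "line") -> StrainDataset:
    """Render evolved states as assay-level inputs.

    ``states`` maps (strain index, timepoint index) to a
    :class:`ParentalState`; probe/gene/compound sets must agree across
    states.  Timepoint index t maps to the month label m{6t}.
    """
    keys = sorted(states)
    first = states[keys[0]]
    for k in keys[1:]:
        s = states[k]
        if (
            not s.loci.index.equals(first.loci.index)
            or not s.cpg_probes.index.equals(first.cpg_probes.index)
            or not s.genes.index.equals(first.genes.index)
            or not s.compounds.index.equals(first.compounds.index)
        ):
            raise ValueError("states must share probe/gene/compound sets")
    sample_names = [_sample_name(s, t) for s, t in keys]
    cn_tracks = {}
    for (strain, tp) in keys:
        rng = _rng(cfg.seed, "cn", strain, tp)
        cn_tracks[_sample_name(strain, tp)] = _segments_to_track(
            states[(strain, tp)], cfg.cn_noise_sd, rng
        )
    intensities, probe_map = _render_methylation(states, cfg)
    return StrainDataset(
        cell_line=cell_line,
        config=cfg,
        sample_names=sample_names,
        strains=sorted({s for s, _ in keys}),
        timepoints=sorted({t for _, t in keys}),
        genotype=_render_genotype(states, cfg, sample_names),
        cn_tracks=cn_tracks,
        methylation=intensities,
        meth_probe_map=probe_map,
        expression=_render_expression(states, cfg),
        drug_plates=_render_drug(states, cfg),
        states=dict(states),
    )


def simulate_dataset(
    cell_line: str,
    cfg: DriftConfig,
    n_loci: int = 20_000,
    n_cpgs: int = 10_000,
    n_genes: int = 5_000,
    n_compounds: int = 20,
    karyotype: dict | None = None,
) -> StrainDataset:
    """Simulate one cell line end to end: parent, strains, timepoints, assays.

    Strain 1 is the newly purchased line; higher-numbered strains carry an
    extra interval of independent laboratory history per index.  Every
    strain is then propagated through ``n_timepoints`` culture timepoints
    (timepoint t adds t intervals of drift relative to its m0).
    """
    parent = simulate_parental(
        n_loci, n_cpgs, n_genes, n_compounds, karyotype=karyotype, seed=cfg.seed
    )
    states = {}
    for strain in range(1, cfg.n_strains + 1):
        base = evolve_strain(parent, cfg, strain - 1, rng_key=(strain, 0))
        states[(strain, 0)] = base
        current = base
        for tp in range(1, cfg.n_timepoints):
            current = evolve_strain(current, cfg, 1, rng_key=(strain, tp))
            states[(strain, tp)] = current
    return render_assays(states, cfg, cell_line=cell_line)


# Drift multipliers for the five simulated cell lines of the default
# fixture, ordered most- to least-drifting (line1 > line2 > ... > line5).
# Geometric spacing (ratio 3) keeps adjacent lines distinguishable against
# the realization noise of a single culture history per seed.
PAPER_LIKE_MULTIPLIERS = {
    "line1": 40.0,
    "line2": 15.0,
    "line3": 6.0,
    "line4": 2.5,
    "line5": 1.0,
}


def paper_like_dataset(
    seed: int = 0,
    scale: float = 1.0,
    base_cfg: DriftConfig | None = None,
    karyotype: dict | None = None,
) -> dict:
    """The default multi-line fixture: five cell lines, three timepoints,
    drift intensity ordered line1 > line2 > ... > line5.

    ``scale`` shrinks the entity counts (loci/CpGs/genes/compounds) for
    fast repeated runs; drift rates are untouched.  Returns a dict mapping
    cell-line name to :class:`StrainDataset`.
    """
    base = base_cfg if base_cfg is not None else DriftConfig(n_strains=1, seed=seed)
    out = {}
    for i, (line, mult) in enumerate(PAPER_LIKE_MULTIPLIERS.items()):
        cfg = dataclasses.replace(base.scaled(mult), seed=seed * 101 + i)
        out[line] = simulate_dataset(
            line,
            cfg,
            n_loci=max(10, int(20_000 * scale)),
            n_cpgs=max(10, int(10_000 * scale)),
            n_genes=max(10, int(5_000 * scale)),
            n_compounds=20,  # fixed library size; not a scalable entity count
            karyotype=karyotype,
        )
    return out


def write_fixture_set(dataset: StrainDataset, out_dir) -> dict:
    """Write every assay layer in its standard text format plus a manifest.

    Emits genotype call and annotation CSVs, per-sample BED-graph-like
    copy-number tracks and SEG-like true segment tables, methylation
    intensity and control CSVs with the CpG map, the count matrix with
    gene/sample metadata, the long-format drug plate CSV, and
    ``manifest.json`` recording the config and a content hash.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def save(frame: pd.DataFrame, name: str, **kw):
        path = out / name
        frame.to_csv(path, **kw)
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    save(dataset.genotype.calls, "genotype_calls.csv")
    save(dataset.genotype.annotations, "locus_annotations.csv")
    for sample, track in dataset.cn_tracks.items():
        save(track.bins, f"cn_track_{sample}.tsv", sep="\t", index=False)
        seg = dataset.states[_parse_sample(sample)].cn_segments
        save(seg, f"cn_segments_{sample}.tsv", sep="\t", index=False)
    mx = dataset.methylation
    save(mx.meth, "meth_intensity_M.csv")
    save(mx.unmeth, "meth_intensity_U.csv")
    save(mx.neg_ctrl_meth, "meth_neg_ctrl_M.csv")
    save(mx.neg_ctrl_unmeth, "meth_neg_ctrl_U.csv")
    save(mx.norm_ctrl_meth, "meth_norm_ctrl_M.csv")
    save(mx.norm_ctrl_unmeth, "meth_norm_ctrl_U.csv")
    save(dataset.meth_probe_map, "cpg_map.csv")
    save(dataset.expression.counts, "counts.csv")
    save(dataset.expression.gene_map, "gene_map.csv")
    save(dataset.expression.samples, "sample_metadata.csv")
    save(dataset.drug_plates.data, "drug_plates.csv", index=False)

    cfg_dict = dataset.config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "cell_line": dataset.cell_line,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sample_name(strain: int, tp: int) -> str:
    return f"s{strain}_{_tp_label(tp)}"


def _parse_sample(sample: str) -> tuple[int, int]:
    strain, month = sample.split("_m")
    return int(strain.lstrip("s")), int(month) // 6
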