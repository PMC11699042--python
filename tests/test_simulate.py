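"""Synthetic drift simulator: determinism, identity limits, drift
statistics, rendering round trips, and fixture I/O."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from straindrift.methylation import beta_values, normalize_intensities
from straindrift.simulate import (
    ALLELE_FREQ_BETA,
    DriftConfig,
    default_karyotype,
    evolve_strain,
    render_assays,
    simulate_dataset,
    simulate_parental,
    write_fixture_set,
)


def zero_drift(**kw):
    return DriftConfig(
        snp_flip_rate=0.0,
        cn_event_rate=0.0,
        meth_drift_rate=0.0,
        expr_de_fraction=0.0,
        drug_potency_sd=0.0,
        **kw,
    )


def states_equal(a, b):
    pd.testing.assert_frame_equal(a.loci, b.loci)
    pd.testing.assert_frame_equal(a.cn_segments, b.cn_segments)
    pd.testing.assert_frame_equal(a.cpg_probes, b.cpg_probes)
    pd.testing.assert_frame_equal(a.genes, b.genes)
    pd.testing.assert_frame_equal(a.compounds, b.compounds)


class TestSimulateParental:
    def test_deterministic_under_seed(self):
        a = simulate_parental(500, 300, 100, 5, seed=42)
        b = simulate_parental(500, 300, 100, 5, seed=42)
        states_equal(a, b)

    def test_counts_and_annotations(self):
        st = simulate_parental(1000, 200, 50, 4, seed=0)
        assert len(st.loci) == 1000
        assert st.loci[["chromosome", "in_exon", "non_synonymous", "genotype"]].notna().all().all()
        assert st.loci["genotype"].isin([0, 1, 2]).all()
        assert ((st.cpg_probes["beta"] > 0) & (st.cpg_probes["beta"] < 1)).all()
        assert (st.genes["dispersion"] > 0).all()
        assert (st.compounds["hill_slope"] > 0).all()
        assert ((st.compounds["floor"] >= 0) & (st.compounds["floor"] < 1)).all()

    def test_allele_frequency_distribution(self):
        st = simulate_parental(50_000, 10, 10, 2, seed=3)
        ks = sps.kstest(st.loci["allele_freq"], sps.beta(*ALLELE_FREQ_BETA).cdf)
        assert ks.pvalue > 0.01

    def test_invalid_karyotype_rejected(self):
        with pytest.raises(ValueError):
            simulate_parental(10, 10, 10, 2, karyotype={"1": (0, 100)})


class TestEvolveStrain:
    def test_zero_rates_identity_any_depth(self):
        parent = simulate_parental(400, 200, 80, 4, seed=1)
        cfg = zero_drift(seed=1)
        for n in (0, 1, 5):
            states_equal(parent, evolve_strain(parent, cfg, n))

    def test_flip_count_binomial(self):
        r = 0.01
        parent = simulate_parental(20_000, 10, 10, 2, seed=9)
        cfg = DriftConfig(snp_flip_rate=r, seed=9)
        child = evolve_strain(parent, cfg, 1, rng_key=(1, 1))
        flips = (parent.loci["genotype"] != child.loci["genotype"]).sum()
        mean, sd = 20_000 * r, np.sqrt(20_000 * r * (1 - r))
        assert abs(flips - mean) <= 4 * sd

    def test_transitions_adjacent_only(self):
        parent = simulate_parental(5000, 10, 10, 2, seed=4)
        cfg = DriftConfig(snp_flip_rate=0.05, seed=4)
        child = evolve_strain(parent, cfg, 1, rng_key=(1, 1))
        a = parent.loci["genotype"].to_numpy()
        b = child.loci["genotype"].to_numpy()
        changed = a != b
        assert not np.any(changed & (np.abs(a - b) == 2) & (a != 1))

    def test_flip_count_monotone_in_rate(self):
        parent = simulate_parental(4000, 10, 10, 2, seed=6)
        rates = [0.002, 0.01, 0.05, 0.2]
        medians = []
        for r in rates:
            cfg = DriftConfig(snp_flip_rate=r, seed=6)
            flips = [
                (parent.loci["genotype"]
                 != evolve_strain(parent, cfg, 1, rng_key=(s, 1)).loci["genotype"]).sum()
                for s in range(20)
            ]
            medians.append(np.median(flips))
        assert all(x < y for x, y in zip(medians, medians[1:]))

    def test_betas_stay_in_unit_interval(self):
        parent = simulate_parental(100, 2000, 10, 2, seed=5)
        cfg = DriftConfig(meth_drift_rate=0.5, meth_shift_sd=5.0, seed=5)
        child = evolve_strain(parent, cfg, 3, rng_key=(1, 1))
        b = child.cpg_probes["beta"]
        assert ((b > 0) & (b < 1)).all()

    def test_cn_floor_zero(self):
        parent = simulate_parental(100, 100, 10, 2, seed=8)
        cfg = DriftConfig(cn_event_rate=50.0, seed=8)
        child = evolve_strain(parent, cfg, 3, rng_key=(1, 1))
        assert (child.cn_segments["cn"] >= 0).all()


class TestRenderAssays:
    def test_zero_noise_neutral_cn_bins_zero(self):
        parent = simulate_parental(50, 50, 20, 2, seed=2)
        parent.cn_segments["cn"] = 2
        cfg = zero_drift(n_strains=1, cn_noise_sd=0.0, seed=2)
        ds = render_assays({(1, 0): parent}, cfg)
        assert (ds.cn_tracks["s1_m0"].bins["log2ratio"] == 0).all()

    def test_vehicle_wells_normalize_to_one(self):
        parent = simulate_parental(10, 10, 10, 3, seed=2)
        cfg = zero_drift(n_strains=1, drug_plate_noise_sd=0.0, seed=2)
        ds = render_assays({(1, 0): parent}, cfg)
        df = ds.drug_plates.data
        veh = df[df["is_vehicle"]]
        assert np.allclose(veh["signal"] / veh.groupby("plate")["signal"].transform("mean"), 1.0)

    def test_beta_round_trip_no_noise(self):
        parent = simulate_parental(10, 300, 10, 2, seed=12)
        cfg = zero_drift(n_strains=1, meth_intensity_noise_sd=0.0, seed=12)
        ds = render_assays({(1, 0): parent}, cfg)
        norm = normalize_intensities(ds.methylation)
        bm = beta_values(norm, ds.meth_probe_map, offset=0.0)
        for col in bm.beta.columns:
            assert np.allclose(
                bm.beta[col].to_numpy(), parent.cpg_probes["beta"].to_numpy(), atol=1e-9
            )

    def test_full_determinism_across_renders(self):
        cfg = DriftConfig(n_strains=2, seed=33)
        d1 = simulate_dataset("x", cfg, n_loci=300, n_cpgs=200, n_genes=80, n_compounds=5)
        d2 = simulate_dataset("x", cfg, n_loci=300, n_cpgs=200, n_genes=80, n_compounds=5)
        pd.testing.assert_frame_equal(d1.genotype.calls, d2.genotype.calls)
        pd.testing.assert_frame_equal(d1.expression.counts, d2.expression.counts)
        pd.testing.assert_frame_equal(d1.methylation.meth, d2.methylation.meth)
        pd.testing.assert_frame_equal(d1.drug_plates.data, d2.drug_plates.data)

    def test_adding_strains_preserves_existing_streams(self):
        base = DriftConfig(n_strains=1, seed=44)
        more = dataclasses.replace(base, n_strains=2)
        d1 = simulate_dataset("x", base, n_loci=200, n_cpgs=100, n_genes=50, n_compounds=4)
        d2 = simulate_dataset("x", more, n_loci=200, n_cpgs=100, n_genes=50, n_compounds=4)
        cols = d1.expression.counts.columns
        pd.testing.assert_frame_equal(d1.expression.counts, d2.expression.counts[cols])
        pd.testing.assert_frame_equal(d1.genotype.calls, d2.genotype.calls.loc[d1.genotype.calls.index])


class TestDriftComposition:
    def test_two_single_intervals_match_one_double_in_distribution(self):
        # summary statistic: number of drifted CpGs; equal interval totals
        parent = simulate_parental(50, 3000, 10, 2, seed=17)
        cfg = DriftConfig(meth_drift_rate=0.05, seed=17)
        two_step, one_shot = [], []
        for s in range(15):
            mid = evolve_strain(parent, cfg, 1, rng_key=(s, 1))
            end = evolve_strain(mid, cfg, 1, rng_key=(s, 2))
            two_step.append((parent.cpg_probes["beta"] != end.cpg_probes["beta"]).sum())
            direct = evolve_strain(parent, cfg, 2, rng_key=(s, 3))
            one_shot.append((parent.cpg_probes["beta"] != direct.cpg_probes["beta"]).sum())
        assert sps.mannwhitneyu(two_step, one_shot).pvalue > 0.01


class TestFixtureIO:
    def test_write_read_round_trip_and_manifest(self, tmp_path):
        cfg = DriftConfig(n_strains=1, seed=5)
        ds = simulate_dataset("x", cfg, n_loci=150, n_cpgs=120, n_genes=60, n_compounds=4)
        manifest = write_fixture_set(ds, tmp_path)
        calls = pd.read_csv(tmp_path / "genotype_calls.csv", index_col=0)
        pd.testing.assert_frame_equal(calls, ds.genotype.calls)
        counts = pd.read_csv(tmp_path / "counts.csv", index_col=0)
        pd.testing.assert_frame_equal(counts, ds.expression.counts)
        with open(tmp_path / "manifest.json") as fh:
            stored = json.load(fh)
        assert stored["config_sha256"] == manifest["config_sha256"]
        assert set(manifest["files"]) == set(stored["files"])

    def test_regeneration_byte_identical(self, tmp_path):
        cfg = DriftConfig(n_strains=1, seed=5)
        ds1 = simulate_dataset("x", cfg, n_loci=100, n_cpgs=80, n_genes=40, n_compounds=4)
        ds2 = simulate_dataset("x", cfg, n_loci=100, n_cpgs=80, n_genes=40, n_compounds=4)
        m1 = write_fixture_set(ds1, tmp_path / "a")
        m2 = write_fixture_set(ds2, tmp_path / "b")
        assert m1["files"] == m2["files"]  # same sha256 for every file


def test_default_karyotype_shape():
    kt = default_karyotype(n_chromosomes=5)
    assert set(kt) == {"1", "2", "3", "4", "5", "X", "Y"}
    assert all(n >= 1 and b >= 1 for n, b in kt.values())
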