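"""Generator contracts: determinism, construction validity, parameter recovery."""

import filecmp
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from targetcall.intervals import GenomicInterval, Peak
from targetcall.motifs import count_sites_near_summits
from targetcall.simulate import (
    SimulationConfig,
    plant_targets,
    read_fixture,
    recover_targets,
    simulate,
    simulate_genes,
    simulate_genome,
    write_fixture,
)

SMALL = dict(n_genes=24, n_target_genes=6, n_background_genes_with_peaks=4,
             chromosome_length=250_000)


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(replicate_sensitivity=1.5)

    def test_planted_genes_cannot_exceed_genes(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=5, n_target_genes=4, n_background_genes_with_peaks=2)

    def test_target_clusters_must_be_known(self):
        with pytest.raises(ValueError):
            SimulationConfig(target_clusters=("nope",))


class TestGenome:
    def test_same_seed_identical(self):
        config = SimulationConfig(seed=5, n_chromosomes=1, chromosome_length=10_000)
        assert simulate_genome(config).sequences == simulate_genome(config).sequences

    def test_lengths_match_config(self):
        config = SimulationConfig(seed=5, n_chromosomes=3, chromosome_length=20_000)
        assert simulate_genome(config).lengths == {f"chr{i}": 20_000 for i in (1, 2, 3)}

    def test_base_frequencies_near_uniform(self):
        config = SimulationConfig(seed=5, n_chromosomes=1, chromosome_length=1_000_000)
        seq = simulate_genome(config)["chr1"]
        n = len(seq)
        se = np.sqrt(0.25 * 0.75 / n)  # binomial standard error of a base fraction
        for base in "ACGT":
            assert abs(seq.count(base) / n - 0.25) < 3 * se


class TestGroundTruthConstruction:
    def test_every_target_has_peak_within_gap_and_matched_atac(self, noiseless_sim):
        sim = noiseless_sim
        genes = {g.gene_id: g for g in sim.genes}
        truth = sim.truth.table
        for row in truth[truth.is_target == 1].itertuples():
            gene = genes[row.gene_id]
            peak_iv = GenomicInterval(row.chrom, row.peak_start, row.peak_end)
            from targetcall.intervals import interval_gap

            assert interval_gap(peak_iv, gene.interval) <= sim.config.peak_gene_max_gap
            # matched ATAC peak restricted to the target clusters
            assert set(row.clusters.split(",")) == set(sim.config.target_clusters)

    def test_planted_ets_sites_rediscovered_by_scanning(self, noiseless_sim):
        sim = noiseless_sim
        truth = sim.truth.table
        targets = truth[truth.is_target == 1]
        peaks = [
            Peak(GenomicInterval(r.chrom, r.peak_start, r.peak_end),
                 summit_offset=r.summit - r.peak_start)
            for r in targets.itertuples()
        ]
        counts = count_sites_near_summits(peaks, sim.genome, sim.config.ets_site_window)
        assert [c.n_sites for c in counts] == [sim.config.n_planted_ets_sites] * len(peaks)

    def test_target_expression_restricted_to_target_clusters(self, noiseless_sim):
        sim = noiseless_sim
        off_clusters = set(sim.config.cluster_labels) - set(sim.config.target_clusters)
        for gid in sim.truth.target_gene_ids:
            expressed = sim.expression.expressed_clusters(gid)
            assert expressed and expressed <= set(sim.config.target_clusters)
            assert all(sim.expression.mean.at[gid, c] == 0 for c in off_clusters)

    def test_infeasible_placement_raises(self):
        config = SimulationConfig(seed=0, chromosome_length=20_000, n_genes=10,
                                  n_target_genes=2, n_background_genes_with_peaks=0)
        with pytest.raises(ValueError, match="infeasible"):
            simulate(config)


class TestReplication:
    def test_expected_peak_count_binomial(self):
        config = SimulationConfig(seed=0, replicate_sensitivity=0.6,
                                  background_peak_rate=0.0, **SMALL)
        n_true = config.n_target_genes + config.n_background_genes_with_peaks
        counts = []
        for seed in range(15):
            sim = simulate(replace(config, seed=seed))
            counts.extend(len(p) for p in sim.chip.values())
        mean = np.mean(counts)
        expected = n_true * config.replicate_sensitivity
        se = np.sqrt(n_true * 0.6 * 0.4 / len(counts))
        assert abs(mean - expected) < 4 * se

    def test_zero_sensitivity_calls_nothing(self):
        sim = simulate(SimulationConfig(seed=2, replicate_sensitivity=0.0,
                                        background_peak_rate=0.0, **SMALL))
        assert all(len(p) == 0 for p in sim.chip.values())
        assert recover_targets(sim).called_genes == []

    def test_retained_peaks_nested_across_sensitivities(self):
        # the coupled retention draws make kept-peak sets nested per seed
        names = {}
        for s in (1.0, 0.6, 0.2):
            sim = simulate(SimulationConfig(seed=4, replicate_sensitivity=s,
                                            background_peak_rate=0.0, **SMALL))
            names[s] = {(r, p.name) for r, peaks in sim.chip.items() for p in peaks}
        assert names[0.2] <= names[0.6] <= names[1.0]


class TestFixtureRoundTrip:
    def test_byte_identical_for_same_config(self, tmp_path):
        config = SimulationConfig(seed=11, **SMALL)
        for d in ("a", "b"):
            write_fixture(simulate(config), tmp_path / d)
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files_a, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_round_trip_reproduces_objects(self, tmp_path, small_sim):
        write_fixture(small_sim, tmp_path / "fx")
        fx = read_fixture(tmp_path / "fx")
        assert fx.genome.sequences == small_sim.genome.sequences
        assert fx.genes == small_sim.genes
        for rep_id, peaks in small_sim.chip.items():
            got = [(p.interval, p.summit_offset, p.name) for p in fx.chip[rep_id]]
            assert got == [(p.interval, p.summit_offset, p.name) for p in peaks]
        for cluster, peaks in small_sim.atac.items():
            assert [p.interval for p in fx.atac[cluster]] == [p.interval for p in peaks]
        pd.testing.assert_frame_equal(
            fx.expression.mean, small_sim.expression.mean,
            atol=1e-4, rtol=0, check_names=False,
        )
        assert set(fx.truth_table.gene_id) == (
            small_sim.truth.target_gene_ids | small_sim.truth.background_gene_ids
        )

    def test_ground_truth_lists_every_planted_gene(self, tmp_path, small_sim):
        write_fixture(small_sim, tmp_path / "fx")
        truth = read_fixture(tmp_path / "fx").truth_table
        assert (truth.is_target == 1).sum() == small_sim.config.n_target_genes

    def test_pipeline_on_reread_fixture_recovers_targets(self, tmp_path, small_sim):
        from targetcall.targets import call_targets

        write_fixture(small_sim, tmp_path / "fx")
        fx = read_fixture(tmp_path / "fx")
        result = call_targets(
            {"chip": fx.chip}, fx.atac, fx.genes, fx.expression, fx.genome,
            target_clusters=small_sim.config.target_clusters,
        )["chip"]
        assert set(result.called_genes) == small_sim.truth.target_gene_ids
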