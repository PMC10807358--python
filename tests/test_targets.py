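"""Specificity scoring (tau), ChIP-ATAC linkage, and four-criteria target calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetcall.expression import ExpressionSummary
from targetcall.intervals import GenomicInterval, Peak
from targetcall.simulate import SimulationConfig, recover_targets, simulate
from targetcall.targets import (
    chip_atac_linked_peaks,
    compare_gene_lists,
    pool_replicate_peaks,
    specificity,
    tau_index,
)

iv = GenomicInterval


def expr_of(means: dict[str, list[float]], clusters: list[str]) -> ExpressionSummary:
    mean = pd.DataFrame(means, index=clusters).T
    mean.columns = clusters
    frac = (mean > 0).astype(float) * 0.5
    return ExpressionSummary(mean, frac)


class TestTau:
    def test_uniform_is_zero(self):
        assert tau_index([5, 5, 5, 5]) == 0.0

    def test_single_cluster_is_one(self):
        assert tau_index([0, 0, 7, 0]) == 1.0

    def test_hand_evaluated_mixed_vector(self):
        # ((1 - 1/4) + (1 - 2/4) + 0) / 2
        assert tau_index([1, 2, 4]) == pytest.approx(0.625)

    def test_all_zero_is_unscorable(self):
        assert tau_index([0, 0, 0]) is None

    @given(
        values=st.lists(
            st.one_of(st.just(0.0), st.floats(1e-3, 100)), min_size=2, max_size=8
        ),
        scale=st.floats(0.01, 50, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounds_and_scale_invariance(self, values, scale):
        tau = tau_index(values)
        if tau is None:
            assert max(values) == 0
        else:
            assert 0.0 <= tau <= 1.0
            assert tau_index([v * scale for v in values]) == pytest.approx(tau)

    def test_requires_at_least_two_clusters(self):
        with pytest.raises(ValueError):
            tau_index([3.0])


class TestSpecificity:
    clusters = ["a", "b", "target"]

    def test_flags_and_top_cluster(self):
        expr = expr_of(
            {"uniform": [5, 5, 5], "spec": [0, 0, 7], "silent": [0, 0, 0]},
            self.clusters,
        )
        scores = {s.gene_id: s for s in specificity(expr, target_clusters={"target"})}
        assert not scores["uniform"].specific
        assert scores["spec"].specific and scores["spec"].in_target_clusters
        assert scores["spec"].top_cluster == "target"
        assert scores["silent"].tau is None and not scores["silent"].specific

    def test_top_cluster_outside_target_set(self):
        expr = expr_of({"g": [7, 0, 0]}, self.clusters)
        (s,) = specificity(expr, target_clusters={"target"})
        assert s.specific and not s.in_target_clusters

    def test_single_cluster_matrix_is_an_error(self):
        expr = ExpressionSummary(
            pd.DataFrame({"only": [1.0]}, index=["g"]),
            pd.DataFrame({"only": [0.5]}, index=["g"]),
        )
        with pytest.raises(ValueError):
            specificity(expr)


class TestPoolingAndLinkage:
    def test_pooled_support_counts_distinct_replicates(self):
        sets = {
            "r1": [Peak(iv("c", 0, 100), replicate_id="r1")],
            "r2": [Peak(iv("c", 50, 150), replicate_id="r2")],
            "r3": [Peak(iv("c", 400, 500), replicate_id="r3")],
        }
        merged = pool_replicate_peaks(sets, min_replicates=2)
        assert len(merged) == 1
        assert merged[0].interval == iv("c", 0, 150)
        assert merged[0].replicates == {"r1", "r2"}

    def test_linkage_is_half_open(self):
        chip = [Peak(iv("c", 100, 200)), Peak(iv("c", 100, 200))]
        atac = {"k": [Peak(iv("c", 150, 160), assay="atac", cluster="k")],
                "m": [Peak(iv("c", 200, 300), assay="atac", cluster="m")]}
        linked = chip_atac_linked_peaks(chip, atac)
        assert linked[0] == (True, frozenset({"k"}))  # [200,300) does not touch [100,200)

    def test_all_planted_peaks_linked_when_match_prob_is_one(self, noiseless_sim):
        result = recover_targets(noiseless_sim)
        target_calls = [c for c in result.calls if c.gene_id in noiseless_sim.truth.target_gene_ids]
        assert all(c.atac_overlapping for c in target_calls)
        for c in target_calls:
            assert c.atac_clusters >= set(noiseless_sim.config.target_clusters)


class TestCallTargets:
    def test_noiseless_recovery_is_exact(self, noiseless_sim):
        result = recover_targets(noiseless_sim)
        assert set(result.called_genes) == noiseless_sim.truth.target_gene_ids

    def test_known_target_excluded_at_c1(self, noiseless_sim):
        victim = sorted(noiseless_sim.truth.target_gene_ids)[0]
        result = recover_targets(noiseless_sim, known_targets={victim})
        assert victim not in result.called_genes
        (call,) = [c for c in result.calls if c.gene_id == victim]
        assert "c1_novel" not in call.passed_criteria
        assert {"c2_chip_2kb", "c3_atac_overlap", "c4_specific"} <= call.passed_criteria

    def test_background_genes_fail_only_specificity(self, noiseless_sim):
        calls = {c.gene_id: c for c in recover_targets(noiseless_sim).calls}
        for gid in noiseless_sim.truth.background_gene_ids:
            assert not calls[gid].verdict
            assert "c4_specific" not in calls[gid].passed_criteria
            assert "c3_atac_overlap" in calls[gid].passed_criteria

    def test_ets_annotation_does_not_gate_calls(self, noiseless_sim):
        result = recover_targets(noiseless_sim)
        called = {c.gene_id for c in result.calls if c.verdict}
        # planted sites exist, but the verdict logic never consults them:
        # calling again without a genome (no Ets annotation) gives the same set
        result_no_genome = recover_targets(noiseless_sim, genome=None)
        assert {c.gene_id for c in result_no_genome.calls if c.verdict} == called
        assert all(c.n_ets_sites_max is None for c in result_no_genome.calls)

    def test_enlarging_window_or_relaxing_tau_never_removes_targets(self):
        sim = simulate(SimulationConfig(seed=13, n_genes=24, n_target_genes=6,
                                        n_background_genes_with_peaks=4,
                                        chromosome_length=250_000,
                                        replicate_sensitivity=0.7))
        called_prev: set = set()
        for window, tau_min in [(500, 0.95), (1000, 0.9), (2000, 0.8), (4000, 0.5)]:
            called = set(recover_targets(sim, window_bp=window, tau_min=tau_min).called_genes)
            assert called_prev <= called
            called_prev = called


class TestCompareGeneLists:
    def test_inclusion_exclusion_worked_example(self):
        common = [f"c{i}" for i in range(42)]
        a = common + [f"a{i}" for i in range(5)]  # |A| = 47
        b = common + [f"b{i}" for i in range(4)]  # |B| = 46
        comparison = compare_gene_lists(a, b)
        assert (comparison.n_a, comparison.n_b) == (47, 46)
        assert comparison.n_intersection == 42
        assert comparison.n_union == 51

    def test_identical_lists(self):
        comparison = compare_gene_lists(["x", "y"], ["y", "x"])
        assert comparison.intersection == comparison.union == {"x", "y"}

    def test_disjoint_lists(self):
        comparison = compare_gene_lists(["x"], ["y", "z"])
        assert comparison.n_union == 3 and comparison.n_intersection == 0

    @given(
        a=st.sets(st.integers(0, 50)),
        b=st.sets(st.integers(0, 50)),
    )
    @settings(derandomize=True, max_examples=200)
    def test_inclusion_exclusion_property(self, a, b):
        comparison = compare_gene_lists(map(str, a), map(str, b))
        assert comparison.n_union == comparison.n_a + comparison.n_b - comparison.n_intersection
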