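import filecmp
from pathlib import Path

import numpy as np
import pytest

import dollotrace as dt


class TestSimulateEvolution:
    def test_zero_rates_zero_loci(self):
        tree = dt.random_tree(4, seed=0)
        config = dt.SimConfig(tree=tree, rates={"copia": {"root": 0.0}}, seed=1)
        truth = dt.simulate_evolution(config)
        assert truth.loci == []
        with pytest.raises(dt.ValidationError):
            truth.truth_matrix()

    def test_poisson_gain_counts(self):
        tree = dt.random_tree(4, seed=0)
        totals = []
        for seed in range(200):
            config = dt.SimConfig(tree=tree, rates={"copia": {"root": 40.0}}, seed=seed)
            totals.append(len(dt.simulate_evolution(config).loci))
        mean = np.mean(totals)
        se = np.sqrt(40.0 / len(totals))
        assert abs(mean - 40.0) <= 3 * se

    def test_unknown_branch_rejected(self):
        tree = dt.random_tree(4, seed=0)
        with pytest.raises(dt.ValidationError, match="unknown branch"):
            dt.SimConfig(tree=tree, rates={"copia": {"nope": 1.0}})

    def test_deletion_bookkeeping(self):
        tree = dt.Tree.from_topology(((0, 1), (2, 3)), ["A", "B", "C", "D"])
        tree.assign_branch_ids()
        clade_ab = next(
            b for b, c in tree.branch_clades().items() if c == frozenset({"A", "B"})
        )
        genome = dt.default_genome()
        deletion = dt.DeletionEvent(clade_ab, "chrX", 0, 23_542_271, (1, 2))
        config = dt.SimConfig(
            tree=tree,
            rates={"copia": {"root": 60.0}},
            deletions=[deletion],
            seed=5,
        )
        truth = dt.simulate_evolution(config)
        removed = {
            i
            for i, locus in enumerate(truth.loci)
            if locus.chrom == "chrX" and locus.haplotype in (1, 2)
        }
        for idx, locus in enumerate(truth.loci):
            for sample in ("A", "B"):
                expected = idx not in removed
                assert (idx in truth.sample_loci[sample]) == expected
            for sample in ("C", "D"):
                assert idx in truth.sample_loci[sample]  # deletion is clade-local
        assert truth.deletion_ledger[0]["n_loci_removed"] == len(removed)

    def test_deletion_does_not_touch_later_gains(self):
        tree = dt.Tree.from_topology(((0, 1), (2, 3)), ["A", "B", "C", "D"])
        tree.assign_branch_ids()
        clade_ab = next(
            b for b, c in tree.branch_clades().items() if c == frozenset({"A", "B"})
        )
        deletion = dt.DeletionEvent(clade_ab, "chrX", 0, 23_542_271, tuple(range(1, 5)))
        config = dt.SimConfig(
            tree=tree,
            rates={"copia": {clade_ab: 0.0, "A": 30.0}},
            deletions=[deletion],
            seed=6,
        )
        truth = dt.simulate_evolution(config)
        # insertions on the terminal branch A postdate the deletion on the
        # ancestral branch and must survive
        for idx, locus in enumerate(truth.loci):
            assert locus.branch == "A"
            assert idx in truth.sample_loci["A"]


class TestEmission:
    def test_full_false_negative_rate_empties_beds(self):
        config = dt.recovery_config(n_taxa=4, gains_per_branch=10, fn_rate=1.0, seed=2)
        truth = dt.simulate_evolution(config)
        calls = dt.generate_sample_calls(truth, config)
        assert all(len(v) == 0 for v in calls.values())

    def test_false_positive_rate(self):
        tree = dt.random_tree(4, seed=0)
        counts = []
        for seed in range(50):
            config = dt.SimConfig(
                tree=tree, rates={"copia": {"root": 0.0, "S1": 1.0}}, fp_rate=5.0, seed=seed
            )
            truth = dt.simulate_evolution(config)
            calls = dt.generate_sample_calls(truth, config)
            counts.extend(
                sum(1 for c in sample_calls if c.support == "fp")
                for sample_calls in calls.values()
            )
        mean = np.mean(counts)
        se = np.sqrt(5.0 / len(counts))
        assert abs(mean - 5.0) <= 3 * se

    def test_jittered_calls_contain_insertion_point(self):
        config = dt.recovery_config(n_taxa=6, gains_per_branch=10, seed=3)
        truth = dt.simulate_evolution(config)
        calls = dt.generate_sample_calls(truth, config)
        by_pos = {(l.chrom, l.strand, l.pos) for l in truth.loci}
        for sample_calls in calls.values():
            for call in sample_calls:
                assert call.end - call.start <= 2 * config.jitter + 1
                assert any(
                    c == call.chrom and s == call.strand and call.start <= p < call.end
                    for c, s, p in by_pos
                )

    def test_zero_noise_zero_jitter_reproduces_truth_ids(self):
        config = dt.recovery_config(n_taxa=6, gains_per_branch=15, seed=9, jitter=0)
        truth = dt.simulate_evolution(config)
        matrix, _, _ = dt.cluster_pipeline(
            dt.generate_sample_calls(truth, config), config.genome
        )
        assert set(matrix.locus_ids) == set(truth.truth_matrix().locus_ids)
        assert dt.align_to_truth(matrix, truth) == truth.truth_matrix()


class TestDepth:
    def test_flat_depth_mean(self):
        genome = dt.GenomeConfig(
            chrom_lengths={"chr1": 5_000_000},
            normal_recomb_regions=[("chr1", 0, 5_000_000)],
        )
        config = dt.SimConfig(
            tree=dt.random_tree(4, seed=0),
            rates={"copia": {"root": 1.0}},
            genome=genome,
            seed=4,
        )
        table = dt.simulate_depth(config, mean_count=100, samples=["S1"])["S1"]
        assert len(table) == 500
        assert abs(table["count"].mean() - 100) < 3 * np.sqrt(100 / len(table))

    def test_segment_scales_depth(self):
        genome = dt.GenomeConfig(
            chrom_lengths={"chr1": 10_000_000},
            normal_recomb_regions=[("chr1", 0, 10_000_000)],
        )
        config = dt.SimConfig(
            tree=dt.random_tree(4, seed=0),
            rates={"copia": {"root": 1.0}},
            genome=genome,
            seed=5,
        )
        segs = {"S1": [("chr1", 0, 5_000_000, 6)]}
        table = dt.simulate_depth(config, cn_segments=segs, mean_count=100, samples=["S1"])["S1"]
        in_seg = table[table["end"] <= 5_000_000]["count"].mean()
        out_seg = table[table["start"] >= 5_000_000]["count"].mean()
        assert in_seg == pytest.approx(150, abs=3 * np.sqrt(150 / 500))
        assert out_seg == pytest.approx(100, abs=3 * np.sqrt(100 / 500))

    def test_overlapping_segments_rejected(self):
        config = dt.SimConfig(
            tree=dt.random_tree(4, seed=0), rates={"copia": {"root": 1.0}}, seed=6
        )
        segs = {"S1": [("chrX", 0, 2_000_000, 6), ("chrX", 1_000_000, 3_000_000, 2)]}
        with pytest.raises(dt.ValidationError, match="overlapping"):
            dt.simulate_depth(config, cn_segments=segs, samples=["S1"])

    def test_low_mappability_windows_flagged_and_excluded(self):
        config = dt.SimConfig(
            tree=dt.random_tree(4, seed=0), rates={"copia": {"root": 1.0}}, seed=7
        )
        table = dt.simulate_depth(
            config, samples=["S1"], low_mappability_fraction=0.1
        )["S1"]
        from dollotrace.cnv_profile import filter_windows

        out = filter_windows(table)
        frac = out["excluded"].mean()
        assert 0.05 < frac < 0.15
        assert (out.loc[out["excluded"], "mappability"] < 0.85).all()


class TestDeterminism:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        config = dt.recovery_config(
            n_taxa=6, gains_per_branch=10, fn_rate=0.1, fp_rate=2.0, seed=11
        )
        for name in ("run1", "run2"):
            truth = dt.simulate_evolution(config)
            dt.emit_sample_beds(truth, config, tmp_path / name)
        files = sorted(p.name for p in (tmp_path / "run1").iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(
                tmp_path / "run1" / name, tmp_path / "run2" / name, shallow=False
            )

    def test_different_seeds_differ(self):
        a = dt.simulate_evolution(dt.recovery_config(n_taxa=4, gains_per_branch=10, seed=1))
        b = dt.simulate_evolution(dt.recovery_config(n_taxa=4, gains_per_branch=10, seed=2))
        assert {(l.chrom, l.pos) for l in a.loci} != {(l.chrom, l.pos) for l in b.loci}
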