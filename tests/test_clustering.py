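import numpy as np
import pytest
from hypothesis import given, strategies as st

import dollotrace as dt
from dollotrace.locus_clustering import (
    build_matrix,
    cluster_calls,
    cluster_pipeline,
    filter_clusters,
    mask_calls,
)

from conftest import make_call


def connected_components_oracle(calls):
    """Exhaustive pairwise-overlap graph -> connected components (union-find)."""
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(calls):
        for j, b in enumerate(calls):
            if j <= i:
                continue
            if (
                a.chrom == b.chrom
                and a.strand == b.strand
                and a.start < b.end
                and b.start < a.end
            ):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def cluster_index_sets(calls):
    index = {id(c): i for i, c in enumerate(calls)}
    return {frozenset(index[id(c)] for c in locus.calls) for locus in cluster_calls(calls)}


class TestMasking:
    def test_region_boundary(self, fly_genome):
        # the chrX euchromatin boundary is quoted 1-based as 405,967
        below = make_call(chrom="chrX", start=399_999, end=400_100)
        inside = make_call(chrom="chrX", start=500_000, end=500_001)
        kept = mask_calls([below, inside], fly_genome)
        assert kept == [inside]

    def test_call_straddling_boundary_removed(self, fly_genome):
        straddle = make_call(chrom="chrX", start=405_960, end=405_980)
        assert mask_calls([straddle], fly_genome) == []

    def test_excluded_family_removed(self, fly_genome):
        ine1 = make_call(chrom="chr2L", start=500_000, end=500_001, family="INE-1")
        copia = make_call(chrom="chr2L", start=500_000, end=500_001, family="copia")
        assert mask_calls([ine1, copia], fly_genome) == [copia]

    def test_unknown_chromosome_is_config_mismatch(self, fly_genome):
        with pytest.raises(dt.ValidationError, match="chrUn"):
            mask_calls([make_call(chrom="chrUn")], fly_genome)


class TestClustering:
    def test_direct_overlap_merges(self):
        a = make_call(sample="s1", start=999, end=1005)
        b = make_call(sample="s2", start=1002, end=1008)
        loci = cluster_calls([a, b])
        assert len(loci) == 1
        assert loci[0].samples == {"s1", "s2"}
        assert (loci[0].start, loci[0].end) == (999, 1008)

    def test_opposite_strands_do_not_merge(self):
        a = make_call(sample="s1", strand="+")
        b = make_call(sample="s2", strand="-")
        assert len(cluster_calls([a, b])) == 2

    def test_transitive_chain(self):
        calls = [
            make_call(sample="s1", start=100, end=200),
            make_call(sample="s2", start=190, end=300),
            make_call(sample="s3", start=290, end=400),
        ]
        loci = cluster_calls(calls)
        assert len(loci) == 1
        assert loci[0].samples == {"s1", "s2", "s3"}

    def test_touching_intervals_do_not_merge(self):
        # half-open: [100,200) and [200,300) share no base
        a = make_call(start=100, end=200)
        b = make_call(sample="s2", start=200, end=300)
        assert len(cluster_calls([a, b])) == 2

    def test_conservation_of_calls(self):
        rng = np.random.default_rng(0)
        calls = [
            make_call(
                sample=f"s{rng.integers(1, 4)}",
                start=int(s),
                end=int(s + rng.integers(1, 50)),
                strand="+" if rng.random() < 0.5 else "-",
            )
            for s in rng.integers(0, 2000, size=40)
        ]
        loci = cluster_calls(calls)
        assert sum(l.n_calls for l in loci) == len(calls)

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            calls = [
                make_call(
                    sample=f"s{rng.integers(1, 5)}",
                    start=int(s),
                    end=int(s + rng.integers(1, 80)),
                    strand="+" if rng.random() < 0.5 else "-",
                )
                for s in rng.integers(0, 1500, size=int(rng.integers(2, 50)))
            ]
            assert cluster_index_sets(calls) == connected_components_oracle(calls)

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=30))
    def test_oracle_property(self, intervals):
        calls = [
            make_call(sample=f"s{i % 3}", start=s, end=s + w)
            for i, (s, w) in enumerate(intervals)
        ]
        assert cluster_index_sets(calls) == connected_components_oracle(calls)

    def test_idempotence_on_locus_intervals(self):
        rng = np.random.default_rng(3)
        calls = [
            make_call(sample=f"s{i % 4}", start=int(s), end=int(s) + 10)
            for i, s in enumerate(rng.integers(0, 5000, size=30))
        ]
        loci = cluster_calls(calls)
        representatives = [
            make_call(sample="rep", start=l.start, end=l.end, strand=l.strand)
            for l in loci
        ]
        again = cluster_calls(representatives)
        assert {(l.chrom, l.start, l.end, l.strand) for l in again} == {
            (l.chrom, l.start, l.end, l.strand) for l in loci
        }


class TestClusterFilters:
    def test_mixed_family_cluster_dropped(self):
        a = make_call(sample="s1", family="copia")
        b = make_call(sample="s2", family="blood")
        (cluster,) = cluster_calls([a, b])
        assert filter_clusters([cluster]) == []

    def test_multi_call_sample_invalidates_cluster(self):
        a = make_call(sample="s1", start=100, end=120)
        b = make_call(sample="s1", start=110, end=130)
        c = make_call(sample="s2", start=105, end=125)
        (cluster,) = cluster_calls([a, b, c])
        assert filter_clusters([cluster]) == []

    def test_clean_cluster_retained(self):
        a = make_call(sample="s1")
        b = make_call(sample="s2")
        (cluster,) = cluster_calls([a, b])
        kept = filter_clusters([cluster])
        assert len(kept) == 1 and kept[0].family == "copia"


class TestBuildMatrix:
    def test_column_pattern(self):
        a = make_call(sample="s1")
        c = make_call(sample="s3")
        loci = filter_clusters(cluster_calls([a, c]))
        matrix = build_matrix(loci, ["s1", "s2", "s3"])
        assert matrix.values[:, 0].tolist() == [1, 0, 1]

    def test_zero_loci_rejected(self):
        with pytest.raises(dt.ValidationError, match="zero loci"):
            build_matrix([], ["s1", "s2"])

    def test_unknown_sample_rejected(self):
        (locus,) = cluster_calls([make_call(sample="ghost")])
        with pytest.raises(dt.ValidationError, match="ghost"):
            build_matrix([locus], ["s1", "s2"])

    def test_private_loci_are_identity_like(self):
        calls = [
            make_call(sample=f"s{i}", start=1000 * i, end=1000 * i + 10)
            for i in range(1, 6)
        ]
        loci = filter_clusters(cluster_calls(calls))
        matrix = build_matrix(loci, [f"s{i}" for i in range(1, 6)])
        assert matrix.values.sum() == 5
        assert (matrix.column_sums() == 1).all()

    def test_columns_sorted_by_coordinates(self):
        calls = [
            make_call(sample="s1", chrom="chr2", start=50, end=60),
            make_call(sample="s1", chrom="chr1", start=500, end=510),
            make_call(sample="s1", chrom="chr1", start=5, end=15),
        ]
        loci = filter_clusters(cluster_calls(calls))
        matrix = build_matrix(loci, ["s1"])
        recs = matrix.locus_records()
        assert recs == sorted(recs)


def test_pipeline_counts(toy_genome):
    calls = {
        "s1": [make_call(sample="s1", start=100, end=110),
               make_call(sample="s1", chrom="chr1", start=5000, end=5010, family="INE-1")],
        "s2": [make_call(sample="s2", start=105, end=115)],
    }
    matrix, loci, stats = cluster_pipeline(calls, toy_genome)
    assert stats["calls_in"] == 3
    assert stats["calls_after_masking"] == 2  # INE-1 removed
    assert stats["loci_retained"] == 1
    assert matrix.n_loci == 1 and matrix.n_samples == 2
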