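import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bittermap.clusters import (
    GeneCluster, call_clusters_fixed, call_clusters_median,
    chromosome_end_distance, cluster_statistics, nearest_in_cluster_fraction,
    position_distribution_compare, repeat_context_comparison,
)
from bittermap.genome_io import ContigInfo, GeneRecord


def genes_at(starts, contig="chr1", width=900):
    return [
        GeneRecord(gene_id=f"g{i + 1:03d}", species="sp", contig_id=contig,
                   start=s, end=s + width, strand="+", protein="M" * 10)
        for i, s in enumerate(starts)
    ]


def oracle_components(genes, gap):
    """Independent oracle: connected components of the graph joining any
    two same-contig genes whose starts differ by <= gap."""
    g = nx.Graph()
    g.add_nodes_from(r.gene_id for r in genes)
    for a in genes:
        for b in genes:
            if (a.gene_id < b.gene_id and a.contig_id == b.contig_id
                    and abs(a.start - b.start) <= gap):
                g.add_edge(a.gene_id, b.gene_id)
    return {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}


class TestFixedGap:
    def test_basic_grouping(self):
        genes = genes_at([1, 500_001, 2_500_001])
        (cluster,) = call_clusters_fixed(genes)
        assert cluster.gene_ids == ["g001", "g002"]

    def test_gap_boundary_is_inclusive(self):
        genes = genes_at([1, 1_000_001])
        assert len(call_clusters_fixed(genes)) == 1

    def test_singleton_is_not_a_cluster(self):
        assert call_clusters_fixed(genes_at([1])) == []

    def test_matches_pairwise_oracle_on_random_placements(self):
        rng = np.random.default_rng(17)
        starts = sorted(int(s) for s in
                        rng.integers(1, 60_000_000, size=500))
        starts = sorted(set(starts))
        genes = genes_at(starts)
        for gap in (100_000, 1_000_000):
            got = {frozenset(c.gene_ids)
                   for c in call_clusters_fixed(genes, gap=gap)}
            assert got == oracle_components(genes, gap)

    def test_clustered_plus_singletons_account_for_all_genes(self):
        rng = np.random.default_rng(3)
        genes = genes_at(sorted(set(int(s) for s in
                                    rng.integers(1, 5_000_000, size=80))))
        clusters = call_clusters_fixed(genes)
        n_clustered = sum(c.n_genes for c in clusters)
        clustered_ids = {g for c in clusters for g in c.gene_ids}
        singletons = [g for g in genes if g.gene_id not in clustered_ids]
        assert n_clustered + len(singletons) == len(genes)


class TestMedianMethod:
    def test_splits_at_large_gap(self):
        # gaps 10k,10k,10k,300k; median 10k; 300k > 20 * 10k
        genes = genes_at([1, 10_001, 20_001, 30_001, 330_001])
        clusters = call_clusters_median(genes)
        assert [c.gene_ids for c in clusters] == [["g001", "g002", "g003",
                                                  "g004"]]

    def test_two_gene_cluster_never_splits(self):
        genes = genes_at([1, 900_001])
        assert len(call_clusters_median(genes)) == 1

    def test_equal_gaps_never_split(self):
        genes = genes_at([1 + 50_000 * i for i in range(10)])
        (cluster,) = call_clusters_median(genes)
        assert cluster.n_genes == 10

    def test_refines_fixed_gap_clusters(self):
        rng = np.random.default_rng(23)
        genes = genes_at(sorted(set(int(s) for s in
                                    rng.integers(1, 30_000_000, size=400))))
        fixed = {frozenset(c.gene_ids) for c in call_clusters_fixed(genes)}
        for med in call_clusters_median(genes):
            members = set(med.gene_ids)
            assert any(members <= f for f in fixed)


class TestClusterStatistics:
    def test_arithmetic_example(self):
        genes = genes_at([1 + 24_000 * i for i in range(6)], width=0) + \
            genes_at([10_000_000 + 2_000_000 * i for i in range(4)],
                     contig="chr2", width=0)[0:4]
        # rename chr2 genes uniquely
        for i, g in enumerate(genes[6:], start=7):
            g.gene_id = f"g{i:03d}"
        cluster = GeneCluster(cluster_id="c1", species="sp", contig_id="chr1",
                              gene_ids=[g.gene_id for g in genes[:6]],
                              span_start=1, span_end=120_001)
        stats = cluster_statistics(genes, [cluster])
        assert stats.fraction_clustered == pytest.approx(0.6)
        assert stats.avg_genes_per_cluster == 6
        assert stats.biggest_kb == pytest.approx(120)
        assert stats.kb_per_receptor == pytest.approx(20)

    def test_no_clusters_all_zero(self):
        stats = cluster_statistics(genes_at([1, 5_000_000]), [])
        assert (stats.n_clusters, stats.fraction_clustered,
                stats.total_cluster_kb) == (0, 0.0, 0.0)

    def test_equal_clusters_tie(self):
        genes = genes_at([1, 10_001], "chr1") + [
            GeneRecord(gene_id=f"h{i}", species="sp", contig_id="chr2",
                       start=s, end=s + 900, strand="+")
            for i, s in enumerate([1, 10_001])]
        clusters = call_clusters_fixed(genes)
        stats = cluster_statistics(genes, clusters)
        assert stats.fraction_in_biggest == pytest.approx(0.5)


class TestNearestInCluster:
    def fake_distance(self, table):
        return lambda a, b: table[frozenset((a, b))]

    def test_identical_pair_in_cluster(self):
        genes = genes_at([1, 10_001])
        genes[0].protein = genes[1].protein = "MKLV" * 60
        (cluster,) = call_clusters_fixed(genes)
        assert nearest_in_cluster_fraction(genes, [cluster]) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        genes = genes_at([1, 10_001, 20_001, 5_000_001, 10_000_001, 10_010_001])
        proteins = {g.gene_id: f"p{i}" for i, g in enumerate(genes)}
        for g in genes:
            g.protein = proteins[g.gene_id]
        dist_table = {}
        for a in genes:
            for b in genes:
                if a.gene_id < b.gene_id:
                    dist_table[frozenset((a.protein, b.protein))] = \
                        float(rng.random())
        dist = self.fake_distance(dist_table)
        clusters = call_clusters_fixed(genes)
        got = nearest_in_cluster_fraction(genes, clusters, distance=dist)
        # oracle: explicit all-pairs argmin
        cluster_of = {g: c.cluster_id for c in clusters for g in c.gene_ids}
        hits = total = 0
        for g in genes:
            if g.gene_id not in cluster_of:
                continue
            total += 1
            others = [o for o in genes if o.gene_id != g.gene_id]
            best = min(others, key=lambda o: (dist(g.protein, o.protein),
                                              o.gene_id))
            hits += cluster_of.get(best.gene_id) == cluster_of[g.gene_id]
        assert got == pytest.approx(hits / total)

    def test_undefined_without_clusters(self):
        assert nearest_in_cluster_fraction(genes_at([1]), []) is None


class TestEndDistance:
    @pytest.mark.parametrize("s,L,d", [(100, 1000, 0.1), (500, 1000, 0.5),
                                       (1000, 1000, 0.0), (1, 1000, 0.001)])
    def test_formula(self, s, L, d):
        assert chromosome_end_distance(s, L) == pytest.approx(d)

    @pytest.mark.parametrize("s", [0, 1001])
    def test_out_of_range(self, s):
        with pytest.raises(ValueError):
            chromosome_end_distance(s, 1000)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=1, max_value=10**9),
           st.integers(min_value=1, max_value=10**9))
    def test_reflection_symmetry(self, s, L):
        if s > L:
            s, L = L, s
        d1 = chromosome_end_distance(s, L)
        d2 = chromosome_end_distance(L - s + 1, L)
        assert abs(d1 - d2) <= 1.0 / L + 1e-12


class TestPositionCompare:
    def test_identical_groups(self):
        res = position_distribution_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["welch_t"] == pytest.approx(0.0)
        assert res["ks_D"] == pytest.approx(0.0)

    def test_matches_hand_computed_welch(self):
        a, b = [0.1, 0.1, 0.1, 0.2], [0.3, 0.4, 0.4, 0.5]
        res = position_distribution_compare(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t = (ma - mb) / np.sqrt(va / 4 + vb / 4)
        df = (va / 4 + vb / 4) ** 2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        assert res["welch_t"] == pytest.approx(t)
        assert res["welch_df"] == pytest.approx(df)

    def test_disjoint_supports_give_D_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.0, 0.2, 100)
        b = rng.uniform(0.3, 0.5, 100)
        assert position_distribution_compare(a, b)["ks_D"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            position_distribution_compare([0.1, 0.1], [0.1, 0.1])


class TestRepeatContext:
    def setup_genome(self, n, seed, enrich):
        """n genomes, each one 10-Mb chromosome with a 2-gene cluster."""
        rng = np.random.default_rng(seed)
        masks, clusters, contigs = [], [], []
        for i in range(n):
            contig = ContigInfo(f"chr1", 10_000_000, True)
            cluster = GeneCluster(
                cluster_id="c1", species=f"sp{i}", contig_id="chr1",
                gene_ids=["a", "b"], span_start=4_000_000, span_end=4_050_000)
            intervals = []
            if enrich == "near_clusters":
                pos = 3_900_000
                while pos < 4_150_000:
                    intervals.append(("chr1", pos, pos + 5_000))
                    pos += 10_000
            elif enrich == "everywhere":
                intervals.append(("chr1", 1, 10_000_000))
            masks.append({"LINE": intervals})
            clusters.append([cluster])
            contigs.append({"chr1": contig})
        return masks, clusters, contigs

    def test_empty_mask_all_zero(self):
        masks, clusters, contigs = self.setup_genome(3, 0, enrich=None)
        res = repeat_context_comparison(masks, clusters, contigs, seed=0)
        assert all(v == 0.0 for v in res.cluster_fraction["LINE"])
        assert np.isnan(res.t["LINE"])

    def test_full_mask_equal_fractions(self):
        masks, clusters, contigs = self.setup_genome(3, 0, enrich="everywhere")
        res = repeat_context_comparison(masks, clusters, contigs, seed=0)
        assert res.cluster_fraction["LINE"] == pytest.approx([1.0] * 3)
        assert res.random_fraction["LINE"] == pytest.approx([1.0] * 3)

    def test_planted_enrichment_detected(self):
        masks, clusters, contigs = self.setup_genome(10, 0,
                                                     enrich="near_clusters")
        res = repeat_context_comparison(masks, clusters, contigs, seed=7)
        diffs = np.array(res.cluster_fraction["LINE"]) - \
            np.array(res.random_fraction["LINE"])
        assert diffs.mean() > 0
        one_sided_p = sps.ttest_rel(
            res.cluster_fraction["LINE"], res.random_fraction["LINE"],
            alternative="greater").pvalue
        assert one_sided_p < 0.05

    def test_genomes_without_clusters_excluded(self):
        masks, clusters, contigs = self.setup_genome(3, 0, enrich="everywhere")
        clusters[1] = []
        res = repeat_context_comparison(masks, clusters, contigs, seed=0)
        assert len(res.cluster_fraction["LINE"]) == 2
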