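import math

import numpy as np
import pytest
from Bio.Seq import Seq

from bittermap import mining, simulate
from bittermap.mining import (
    CandidateGene, MiningConfig, SearchHit, SeededSmithWatermanEngine,
    count_tm_segments, extract_candidate_region, filter_candidates,
    largest_orf, reciprocal_validate, translated_search,
)


def brute_force_orfs(region: str):
    """Independent oracle: enumerate every ATG..stop ORF on six frames."""
    region = region.upper()
    L = len(region)
    out = []
    for strand in "+-":
        seq = region if strand == "+" else str(Seq(region).reverse_complement())
        for start in range(len(seq) - 2):
            if seq[start:start + 3] != "ATG":
                continue
            for stop in range(start + 3, len(seq) - 2, 3):
                codon = seq[stop:stop + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    a, b = start, stop + 2
                    if strand == "+":
                        gs, ge = a + 1, b + 1
                    else:
                        gs, ge = L - b, L - a
                    out.append(((b - a + 1) // 3, gs, ge, strand,
                                str(Seq(seq[a:stop]).translate())))
                    break
    return out


class TestLargestOrf:
    def test_simple_orf(self):
        assert largest_orf("ATGAAATAA") == ("MK", 1, 9, "+")

    def test_no_start_codon(self):
        assert largest_orf("CCCCCC") is None

    def test_reverse_strand(self):
        seq = str(Seq("ATGAAAGGGTAA").reverse_complement())
        prot, start, end, strand = largest_orf(seq)
        assert (prot, strand) == ("MKG", "-")
        assert (start, end) == (1, 12)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        n_with_orf = 0
        for _ in range(1000):
            region = "".join(rng.choice(list("ACGT"), rng.integers(6, 301)))
            got = largest_orf(region)
            expected = brute_force_orfs(region)
            if not expected:
                assert got is None
                continue
            n_with_orf += 1
            best = min(expected, key=lambda o: (-o[0], o[1], o[3] != "+"))
            assert got == (best[4], best[1], best[2], best[3])
        assert n_with_orf > 300  # the sweep exercises real ORFs

    def test_tie_broken_by_genomic_start_then_plus_strand(self):
        # two single-codon ORFs; the + strand one starts first
        region = "ATGTAA" + "C" * 6
        assert largest_orf(region)[1] == 1


class TestExtractRegion:
    GENOME = {"c": "A" * 100_000}

    def hit(self, start, end, qstart, strand="+"):
        return SearchHit(contig_id="c", subject_start=start, subject_end=end,
                         strand=strand, query_id="q", query_start=qstart,
                         evalue=1e-20, score=100)

    def test_plain_extension(self):
        s, e, _ = extract_candidate_region(self.hit(5000, 6000, 3), self.GENOME)
        assert (s, e) == (3500, 7500)

    def test_query_start_one_suppresses_upstream(self):
        s, e, _ = extract_candidate_region(self.hit(5000, 6000, 1), self.GENOME)
        assert (s, e) == (5000, 7500)

    def test_query_start_one_minus_strand_suppresses_downstream(self):
        s, e, _ = extract_candidate_region(self.hit(5000, 6000, 1, "-"),
                                           self.GENOME)
        assert (s, e) == (3500, 6000)

    def test_clamped_to_contig(self):
        s, e, seq = extract_candidate_region(self.hit(800, 1200, 3), self.GENOME)
        assert (s, e) == (1, 2700)
        assert len(seq) == 2700


class TestFilters:
    def cand(self, protein, evalue=1e-12):
        return CandidateGene(contig_id="c", region_start=1, region_end=10,
                             protein=protein, evalue=evalue)

    def test_length_boundaries(self):
        kept, discarded = filter_candidates([
            self.cand("M" * 199), self.cand("M" * 200), self.cand("M" * 500),
            self.cand("M" * 501)])
        assert [len(c.protein) for c in kept] == [200, 500]
        assert [d.discard_reason for d in discarded] == ["too_short", "too_long"]

    def test_evalue_strictly_greater_discarded(self):
        kept, discarded = filter_candidates(
            [self.cand("A" * 300, evalue=1e-10),
             self.cand("C" * 300, evalue=1.01e-10)])
        assert len(kept) == 1
        assert discarded[0].discard_reason == "evalue"

    def test_exact_duplicate_of_earlier_kept(self):
        a, b = self.cand("M" * 300), self.cand("M" * 300)
        kept, discarded = filter_candidates([a, b])
        assert kept == [a]
        assert discarded[0].discard_reason == "duplicate"

    def test_order_stable_for_distinct_proteins(self):
        cands = [self.cand(aa * 300) for aa in "ACDEFG"]
        kept_fwd, _ = filter_candidates(list(cands))
        for c in cands:
            c.discard_reason = None
        kept_rev, _ = filter_candidates(list(reversed(cands)))
        assert {c.protein for c in kept_fwd} == {c.protein for c in kept_rev}


class TestTmPrediction:
    def test_template_has_seven_segments(self):
        rng = np.random.default_rng(0)
        protein, _ = simulate.make_template_protein(rng)
        assert count_tm_segments(protein) == 7

    def test_six_helix_variant(self):
        rng = np.random.default_rng(0)
        protein, spans = simulate.make_template_protein(rng)
        s, e = spans[2]
        variant = protein[:s] + "N" * (e - s) + protein[e:]
        assert count_tm_segments(variant) == 6

    def test_hydrophilic_protein_has_none(self):
        assert count_tm_segments("N" * 300) == 0

    def test_short_protein_returns_zero(self):
        assert count_tm_segments("MLLLLL") == 0


@pytest.fixture(scope="module")
def engine():
    return SeededSmithWatermanEngine()


@pytest.fixture(scope="module")
def template_and_cds():
    rng = np.random.default_rng(7)
    protein, _ = simulate.make_template_protein(rng)
    return protein, simulate.back_translate(protein, rng)


class TestTranslatedSearch:
    def test_exact_copy_recovered_with_tiny_evalue(self, engine, template_and_cds):
        protein, cds = template_and_cds
        rng = np.random.default_rng(1)
        genome = {"c1": simulate._guarded_background(5000, rng) + cds
                  + simulate._guarded_background(5000, rng)}
        hits = translated_search(genome, {"q": protein}, engine=engine)
        assert hits
        top = max(hits, key=lambda h: h.score)
        assert top.evalue < 1e-50
        assert top.subject_start <= 5001 + 3 and top.subject_end >= 5000 + len(cds) - 6

    def test_random_sequence_yields_no_significant_hit(self, engine,
                                                       template_and_cds):
        protein, _ = template_and_cds
        rng = np.random.default_rng(7)
        genome = {"rand": "".join(rng.choice(list("ACGT"), 50_000))}
        hits = translated_search(genome, {"q": protein}, engine=engine)
        assert all(h.evalue > 1e-10 for h in hits)

    def test_empty_genome(self, engine, template_and_cds):
        assert translated_search({}, {"q": template_and_cds[0]},
                                 engine=engine) == []

    def test_empty_query_set_rejected(self, engine):
        with pytest.raises(ValueError, match="empty query set"):
            translated_search({"c": "ACGT" * 100}, {}, engine=engine)

    def test_hits_sorted_by_contig_then_start(self, genome_sim, engine):
        hits = translated_search(genome_sim.genome, genome_sim.queries,
                                 engine=engine)
        keys = [(h.contig_id, h.subject_start) for h in hits]
        assert keys == sorted(keys)

    def test_chunked_scan_equals_whole_genome_scan(self, engine,
                                                   template_and_cds):
        protein, cds = template_and_cds
        rng = np.random.default_rng(3)
        contig = (simulate._guarded_background(40_000, rng) + cds
                  + simulate._guarded_background(40_000, rng))
        genome = {"c1": contig}
        whole = translated_search(genome, {"q": protein}, engine=engine)
        chunked = translated_search(genome, {"q": protein}, engine=engine,
                                    chunk_size=30_000, chunk_overlap=3_000)
        assert [(h.subject_start, h.subject_end, h.strand) for h in whole] == \
               [(h.subject_start, h.subject_end, h.strand) for h in chunked]


class TestReciprocal:
    def test_reference_gene_self_recovers(self, genome_sim, engine):
        cand = CandidateGene(contig_id="c", region_start=1, region_end=10,
                             protein=genome_sim.queries["query_main"])
        assert reciprocal_validate(cand, genome_sim.reference_genome,
                                   genome_sim.validated_intervals, engine)

    def test_planted_paralog_fails(self, genome_sim, mining_result):
        fails = [d for d in mining_result.discards
                 if d.discard_reason == "reciprocal_fail"]
        assert len(fails) == 1

    def test_no_hit_is_false_not_error(self, genome_sim, engine):
        # tryptophan/proline repeat: shares no 4-mer with any planted protein
        cand = CandidateGene(contig_id="c", region_start=1, region_end=10,
                             protein="WPWA" * 80)
        assert not reciprocal_validate(cand, genome_sim.reference_genome,
                                       genome_sim.validated_intervals, engine)

    def test_empty_reference_annotation_rejected(self, genome_sim, engine):
        cand = CandidateGene(contig_id="c", region_start=1, region_end=10,
                             protein="M" * 300)
        with pytest.raises(ValueError):
            reciprocal_validate(cand, genome_sim.reference_genome, [], engine)


class TestMineGenome:
    def test_planted_genes_recovered_exactly(self, genome_sim, mining_result):
        mined = {(g.contig_id, g.start, g.end, g.strand): g.protein
                 for g in mining_result.genes}
        truth = {(g.contig_id, g.start, g.end, g.strand): g.protein
                 for g in genome_sim.genes}
        assert mined == truth

    def test_each_decoy_discarded_for_designed_reason(self, genome_sim,
                                                      mining_result):
        # match decoys to discards by location
        matched = set()
        for planted in genome_sim.decoys:
            overlapping = [
                i for i, d in enumerate(mining_result.discards)
                if d.contig_id == planted.contig_id
                and d.region_start <= planted.end
                and d.region_end >= planted.start
            ]
            assert len(overlapping) == 1, planted.decoy_id
            assert mining_result.discards[overlapping[0]].discard_reason == \
                planted.reason, planted.decoy_id
            matched.add(overlapping[0])
        # anything else in the log must be an insignificant background hit
        # that the e-value filter correctly removed
        for i, d in enumerate(mining_result.discards):
            if i not in matched:
                assert d.discard_reason == "evalue" and d.evalue > 1e-10

    def test_deterministic(self, genome_sim, mining_result):
        again = mining.mine_genome(
            genome_sim.genome, genome_sim.queries, genome_sim.reference_genome,
            genome_sim.validated_intervals, species="synthsp")
        assert [(g.gene_id, g.start, g.end, g.protein)
                for g in again.genes] == \
               [(g.gene_id, g.start, g.end, g.protein)
                for g in mining_result.genes]

    def test_genome_without_hits_yields_empty_outputs(self, genome_sim):
        rng = np.random.default_rng(5)
        genome = {"c": "".join(rng.choice(list("ACGT"), 20_000))}
        res = mining.mine_genome(genome, genome_sim.queries,
                                 genome_sim.reference_genome,
                                 genome_sim.validated_intervals)
        assert res.genes == [] and res.discards == []


def test_karlin_altschul_evalue_monotone_in_score(engine):
    hit_args = dict(contig_id="c", contig_len=10_000, strand="+", frame=0,
                    n_space=10_000)
    # higher raw score must give smaller e-value
    bits = [(engine.LAMBDA * s - math.log(engine.KA_K)) / math.log(2)
            for s in (60, 120, 240)]
    evalues = [300 * 10_000 * 2 ** (-b) for b in bits]
    assert evalues == sorted(evalues, reverse=True)
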