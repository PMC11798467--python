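"""Receptor gene discovery from genome assemblies.

The pipeline mirrors the classic homology-mining recipe for intronless
GPCR families: a translated similarity search of receptor protein
queries against the genome, extraction of a window around each hit,
calling of the largest open reading frame in that window, filters on
significance, protein length and exact duplicates, reciprocal validation
against a well-annotated reference genome, and finally a topology filter
that keeps only proteins with exactly seven predicted transmembrane
helices.

Both compute engines are injectable.  The built-in search engine is a
seeded Smith–Waterman: exact amino-acid 4-mer seeds locate candidate
loci on six-frame translations, each locus is re-aligned with a local
BLOSUM62 affine-gap alignment, and significance is estimated with a
Karlin–Altschul-style e-value.  The built-in topology predictor is
Kyte–Doolittle hydropathy (window 19, mean threshold 1.6, merged
segments kept at >= 15 residues).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .genome_io import GeneRecord

__all__ = [
    "SearchHit",
    "CandidateGene",
    "MiningConfig",
    "SeededSmithWatermanEngine",
    "KyteDoolittlePredictor",
    "translated_search",
    "extract_candidate_region",
    "largest_orf",
    "filter_candidates",
    "reciprocal_validate",
    "count_tm_segments",
    "mine_genome",
]

DISCARD_REASONS = (
    "evalue", "too_short", "too_long", "duplicate",
    "no_orf", "reciprocal_fail", "tm_count",
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

# vectorized codon translation (standard code, '*' for stops, 'X' ambiguous)
_NT_CODE = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _NT_CODE[ord(_c)] = _i
_CODON_AA = np.full(125, ord("X"), dtype=np.uint8)
for _i0, _a in enumerate("ACGT"):
    for _i1, _b in enumerate("ACGT"):
        for _i2, _c in enumerate("ACGT"):
            _CODON_AA[_i0 * 25 + _i1 * 5 + _i2] = ord(
                str(Seq(_a + _b + _c).translate())
            )


def _translate_frame(nt: str, frame: int) -> str:
    """Translate one reading frame of ``nt`` (ambiguous codons -> X)."""
    codes = _NT_CODE[np.frombuffer(nt.encode("ascii", "replace"), dtype=np.uint8)]
    usable = (len(nt) - frame) // 3
    if usable <= 0:
        return ""
    c = codes[frame : frame + 3 * usable].reshape(-1, 3)
    idx = c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]
    return _CODON_AA[idx].tobytes().decode("ascii")


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(spans):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


@dataclass(frozen=True)
class SearchHit:
    """One local alignment of a protein query against the genome."""

    contig_id: str
    subject_start: int   # 1-based inclusive, nucleotides
    subject_end: int     # 1-based inclusive
    strand: str
    query_id: str
    query_start: int     # 1-based aa position in the query
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start > subject_end")
        if self.query_start < 1:
            raise ValueError("query_start must be >= 1")


@dataclass
class CandidateGene:
    """A windowed hit region with its called ORF, pre- or post-filter."""

    contig_id: str
    region_start: int
    region_end: int
    orf_start: int = 0
    orf_end: int = 0
    strand: str = "+"
    protein: str = ""
    evalue: float = math.inf
    query_id: str = ""
    discard_reason: str | None = None


@dataclass
class MiningConfig:
    """Tunable thresholds of the discovery pipeline (defaults are the
    standard operating point: e-value 1e-10, 1,500 bp flanks, 200-500 aa,
    exactly 7 transmembrane segments)."""

    evalue_max: float = 1e-10
    flank: int = 1500
    len_min: int = 200
    len_max: int = 500
    tm_expected: int = 7
    chunk_size: int | None = None   # optional windowed scanning of large contigs


# ---------------------------------------------------------------------------
# Built-in translated search engine

class SeededSmithWatermanEngine:
    """Seeded local-alignment search of proteins against six-frame
    translations.

    Exact 4-mer matches between query and frame translation seed
    candidate loci (clustered by diagonal); each locus is realigned with
    a Smith–Waterman BLOSUM62 alignment (gap open 11, extend 1) and
    scored with a Karlin–Altschul-style e-value using the standard
    gapped BLOSUM62 parameters (lambda = 0.267, K = 0.041).
    """

    KMER = 4
    LAMBDA = 0.267
    KA_K = 0.041
    #: minimal raw alignment score to report a hit; below this the local
    #: alignment is indistinguishable from compositional noise
    MIN_RAW_SCORE = 55.0
    #: minimal seeds in a diagonal cluster before alignment is attempted
    MIN_SEEDS = 3
    AA = "ACDEFGHIKLMNPQRSTVWY*X"

    def __init__(self) -> None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        self._aligner = aligner
        lut = np.full(256, self.AA.index("X"), dtype=np.int64)
        for i, c in enumerate(self.AA):
            lut[ord(c)] = i
        self._lut = lut

    # -- seeding helpers ---------------------------------------------------

    def _encode(self, protein: str) -> np.ndarray:
        raw = np.frombuffer(protein.encode("ascii", "replace"), dtype=np.uint8)
        return self._lut[raw]

    def _kmer_hashes(self, encoded: np.ndarray) -> np.ndarray:
        k, base = self.KMER, len(self.AA)
        if len(encoded) < k:
            return np.empty(0, dtype=np.int64)
        h = np.zeros(len(encoded) - k + 1, dtype=np.int64)
        for j in range(k):
            h = h * base + encoded[j : len(encoded) - k + 1 + j]
        return h

    def search(self, genome: dict[str, str], queries: dict[str, str]) -> list[SearchHit]:
        if not queries:
            raise ValueError("empty query set")
        total_nt = sum(len(s) for s in genome.values())
        n_space = max(2 * total_nt // 3, 1)  # aa positions over six frames
        query_index = {}
        for qid, q in queries.items():
            qh = self._kmer_hashes(self._encode(q.upper()))
            by_hash: dict[int, list[int]] = {}
            for qpos, h in enumerate(qh.tolist()):
                by_hash.setdefault(h, []).append(qpos)
            query_index[qid] = (qh, by_hash)
        hits: list[SearchHit] = []
        for contig_id in sorted(genome):
            seq = genome[contig_id].upper()
            if len(seq) < 3 * self.KMER:
                continue
            for strand in "+-":
                nt = seq if strand == "+" else str(Seq(seq).reverse_complement())
                for frame in range(3):
                    aa = _translate_frame(nt, frame)
                    if not aa:
                        continue
                    hits.extend(
                        self._search_frame(
                            aa, contig_id, len(seq), strand, frame,
                            queries, query_index, n_space,
                        )
                    )
        hits = self._dedupe(hits)
        hits.sort(key=lambda h: (h.contig_id, h.subject_start, h.strand, h.query_id))
        return hits

    def _search_frame(self, aa, contig_id, contig_len, strand, frame,
                      queries, query_index, n_space) -> list[SearchHit]:
        frame_h = self._kmer_hashes(self._encode(aa))
        if frame_h.size == 0:
            return []
        out: list[SearchHit] = []
        for qid, (qh, by_hash) in query_index.items():
            if qh.size == 0:
                continue
            uniq = np.unique(qh)
            seed_pos = np.nonzero(np.isin(frame_h, uniq))[0]
            if seed_pos.size == 0:
                continue
            seeds = [
                (int(t) - q, int(t))
                for t in seed_pos
                for q in by_hash[int(frame_h[t])]
            ]
            qlen = len(queries[qid])
            for lo, hi in self._cluster_seeds(seeds, qlen):
                wstart = max(0, lo - qlen - 10)
                wend = min(len(aa), hi + qlen + 10)
                hit = self._align_window(
                    queries[qid].upper(), qid, aa[wstart:wend], wstart,
                    contig_id, contig_len, strand, frame, n_space,
                )
                if hit is not None:
                    out.append(hit)
        return out

    def _cluster_seeds(self, seeds: list[tuple[int, int]], qlen: int,
                       diag_band: int = 16):
        """Group seeds lying on nearby diagonals into candidate loci;
        only clusters of >= MIN_SEEDS seeds (a near-colinear run, which
        chance 4-mer matches essentially never produce) are aligned."""
        gap = max(qlen, 50)
        seeds = sorted(seeds)
        clusters: list[tuple[int, int]] = []
        cur: list[tuple[int, int]] = []
        for diag, tpos in seeds:
            if cur and (diag - cur[-1][0] > diag_band
                        or (diag == cur[-1][0] and tpos - cur[-1][1] > gap)):
                if len(cur) >= self.MIN_SEEDS:
                    clusters.append((min(t for _, t in cur),
                                     max(t for _, t in cur)))
                cur = []
            cur.append((diag, tpos))
        if len(cur) >= self.MIN_SEEDS:
            clusters.append((min(t for _, t in cur), max(t for _, t in cur)))
        return _merge_spans(clusters)

    def _align_window(self, query, qid, window, wstart, contig_id,
                      contig_len, strand, frame, n_space) -> SearchHit | None:
        if not window:
            return None
        try:
            alignments = self._aligner.align(window, query)
            best = alignments[0]
        except (IndexError, ValueError):
            return None
        score = float(best.score)
        if score < self.MIN_RAW_SCORE:
            return None
        t_blocks, q_blocks = best.aligned
        t0 = int(t_blocks[0][0]) + wstart          # 0-based aa, frame coords
        t1 = int(t_blocks[-1][1]) + wstart         # exclusive
        qstart = int(q_blocks[0][0]) + 1           # 1-based aa in query
        if strand == "+":
            sub_start = frame + 3 * t0 + 1
            sub_end = frame + 3 * t1
        else:
            sub_end = contig_len - frame - 3 * t0
            sub_start = contig_len - frame - 3 * t1 + 1
        sub_start = max(1, sub_start)
        sub_end = min(contig_len, sub_end)
        bits = (self.LAMBDA * score - math.log(self.KA_K)) / math.log(2.0)
        evalue = len(query) * n_space * 2.0 ** (-bits)
        return SearchHit(
            contig_id=contig_id, subject_start=sub_start, subject_end=sub_end,
            strand=strand, query_id=qid, query_start=qstart,
            evalue=evalue, score=score,
        )

    @staticmethod
    def _dedupe(hits: list[SearchHit]) -> list[SearchHit]:
        """One hit per (query, locus): among hits of one query whose
        subject intervals overlap on a contig — regardless of strand —
        keep the best scoring one (ties to the earlier interval).  This
        in particular suppresses the reverse-frame 'shadow' alignment
        that a hydrophobic seven-helix protein produces on the opposite
        strand of a genuine gene."""
        hits = sorted(hits, key=lambda h: (h.contig_id, h.query_id,
                                           h.subject_start, -h.score, h.strand))
        kept: list[SearchHit] = []
        group_end = -1
        for h in hits:
            prev = kept[-1] if kept else None
            if (prev is not None and prev.contig_id == h.contig_id
                    and prev.query_id == h.query_id
                    and h.subject_start <= group_end):
                group_end = max(group_end, h.subject_end)
                if h.score > prev.score:
                    kept[-1] = h
            else:
                kept.append(h)
                group_end = h.subject_end
        return kept


def translated_search(genome: dict[str, str], queries: dict[str, str],
                      engine=None, chunk_size: int | None = None,
                      chunk_overlap: int = 1500) -> list[SearchHit]:
    """Search protein ``queries`` against ``genome``; hits are returned
    sorted by (contig, subject_start) and are *not* e-value filtered.

    With ``chunk_size`` set, each contig is scanned in overlapping
    windows (overlap ``chunk_overlap``) and coordinates are mapped back;
    results are invariant to chunking for hits shorter than the overlap.
    """
    if not queries:
        raise ValueError("empty query set")
    engine = engine or SeededSmithWatermanEngine()
    if chunk_size is None:
        return engine.search(genome, queries)
    all_hits: list[SearchHit] = []
    for contig_id, seq in genome.items():
        if len(seq) <= chunk_size:
            all_hits.extend(engine.search({contig_id: seq}, queries))
            continue
        step = chunk_size - chunk_overlap
        for offset in range(0, len(seq), step):
            chunk = seq[offset : offset + chunk_size]
            for h in engine.search({contig_id: chunk}, queries):
                all_hits.append(replace(
                    h,
                    subject_start=h.subject_start + offset,
                    subject_end=h.subject_end + offset,
                ))
            if offset + chunk_size >= len(seq):
                break
    uniq = {(h.contig_id, h.subject_start, h.subject_end, h.strand,
             h.query_id): h for h in sorted(all_hits, key=lambda h: h.score)}
    hits = list(uniq.values())
    # overlapping-window duplicates of one locus: keep best score
    hits = SeededSmithWatermanEngine._dedupe(hits)
    hits.sort(key=lambda h: (h.contig_id, h.subject_start, h.strand, h.query_id))
    return hits


# ---------------------------------------------------------------------------
# Region extraction and ORF calling

def extract_candidate_region(hit: SearchHit, genome: dict[str, str],
                             flank: int = 1500) -> tuple[int, int, str]:
    """Extend the hit by ``flank`` bp on both sides, clamped to the contig.

    When the alignment begins at query position 1 the very start of the
    query protein is already matched, so the extension on the gene-5'
    side is suppressed to avoid picking up in-frame start codons
    upstream of the true one (upstream of ``subject_start`` on the +
    strand; downstream of ``subject_end`` on the - strand).
    """
    contig = genome[hit.contig_id]
    start = hit.subject_start - flank
    end = hit.subject_end + flank
    if hit.query_start == 1:
        if hit.strand == "+":
            start = hit.subject_start
        else:
            end = hit.subject_end
    start = max(1, start)
    end = min(len(contig), end)
    return start, end, contig[start - 1 : end]


def largest_orf(region: str) -> tuple[str, int, int, str] | None:
    """Largest ATG-initiated, stop-terminated ORF fully inside ``region``.

    Both strands and all three frames are scanned.  Returns
    ``(protein, start, end, strand)`` with 1-based inclusive coordinates
    on the forward orientation of the region (the stop codon included in
    the span), or ``None`` when no ORF exists.  Ties in codon count are
    broken by the smaller region start, then by the + strand.
    """
    region = region.upper()
    L = len(region)
    best: tuple[int, int, int, str, int, int] | None = None  # (-n, start, strandrank, prot, s, e)
    for strand in "+-":
        seq = region if strand == "+" else str(Seq(region).reverse_complement())
        for frame in range(3):
            i = frame
            orf_open: int | None = None   # 0-based index of the ATG
            while i + 3 <= len(seq):
                codon = seq[i : i + 3]
                if orf_open is None:
                    if codon == "ATG":
                        orf_open = i
                elif codon in STOP_CODONS:
                    a, b = orf_open, i + 2           # 0-based inclusive, stop incl.
                    ncod = (b - a + 1) // 3          # codons incl. stop
                    if strand == "+":
                        gs, ge = a + 1, b + 1
                    else:
                        gs, ge = L - b, L - a
                    key = (-ncod, gs, 0 if strand == "+" else 1)
                    if best is None or key < (best[0], best[1], best[2]):
                        prot = str(Seq(seq[a : i]).translate())
                        best = (-ncod, gs, 0 if strand == "+" else 1, prot, gs, ge)
                    orf_open = None
                i += 3
    if best is None:
        return None
    _, _, rank, prot, gs, ge = best
    return prot, gs, ge, "+" if rank == 0 else "-"


# ---------------------------------------------------------------------------
# Filters

def filter_candidates(candidates: list[CandidateGene],
                      evalue_max: float = 1e-10,
                      len_min: int = 200,
                      len_max: int = 500) -> tuple[list[CandidateGene], list[CandidateGene]]:
    """Apply the e-value, length, and exact-duplicate filters.

    A candidate is discarded iff its originating hit's e-value exceeds
    ``evalue_max``, its protein is shorter than ``len_min`` or longer
    than ``len_max`` (boundaries kept), or its protein string exactly
    equals that of an earlier *kept* candidate.  Returns
    ``(kept, discard log)``; each discarded candidate carries its reason.
    """
    kept: list[CandidateGene] = []
    discarded: list[CandidateGene] = []
    seen: set[str] = set()
    for cand in candidates:
        if cand.evalue > evalue_max:
            cand.discard_reason = "evalue"
        elif len(cand.protein) < len_min:
            cand.discard_reason = "too_short"
        elif len(cand.protein) > len_max:
            cand.discard_reason = "too_long"
        elif cand.protein in seen:
            cand.discard_reason = "duplicate"
        if cand.discard_reason:
            discarded.append(cand)
        else:
            seen.add(cand.protein)
            kept.append(cand)
    return kept, discarded


def reciprocal_validate(candidate: CandidateGene,
                        reference_genome: dict[str, str],
                        validated_intervals: list[tuple[str, int, int]],
                        engine=None) -> bool:
    """True iff the candidate's top reciprocal hit against the reference
    genome overlaps (>= 1 bp) a validated receptor interval."""
    if not validated_intervals:
        raise ValueError("reference annotation is empty")
    engine = engine or SeededSmithWatermanEngine()
    hits = engine.search(reference_genome, {"candidate": candidate.protein})
    if not hits:
        return False
    top = max(hits, key=lambda h: h.score)
    return _overlaps_validated(top, validated_intervals)


def _overlaps_validated(hit: SearchHit,
                        validated_intervals: list[tuple[str, int, int]]) -> bool:
    return any(
        hit.contig_id == contig and hit.subject_start <= end
        and hit.subject_end >= start
        for contig, start, end in validated_intervals
    )


def _reciprocal_validate_batch(candidates: list[CandidateGene],
                               reference_genome: dict[str, str],
                               validated_intervals: list[tuple[str, int, int]],
                               engine) -> list[bool]:
    """Reciprocal validation of many candidates in one reference search
    (each candidate protein is its own query)."""
    if not validated_intervals:
        raise ValueError("reference annotation is empty")
    queries = {f"cand_{i}": c.protein for i, c in enumerate(candidates)}
    hits = engine.search(reference_genome, queries)
    best: dict[str, SearchHit] = {}
    for h in hits:
        if h.query_id not in best or h.score > best[h.query_id].score:
            best[h.query_id] = h
    out = []
    for i in range(len(candidates)):
        top = best.get(f"cand_{i}")
        out.append(top is not None and _overlaps_validated(top, validated_intervals))
    return out


# ---------------------------------------------------------------------------
# Transmembrane topology

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


class KyteDoolittlePredictor:
    """Sliding-window hydropathy TM predictor.

    Windows of ``window`` residues whose mean hydropathy is at least
    ``threshold`` are merged where they overlap; a merged stretch counts
    as a transmembrane segment when it spans at least ``min_len``
    residues.
    """

    def __init__(self, window: int = 19, threshold: float = 1.6,
                 min_len: int = 15) -> None:
        self.window = window
        self.threshold = threshold
        self.min_len = min_len

    def segments(self, protein: str) -> list[tuple[int, int]]:
        """Disjoint TM segments as 0-based half-open residue intervals."""
        protein = protein.upper()
        n = len(protein)
        if n < self.window:
            return []
        values = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in protein])
        means = np.convolve(values, np.ones(self.window) / self.window,
                            mode="valid")
        covered = np.zeros(n, dtype=bool)
        for i in np.nonzero(means >= self.threshold)[0]:
            covered[i : i + self.window] = True
        segments: list[tuple[int, int]] = []
        i = 0
        while i < n:
            if covered[i]:
                j = i
                while j < n and covered[j]:
                    j += 1
                if j - i >= self.min_len:
                    segments.append((i, j))
                i = j
            else:
                i += 1
        return segments


def count_tm_segments(protein: str, predictor=None) -> int:
    """Number of predicted transmembrane segments in ``protein``."""
    predictor = predictor or KyteDoolittlePredictor()
    return len(predictor.segments(protein))


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass
class MiningResult:
    genes: list[GeneRecord]
    discards: list[CandidateGene]
    hits: list[SearchHit] = field(default_factory=list)


def mine_genome(genome: dict[str, str], queries: dict[str, str],
                reference_genome: dict[str, str],
                validated_intervals: list[tuple[str, int, int]],
                config: MiningConfig | None = None,
                species: str = "", engine=None, predictor=None) -> MiningResult:
    """Run the full discovery pipeline on one genome.

    Stages: translated search, window extraction (with 5' suppression
    when the query matches from residue 1), largest-ORF calling, the
    e-value/length/duplicate filters, reciprocal validation against the
    reference annotation, and the 7-TM topology filter.  Candidates from
    different queries that resolve to the same ORF locus are merged
    (best e-value retained) before filtering.  Deterministic for fixed
    inputs.
    """
    config = config or MiningConfig()
    engine = engine or SeededSmithWatermanEngine()
    predictor = predictor or KyteDoolittlePredictor()
    hits = translated_search(genome, queries, engine=engine,
                             chunk_size=config.chunk_size,
                             chunk_overlap=config.flank)

    candidates: list[CandidateGene] = []
    no_orf_raw: list[CandidateGene] = []
    for hit in hits:
        rstart, rend, rseq = extract_candidate_region(hit, genome, config.flank)
        cand = CandidateGene(
            contig_id=hit.contig_id, region_start=rstart, region_end=rend,
            evalue=hit.evalue, query_id=hit.query_id,
        )
        orf = largest_orf(rseq)
        if orf is None:
            cand.discard_reason = "no_orf"
            no_orf_raw.append(cand)
            continue
        prot, os_, oe_, ostrand = orf
        cand.protein = prot
        cand.orf_start = rstart + os_ - 1
        cand.orf_end = rstart + oe_ - 1
        cand.strand = ostrand
        candidates.append(cand)

    # one candidate per ORF locus: queries hitting the same gene collapse
    by_locus: dict[tuple, CandidateGene] = {}
    for cand in candidates:
        key = (cand.contig_id, cand.orf_start, cand.orf_end, cand.strand)
        prev = by_locus.get(key)
        if prev is None or cand.evalue < prev.evalue:
            by_locus[key] = cand
    merged = sorted(by_locus.values(),
                    key=lambda c: (c.contig_id, c.orf_start, c.strand))

    # ORF-less candidates from different queries at one locus collapse too
    no_orf: list[CandidateGene] = []
    for cand in sorted(no_orf_raw, key=lambda c: (c.contig_id, c.region_start)):
        prev = no_orf[-1] if no_orf else None
        if (prev is not None and prev.contig_id == cand.contig_id
                and cand.region_start <= prev.region_end):
            continue
        no_orf.append(cand)

    kept, discards = filter_candidates(
        merged, config.evalue_max, config.len_min, config.len_max)
    discards = no_orf + discards

    validated: list[CandidateGene] = []
    if kept:
        reciprocal_ok = _reciprocal_validate_batch(
            kept, reference_genome, validated_intervals, engine)
        for cand, ok in zip(kept, reciprocal_ok):
            if ok:
                validated.append(cand)
            else:
                cand.discard_reason = "reciprocal_fail"
                discards.append(cand)

    genes: list[GeneRecord] = []
    for cand in validated:
        if count_tm_segments(cand.protein, predictor) != config.tm_expected:
            cand.discard_reason = "tm_count"
            discards.append(cand)
            continue
        gene_id = f"{species or 'sp'}_TAS2R{len(genes) + 1:03d}"
        genes.append(GeneRecord(
            gene_id=gene_id, species=species, contig_id=cand.contig_id,
            start=cand.orf_start, end=cand.orf_end, strand=cand.strand,
            protein=cand.protein,
        ))
    return MiningResult(genes=genes, discards=discards, hits=hits)
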