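"""Tandem-cluster calling and genomic-architecture statistics.

Two cluster definitions are provided.  The fixed-gap method joins
consecutive same-contig genes whose start codons are within a gap
threshold (default 1 Mb, inclusive); the median method starts from
fixed-gap clusters and splits them at any internal gap exceeding
``median_factor`` times the median gap of the original cluster (single
pass).  Singleton genes are never clusters.

Positional statistics use the chromosome-end distance
``d = min((L - s)/L, s/L)`` for a gene starting at ``s`` on a
chromosome of length ``L``; genes on non-chromosome contigs are
excluded.  The repeat-context comparison contrasts repeat coverage in
100-kb cluster flanks against randomly placed 100-kb windows, paired
across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome_io import ContigInfo, GeneRecord

__all__ = [
    "GeneCluster",
    "ClusterStats",
    "PositionRecord",
    "RepeatContextResult",
    "call_clusters_fixed",
    "call_clusters_median",
    "cluster_statistics",
    "nearest_in_cluster_fraction",
    "chromosome_end_distance",
    "position_distribution_compare",
    "repeat_context_comparison",
    "identity_distance",
]


@dataclass
class GeneCluster:
    """A run of >= 2 same-contig genes with bounded start-to-start gaps."""

    cluster_id: str
    species: str
    contig_id: str
    gene_ids: list[str]
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("a cluster needs at least 2 members")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def length_kb(self) -> float:
        return (self.span_end - self.span_start) / 1000.0


@dataclass
class ClusterStats:
    n_clusters: int
    avg_genes_per_cluster: float
    fraction_clustered: float
    fraction_in_biggest: float
    biggest_kb: float
    total_cluster_kb: float
    kb_per_receptor: float
    nearest_in_cluster_fraction: float | None = None


@dataclass(frozen=True)
class PositionRecord:
    gene_id: str
    chromosome_length: int
    gene_start: int
    end_distance: float


@dataclass
class RepeatContextResult:
    """Per-class paired comparison of cluster-flank vs random-window
    repeat coverage across genomes."""

    classes: list[str]
    cluster_fraction: dict[str, list[float]]   # per genome, per class
    random_fraction: dict[str, list[float]]
    t: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)


def _sorted_by_contig(genes: list[GeneRecord]) -> dict[str, list[GeneRecord]]:
    per: dict[str, list[GeneRecord]] = {}
    for g in genes:
        per.setdefault(g.contig_id, []).append(g)
    for members in per.values():
        members.sort(key=lambda g: (g.start, g.gene_id))
    return per


def _make_cluster(members: list[GeneRecord], idx: int) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"cluster_{idx:03d}",
        species=members[0].species,
        contig_id=members[0].contig_id,
        gene_ids=[g.gene_id for g in members],
        span_start=min(g.start for g in members),
        span_end=max(g.end for g in members),
    )


def call_clusters_fixed(genes: list[GeneRecord], gap: int = 1_000_000) -> list[GeneCluster]:
    """Fixed-gap cluster calling.

    Consecutive genes on one contig whose start-to-start distance is
    <= ``gap`` (inclusive) join one cluster; maximal runs of >= 2 genes
    are emitted and remaining genes stay singletons.
    """
    clusters: list[GeneCluster] = []
    for contig_id in sorted(_sorted_by_contig(genes)):
        members = _sorted_by_contig(genes)[contig_id]
        run: list[GeneRecord] = [members[0]]
        for g in members[1:]:
            if g.start - run[-1].start <= gap:
                run.append(g)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(run, len(clusters) + 1))
                run = [g]
        if len(run) >= 2:
            clusters.append(_make_cluster(run, len(clusters) + 1))
    return clusters


def call_clusters_median(genes: list[GeneRecord], initial_gap: int = 1_000_000,
                         median_factor: float = 20.0) -> list[GeneCluster]:
    """Median-method cluster calling.

    Fixed-gap clusters (gap ``initial_gap``) are split, in a single pass,
    at every internal start-to-start gap greater than ``median_factor``
    times the median gap of the *original* cluster; fragments of one gene
    become singletons.  The result is always a refinement of the
    fixed-gap clustering.
    """
    by_id = {g.gene_id: g for g in genes}
    out: list[GeneCluster] = []
    for cluster in call_clusters_fixed(genes, gap=initial_gap):
        members = [by_id[g] for g in cluster.gene_ids]
        gaps = np.diff([g.start for g in members])
        cutoff = median_factor * float(np.median(gaps))
        fragment: list[GeneRecord] = [members[0]]
        fragments: list[list[GeneRecord]] = []
        for g, gp in zip(members[1:], gaps):
            if gp > cutoff:
                fragments.append(fragment)
                fragment = [g]
            else:
                fragment.append(g)
        fragments.append(fragment)
        for frag in fragments:
            if len(frag) >= 2:
                out.append(_make_cluster(frag, len(out) + 1))
    return out


def cluster_statistics(genes: list[GeneRecord],
                       clusters: list[GeneCluster],
                       nearest_fraction: float | None = None) -> ClusterStats:
    """The per-genome architecture statistics.

    Cluster length is span (min member start to max member end) in kb;
    ``kb_per_receptor`` divides the summed cluster length by the number
    of clustered genes.  With no clusters every field is zero.  Ties for
    the biggest cluster resolve to the first cluster id.
    """
    n_total = len(genes)
    if not clusters:
        return ClusterStats(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, nearest_fraction)
    n_clustered = sum(c.n_genes for c in clusters)
    biggest = max(clusters, key=lambda c: (c.n_genes, c.length_kb,
                                           c.cluster_id))
    total_kb = sum(c.length_kb for c in clusters)
    return ClusterStats(
        n_clusters=len(clusters),
        avg_genes_per_cluster=n_clustered / len(clusters),
        fraction_clustered=n_clustered / n_total if n_total else 0.0,
        fraction_in_biggest=biggest.n_genes / n_total if n_total else 0.0,
        biggest_kb=biggest.length_kb,
        total_cluster_kb=total_kb,
        kb_per_receptor=total_kb / n_clustered,
        nearest_in_cluster_fraction=nearest_fraction,
    )


def identity_distance(a: str, b: str) -> float:
    """1 - global-alignment identity between two proteins (default
    pairwise distance for the nearest-in-cluster statistic)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(a, b)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        matches += sum(1 for x, y in zip(a[ts:te], b[qs:qe]) if x == y)
    return 1.0 - matches / max(len(a), len(b))


def nearest_in_cluster_fraction(genes: list[GeneRecord],
                                clusters: list[GeneCluster],
                                distance=None) -> float | None:
    """Fraction of clustered genes whose most similar other gene lies in
    the same cluster.

    The nearest neighbour of each gene is the argmin of ``distance``
    over all other genes (ties go to the lexicographically smaller
    gene id).  Undefined (``None``) with fewer than 2 genes or no
    clusters.
    """
    if len(genes) < 2 or not clusters:
        return None
    distance = distance or identity_distance
    cluster_of: dict[str, str] = {}
    for c in clusters:
        for gid in c.gene_ids:
            cluster_of[gid] = c.cluster_id
    ordered = sorted(genes, key=lambda g: g.gene_id)
    n_hit = 0
    n_clustered = 0
    for g in ordered:
        if g.gene_id not in cluster_of:
            continue
        n_clustered += 1
        best = min(
            (other for other in ordered if other.gene_id != g.gene_id),
            key=lambda o: (distance(g.protein, o.protein), o.gene_id),
        )
        if cluster_of.get(best.gene_id) == cluster_of[g.gene_id]:
            n_hit += 1
    return n_hit / n_clustered


def chromosome_end_distance(s: int, L: int) -> float:
    """Relative distance of a gene start ``s`` from the nearest end of a
    chromosome of length ``L``: ``min((L - s)/L, s/L)``, in [0, 0.5]."""
    if not 1 <= s <= L:
        raise ValueError(f"gene start {s} outside [1, {L}]")
    return min((L - s) / L, s / L)


def position_records(genes: list[GeneRecord],
                     contigs: dict[str, ContigInfo]) -> list[PositionRecord]:
    """End-distance records for genes on chromosome-scale contigs only."""
    out = []
    for g in genes:
        info = contigs.get(g.contig_id)
        if info is None or not info.is_chromosome:
            continue
        out.append(PositionRecord(
            gene_id=g.gene_id, chromosome_length=info.length,
            gene_start=g.start,
            end_distance=chromosome_end_distance(g.start, info.length),
        ))
    return out


def position_distribution_compare(group_a, group_b) -> dict[str, float]:
    """Welch's two-sample t (Satterthwaite df) and two-sided KS test
    between two sets of end distances."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    t_res = stats.ttest_ind(a, b, equal_var=False)
    ks_res = stats.ks_2samp(a, b, alternative="two-sided")
    return {
        "welch_t": float(t_res.statistic),
        "welch_df": float(t_res.df),
        "welch_p": float(t_res.pvalue),
        "ks_D": float(ks_res.statistic),
        "ks_p": float(ks_res.pvalue),
    }


# ---------------------------------------------------------------------------
# Repeat context

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "total")


def _covered_fraction(intervals: list[tuple[int, int]],
                      windows: list[tuple[int, int]]) -> float:
    """Fraction of the union of ``windows`` covered by ``intervals``
    (all 1-based inclusive)."""
    windows = _merge(windows)
    total = sum(e - s + 1 for s, e in windows)
    if total == 0:
        return 0.0
    covered = 0
    for ws, we in windows:
        clipped = [(max(s, ws), min(e, we)) for s, e in intervals
                   if s <= we and e >= ws]
        covered += sum(e - s + 1 for s, e in _merge(clipped))
    return covered / total


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def repeat_context_comparison(masks_per_genome: list[dict[str, list[tuple[str, int, int]]]],
                              clusters_per_genome: list[list[GeneCluster]],
                              contigs_per_genome: list[dict[str, ContigInfo]],
                              flank: int = 100_000, n_random: int = 10,
                              seed: int = 0) -> RepeatContextResult:
    """Compare repeat coverage in cluster flanks against random windows.

    For each genome, the per-class repeat fraction inside the union of
    ``[cluster span - flank, cluster span + flank]`` windows is paired
    with the mean fraction over ``n_random`` randomly placed windows of
    width ``2 * flank`` (sampled with replacement, uniformly over
    chromosomes weighted by length).  Genomes without clusters are
    excluded.  A paired t-test is run per repeat class across genomes.
    """
    rng = np.random.default_rng(seed)
    result = RepeatContextResult(
        classes=list(REPEAT_CLASSES),
        cluster_fraction={c: [] for c in REPEAT_CLASSES},
        random_fraction={c: [] for c in REPEAT_CLASSES},
    )
    for mask, clusters, contigs in zip(masks_per_genome, clusters_per_genome,
                                       contigs_per_genome):
        if not clusters:
            continue
        chrom = [c for c in contigs.values() if c.is_chromosome]
        if not chrom:
            continue
        lengths = np.array([c.length for c in chrom], dtype=float)
        width = 2 * flank
        cluster_windows: dict[str, list[tuple[int, int]]] = {}
        for cl in clusters:
            info = contigs.get(cl.contig_id)
            if info is None:
                continue
            cluster_windows.setdefault(cl.contig_id, []).append(
                (max(1, cl.span_start - flank), min(info.length, cl.span_end + flank)))
        random_windows: dict[str, list[list[tuple[int, int]]]] = {}
        draws = []
        for _ in range(n_random):
            ci = rng.choice(len(chrom), p=lengths / lengths.sum())
            c = chrom[ci]
            start = int(rng.integers(1, max(2, c.length - width + 2)))
            draws.append((c.contig_id, start, min(c.length, start + width - 1)))
        for cls in REPEAT_CLASSES:
            per_contig: dict[str, list[tuple[int, int]]] = {}
            for rcls, contig, s, e in _iter_mask(mask):
                if cls == "total" or rcls == cls:
                    per_contig.setdefault(contig, []).append((s, e))
            cf_num, cf_den = 0.0, 0
            for contig, wins in cluster_windows.items():
                span = sum(e - s + 1 for s, e in _merge(wins))
                cf_num += _covered_fraction(per_contig.get(contig, []), wins) * span
                cf_den += span
            result.cluster_fraction[cls].append(cf_num / cf_den if cf_den else 0.0)
            fracs = [
                _covered_fraction(per_contig.get(contig, []), [(s, e)])
                for contig, s, e in draws
            ]
            result.random_fraction[cls].append(float(np.mean(fracs)))
    for cls in REPEAT_CLASSES:
        a = np.array(result.cluster_fraction[cls])
        b = np.array(result.random_fraction[cls])
        if len(a) >= 2 and np.std(a - b) > 0:
            t = stats.ttest_rel(a, b)
            result.t[cls] = float(t.statistic)
            result.p[cls] = float(t.pvalue)
        else:
            result.t[cls] = float("nan")
            result.p[cls] = float("nan")
    return result


def _iter_mask(mask: dict[str, list[tuple[str, int, int]]]):
    for rcls, intervals in mask.items():
        for contig, s, e in intervals:
            yield rcls, contig, s, e
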