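"""Deep synteny conservation of receptor loci via flanking single-copy
markers.

Each receptor locus (a cluster span or a singleton gene) is annotated
with the single-copy marker genes overlapping a +/- 1 Mb window; loci
with at least two markers are compared across species with an
upper-tail hypergeometric test on shared markers, Bonferroni-corrected
over all tested pairs.  Connected components of significant links form
conserved locus groups, dated by the species-tree MRCA age of their
species — a *minimum* age: the approach is conservative and absence of
a link is never evidence of locus absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
from scipy import stats

from .genome_io import TimeTree

__all__ = [
    "SyntenyLocus",
    "SyntenyConfig",
    "LocusLink",
    "ConservedLocusGroup",
    "assign_flanking_markers",
    "locus_pair_pvalue",
    "link_loci",
    "conserved_groups",
    "minimum_group_age",
]


@dataclass
class SyntenyLocus:
    locus_id: str
    species: str
    contig_id: str
    span_start: int
    span_end: int
    marker_ids: frozenset[str] = frozenset()


@dataclass
class SyntenyConfig:
    """Parameters of the linking test.

    ``universe_size`` is the hypergeometric population size N; when
    ``None`` it defaults, per species pair, to the number of distinct
    marker ids annotated across the two species being compared.
    ``correction`` scopes the Bonferroni family: ``"global"`` counts all
    tested pairs, ``"per_species_pair"`` only the pairs between the same
    two species.
    """

    window: int = 1_000_000
    alpha: float = 0.05
    universe_size: int | None = None
    correction: str = "global"


@dataclass
class LocusLink:
    locus_a: str
    locus_b: str
    shared: int
    p_raw: float
    p_adj: float
    significant: bool
    universe_size: int = 0


@dataclass
class ConservedLocusGroup:
    group_id: str
    locus_ids: list[str]
    species: set[str]
    min_age: float | None = None


def assign_flanking_markers(span_start: int, span_end: int,
                            markers: list[tuple[str, int, int]],
                            window: int = 1_000_000) -> frozenset[str]:
    """Marker ids whose intervals overlap ``[span_start - window,
    span_end + window]`` (all coordinates 1-based inclusive, same
    contig)."""
    lo, hi = span_start - window, span_end + window
    return frozenset(
        mid for mid, mstart, mend in markers if mstart <= hi and mend >= lo
    )


def locus_pair_pvalue(size_a: int, size_b: int, k: int, n_universe: int) -> float:
    """Upper-tail hypergeometric probability of sharing >= ``k`` markers.

    ``X ~ Hypergeometric(N = n_universe, K = size_a, n = size_b)``;
    returns ``P(X >= k)``.
    """
    if k < 0 or k > min(size_a, size_b):
        raise ValueError("k must satisfy 0 <= k <= min(size_a, size_b)")
    if size_a > n_universe or size_b > n_universe:
        raise ValueError("marker set sizes cannot exceed the universe size")
    return float(stats.hypergeom.sf(k - 1, n_universe, size_a, size_b))


def link_loci(loci: list[SyntenyLocus],
              config: SyntenyConfig | None = None) -> list[LocusLink]:
    """Test all cross-species locus pairs for shared flanking markers.

    Loci must be pre-filtered to >= 2 markers.  ``n_tests`` is the
    number of pairs tested; a pair is significant iff its Bonferroni-
    adjusted p-value (``min(1, p_raw * n_tests)``) is below
    ``config.alpha``.
    """
    config = config or SyntenyConfig()
    pairs = [(a, b) for a, b in combinations(loci, 2)
             if a.species != b.species]
    if config.correction == "per_species_pair":
        family_size: dict[frozenset, int] = {}
        for a, b in pairs:
            key = frozenset((a.species, b.species))
            family_size[key] = family_size.get(key, 0) + 1
    elif config.correction != "global":
        raise ValueError("correction must be 'global' or 'per_species_pair'")
    links: list[LocusLink] = []
    for a, b in pairs:
        n_tests = (len(pairs) if config.correction == "global"
                   else family_size[frozenset((a.species, b.species))])
        if config.universe_size is not None:
            n_universe = config.universe_size
        else:
            n_universe = len(a.marker_ids | b.marker_ids) + _species_pair_extra(
                loci, a.species, b.species, exclude=(a, b))
        k = len(a.marker_ids & b.marker_ids)
        p_raw = locus_pair_pvalue(len(a.marker_ids), len(b.marker_ids),
                                  k, n_universe)
        p_adj = min(1.0, p_raw * n_tests)
        links.append(LocusLink(
            locus_a=a.locus_id, locus_b=b.locus_id, shared=k,
            p_raw=p_raw, p_adj=p_adj,
            significant=p_adj < config.alpha, universe_size=n_universe,
        ))
    return links


def _species_pair_extra(loci, sp_a, sp_b, exclude) -> int:
    """Markers annotated in the two species beyond the tested pair's own."""
    pair_ids = exclude[0].marker_ids | exclude[1].marker_ids
    other = set()
    for locus in loci:
        if locus.species in (sp_a, sp_b) and locus not in exclude:
            other |= locus.marker_ids
    return len(other - pair_ids)


def conserved_groups(links: list[LocusLink],
                     loci: list[SyntenyLocus] | None = None,
                     species_tree: TimeTree | None = None) -> list[ConservedLocusGroup]:
    """Connected components of significant links.

    Loci without any significant link are omitted.  When ``loci`` and
    ``species_tree`` are given, each group is dated with the MRCA age of
    its species set.
    """
    graph = nx.Graph()
    for link in links:
        if link.significant:
            graph.add_edge(link.locus_a, link.locus_b)
    species_of = {l.locus_id: l.species for l in (loci or [])}
    groups: list[ConservedLocusGroup] = []
    for i, component in enumerate(
            sorted(nx.connected_components(graph), key=sorted), start=1):
        members = sorted(component)
        sps = {species_of[m] for m in members if m in species_of}
        age = None
        if species_tree is not None and len(sps) >= 2:
            age = minimum_group_age(sps, species_tree)
        groups.append(ConservedLocusGroup(
            group_id=f"group_{i:03d}", locus_ids=members,
            species=sps, min_age=age,
        ))
    return groups


def minimum_group_age(group_species: set[str], time_tree: TimeTree) -> float:
    """Minimum age (MY) of a conserved group: the MRCA age of its
    species set on the calibrated species tree."""
    if len(group_species) < 2:
        raise ValueError("a dated group needs at least two species")
    return time_tree.mrca_age(group_species)
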