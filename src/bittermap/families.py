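"""Gene-family evolution: family partitioning, copy-number-constrained
orthologs (CNCOs), trio orthology categories, and information-criterion
model weights.

A CNCO is a gene family kept at single copy across most of the species
expected to carry it: among the species descending from the
species-tree MRCA of the family's members, fewer than 5% have two or
more copies and more than 50% have exactly one (both strict).

Trio orthology compares the genes of two focal species on a gene tree
rooted with an outgroup: each maximal clade whose tips come exclusively
from the two focal species is classified by its per-species tip counts
into one-to-one, one-to-many, many-to-many, one-to-zero or
many-to-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .genome_io import TimeTree

__all__ = [
    "GeneFamily",
    "CopyProfile",
    "TrioResult",
    "ModelScoreTable",
    "EnrichmentResult",
    "partition_gene_families",
    "expected_species",
    "classify_cnco",
    "cnco_cluster_enrichment",
    "classify_trio_orthology",
    "ic_weights",
    "default_species_of",
]

TRIO_CATEGORIES = ("one_to_one", "one_to_many", "many_to_many",
                   "one_to_zero", "many_to_zero")


def default_species_of(tip_label: str) -> str:
    """Species name of a gene-tree tip labelled ``<gene>_<species>``."""
    return tip_label.rsplit("_", 1)[-1]


@dataclass
class GeneFamily:
    family_id: str
    members: list[tuple[str, str]]          # (gene label, species)
    usable: bool = True

    @property
    def species(self) -> set[str]:
        return {sp for _, sp in self.members}


@dataclass
class CopyProfile:
    """Per-species copy classes of one family over its expected species."""

    family_id: str
    expected_species: frozenset[str]
    copy_class: dict[str, int]              # 0, 1, or 2 (meaning 2+)

    @classmethod
    def from_counts(cls, family_id: str, expected: set[str],
                    counts: dict[str, int]) -> "CopyProfile":
        classes = {sp: min(counts.get(sp, 0), 2) for sp in expected}
        return cls(family_id, frozenset(expected), classes)

    @property
    def f1(self) -> float:
        n = len(self.expected_species)
        return sum(1 for v in self.copy_class.values() if v == 1) / n

    @property
    def f2(self) -> float:
        n = len(self.expected_species)
        return sum(1 for v in self.copy_class.values() if v >= 2) / n

    @property
    def is_cnco(self) -> bool:
        return classify_cnco(self)


@dataclass
class TrioResult:
    counts: dict[str, int]                  # genes per category
    assignments: dict[str, str]             # gene tip label -> category

    @property
    def total_genes(self) -> int:
        return sum(self.counts.values())


@dataclass
class ModelScoreTable:
    names: list[str]
    scores: list[float]
    deltas: list[float]
    weights: list[float]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.scores))


@dataclass
class EnrichmentResult:
    expected_conditional: float
    observed_conditional: float
    z: float
    p: float
    n_obs: int


# ---------------------------------------------------------------------------
# Family partitioning

def _as_dendropy(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    if isinstance(tree, TimeTree):
        return tree.tree
    out = dendropy.Tree.get(data=tree, schema="newick",
                            suppress_internal_node_taxa=True,
                            preserve_underscores=True)
    out.is_rooted = True
    return out


def partition_gene_families(gene_tree, species_tree: TimeTree,
                            young_age_my: float = 50.0,
                            recent_dup_dist: float = 0.05,
                            species_of=default_species_of) -> list[GeneFamily]:
    """Deterministic heuristic partition of a gene tree into families.

    Families are maximal clades in which no species occurs more than
    once, except tips of one species whose pairwise gene-tree
    (patristic) divergence is below ``recent_dup_dist`` — i.e. very
    recent duplicates.  Families spanning fewer than two species, or
    whose species-tree MRCA is younger than ``young_age_my``, are
    greedily merged with their sister clades while the no-repetition
    rule still holds; families that cannot be resolved are kept but
    flagged ``usable=False``.
    """
    tree = _as_dendropy(gene_tree)
    for leaf in tree.leaf_node_iter():
        sp = species_of(leaf.taxon.label)
        if sp not in species_tree.species:
            raise KeyError(f"gene-tree tip {leaf.taxon.label!r} maps to "
                           f"unknown species {sp!r}")
    pdm = tree.phylogenetic_distance_matrix()

    def tips(node):
        return list(node.leaf_iter())

    def rule_ok(node) -> bool:
        per_sp: dict[str, list] = {}
        for leaf in tips(node):
            per_sp.setdefault(species_of(leaf.taxon.label), []).append(leaf)
        for leaves in per_sp.values():
            for i in range(len(leaves)):
                for j in range(i + 1, len(leaves)):
                    d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
                    if d >= recent_dup_dist:
                        return False
        return True

    # maximal clades satisfying the rule (preorder, stop at first ok node)
    family_nodes: list = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if rule_ok(node):
            family_nodes.append(node)
        else:
            stack.extend(reversed(node.child_nodes()))

    def needs_merge(node) -> bool:
        sps = {species_of(l.taxon.label) for l in tips(node)}
        if len(sps) < 2:
            return True
        return species_tree.mrca_age(sps) < young_age_my

    unusable: set = set()
    changed = True
    while changed:
        changed = False
        for node in list(family_nodes):
            if node not in family_nodes or node in unusable:
                continue
            if not needs_merge(node):
                continue
            parent = node.parent_node
            if parent is None or not rule_ok(parent):
                unusable.add(node)
                continue
            # absorb every current family under the parent into one
            absorbed = [n for n in family_nodes
                        if n is parent or _is_descendant(n, parent)]
            for n in absorbed:
                family_nodes.remove(n)
                unusable.discard(n)
            family_nodes.append(parent)
            changed = True

    families: list[GeneFamily] = []
    ordered = sorted(family_nodes,
                     key=lambda n: min(l.taxon.label for l in tips(n)))
    for i, node in enumerate(ordered, start=1):
        members = sorted(
            (l.taxon.label, species_of(l.taxon.label)) for l in tips(node)
        )
        families.append(GeneFamily(
            family_id=f"family_{i:03d}", members=members,
            usable=node not in unusable,
        ))
    return families


def _is_descendant(node, ancestor) -> bool:
    p = node.parent_node
    while p is not None:
        if p is ancestor:
            return True
        p = p.parent_node
    return False


def expected_species(family_species: set[str], species_tree: TimeTree) -> set[str]:
    """All species under the species-tree MRCA of the family's species
    (the species 'between' its two most distant members)."""
    if not family_species:
        raise ValueError("family spans no species")
    return species_tree.clade_species(set(family_species))


# ---------------------------------------------------------------------------
# CNCO classification and cluster enrichment

def classify_cnco(profile: CopyProfile) -> bool:
    """True iff fewer than 5% of expected species carry two or more
    copies and more than 50% carry exactly one (both strict)."""
    if not profile.expected_species:
        raise ValueError("expected species set is empty")
    return profile.f2 < 0.05 and profile.f1 > 0.50


def cnco_cluster_enrichment(cluster_cnco_counts: list[tuple[int, int]],
                            p: float) -> EnrichmentResult:
    """Test whether clusters holding one CNCO tend to hold a second.

    ``cluster_cnco_counts`` lists ``(cluster size n_c, observed CNCO
    genes in the cluster)``.  Under the null each cluster gene is CNCO
    independently with the genome-wide proportion ``p``, so with
    ``X_c ~ Binomial(n_c, p)`` the expected conditional probability of a
    second CNCO is ``sum_c P(X_c >= 2) / sum_c P(X_c >= 1)``.  The
    observed conditional is the fraction of CNCO-containing clusters
    with two or more.  Both proportions are compared with a pooled
    two-proportion z-test, with both sample sizes set to the observed
    number of CNCO-containing clusters (reported as ``n_obs``).
    """
    n_with_1 = sum(1 for _, k in cluster_cnco_counts if k >= 1)
    n_with_2 = sum(1 for _, k in cluster_cnco_counts if k >= 2)
    if p == 0:
        if n_with_1:
            raise ValueError("p = 0 but CNCO-containing clusters observed")
        return EnrichmentResult(0.0, 0.0, float("nan"), float("nan"), 0)
    exp_ge1 = sum(1.0 - stats.binom.pmf(0, n, p) for n, _ in cluster_cnco_counts)
    exp_ge2 = sum(1.0 - stats.binom.cdf(1, n, p) for n, _ in cluster_cnco_counts)
    expected = exp_ge2 / exp_ge1 if exp_ge1 > 0 else 0.0
    observed = n_with_2 / n_with_1 if n_with_1 else 0.0
    if n_with_1 == 0:
        return EnrichmentResult(expected, observed, float("nan"), float("nan"), 0)
    n = n_with_1
    pooled = (observed + expected) / 2.0
    denom = math.sqrt(pooled * (1.0 - pooled) * (2.0 / n)) if 0 < pooled < 1 else 0.0
    if denom == 0:
        z, pval = float("nan"), float("nan")
    else:
        z = (observed - expected) / denom
        pval = 2.0 * stats.norm.sf(abs(z))
    return EnrichmentResult(expected, observed, z, pval, n)


# ---------------------------------------------------------------------------
# Trio orthology

def classify_trio_orthology(gene_tree, species_a: str, species_b: str,
                            outgroup_species: str,
                            species_of=default_species_of,
                            support_collapse: float | None = None) -> TrioResult:
    """Classify every focal-species gene into a trio orthology category.

    The tree is rooted on the outgroup species' tips; maximal clades
    whose tips come exclusively from the two focal species are then
    classified by their tip counts ``(n_A, n_B)``: (1,1) one-to-one,
    (1,>1) or (>1,1) one-to-many, (>=2,>=2) many-to-many, a clade of a
    single species one-to-zero (one tip) or many-to-zero (several).

    Classification is topology-only; with ``support_collapse`` set,
    internal nodes whose label parses as a support value below the
    threshold are collapsed into polytomies first.
    """
    tree = _as_dendropy(gene_tree).clone(depth=1)
    if support_collapse is not None:
        for node in list(tree.preorder_internal_node_iter()):
            if node is tree.seed_node:
                continue
            try:
                support = float(node.label)
            except (TypeError, ValueError):
                continue
            if support < support_collapse:
                node.edge.collapse()
    focal = {species_a, species_b}
    out_leaves = [l for l in tree.leaf_node_iter()
                  if species_of(l.taxon.label) == outgroup_species]
    ab_leaves = [l for l in tree.leaf_node_iter()
                 if species_of(l.taxon.label) in focal]
    if not ab_leaves:
        raise ValueError("tree contains no tips from the focal species")
    if out_leaves:
        if len(out_leaves) == 1:
            root_at = out_leaves[0]
        else:
            root_at = tree.mrca(taxa=[l.taxon for l in out_leaves])
        if root_at is not tree.seed_node:
            tree.reroot_at_edge(root_at.edge, update_bipartitions=False)

    counts = {c: 0 for c in TRIO_CATEGORIES}
    assignments: dict[str, str] = {}
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        leaves = list(node.leaf_iter())
        species = {species_of(l.taxon.label) for l in leaves}
        if species <= focal:
            n_a = sum(1 for l in leaves
                      if species_of(l.taxon.label) == species_a)
            n_b = len(leaves) - n_a
            category = _trio_category(n_a, n_b)
            counts[category] += len(leaves)
            for l in leaves:
                assignments[l.taxon.label] = category
        else:
            stack.extend(reversed(node.child_nodes()))
    return TrioResult(counts=counts, assignments=assignments)


def _trio_category(n_a: int, n_b: int) -> str:
    lo, hi = sorted((n_a, n_b))
    if lo == 1 and hi == 1:
        return "one_to_one"
    if lo == 1 and hi > 1:
        return "one_to_many"
    if lo >= 2:
        return "many_to_many"
    # lo == 0
    return "one_to_zero" if hi == 1 else "many_to_zero"


# ---------------------------------------------------------------------------
# Information-criterion weights

def ic_weights(scores, names=None) -> ModelScoreTable:
    """Akaike/pBIC-style model weights.

    ``w_i = exp(-0.5 * delta_i) / sum_k exp(-0.5 * delta_k)`` with
    ``delta_i = score_i - min(score)``; the minimum is subtracted before
    exponentiation for numerical stability.  Weights sum to one and are
    invariant under adding a constant to all scores.
    """
    scores = [float(s) for s in scores]
    if not scores:
        raise ValueError("at least one score is required")
    if any(not math.isfinite(s) for s in scores):
        raise ValueError("scores must be finite")
    best = min(scores)
    deltas = [s - best for s in scores]
    raw = np.exp(-0.5 * np.asarray(deltas))
    weights = raw / raw.sum()
    if names is None:
        names = [f"model_{i + 1}" for i in range(len(scores))]
    return ModelScoreTable(names=list(names), scores=scores,
                           deltas=deltas, weights=[float(w) for w in weights])
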