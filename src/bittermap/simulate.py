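"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator is a pure function of its parameters and a single
integer seed; each draws from its own named RNG stream so that adding a
generator never shifts another's draws.  The generated data emulate the
*structure* of real inputs — clustered intronless 7-TM genes with
per-filter decoys, time-calibrated species trees with scripted
duplication/loss events, single-copy marker landscapes with planted
conserved loci, overdispersed tissue counts, and luminescence plates
with planted agonists — not realistic sequence evolution.

Planted coding sequences are embedded between short stop-rich guard
blocks, and the intergenic background is interleaved with the same
guards, so that the largest open reading frame of any extracted window
is the planted one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GeneRecord, TimeTree, parse_newick
from .synteny import SyntenyLocus

__all__ = [
    "GenomeSimulation",
    "generate_genome",
    "generate_species_tree",
    "generate_trio_gene_tree",
    "generate_cnco_families",
    "generate_marker_landscape",
    "generate_counts",
    "generate_assay",
]

# fixed stream ids: adding a stream never shifts existing ones
_STREAMS = {
    "genome": 1, "trees": 2, "markers": 3, "counts": 4, "assay": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# Protein / CDS construction

TM_CORE = "ILVF"        # strongly hydrophobic (Kyte-Doolittle >= 2.8)
TM_WEAK = "AC"          # mildly hydrophobic (1.8 / 2.5); at most 4 per helix
# H is excluded: its only ATG/CAT-free codon (CAC) cannot precede an
# isoleucine codon (AT*) without forming CAT across the junction
LOOP_STRONG = "DEKRNQ"  # strongly hydrophilic (<= -3.5)
LOOP_WEAK = "STGPY"     # mildly hydrophilic; kept away from helix borders
TM_AA = TM_CORE          # backwards-compatible aliases
LOOP_AA = LOOP_STRONG
TM_LEN = 21
#: stop codons in all six frames, no ATG/CAT on either strand
GUARD = "TAATTAATTAATTAA"

_CODONS = {
    "I": ("ATA", "ATC", "ATT"), "L": ("CTA", "CTC", "CTG", "CTT", "TTA", "TTG"),
    "V": ("GTA", "GTC", "GTG", "GTT"), "F": ("TTC", "TTT"),
    "D": ("GAC", "GAT"), "E": ("GAA", "GAG"), "K": ("AAA", "AAG"),
    "R": ("AGA", "AGG", "CGA", "CGC", "CGG", "CGT"),
    "N": ("AAC", "AAT"), "Q": ("CAA", "CAG"), "M": ("ATG",),
    "A": ("GCA", "GCC", "GCG", "GCT"), "G": ("GGA", "GGC", "GGG", "GGT"),
    "S": ("AGC", "AGT", "TCA", "TCC", "TCG", "TCT"),
    "T": ("ACA", "ACC", "ACG", "ACT"),
    "H": ("CAC",), "P": ("CCA", "CCC", "CCG", "CCT"),
    "Y": ("TAC", "TAT"), "C": ("TGC", "TGT"), "W": ("TGG",),
}
_FORBIDDEN = ("ATG", "CAT")


def _check_guard() -> None:
    from Bio.Seq import Seq
    for seq in (GUARD, str(Seq(GUARD).reverse_complement())):
        for frame in range(3):
            codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
            assert any(c in ("TAA", "TAG", "TGA") for c in codons)
        assert "ATG" not in seq and "CAT" not in seq


_check_guard()


def _tm_segment(rng: np.random.Generator) -> str:
    """A 21-residue helix: I/L/V/F with at most 4 milder A/C positions,
    so every 19-window inside it keeps a mean hydropathy >= 1.6."""
    tm = list(rng.choice(list(TM_CORE), TM_LEN))
    for i in rng.choice(TM_LEN, size=int(rng.integers(0, 5)), replace=False):
        tm[i] = str(rng.choice(list(TM_WEAK)))
    return "".join(tm)


def _loop(rng: np.random.Generator, length: int) -> str:
    """A hydrophilic loop whose 5 border residues on each side are
    strongly hydrophilic, which bounds how far hydropathy windows can
    bleed out of an adjacent helix (< half the loop, so helices never
    merge)."""
    out = []
    for i in range(length):
        border = i < 5 or i >= length - 5
        if border or rng.random() < 0.6:
            out.append(str(rng.choice(list(LOOP_STRONG))))
        else:
            out.append(str(rng.choice(list(LOOP_WEAK))))
    return "".join(out)


def make_template_protein(rng: np.random.Generator,
                          n_tm: int = 7) -> tuple[str, list[tuple[int, int]]]:
    """A receptor-like scaffold: M + hydrophilic N-tail, ``n_tm``
    hydrophobic helices of 21 residues separated by >= 20-residue
    hydrophilic loops.  Returns the protein and its helix intervals
    (0-based half-open)."""
    parts = ["M" + _loop(rng, 20)]
    tm_spans: list[tuple[int, int]] = []
    pos = 21
    for i in range(n_tm):
        parts.append(_tm_segment(rng))
        tm_spans.append((pos, pos + TM_LEN))
        pos += TM_LEN
        loop_len = int(rng.integers(20, 27)) if i < n_tm - 1 else 12
        parts.append(_loop(rng, loop_len))
        pos += loop_len
    return "".join(parts), tm_spans


def _same_category(c: str) -> str:
    for cat in (TM_CORE, TM_WEAK, LOOP_STRONG, LOOP_WEAK):
        if c in cat:
            return cat
    return c


def mutate_protein(protein: str, tm_spans: list[tuple[int, int]],
                   rng: np.random.Generator, rate: float = 0.12) -> str:
    """Mutate each residue within its own hydropathy category (strong
    helix, mild helix, strong loop, mild loop), so topology and
    detectability are preserved; substitutions are capped at 15% of the
    length."""
    max_mut = int(0.15 * len(protein))
    positions = [i for i in range(1, len(protein)) if rng.random() < rate]
    out = list(protein)
    for i in positions[:max_mut]:
        choices = [c for c in _same_category(out[i]) if c != out[i]]
        if choices:
            out[i] = str(rng.choice(choices))
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator,
                   stop: bool = True) -> str:
    """Random synonymous back-translation avoiding any 'ATG'/'CAT'
    substring after the start codon (so planted regions carry no stray
    start codons on either strand)."""
    aas = list(protein) + (["*"] if stop else [])
    codon_sets = {"*": ("TAA", "TGA", "TAG"), **_CODONS}
    chunks: list[str] = []
    banned: list[set[str]] = [set() for _ in aas]
    i = 0
    while i < len(aas):
        if i == 0 and aas[0] == "M":
            chunks.append("ATG")
            i = 1
            continue
        tail = chunks[-1][-2:] if chunks else ""
        options = [c for c in codon_sets[aas[i]]
                   if c not in banned[i]
                   and not any(f in tail + c for f in _FORBIDDEN)]
        if options:
            chunks.append(str(rng.choice(options)))
            i += 1
        else:
            # dead end: the previous codon's tail blocks every choice here
            banned[i].clear()
            banned[i - 1].add(chunks.pop())
            i -= 1
    cds = "".join(chunks)
    assert "ATG" not in cds[1:] and "CAT" not in cds
    return cds


def _guarded_background(length: int, rng: np.random.Generator) -> str:
    """Random intergenic filler interleaved with stop-rich guards every
    ~100 bp, so no long ORF can arise in the background."""
    parts: list[str] = []
    n = 0
    while n < length:
        parts.append(GUARD)
        n += len(GUARD)
        chunk = "".join(rng.choice(list("ACGT"), 85))
        parts.append(chunk)
        n += len(chunk)
    return "".join(parts)[:length]


def _scrub(seq: str, rng: np.random.Generator) -> str:
    """Remove every ATG/CAT substring by substitution (used for the
    no-ORF decoy zone)."""
    s = list(seq)
    text = "".join(s)
    while True:
        idx = min((text.find(f) for f in _FORBIDDEN if f in text), default=-1)
        if idx < 0:
            return text
        s[idx + 1] = "G" if text[idx + 1] == "T" else "T"
        text = "".join(s)


# ---------------------------------------------------------------------------
# Genome generation

@dataclass
class PlantedDecoy:
    decoy_id: str
    reason: str
    contig_id: str
    start: int
    end: int


@dataclass
class GenomeSimulation:
    """A synthetic assembly plus everything needed to mine and verify it."""

    genome: dict[str, str]
    queries: dict[str, str]
    reference_genome: dict[str, str]
    validated_intervals: list[tuple[str, int, int]]
    genes: list[GeneRecord]                   # planted truth
    clusters: list[list[str]]                 # gene ids per planted cluster
    decoys: list[PlantedDecoy]
    seed: int


DEFAULT_DECOYS = ("evalue", "too_short", "too_long", "duplicate",
                  "no_orf", "reciprocal_fail", "tm_count")


def generate_genome(n_chromosomes: int = 2,
                    cluster_spec: list[tuple[float, int, int]] | None = None,
                    decoy_spec: tuple[str, ...] = DEFAULT_DECOYS,
                    chromosome_length: int = 2_500_000,
                    seed: int = 0,
                    species: str = "synthsp") -> GenomeSimulation:
    """Plant clustered/singleton receptor genes and per-filter decoys.

    ``cluster_spec`` lists ``(position fraction, n_genes, start-to-start
    gap bp)`` entries assigned to chromosomes round-robin; entries with
    ``n_genes == 1`` plant singletons.  Planted genes are intronless
    ORFs of ~300 codons with exactly seven detectable TM stretches and
    >= 80% identity to the emitted query proteins.  Each decoy is built
    to fail exactly one pipeline filter.  Decoys are placed in the upper
    coordinate range of the last chromosome, after all planted genes.
    """
    if cluster_spec is None:
        # two clusters and a singleton, all > 1 Mb apart at the default
        # chromosome length so the fixed-gap caller separates them
        cluster_spec = [(0.04, 5, 20_000), (0.45, 3, 30_000), (0.52, 1, 0)]
    rng = _rng(seed, "genome")
    template, tm_spans = make_template_protein(rng)
    queries = {
        "query_main": template,
        "query_var": mutate_protein(template, tm_spans, rng, rate=0.05),
    }

    for frac, _, _ in cluster_spec:
        if not 0.0 < frac < 1.0:
            raise ValueError("cluster position fractions must be in (0, 1)")
        if frac > 0.55:
            raise ValueError("cluster position fractions must be <= 0.55 "
                             "(the upper range is reserved for decoys)")

    chrom_ids = [f"chr{i + 1}" for i in range(n_chromosomes)]
    # (contig, target start, cds, kind, payload)
    elements: list[tuple[str, int, str, str, dict]] = []

    genes_truth: list[dict] = []
    clusters_truth: list[list[str]] = []
    gene_no = 0
    for ci, (frac, n_genes, gap) in enumerate(cluster_spec):
        contig = chrom_ids[ci % n_chromosomes]
        base = int(frac * chromosome_length)
        members: list[str] = []
        for j in range(n_genes):
            gene_no += 1
            gid = f"{species}_planted{gene_no:03d}"
            prot = mutate_protein(template, tm_spans, rng)
            cds = back_translate(prot, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            elements.append((contig, base + j * gap, cds, "gene",
                             {"gene_id": gid, "protein": prot,
                              "strand": strand}))
            members.append(gid)
        if n_genes >= 2:
            clusters_truth.append(members)

    # ---- decoys ---------------------------------------------------------
    decoy_payloads: list[tuple[str, str, dict]] = []
    for i, reason in enumerate(decoy_spec):
        did = f"decoy_{reason}_{i + 1}"
        if reason == "evalue":
            # body drawn from A/G/S/T: net-negative BLOSUM62 against both
            # the template's loop and TM alphabets, so only the two short
            # conserved patches align (seedable, but far from significant)
            body = "M" + "".join(rng.choice(list("AGST"), 299))
            body = (body[:40] + template[40:55] + body[55:120]
                    + template[120:135] + body[135:])
            cds = back_translate(body, rng)
        elif reason == "too_short":
            prot = mutate_protein(template, tm_spans, rng)
            cds = back_translate(prot, rng)
            cds = cds[:450] + "TAA" + cds[453:]      # stop at codon 151
        elif reason == "too_long":
            prot = mutate_protein(template, tm_spans, rng)
            mid = tm_spans[3][1] + 5
            prot = prot[:mid] + "".join(rng.choice(list(LOOP_AA), 215)) + prot[mid:]
            cds = back_translate(prot, rng)
        elif reason == "duplicate":
            original = next(e for e in elements if e[3] == "gene")
            cds = original[2]
        elif reason == "no_orf":
            prot = mutate_protein(template, tm_spans, rng)
            cds = back_translate(prot, rng, stop=False)
            cds = "GCG" + cds[3:]                    # remove the start codon
        elif reason == "reciprocal_fail":
            prot = mutate_protein(template, tm_spans, rng, rate=1.0)
            # rate capped at 15% per call: apply repeatedly for ~40% divergence
            for _ in range(3):
                prot = mutate_protein(prot, tm_spans, rng, rate=1.0)
            cds = back_translate(prot, rng)
            decoy_payloads.append(("paralog", did, {"cds": cds}))
        elif reason == "tm_count":
            prot = mutate_protein(template, tm_spans, rng)
            s, e = tm_spans[3]
            prot = prot[:s] + "".join(rng.choice(list(LOOP_AA), e - s)) + prot[e:]
            cds = back_translate(prot, rng)
        else:
            raise ValueError(f"unknown decoy reason {reason!r}")
        decoy_payloads.append((reason, did, {"cds": cds}))

    decoy_contig = chrom_ids[-1]
    frac = 0.62
    decoy_meta: list[tuple[str, str, int]] = []
    for reason, did, payload in decoy_payloads:
        if reason == "paralog":
            continue
        target = int(frac * chromosome_length)
        elements.append((decoy_contig, target, payload["cds"],
                         "decoy" if reason != "no_orf" else "decoy_scrub",
                         {"decoy_id": did, "reason": reason}))
        frac += 0.045

    # ---- assemble chromosomes ------------------------------------------
    genome: dict[str, str] = {}
    decoys_truth: list[PlantedDecoy] = []
    for contig in chrom_ids:
        contig_elements = sorted(
            (e for e in elements if e[0] == contig), key=lambda e: e[1])
        parts: list[str] = []
        pos = 0  # 0-based length so far
        for _, target, cds, kind, payload in contig_elements:
            if kind == "decoy_scrub":
                # spacers keep ATG/CAT from forming across any junction:
                # "CC" blocks patterns entering the CDS, "CCGG" blocks a
                # flank that starts with AT from completing a CAT
                left = _scrub("".join(rng.choice(list("ACGT"), 1700)), rng) + "CC"
                right = "CCGG" + _scrub("".join(rng.choice(list("ACGT"), 1700)), rng)
                block = left + cds + right
                offset = len(left)
            else:
                block = GUARD + (cds if payload.get("strand", "+") == "+"
                                 else _revcomp(cds)) + GUARD
                offset = len(GUARD)
            if target < pos:
                raise ValueError(
                    f"overlapping placements on {contig} at {target}")
            parts.append(_guarded_background(target - pos, rng))
            start = target + offset + 1            # 1-based CDS start
            end = start + len(cds) - 1
            if kind == "gene":
                genes_truth.append({
                    "gene_id": payload["gene_id"], "contig": contig,
                    "start": start, "end": end,
                    "strand": payload["strand"], "protein": payload["protein"],
                })
            else:
                decoys_truth.append(PlantedDecoy(
                    decoy_id=payload["decoy_id"], reason=payload["reason"],
                    contig_id=contig, start=start, end=end))
            parts.append(block)
            pos = target + len(block)
        parts.append(_guarded_background(chromosome_length - pos, rng))
        genome[contig] = "".join(parts)[:chromosome_length]

    # ---- reference genome ----------------------------------------------
    ref_parts = [_guarded_background(3_000, rng)]
    ref_pos = len(ref_parts[0])
    template_cds = back_translate(template, rng)
    ref_parts.append(GUARD + template_cds + GUARD)
    validated = [("ref_chr", ref_pos + len(GUARD) + 1,
                  ref_pos + len(GUARD) + len(template_cds))]
    ref_pos += len(ref_parts[-1])
    for reason, did, payload in decoy_payloads:
        if reason != "paralog":
            continue
        ref_parts.append(_guarded_background(3_000, rng))
        ref_pos += 3_000
        ref_parts.append(GUARD + payload["cds"] + GUARD)
        ref_pos += len(ref_parts[-1])
    ref_parts.append(_guarded_background(3_000, rng))
    reference = {"ref_chr": "".join(ref_parts)}

    gene_records = [
        GeneRecord(gene_id=g["gene_id"], species=species, contig_id=g["contig"],
                   start=g["start"], end=g["end"], strand=g["strand"],
                   protein=g["protein"])
        for g in genes_truth
    ]
    return GenomeSimulation(
        genome=genome, queries=queries, reference_genome=reference,
        validated_intervals=validated, genes=gene_records,
        clusters=clusters_truth, decoys=decoys_truth, seed=seed,
    )


def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Trees, trios and CNCO truth

def generate_species_tree(n_species: int, root_age: float = 300.0,
                          seed: int = 0) -> TimeTree:
    """Random ultrametric species tree with tips ``sp01..spNN`` and the
    requested root age (MY), built by successive random joins at
    strictly increasing ages."""
    rng = _rng(seed, "trees")
    nodes = [(f"sp{i + 1:02d}", 0.0) for i in range(n_species)]
    age = 0.0
    while len(nodes) > 1:
        age += float(rng.exponential(1.0)) + 1e-3
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, aa), (nb, ab) = nodes[i], nodes[j]
        merged = (f"({na}:{age - aa:.6f},{nb}:{age - ab:.6f})", age)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick, total = nodes[0]
    scale = root_age / total
    tree = parse_newick(_rescale_newick(newick, scale) + ";", calibrated=True)
    return tree


def _rescale_newick(newick: str, scale: float) -> str:
    import re

    def repl(m):
        return f":{float(m.group(1)) * scale:.6f}"

    return re.sub(r":([0-9.]+)", repl, newick)


def generate_trio_gene_tree(clade_script: list[tuple[int, int]],
                            species_a: str = "A", species_b: str = "B",
                            outgroup: str = "O",
                            seed: int = 0) -> tuple[str, dict[str, int]]:
    """Gene tree with scripted trio-orthology truth.

    ``clade_script`` lists ``(n_A, n_B)`` tip counts for each maximal
    focal clade; outgroup tips are interleaved between clades so that
    the scripted clades are exactly the maximal A/B-exclusive clades.
    Returns (newick string, expected per-category gene counts).
    """
    from .families import _trio_category

    counts = {c: 0 for c in ("one_to_one", "one_to_many", "many_to_many",
                             "one_to_zero", "many_to_zero")}
    idx_a = idx_b = idx_o = 0

    def clade(n_a: int, n_b: int) -> str:
        nonlocal idx_a, idx_b
        tips = []
        for _ in range(n_a):
            idx_a += 1
            tips.append(f"a{idx_a}_{species_a}:1")
        for _ in range(n_b):
            idx_b += 1
            tips.append(f"b{idx_b}_{species_b}:1")
        sub = tips[0]
        for tip in tips[1:]:
            sub = f"({sub},{tip}):1"
        return sub

    if not clade_script:
        raise ValueError("clade script is empty")
    tree = None
    for n_a, n_b in clade_script:
        counts[_trio_category(n_a, n_b)] += n_a + n_b
        sub = clade(n_a, n_b)
        if tree is None:
            tree = sub
        else:
            idx_o += 1
            tree = f"(({tree},o{idx_o}_{outgroup}:1):1,{sub}):1"
    newick = f"({tree},oroot_{outgroup}:1);"
    return newick, counts


@dataclass
class FamilyTruth:
    family_id: str
    expected_species: set[str]
    counts: dict[str, int]
    is_cnco: bool
    gene_tree: str


def generate_cnco_families(species_tree: TimeTree, n_families: int = 50,
                           seed: int = 0) -> list[FamilyTruth]:
    """Families with planted per-species copy tables and CNCO labels.

    Each family occupies a random species-tree clade (both child
    subtrees populated, so the expected-species rule recovers exactly
    that clade).  CNCO families get zero multi-copy species and a
    strictly-majority single-copy fraction; non-CNCO families violate
    one of the two thresholds.
    """
    rng = _rng(seed, "trees")
    internal = [n for n in species_tree.tree.preorder_internal_node_iter()]
    out: list[FamilyTruth] = []
    for i in range(n_families):
        node = internal[int(rng.integers(0, len(internal)))]
        children = node.child_nodes()
        sides = [sorted(l.taxon.label for l in ch.leaf_iter()) for ch in children]
        clade_sp = sorted(l.taxon.label for l in node.leaf_iter())
        n = len(clade_sp)
        planted_cnco = bool(rng.random() < 0.5)
        counts = {sp: 0 for sp in clade_sp}
        if planted_cnco:
            k1 = int(rng.integers(n // 2 + 1, n + 1))
            singles = list(rng.choice(clade_sp, size=k1, replace=False))
            for sp in singles:
                counts[sp] = 1
            k2 = 0
        else:
            if n >= 3 and rng.random() < 0.5:
                # violate the multi-copy threshold
                k2 = max(1, int(np.ceil(0.05 * n)))
                k1 = int(rng.integers(n // 2 + 1, n + 1 - k2))
            else:
                # violate the single-copy threshold
                k2 = 0
                k1 = max(1, n // 2)
            chosen = list(rng.choice(clade_sp, size=k1 + k2, replace=False))
            for sp in chosen[:k1]:
                counts[sp] = 1
            for sp in chosen[k1:]:
                counts[sp] = 2
        # both clade sides must hold a present species so the MRCA is the clade
        for side in sides:
            if not any(counts[sp] > 0 for sp in side):
                pick = side[int(rng.integers(0, len(side)))]
                counts[pick] = 1
        from .families import CopyProfile, classify_cnco
        profile = CopyProfile.from_counts(f"family_{i + 1:03d}",
                                          set(clade_sp), counts)
        out.append(FamilyTruth(
            family_id=profile.family_id, expected_species=set(clade_sp),
            counts=counts, is_cnco=classify_cnco(profile),
            gene_tree=_family_gene_tree(species_tree, counts, i),
        ))
    return out


def _family_gene_tree(species_tree: TimeTree, counts: dict[str, int],
                      family_index: int) -> str:
    """Newick gene tree matching the species subtree of the present
    species, with recent-duplicate cherries for multi-copy species."""
    present = [sp for sp, c in counts.items() if c > 0]
    if len(present) < 2:
        sp = present[0]
        return f"g{family_index}a_{sp}:0.1;"
    tree = species_tree.tree.extract_tree_with_taxa_labels(present)
    newick = tree.as_string(schema="newick").strip().lstrip("[&R] ").strip()
    # relabel tips as genes; duplicate-copy species become tiny cherries
    import re

    def repl(m):
        sp = m.group(1)
        brlen = m.group(2) or ":1.0"
        if counts.get(sp, 0) >= 2:
            return (f"(g{family_index}a_{sp}:0.01,"
                    f"g{family_index}b_{sp}:0.01){brlen}")
        return f"g{family_index}a_{sp}{brlen}"

    return re.sub(r"\b(sp\d+)(:[0-9.eE+-]+)?", repl, newick)


# ---------------------------------------------------------------------------
# Marker landscapes

@dataclass
class MarkerLandscapeTruth:
    groups: list[dict]          # {"locus_ids", "species", "clade_age"}
    decoy_locus_ids: list[str]


def generate_marker_landscape(species_tree: TimeTree,
                              group_specs: list[dict] | None = None,
                              n_decoy_loci: int = 6,
                              universe_size: int = 3000,
                              markers_per_locus: int = 8,
                              shared_markers: int = 6,
                              seed: int = 0) -> tuple[list[SyntenyLocus], MarkerLandscapeTruth]:
    """Marker-annotated receptor loci with planted conserved groups.

    Each group spec is ``{"species": [...]}`` (default: one group over
    all species): its member loci share ``shared_markers`` markers plus
    private ones.  Decoy loci draw markers uniformly from the universe.
    """
    if universe_size < 10 * markers_per_locus:
        raise ValueError("marker universe too small")
    rng = _rng(seed, "markers")
    universe = [f"M{i + 1:05d}" for i in range(universe_size)]
    species = sorted(species_tree.species)
    if group_specs is None:
        group_specs = [{"species": species}]
    loci: list[SyntenyLocus] = []
    groups: list[dict] = []
    n = 0
    for gi, spec in enumerate(group_specs, start=1):
        members = spec["species"]
        if len(members) < 2:
            raise ValueError("a planted group needs >= 2 species")
        shared = list(rng.choice(universe, size=shared_markers, replace=False))
        ids = []
        for sp in members:
            n += 1
            private = list(rng.choice(universe,
                                      size=markers_per_locus - shared_markers,
                                      replace=False))
            locus = SyntenyLocus(
                locus_id=f"locus_{n:03d}", species=sp, contig_id=f"{sp}_chr1",
                span_start=1_000_000, span_end=1_200_000,
                marker_ids=frozenset(shared) | frozenset(private),
            )
            loci.append(locus)
            ids.append(locus.locus_id)
        groups.append({
            "locus_ids": sorted(ids), "species": set(members),
            "clade_age": species_tree.mrca_age(set(members)),
        })
    decoy_ids = []
    for _ in range(n_decoy_loci):
        n += 1
        sp = species[int(rng.integers(0, len(species)))]
        locus = SyntenyLocus(
            locus_id=f"locus_{n:03d}", species=sp, contig_id=f"{sp}_chr2",
            span_start=5_000_000, span_end=5_100_000,
            marker_ids=frozenset(rng.choice(universe, size=markers_per_locus,
                                            replace=False)),
        )
        loci.append(locus)
        decoy_ids.append(locus.locus_id)
    return loci, MarkerLandscapeTruth(groups=groups, decoy_locus_ids=decoy_ids)


# ---------------------------------------------------------------------------
# Expression counts

@dataclass
class CountsTruth:
    gene_class: dict[str, str]      # tongue_only / extraoral_only / ubiquitous / silent
    specific_tissue: dict[str, str]


def generate_counts(n_genes: int = 200, n_replicates: int = 3,
                    tissues: tuple[str, ...] = ("tongue", "brain", "stomach",
                                                "intestines", "liver",
                                                "dorsal skin", "ventral skin"),
                    proportions: dict[str, float] | None = None,
                    mean_count: float = 80.0, dispersion: float = 0.3,
                    mapped_total: float = 2e7,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.Series, pd.Series,
                                            pd.Series, CountsTruth]:
    """Overdispersed tissue-specific count matrix with planted truth.

    Gene classes: ``tongue_only`` (expressed in the tongue only),
    ``extraoral_only`` (one random non-tongue tissue), ``ubiquitous``
    (all tissues), ``silent`` (zero everywhere) and ``gut_program``
    (a shared stomach+intestines module, for colocalization tests).  Counts in an
    expressing tissue are negative-binomial around ``mean_count`` with
    at least one read in the first replicate, so the planted truth is
    exactly recoverable at the FPKM > 0.01 threshold; non-expressing
    tissues have zero counts.

    Returns (counts, sample->tissue, gene lengths, per-sample mapped
    totals, truth).
    """
    proportions = proportions or {"tongue_only": 0.3, "extraoral_only": 0.2,
                                  "ubiquitous": 0.3, "silent": 0.2}
    rng = _rng(seed, "counts")
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    classes = list(proportions)
    probs = np.array([proportions[c] for c in classes], dtype=float)
    probs /= probs.sum()
    assignment = rng.choice(classes, size=n_genes, p=probs)
    samples = [f"{t}_rep{r + 1}" for t in tissues for r in range(n_replicates)]
    sample_tissue = pd.Series({s: s.rsplit("_rep", 1)[0] for s in samples})
    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    truth = CountsTruth(gene_class={}, specific_tissue={})
    extraoral = [t for t in tissues if t != "tongue"]
    nb_n = 1.0 / dispersion
    for gene, cls in zip(genes, assignment):
        truth.gene_class[gene] = cls
        if cls == "silent":
            continue
        if cls == "tongue_only":
            express_in = ["tongue"]
            truth.specific_tissue[gene] = "tongue"
        elif cls == "extraoral_only":
            tissue = str(rng.choice(extraoral))
            express_in = [tissue]
            truth.specific_tissue[gene] = tissue
        elif cls == "gut_program":
            express_in = ["stomach", "intestines"]
        else:
            express_in = list(tissues)
        for tissue in express_in:
            nb_p = nb_n / (nb_n + mean_count)
            draws = rng.negative_binomial(nb_n, nb_p, size=n_replicates)
            draws[0] = max(1, draws[0])
            for r in range(n_replicates):
                counts.loc[gene, f"{tissue}_rep{r + 1}"] = int(draws[r])
    lengths = pd.Series(rng.integers(900, 1000, size=n_genes).astype(float),
                        index=genes)
    totals = pd.Series(
        mapped_total * (1.0 + 0.05 * rng.standard_normal(len(samples))),
        index=samples,
    ).clip(lower=1.0)
    return counts, sample_tissue, lengths, totals, truth


# ---------------------------------------------------------------------------
# Assay plates

@dataclass
class AssayTruth:
    agonist: dict[tuple[str, str], bool]


def generate_assay(n_receptors: int = 4, n_substances: int = 28,
                   agonist_matrix: dict[tuple[str, str], bool] | None = None,
                   effect_sd: float = 5.0, noise_sd: float = 20.0,
                   n_buffer: int = 14, n_replicates: int = 6,
                   seed: int = 0) -> tuple[pd.DataFrame, AssayTruth]:
    """Luminescence plate with planted agonist truth.

    Buffer wells are N(baseline_r, noise_sd) with ``n_buffer`` >= 14
    replicates; substance wells add ``effect_sd * noise_sd`` RLU for
    planted agonists.  When ``agonist_matrix`` is None, each receptor
    gets two planted agonists.  Returns a long-format plate table and
    the truth matrix.
    """
    rng = _rng(seed, "assay")
    receptors = [f"R{i + 1:02d}" for i in range(n_receptors)]
    substances = [f"S{i + 1:02d}" for i in range(n_substances)]
    if agonist_matrix is None:
        agonist_matrix = {}
        for r in receptors:
            hits = rng.choice(substances, size=2, replace=False)
            for s in substances:
                agonist_matrix[(r, s)] = s in hits
    rows = []
    for r in receptors:
        baseline = float(rng.uniform(80, 160))
        for _ in range(n_buffer):
            rows.append((r, "buffer", baseline + float(rng.normal(0, noise_sd))))
        for s in substances:
            effect = effect_sd * noise_sd if agonist_matrix.get((r, s)) else 0.0
            for _ in range(n_replicates):
                rows.append((r, s, baseline + effect
                             + float(rng.normal(0, noise_sd))))
    plate = pd.DataFrame(rows, columns=["receptor", "substance", "response"])
    return plate, AssayTruth(agonist=agonist_matrix)
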