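"""Readers and writers for the formats the pipeline touches.

All genomic coordinates in this package are GTF-style: 1-based and
inclusive at both ends.  BED input (0-based, half-open) is converted at
the boundary by :func:`read_bed_intervals`.  Calibrated trees carry
branch lengths in million years (MY); node ages are heights above the
tips of an ultrametric tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

__all__ = [
    "ContigInfo",
    "GeneRecord",
    "TimeTree",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_bed_intervals",
    "detect_chromosomes",
    "read_newick",
    "parse_newick",
]

#: Substrings of a FASTA header that mark a sequence as a full
#: chromosome rather than an unplaced scaffold.  Matching is plain,
#: case-sensitive substring search on each token.
CHROMOSOME_TOKENS = ("Chromosome", "chromosome", "chr", "linkage group", "LG")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ContigInfo:
    """A contig of an assembly and whether it is a full chromosome."""

    contig_id: str
    length: int
    is_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.contig_id!r}: length must be > 0")


@dataclass
class GeneRecord:
    """One annotated receptor gene.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on
    ``contig_id``; ``protein`` is the translated coding sequence (may be
    empty when the record comes from a bare GTF without its companion
    FASTA).
    """

    gene_id: str
    species: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: coordinates are 1-based")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a nucleotide/protein FASTA into ``{record id: sequence}``.

    Record ids must be unique; a sequence line appearing before any
    header is a parse error naming the offending line.
    """
    with open(path) as fh:
        text = fh.read()
    return parse_fasta(text)


def parse_fasta(text: str) -> dict[str, str]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FormatError(f"line {lineno}: sequence data before first header")
        break
    records: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicated record id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    """Inverse of :func:`read_fasta` (up to line wrapping)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF (9-column, 1-based inclusive)

def read_gtf(path, species: str = "") -> list[GeneRecord]:
    """Read a 9-column GTF into :class:`GeneRecord` objects.

    The attribute column must carry ``gene_id``; a ``species`` attribute,
    when present, overrides the ``species`` argument.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            contig, _source, _feature, start_s, end_s, _score, strand, _frame, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            attributes = _parse_gtf_attributes(attrs)
            gene_id = attributes.get("gene_id", f"gene_{lineno}")
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        species=attributes.get("species", species),
                        contig_id=contig,
                        start=start,
                        end=end,
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    return genes


def _parse_gtf_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def write_gtf(genes: list[GeneRecord], path, source: str = "bittermap",
              feature: str = "CDS") -> None:
    """Inverse of :func:`read_gtf` modulo attribute order."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            if g.species:
                attrs += f' species "{g.species}";'
            fh.write(
                f"{g.contig_id}\t{source}\t{feature}\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED (converted to 1-based inclusive at the boundary)

def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """Read a BED file into ``(contig, start, end, name)`` tuples.

    BED is 0-based half-open on disk; the returned coordinates are
    1-based inclusive like the rest of the package.
    """
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {lineno}: expected >=3 BED columns")
            name = cols[3] if len(cols) > 3 else f"feature_{lineno}"
            out.append((cols[0], int(cols[1]) + 1, int(cols[2]), name))
    return out


# ---------------------------------------------------------------------------
# Contig classification

def detect_chromosomes(headers: list[str]) -> dict[str, bool]:
    """Classify each FASTA header as chromosome-scale or not.

    A contig counts as a full chromosome when its header contains any of
    the tokens in :data:`CHROMOSOME_TOKENS` as a case-sensitive
    substring.  The key of the returned map is the contig id (first
    whitespace-separated word, leading ``>`` stripped).
    """
    out: dict[str, bool] = {}
    for header in headers:
        text = header.lstrip(">").strip()
        contig_id = text.split()[0] if text.split() else text
        out[contig_id] = any(tok in text for tok in CHROMOSOME_TOKENS)
    return out


# ---------------------------------------------------------------------------
# Time-calibrated trees

@dataclass
class TimeTree:
    """A rooted tree with node ages (heights above the tips, in MY).

    For calibrated trees the input must be ultrametric: every
    root-to-tip path length equal within ``tolerance``.  Ages are then
    height above the tips, so tips have age 0 and the root has the
    maximum age.
    """

    tree: dendropy.Tree
    calibrated: bool = True
    _ages: dict = field(default_factory=dict, repr=False)

    ULTRAMETRIC_TOL = 1e-6

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        self.tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )
        depths = [leaf.root_distance for leaf in self.tree.leaf_node_iter()]
        height = max(depths) if depths else 0.0
        if self.calibrated and depths:
            spread = max(depths) - min(depths)
            if spread > self.ULTRAMETRIC_TOL * max(1.0, height):
                raise ValueError(
                    f"calibrated tree is not ultrametric (tip-depth spread {spread:g})"
                )
        for node in self.tree.preorder_node_iter():
            age = height - node.root_distance
            if node.is_leaf() and self.calibrated:
                age = 0.0
            self._ages[node] = max(age, 0.0)

    @property
    def species(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    @property
    def root_age(self) -> float:
        return self._ages[self.tree.seed_node]

    def node_age(self, node) -> float:
        return self._ages[node]

    def mrca(self, species: set[str]):
        missing = set(species) - self.species
        if missing:
            raise KeyError(f"species not on tree: {sorted(missing)}")
        if len(set(species)) == 1:
            taxon = self.tree.taxon_namespace.get_taxon(next(iter(species)))
            return self.tree.find_node_with_taxon_label(taxon.label)
        return self.tree.mrca(taxa=[
            self.tree.taxon_namespace.get_taxon(s) for s in species
        ])

    def mrca_age(self, species: set[str]) -> float:
        """Age (MY) of the most recent common ancestor of ``species``."""
        return self._ages[self.mrca(species)]

    def clade_species(self, species: set[str]) -> set[str]:
        """All tip species descending from the MRCA of ``species``."""
        node = self.mrca(species)
        return {leaf.taxon.label for leaf in node.leaf_iter()}


def parse_newick(text: str, calibrated: bool = True) -> TimeTree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"invalid newick: {exc}") from exc
    tree.is_rooted = True
    return TimeTree(tree=tree, calibrated=calibrated)


def read_newick(path, calibrated: bool = True) -> TimeTree:
    """Read a newick tree; enforce ultrametricity when ``calibrated``."""
    with open(path) as fh:
        return parse_newick(fh.read(), calibrated=calibrated)
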