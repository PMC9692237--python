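"""Minimalistic gene-order genome representation and phylogeny I/O.

A genome is a set of chromosomes; a chromosome is an ordered list of signed
integer gene identifiers.  The magnitude identifies the ortholog family, the
sign the strand (positive = reference strand).  Which strand of a chromosome
is called "reference" is arbitrary, so a chromosome and its reverse-negation
(order reversed, every sign flipped) denote the same physical molecule.

All genomes in a :class:`GenomeSet` share the same gene content (the core
genome): the magnitudes over all chromosomes of every genome are exactly
``1..n_root``, each once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Chromosome",
    "Genome",
    "GenomeSet",
    "GenomeValidationError",
    "LocationIndex",
    "PhyloTree",
    "canonical_chromosome",
    "reverse_negate",
    "build_index",
    "parse_genomes",
    "write_genomes",
    "read_genomes",
    "parse_tree",
    "read_tree",
    "write_tree",
]

Chromosome = tuple[int, ...]


class GenomeValidationError(ValueError):
    """Raised when gene-order data violates the format invariants."""


def reverse_negate(chrom: Sequence[int]) -> Chromosome:
    """Return the chromosome read from the other strand: reversed, signs flipped."""
    return tuple(-g for g in reversed(chrom))


def canonical_chromosome(chrom: Sequence[int]) -> Chromosome:
    """Strand-insensitive representative: the lexicographic min of the
    chromosome and its reverse-negation (signed integers compared left to
    right)."""
    c = tuple(chrom)
    rn = reverse_negate(c)
    return c if c <= rn else rn


@dataclass(frozen=True)
class Genome:
    """An unordered collection of chromosomes.

    Chromosome order is an arbitrary labelling 1, 2, ...; none of the summary
    statistics depend on it.
    """

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "chromosomes", tuple(tuple(c) for c in self.chromosomes)
        )

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def genes(self) -> Iterator[int]:
        for chrom in self.chromosomes:
            yield from chrom

    def canonical(self) -> "Genome":
        """Representative invariant to per-chromosome strand choice and
        chromosome order."""
        return Genome(tuple(sorted(canonical_chromosome(c) for c in self.chromosomes)))

    def validate(self, n_root: int | None = None, name: str = "?") -> int:
        """Check the format invariants; return the gene count.

        Raises :class:`GenomeValidationError` naming ``name`` on violation.
        """
        if any(len(chrom) == 0 for chrom in self.chromosomes):
            raise GenomeValidationError(f"genome {name!r}: empty chromosome")
        flat = np.concatenate(
            [np.asarray(c, dtype=np.int64) for c in self.chromosomes]
        ) if self.chromosomes else np.empty(0, dtype=np.int64)
        if np.any(flat == 0):
            raise GenomeValidationError(f"genome {name!r}: zero gene identifier")
        mags = np.sort(np.abs(flat))
        n = mags.size
        if n and not np.array_equal(mags, np.arange(1, n + 1)):
            dup = mags[:-1][mags[1:] == mags[:-1]]
            if dup.size:
                raise GenomeValidationError(
                    f"genome {name!r}: duplicate gene {int(dup[0])}"
                )
            raise GenomeValidationError(
                f"genome {name!r}: gene magnitudes are not exactly 1..{n}"
            )
        if n_root is not None and n != n_root:
            raise GenomeValidationError(
                f"genome {name!r}: {n} genes, expected {n_root}"
            )
        return n


@dataclass(frozen=True)
class GenomeSet:
    """Mapping species name -> Genome, all sharing gene content 1..n_root."""

    genomes: Mapping[str, Genome]
    n_root: int = field(default=0)

    def __post_init__(self) -> None:
        genomes = dict(self.genomes)
        if not genomes:
            raise GenomeValidationError("empty genome set")
        n_root = self.n_root
        for name, g in genomes.items():
            n = g.validate(n_root if n_root else None, name=name)
            if not n_root:
                n_root = n
        object.__setattr__(self, "genomes", genomes)
        object.__setattr__(self, "n_root", n_root)

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, name: str) -> Genome:
        return self.genomes[name]

    def names(self) -> list[str]:
        return list(self.genomes)

    def items(self):
        return self.genomes.items()


class LocationIndex:
    """Constant-time lookup of sign, chromosome and 1-based position per gene.

    Lookups disregard the sign of the query: ``location(g) == location(-g)``.
    Construction is O(n_root); arrays are indexed by gene magnitude.
    """

    __slots__ = ("_sign", "_chr", "_loc", "_chrom_lens", "genome")

    def __init__(self, genome: Genome):
        n = genome.n_genes
        sign = [0] * (n + 1)
        chrn = [0] * (n + 1)
        loc = [0] * (n + 1)
        for ci, chrom in enumerate(genome.chromosomes, start=1):
            for pos, g in enumerate(chrom, start=1):
                m = abs(g)
                sign[m] = 1 if g > 0 else -1
                chrn[m] = ci
                loc[m] = pos
        self._sign = sign
        self._chr = chrn
        self._loc = loc
        self._chrom_lens = [len(c) for c in genome.chromosomes]
        self.genome = genome

    def sign(self, g: int) -> int:
        return self._sign[abs(g)]

    def chromosome(self, g: int) -> int:
        """1-based chromosome label of gene ``g``."""
        return self._chr[abs(g)]

    def location(self, g: int) -> int:
        """1-based position of gene ``g`` within its chromosome."""
        return self._loc[abs(g)]

    def chromosome_length(self, label: int) -> int:
        return self._chrom_lens[label - 1]

    def gene_at(self, chrom_label: int, pos: int) -> int | None:
        """Signed gene at (chromosome, position), or None if off the end."""
        if not (1 <= chrom_label <= len(self._chrom_lens)):
            return None
        if not (1 <= pos <= self._chrom_lens[chrom_label - 1]):
            return None
        return self.genome.chromosomes[chrom_label - 1][pos - 1]


def build_index(genome: Genome) -> LocationIndex:
    return LocationIndex(genome)


# ---------------------------------------------------------------------------
# File dialect: one record per genome, ">name" header, one chromosome per
# whitespace-separated line of signed integers; blank lines ignored.

def parse_genomes(text: str) -> GenomeSet:
    """Parse minimalistic-format text into a validated :class:`GenomeSet`."""
    genomes: dict[str, Genome] = {}
    name: str | None = None
    chroms: list[Chromosome] = []

    def _flush() -> None:
        nonlocal name, chroms
        if name is not None:
            if name in genomes:
                raise GenomeValidationError(f"duplicate genome record {name!r}")
            genomes[name] = Genome(tuple(chroms))
        name, chroms = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):  # blank and comment lines
            continue
        if line.startswith(">"):
            _flush()
            name = line[1:].strip()
            if not name:
                raise GenomeValidationError(f"line {lineno}: empty genome name")
        else:
            if name is None:
                raise GenomeValidationError(
                    f"line {lineno}: chromosome data before any '>' header"
                )
            try:
                chroms.append(tuple(int(tok) for tok in line.split()))
            except ValueError as exc:
                raise GenomeValidationError(
                    f"genome {name!r}, line {lineno}: non-integer gene id"
                ) from exc
    _flush()
    if not genomes:
        raise GenomeValidationError("no genome records found")
    # per-genome invariants are checked in GenomeSet; content equality too
    return GenomeSet(genomes)


def write_genomes(gs: GenomeSet) -> str:
    buf = io.StringIO()
    for name, g in gs.items():
        buf.write(f">{name}\n")
        for chrom in g.chromosomes:
            buf.write(" ".join(str(x) for x in chrom) + "\n")
    return buf.getvalue()


def read_genomes(path: str) -> GenomeSet:
    with open(path) as fh:
        return parse_genomes(fh.read())


# ---------------------------------------------------------------------------
# Phylogeny: thin wrapper over dendropy keeping rooted semantics and
# branch lengths in expected substitutions per site.

class PhyloTree:
    """Rooted phylogeny with branch lengths; multifurcations permitted."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.head_node.parent_node is not None
        )

    def scale_branch_lengths(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        clone = dendropy.Tree(self.tree)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return PhyloTree(clone)

    def check_leaves(self, names: Iterable[str]) -> None:
        want = set(names)
        have = set(self.leaf_names)
        if want != have:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise GenomeValidationError(
                f"tree/genome name mismatch: missing leaves {missing}, extra leaves {extra}"
            )


def parse_tree(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def read_tree(path: str) -> PhyloTree:
    with open(path) as fh:
        return parse_tree(fh.read())


def write_tree(tree: PhyloTree) -> str:
    return tree.to_newick()
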