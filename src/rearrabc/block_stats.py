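"""Unique blocks (UBs), probably inverted unique blocks (PIUBs) and the
gene-order summary statistics.

A *unique block* is a maximal gene sequence shared by two genomes in the
same or inverted orientation ([1,2,3] matches [1,2,3] or [-3,-2,-1]).
Blocks are found by a single left-to-right scan of the first genome:
the current block is extended while the next gene of G1 sits next to the
current gene in G2, in the direction given by the product of strands, and
with the matching sign; it closes at chromosome ends or mismatches.  The
scan is O(n_root) per genome pair given the location index.

A UB is a *PIUB* when at least one of its common neighbors flanks it in
reversed orientation in the other genome — the signature of an inversion.
With G1 locally reading [a, B, c], B is a PIUB iff G2 contains one of
[x, -B, c], [-c, B, x], [a, -B, x], [x, B, -a].

Across the all-versus-all genome comparison, blocks identical up to whole-
block strand flip are counted once; the PIUB flag is OR-merged over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import Genome, GenomeSet, canonical_chromosome

__all__ = [
    "Block",
    "pairwise_unique_blocks",
    "collect_unique_blocks",
    "m0_summary",
    "breakpoint_count",
    "M0_STAT_NAMES",
    "DEFAULT_S_BL",
]

DEFAULT_S_BL = 10


@dataclass(frozen=True)
class Block:
    """A shared gene block, read along G1, with its inversion signature."""

    genes: tuple[int, ...]
    is_piub: bool

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def canonical(self) -> tuple[int, ...]:
        return canonical_chromosome(self.genes)


class _FlatGenome:
    """Concatenated-array view of a genome for the vectorized scan."""

    __slots__ = (
        "signed", "mag", "chrom", "loc", "offset", "chrom_len", "n", "_tables"
    )

    def __init__(self, genome: Genome):
        chroms = genome.chromosomes
        signed = np.concatenate([np.asarray(c, dtype=np.int64) for c in chroms])
        n = signed.size
        mag = np.abs(signed)
        chrom = np.empty(n, dtype=np.int64)
        loc = np.empty(n, dtype=np.int64)
        chrom_len = np.array([len(c) for c in chroms], dtype=np.int64)
        offset = np.concatenate([[0], np.cumsum(chrom_len)])
        for ci, c in enumerate(chroms):
            sl = slice(offset[ci], offset[ci + 1])
            chrom[sl] = ci + 1
            loc[sl] = np.arange(1, len(c) + 1)
        self.signed = signed
        self.mag = mag
        self.chrom = chrom
        self.loc = loc
        self.offset = offset
        self.chrom_len = chrom_len
        self.n = n
        self._tables: dict[int, tuple] = {}

    def position_tables(self, size: int | None = None):
        """Per gene magnitude (index 1..size): sign, chromosome, location and
        flat concatenated index.  Magnitudes absent from this genome keep
        zeros, which can never satisfy a match condition."""
        n = max(size or 0, int(self.mag.max()) if self.n else 0)
        if n in self._tables:
            return self._tables[n]
        sign = np.zeros(n + 1, dtype=np.int64)
        chrom = np.zeros(n + 1, dtype=np.int64)
        loc = np.zeros(n + 1, dtype=np.int64)
        flat = np.zeros(n + 1, dtype=np.int64)
        sign[self.mag] = np.sign(self.signed)
        chrom[self.mag] = self.chrom
        loc[self.mag] = self.loc
        flat[self.mag] = np.arange(self.n)
        self._tables[n] = (sign, chrom, loc, flat)
        return sign, chrom, loc, flat


def _scan_blocks(f1: _FlatGenome, f2: _FlatGenome) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized left-to-right scan of G1 against G2.

    Returns (starts, ends, direction): flat index ranges [start, end) into
    G1's concatenation, one per maximal block, plus the strand-product
    direction d of each block (d of its first gene).
    """
    size = int(max(f1.mag.max(), f2.mag.max()))
    sign2, chrom2, loc2, _ = f2.position_tables(size)
    g = f1.mag
    s1 = np.sign(f1.signed)
    d = s1 * sign2[g]

    n = f1.n
    if n == 1:
        return np.array([0]), np.array([1]), d[:1]

    cur, nxt = g[:-1], g[1:]
    same_chrom_g1 = f1.chrom[:-1] == f1.chrom[1:]
    extend = (
        same_chrom_g1
        & (chrom2[nxt] == chrom2[cur])
        & (loc2[nxt] == loc2[cur] + d[:-1])
        & (sign2[nxt] * d[:-1] == s1[1:])
    )
    # block boundaries: position i starts a block iff i==0 or not extend[i-1]
    starts = np.flatnonzero(np.concatenate([[True], ~extend]))
    ends = np.concatenate([starts[1:], [n]])
    return starts, ends, d[starts]


def _piub_flags(
    f1: _FlatGenome,
    f2: _FlatGenome,
    starts: np.ndarray,
    ends: np.ndarray,
    direction: np.ndarray,
) -> np.ndarray:
    """PIUB test per block, vectorized over blocks.

    For G1 neighborhood [a, B, c] the four G2 patterns reduce to signed
    comparisons of the genes flanking B's occurrence in G2.
    """
    size = int(max(f1.mag.max(), f2.mag.max()))
    sign2, chrom2, loc2, flat2 = f2.position_tables(size)

    first = f1.mag[starts]           # first gene of B along G1
    last = f1.mag[ends - 1]          # last gene of B along G1
    # flat G2 indices of the two ends of the block's occurrence in G2
    i_first = flat2[first]
    i_last = flat2[last]
    lo2 = np.minimum(i_first, i_last)
    hi2 = np.maximum(i_first, i_last)

    # G1 neighbors a (before) and c (after), signed; 0 when absent
    n1 = f1.n
    a_idx = starts - 1
    c_idx = ends
    has_a = (a_idx >= 0) & (np.where(a_idx >= 0, f1.chrom[np.maximum(a_idx, 0)], -1)
                            == f1.chrom[starts])
    has_c = (c_idx < n1) & (np.where(c_idx < n1, f1.chrom[np.minimum(c_idx, n1 - 1)], -1)
                            == f1.chrom[ends - 1])
    a = np.where(has_a, f1.signed[np.maximum(a_idx, 0)], 0)
    c = np.where(has_c, f1.signed[np.minimum(c_idx, n1 - 1)], 0)

    # G2 flanking genes of the block occurrence; 0 when off the chromosome
    n2 = f1.n
    left_idx = lo2 - 1
    right_idx = hi2 + 1
    blk_chrom = chrom2[first]
    has_left = (left_idx >= 0) & (
        np.where(left_idx >= 0, f2.chrom[np.maximum(left_idx, 0)], -1) == blk_chrom
    )
    has_right = (right_idx < n2) & (
        np.where(right_idx < n2, f2.chrom[np.minimum(right_idx, n2 - 1)], -1) == blk_chrom
    )
    left = np.where(has_left, f2.signed[np.maximum(left_idx, 0)], 0)
    right = np.where(has_right, f2.signed[np.minimum(right_idx, n2 - 1)], 0)

    fwd = direction > 0
    # d=+1: [-c, B, x] -> left == -c ; [x, B, -a] -> right == -a
    piub_fwd = (has_c & has_left & (left == -c)) | (has_a & has_right & (right == -a))
    # d=-1: B appears reversed in G2 spanning [lo2, hi2]:
    # [x, -B, c] -> right == c ; [a, -B, x] -> left == a
    piub_rev = (has_c & has_right & (right == c)) | (has_a & has_left & (left == a))
    # blocks led by a gene absent from G2 have no occurrence there
    return np.where(fwd, piub_fwd, piub_rev) & (direction != 0)


def pairwise_unique_blocks(g1: Genome, g2: Genome) -> list[Block]:
    """All maximal shared blocks between two genomes, read along ``g1``.

    The returned blocks partition ``g1``: every gene appears in exactly one
    block.  Genes absent from ``g2`` form (or terminate) their own blocks
    and are never PIUBs; core-genome inputs never contain such genes.
    """
    f1, f2 = _FlatGenome(g1), _FlatGenome(g2)
    starts, ends, direction = _scan_blocks(f1, f2)
    piub = _piub_flags(f1, f2, starts, ends, direction)
    signed = f1.signed
    return [
        Block(tuple(int(x) for x in signed[s:e]), bool(p))
        for s, e, p in zip(starts, ends, piub)
    ]


def piub_flag(block_genes: tuple[int, ...], g1: Genome, g2: Genome) -> bool:
    """Whether the UB ``block_genes`` (as read along ``g1``) is a PIUB of the
    pair.  The block must be one of the pair's unique blocks."""
    for b in pairwise_unique_blocks(g1, g2):
        if b.genes == tuple(block_genes):
            return b.is_piub
    raise ValueError("block is not a unique block of this genome pair")


def _canonicalize_blocks(
    signed: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Per-block strand canonicalization, vectorized.

    Returns a copy of ``signed`` in which every block [start, end) is
    replaced by the lexicographic min of itself and its reverse-negation.
    """
    n = signed.size
    lens = ends - starts
    block_id = np.repeat(np.arange(starts.size), lens)
    idx = np.arange(n)
    rev_idx = (starts + ends - 1)[block_id] - idx
    revneg = -signed[rev_idx]
    diff = signed - revneg
    # first differing position per block decides the orientation
    pos = np.where(diff != 0, idx, n)
    first = np.minimum.reduceat(pos, starts)
    take_fwd = np.where(
        first < n, np.concatenate([diff, [0]])[first] < 0, True
    )
    return np.where(take_fwd[block_id], signed, revneg)


def collect_unique_blocks(gs: GenomeSet) -> dict[tuple[int, ...], bool]:
    """All-versus-all UBs, deduplicated by canonical (strand-blind) form.

    Returns canonical block -> PIUB flag (OR over all pair occurrences).
    Both orderings of every pair are scanned, so blocks of either genome
    enter the union.
    """
    if len(gs) < 2:
        raise ValueError("need at least two genomes")
    names = gs.names()
    flats = {n: _FlatGenome(gs[n]) for n in names}
    out: dict[tuple[int, ...], bool] = {}
    for na in names:
        for nb in names:
            if na == nb:
                continue
            f1, f2 = flats[na], flats[nb]
            starts, ends, direction = _scan_blocks(f1, f2)
            piub = _piub_flags(f1, f2, starts, ends, direction)
            canon = _canonicalize_blocks(f1.signed, starts, ends).tolist()
            for s, e, p in zip(starts.tolist(), ends.tolist(), piub.tolist()):
                key = tuple(canon[s:e])
                if p:
                    out[key] = True
                elif key not in out:
                    out[key] = False
    return out


def m0_summary(gs: GenomeSet, s_bl: int = DEFAULT_S_BL) -> np.ndarray:
    """The 2*s_bl+2 gene-order summary vector (22 by default).

    Entries 0..s_bl-1: deduplicated UB counts by size 1..s_bl; entry s_bl:
    UBs larger than s_bl; entries s_bl+1..2*s_bl+1: the same for PIUBs.
    """
    blocks = collect_unique_blocks(gs)
    ub = np.zeros(s_bl + 1, dtype=np.int64)
    piub = np.zeros(s_bl + 1, dtype=np.int64)
    for genes, flag in blocks.items():
        b = min(len(genes), s_bl + 1) - 1
        ub[b] += 1
        if flag:
            piub[b] += 1
    return np.concatenate([ub, piub])


def M0_STAT_NAMES(s_bl: int = DEFAULT_S_BL) -> list[str]:
    names = [f"ub_size_{k}" for k in range(1, s_bl + 1)] + [f"ub_gt_{s_bl}"]
    names += [f"piub_size_{k}" for k in range(1, s_bl + 1)] + [f"piub_gt_{s_bl}"]
    return names


def breakpoint_count(g1: Genome, g2: Genome) -> int:
    """Signed breakpoints between two single-chromosome genomes.

    An adjacency (x, y) of G1 is conserved when (x, y) or (-y, -x) is
    adjacent in G2; breakpoints are the non-conserved adjacencies.  For two
    single-chromosome genomes the UB count approximately satisfies
    UB = Br + 1 (events at chromosome edges break the relation).
    """
    if g1.n_chromosomes != 1 or g2.n_chromosomes != 1:
        raise ValueError("breakpoint count is defined for single-chromosome genomes")
    c1, c2 = g1.chromosomes[0], g2.chromosomes[0]
    adj2 = set()
    for x, y in zip(c2, c2[1:]):
        adj2.add((x, y))
        adj2.add((-y, -x))
    return sum(1 for x, y in zip(c1, c1[1:]) if (x, y) not in adj2)
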