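"""Shared fixtures and independent brute-force oracles.

The oracles deliberately take a different computational route from the
package (substring search on token strings vs. index-walk scan) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from rearrabc import Genome, GenomeSet
from rearrabc.genomes import canonical_chromosome, reverse_negate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_signed_genome(
    rng: np.random.Generator, n: int, n_chrom: int = 1
) -> Genome:
    """Uniform random signed permutation split into n_chrom chromosomes."""
    perm = rng.permutation(np.arange(1, n + 1))
    signs = rng.choice([-1, 1], size=n)
    genes = (perm * signs).tolist()
    n_chrom = min(n_chrom, n)
    if n_chrom == 1:
        return Genome((tuple(genes),))
    cuts = np.sort(rng.choice(np.arange(1, n), size=n_chrom - 1, replace=False))
    chroms, prev = [], 0
    for c in list(cuts) + [n]:
        chroms.append(tuple(genes[prev:c]))
        prev = c
    return Genome(tuple(chroms))


# --- brute-force unique-block oracle ---------------------------------------

def _occurs(sub: tuple[int, ...], g2: Genome) -> bool:
    """Contiguous occurrence of ``sub`` in g2, either strand reading."""
    for chrom in g2.chromosomes:
        for seq in (chrom, reverse_negate(chrom)):
            for i in range(len(seq) - len(sub) + 1):
                if seq[i : i + len(sub)] == sub:
                    return True
    return False


def brute_force_blocks(g1: Genome, g2: Genome) -> list[tuple[int, ...]]:
    """Maximal shared blocks along g1, by exhaustive substring search."""
    out = []
    for chrom in g1.chromosomes:
        n = len(chrom)
        i = 0
        while i < n:
            j = i + 1
            while j <= n and _occurs(chrom[i:j], g2):
                j += 1
            j -= 1  # longest occurring prefix starting at i
            if j == i:  # single gene absent from g2
                j = i + 1
            out.append(chrom[i:j])
            i = j
    return out


def brute_force_piub(block: tuple[int, ...], g1: Genome, g2: Genome) -> bool:
    """Literal enumeration of the four inverted-neighbor patterns in g2."""
    # locate the block's G1 neighborhood [a, B, c]
    a = c = None
    for chrom in g1.chromosomes:
        for i in range(len(chrom) - len(block) + 1):
            if chrom[i : i + len(block)] == block:
                a = chrom[i - 1] if i > 0 else None
                c = chrom[i + len(block)] if i + len(block) < len(chrom) else None
                break
    neg = reverse_negate(block)
    pats = []
    if c is not None:
        pats.append(neg + (c,))          # [x, -B, c]
        pats.append((-c,) + block)       # [-c, B, x]
    if a is not None:
        pats.append((a,) + neg)          # [a, -B, x]
        pats.append(block + (-a,))       # [x, B, -a]
    return any(_occurs(p, g2) for p in pats)


def brute_force_collection(gs: GenomeSet) -> dict[tuple[int, ...], bool]:
    """Union over ordered pairs of maximal blocks, canonical dedup,
    PIUB flag OR-merged."""
    out: dict[tuple[int, ...], bool] = {}
    names = gs.names()
    for na in names:
        for nb in names:
            if na == nb:
                continue
            g1, g2 = gs[na], gs[nb]
            for b in brute_force_blocks(g1, g2):
                key = canonical_chromosome(b)
                flag = brute_force_piub(b, g1, g2)
                out[key] = out.get(key, False) or flag
    return out
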