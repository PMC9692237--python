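"""Continuous-time genome-rearrangement simulation along a phylogeny.

Two nested models:

* **M0** — a single linear chromosome; inversions (reverse a gene block in
  place, flipping strands) and translocations (excise a block and reinsert
  it elsewhere, in either orientation) at rates ``r_inv`` and ``r_trans``
  per gene per unit branch length.
* **M1** — multiple chromosomes; adds chromosome fission (rate ``r_fis``
  per gene) and fusion (rate ``r_fus`` per *chromosome*), plus the root
  chromosome count ``ch_root``.  Fission depends on DNA breaks and so
  scales with gene count; fusion joins two chromosome ends and so scales
  with chromosome count.

Block sizes follow a trimmed Zipfian law
``f(k | a, m_zip) = k^-a / sum_{i=1}^{m_zip} i^-a`` on ``{1..m_zip}``.

Events are drawn as an exact jump process: waiting times are exponential
in the current total hazard, which is recomputed after every event so the
fusion hazard tracks the changing chromosome count within a branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomes import Genome, GenomeSet, PhyloTree, reverse_negate

__all__ = [
    "ModelParams",
    "EventRecord",
    "zipf_block_pmf",
    "sample_block_size",
    "make_root_genome",
    "apply_inversion",
    "apply_translocation",
    "apply_fission",
    "apply_fusion",
    "simulate_branch",
    "simulate_tree",
]

DEFAULT_M_ZIP = 50


@dataclass(frozen=True)
class ModelParams:
    """Rate parameters of the rearrangement model.

    Rates are events per gene per unit branch length (branch lengths in
    expected substitutions per site), except ``r_fus`` which is per
    chromosome per unit branch length.
    """

    model: str = "M0"  # "M0" or "M1"
    r_inv: float = 0.0
    r_trans: float = 0.0
    a: float = 1.5  # Zipf exponent of the block-size law
    m_zip: int = DEFAULT_M_ZIP
    ch_root: int = 1
    r_fus: float = 0.0
    r_fis: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("M0", "M1"):
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.r_inv, self.r_trans, self.r_fus, self.r_fis) < 0:
            raise ValueError("rates must be non-negative")
        if self.a <= 1.0:
            raise ValueError("Zipf exponent a must exceed 1")
        if self.m_zip < 1 or self.ch_root < 1:
            raise ValueError("m_zip and ch_root must be >= 1")
        if self.model == "M0" and (
            self.ch_root != 1 or self.r_fus != 0.0 or self.r_fis != 0.0
        ):
            raise ValueError("M0 requires ch_root=1 and zero fusion/fission rates")

    # convenient for the ABC layer
    def as_dict(self) -> dict[str, float]:
        d = {"r_inv": self.r_inv, "r_trans": self.r_trans, "a": self.a}
        if self.model == "M1":
            d.update(ch_root=self.ch_root, r_fus=self.r_fus, r_fis=self.r_fis)
        return d


@dataclass(frozen=True)
class EventRecord:
    """One applied rearrangement event (for provenance and testing)."""

    branch: str
    kind: str  # inversion | translocation | fission | fusion
    time: float  # position within the branch, in branch-length units
    detail: dict = field(default_factory=dict)


def zipf_block_pmf(a: float, m_zip: int) -> np.ndarray:
    """Probability vector of the trimmed Zipfian block-size law on 1..m_zip."""
    if a <= 0 or m_zip < 1:
        raise ValueError("need a > 0 and m_zip >= 1")
    k = np.arange(1, m_zip + 1, dtype=float)
    w = k ** (-a)
    return w / w.sum()


class _ZipfSampler:
    """Precomputed inverse-CDF sampler for the trimmed Zipfian law."""

    def __init__(self, a: float, m_zip: int):
        self.cdf = np.cumsum(zipf_block_pmf(a, m_zip))

    def draw(self, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self.cdf, rng.random(), side="right")) + 1


def sample_block_size(
    a: float, m_zip: int, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw ``n`` block sizes from the trimmed Zipfian law."""
    cdf = np.cumsum(zipf_block_pmf(a, m_zip))
    return np.searchsorted(cdf, rng.random(n), side="right") + 1


def make_root_genome(n_root: int, ch_root: int, rng: np.random.Generator) -> Genome:
    """Identity-ordered root genome split into ``ch_root`` chromosomes.

    Genes ``1..ch_root`` seed one chromosome each so none is empty; the
    remaining genes are placed uniformly at random, giving a near-multinomial
    chromosome-size distribution conditioned on no empty chromosome.
    """
    if ch_root > n_root:
        raise ValueError(f"ch_root={ch_root} exceeds n_root={n_root}")
    chroms: list[list[int]] = [[g] for g in range(1, ch_root + 1)]
    if n_root > ch_root:
        assignment = rng.integers(0, ch_root, size=n_root - ch_root)
        for g, c in zip(range(ch_root + 1, n_root + 1), assignment):
            chroms[c].append(g)
    return Genome(tuple(tuple(c) for c in chroms))


# ---------------------------------------------------------------------------
# Elementary events.  All take/return immutable Genome objects; chromosome
# labels are 1-based, positions 1-based within chromosomes.

def apply_inversion(g: Genome, chrom: int, start: int, size: int) -> Genome:
    """Reverse the block [start, start+size-1] of chromosome ``chrom`` in
    place, flipping every sign."""
    c = list(g.chromosomes[chrom - 1])
    if start < 1 or size < 1 or start + size - 1 > len(c):
        raise ValueError("inversion block exceeds chromosome bounds")
    lo, hi = start - 1, start - 1 + size
    c[lo:hi] = [-x for x in reversed(c[lo:hi])]
    new = list(g.chromosomes)
    new[chrom - 1] = tuple(c)
    return Genome(tuple(new))


def apply_translocation(
    g: Genome,
    src_chr: int,
    start: int,
    size: int,
    dest_chr: int,
    dest_pos: int,
    inverted: bool,
) -> Genome:
    """Excise the block [start, start+size-1] of ``src_chr`` and reinsert it
    immediately after the gene at ``(dest_chr, dest_pos)``.

    ``dest_pos`` is given in pre-excision coordinates; ``dest_pos = 0``
    inserts at the chromosome start.  Destinations inside the excised span
    are ill-defined, and the identity placement (just before the block,
    same orientation) is a null event; both raise ``ValueError``.
    """
    src = list(g.chromosomes[src_chr - 1])
    if start < 1 or size < 1 or start + size - 1 > len(src):
        raise ValueError("translocation block exceeds chromosome bounds")
    dest_len = len(g.chromosomes[dest_chr - 1])
    if dest_pos < 0 or dest_pos > dest_len:
        raise ValueError("destination position out of range")
    if dest_chr == src_chr:
        if start <= dest_pos <= start + size - 1:
            raise ValueError("destination inside the excised block area")
        if dest_pos == start - 1 and not inverted:
            raise ValueError("null translocation (identity placement)")
    block = src[start - 1 : start - 1 + size]
    if inverted:
        block = list(reverse_negate(block))
    del src[start - 1 : start - 1 + size]

    new = list(g.chromosomes)
    new[src_chr - 1] = tuple(src)
    dest = list(new[dest_chr - 1])
    # translate pre-excision coordinate to post-excision insertion index
    ins = dest_pos
    if dest_chr == src_chr and dest_pos >= start + size:
        ins = dest_pos - size
    dest[ins:ins] = block
    new[dest_chr - 1] = tuple(dest)
    out = tuple(c for c in new if c)  # src may empty out only if size==len; keep content
    if sum(len(c) for c in out) != g.n_genes:
        raise AssertionError("translocation lost genes")
    return Genome(out)


def apply_fission(g: Genome, chrom: int, pos: int) -> Genome:
    """Split chromosome ``chrom`` after position ``pos`` (1 <= pos < length)."""
    c = g.chromosomes[chrom - 1]
    if not (1 <= pos <= len(c) - 1):
        raise ValueError("fission at a chromosome edge is a null event")
    new = list(g.chromosomes)
    new[chrom - 1 : chrom] = [c[:pos], c[pos:]]
    return Genome(tuple(new))


def apply_fusion(g: Genome, chr_a: int, end_a: str, chr_b: int, end_b: str) -> Genome:
    """Fuse chromosome ``chr_b`` onto chromosome ``chr_a``.

    ``end_a``/``end_b`` in {"head", "tail"} select which ends meet at the
    junction; the attached chromosome is reverse-negated when needed so the
    junction reads consistently.  E.g. head-of-B onto tail-of-A concatenates
    A + B; tail-of-B onto tail-of-A concatenates A + reverse_negate(B).
    """
    if chr_a == chr_b:
        raise ValueError("cannot fuse a chromosome with itself")
    if end_a not in ("head", "tail") or end_b not in ("head", "tail"):
        raise ValueError("ends must be 'head' or 'tail'")
    a = g.chromosomes[chr_a - 1]
    b = g.chromosomes[chr_b - 1]
    if end_a == "tail":
        fused = a + (b if end_b == "head" else reverse_negate(b))
    else:
        fused = (reverse_negate(b) if end_b == "head" else b) + a
    new = [c for i, c in enumerate(g.chromosomes, start=1) if i not in (chr_a, chr_b)]
    new.insert(min(chr_a, chr_b) - 1, fused)
    return Genome(tuple(new))


# ---------------------------------------------------------------------------
# Event sampling helpers (operate on a mutable list-of-lists genome state
# for speed inside the jump process).

_MAX_SIZE_REDRAWS = 1000


def _draw_start(chrom_lens: list[int], rng: np.random.Generator) -> tuple[int, int]:
    """Uniform gene position genome-wide -> (chromosome label, 1-based pos)."""
    n = sum(chrom_lens)
    u = int(rng.integers(0, n))
    for ci, ln in enumerate(chrom_lens, start=1):
        if u < ln:
            return ci, u + 1
        u -= ln
    raise AssertionError("unreachable")


def _draw_block(
    chrom_lens: list[int], zipf: _ZipfSampler, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Draw (chromosome, start, size): start uniform over genes, size from the
    Zipfian law redrawn while the block would overrun the chromosome end."""
    ci, start = _draw_start(chrom_lens, rng)
    limit = chrom_lens[ci - 1] - start + 1
    size = zipf.draw(rng)
    tries = 0
    while size > limit:
        tries += 1
        if tries >= _MAX_SIZE_REDRAWS:
            size = 1
            break
        size = zipf.draw(rng)
    return ci, start, size


def simulate_branch(
    genome: Genome,
    t: float,
    params: ModelParams,
    rng: np.random.Generator,
    branch: str = "",
    record_events: bool = False,
) -> tuple[Genome, list[EventRecord]]:
    """Evolve ``genome`` for branch length ``t`` under ``params``.

    Exact jump process: with n genes and C chromosomes the total hazard is
    ``(r_inv + r_trans + r_fis) * n + r_fus * C``; kinds are chosen
    proportional to their hazard terms.  Fusion is infeasible at C = 1 and
    fission when every chromosome is a singleton; infeasible kinds
    contribute no hazard.
    """
    if t < 0:
        raise ValueError("negative branch length")
    state = [list(c) for c in genome.chromosomes]
    n = sum(len(c) for c in state)
    zipf = _ZipfSampler(params.a, params.m_zip)
    events: list[EventRecord] = []
    clock = 0.0

    while True:
        lens = [len(c) for c in state]
        C = len(state)
        h_inv = params.r_inv * n
        h_trans = params.r_trans * n if n >= 2 else 0.0
        h_fis = params.r_fis * n if any(ln >= 2 for ln in lens) else 0.0
        h_fus = params.r_fus * C if C >= 2 else 0.0
        total = h_inv + h_trans + h_fis + h_fus
        if total <= 0.0:
            break
        clock += rng.exponential(1.0 / total)
        if clock > t:
            break
        u = rng.random() * total
        if u < h_inv:
            kind = "inversion"
        elif u < h_inv + h_trans:
            kind = "translocation"
        elif u < h_inv + h_trans + h_fis:
            kind = "fission"
        else:
            kind = "fusion"

        if kind == "inversion":
            ci, start, size = _draw_block(lens, zipf, rng)
            c = state[ci - 1]
            lo, hi = start - 1, start - 1 + size
            c[lo:hi] = [-x for x in reversed(c[lo:hi])]
            detail = {"chrom": ci, "start": start, "size": size}
        elif kind == "translocation":
            ci, start, size = _draw_block(lens, zipf, rng)
            if size == n:
                # whole-genome block has no destination; treat as infeasible draw
                continue
            inverted = bool(rng.random() < 0.5)
            # destination: uniform over insertion slots (after-gene positions,
            # 0..len per chromosome) excluding the excised span and, for the
            # non-inverted case, the identity placement
            while True:
                dci, dpos_gene = _draw_start([ln + 1 for ln in lens], rng)
                dpos = dpos_gene - 1  # 0..len
                if dci == ci:
                    if start <= dpos <= start + size - 1:
                        continue
                    if dpos == start - 1 and not inverted:
                        continue
                break
            block = state[ci - 1][start - 1 : start - 1 + size]
            if inverted:
                block = [-x for x in reversed(block)]
            del state[ci - 1][start - 1 : start - 1 + size]
            ins = dpos
            if dci == ci and dpos >= start + size:
                ins = dpos - size
            state[dci - 1][ins:ins] = block
            if not state[ci - 1]:
                del state[ci - 1]
            detail = {
                "src_chr": ci, "start": start, "size": size,
                "dest_chr": dci, "dest_pos": dpos, "inverted": inverted,
            }
        elif kind == "fission":
            # uniform over internal cut points of the genome
            internal = [ln - 1 for ln in lens]
            tot_cuts = sum(internal)
            u2 = int(rng.integers(0, tot_cuts))
            for ci, k in enumerate(internal, start=1):
                if u2 < k:
                    pos = u2 + 1
                    break
                u2 -= k
            c = state[ci - 1]
            state[ci - 1 : ci] = [c[:pos], c[pos:]]
            detail = {"chrom": ci, "pos": pos}
        else:  # fusion
            ia, ib = rng.choice(C, size=2, replace=False)
            end_a = "tail" if rng.random() < 0.5 else "head"
            end_b = "head" if rng.random() < 0.5 else "tail"
            a, b = state[int(ia)], state[int(ib)]
            if end_a == "tail":
                fused = a + (b if end_b == "head" else [-x for x in reversed(b)])
            else:
                fused = ([-x for x in reversed(b)] if end_b == "head" else b) + a
            keep = [c for j, c in enumerate(state) if j not in (int(ia), int(ib))]
            keep.insert(min(int(ia), int(ib)), fused)
            state = keep
            detail = {"chr_a": int(ia) + 1, "end_a": end_a,
                      "chr_b": int(ib) + 1, "end_b": end_b}
        if record_events:
            events.append(EventRecord(branch=branch, kind=kind, time=clock,
                                      detail=detail))
        elif events is not None:
            events.append(EventRecord(branch=branch, kind=kind, time=clock))

    return Genome(tuple(tuple(c) for c in state)), events


def simulate_tree(
    tree: PhyloTree,
    params: ModelParams,
    n_root: int,
    rng: np.random.Generator,
    record_events: bool = False,
) -> tuple[GenomeSet, list[EventRecord]]:
    """Simulate leaf genomes by evolving a root genome down ``tree``.

    The root is the identity gene order split into ``params.ch_root``
    chromosomes; every branch evolves independently given its parent state.
    Returns the leaf genomes keyed by leaf label plus the event log.
    """
    ch_root = params.ch_root if params.model == "M1" else 1
    root_genome = make_root_genome(n_root, ch_root, rng)
    genomes: dict[str, Genome] = {}
    log: list[EventRecord] = []

    dtree = tree.tree
    states: dict[int, Genome] = {id(dtree.seed_node): root_genome}
    for i, node in enumerate(dtree.preorder_node_iter()):
        if node.parent_node is None:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        label = (
            node.taxon.label if node.taxon is not None else f"node{i}"
        )
        g, ev = simulate_branch(
            parent_state, t, params, rng, branch=label, record_events=record_events
        )
        states[id(node)] = g
        log.extend(ev)
        if node.is_leaf():
            genomes[node.taxon.label] = g
    return GenomeSet(genomes, n_root=n_root), log
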