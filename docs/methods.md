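# Methods

## The models

`rearrabc` treats a genome as an unordered set of chromosomes, each an
ordered list of signed integers: the magnitude names an ortholog family,
the sign the strand. Gene content is fixed (core genome), so the only
evolutionary moves are rearrangements. Two nested continuous-time Markov
models are implemented:

* **M0** — one linear chromosome; *inversions* (a block of adjacent genes
  is reversed in place and strand-flipped) at rate `r_inv` per gene per
  unit branch length, and *translocations* (a block is excised and
  reinserted elsewhere, in either orientation with equal probability) at
  rate `r_trans` per gene per unit branch length.
* **M1** — several chromosomes; adds *fission* (a chromosome splits at an
  internal point) at rate `r_fis` per gene, and *fusion* (two chromosome
  ends join) at rate `r_fus` per **chromosome**, plus the root chromosome
  count `ch_root`. Fission follows from a DNA break and so scales with
  gene count; fusion joins two ends and so scales with chromosome count.

Branch lengths are expected substitutions per site; all rates are per unit
of that length. Block sizes follow a trimmed Zipfian law
`f(k|a, m_zip) = k^-a / sum_{i<=m_zip} i^-a` with exponent `a > 1` and cap
`m_zip = 50` by default.

### Event sampling

Within a branch, events form an exact jump process (Gillespie): the total
hazard at a state with `n` genes and `C` chromosomes is
`(r_inv + r_trans + r_fis)·n + r_fus·C`, waiting times are exponential,
and the event kind is chosen proportionally to its hazard term. The
per-chromosome fusion hazard therefore tracks `C` as it changes inside a
branch, which a fixed-count Poisson draw would mis-weight. Infeasible
kinds (fusion at `C = 1`, fission when every chromosome is a singleton)
contribute no hazard.

Coordinates: the block start is uniform over gene positions genome-wide;
the Zipfian size is redrawn while the block would overrun its chromosome
end (after 1,000 redraws the size falls back to 1 — reachable only from
the last position). Translocation destinations are uniform over insertion
slots outside the excised span, excluding the identity placement in the
non-inverted case, so no event is a null event. Fission points are uniform
over internal positions; fusion picks an ordered chromosome pair and one
of four end pairings uniformly, reverse-negating the attached chromosome
as the junction requires.

The root genome is the identity order `1..n_root`. Under M1 it is split
into `ch_root` chromosomes by seeding each with one gene and placing the
rest uniformly (near-multinomial sizes conditioned on no empty
chromosome). Summary statistics are invariant to the root labeling, so the
identity order loses no generality.

## Summary statistics

**Gene order (22 dims).** A *unique block* (UB) is a maximal gene run
shared by two genomes in the same or inverted orientation. Blocks are
found by a single left-to-right scan of the first genome using a
location index of the second (O(n_root) per pair; the implementation
evaluates the same recurrence with vectorized array operations). A UB is
a *probably inverted* UB (PIUB) when a common neighbor flanks it reversed
in the partner genome — with G1 locally `[a, B, c]`, G2 showing
`[x, -B, c]`, `[-c, B, x]`, `[a, -B, x]` or `[x, B, -a]` — the signature
of an inversion rather than a translocation. All ordered genome pairs are
scanned; blocks identical up to a whole-block strand flip are counted
once, the PIUB flag OR-merged across pairs. The statistics are the
deduplicated UB counts by size 1..10 plus an overflow bin, and the same
for PIUBs. For two single-chromosome genomes the scan yields
`UB = breakpoints + 1`; events touching chromosome edges can perturb the
bookkeeping on both sides at once, so the relation is checked
statistically rather than assumed.

**Chromosome level (8 dims).** A chromosome's *tips* are its first and
last genes (orientation ignored); its *minimalized chromosome* (MC) is the
ordered signed tip pair with `[A, B] ≡ [-B, -A]` but `≠ [-A, B]`; a
single-gene chromosome `[x]` has MC `[x, x]`. Internal tree nodes carry
the union of their children's MC sets. The eight statistics are the min,
max, mean and population variance of leaf chromosome counts, the root
MC-set and tip-set sizes, the number of *unique tips* (present in a node
but in no sibling) and the number of *probable fission-fusions* (an MC
present in one child, absent in both orientations from a sibling whose
tip set still holds both of its tips), counted once per (internal node,
MC). Population variance (divide by L) is used; a configuration switch is
deliberately not exposed — the statistic only needs to be computed
consistently between observation and simulation for ABC to work.

## Rejection ABC

The proposal equals the prior (defaults: `a ~ U(1.001, 2)`,
`r_inv, r_trans ~ U(0, 1.5)`, `ch_root ~ U{4..18}`, `r_fus ~ U(0, 0.8)`,
`r_fis ~ U(0, 0.03)`; log-normal, gamma and Poisson families are also
available). `s_abc` datasets are simulated along the input tree; the
distance between summary vectors is Euclidean after dividing each
dimension by its standard deviation across the pool ("weighting by the
standard deviation" is read as standardization — multiplying would let
high-variance dimensions dominate, defeating the purpose; the literal
multiply-by-std reading is kept behind ``weight_mode='multiply'`` for
comparison). Zero-variance dimensions are skipped. The `m` closest
simulations are retained (a uniform kernel with a dynamic threshold equal
to the largest retained distance; ties break by pool order). The point
estimate is the retained mean; the 90% credible interval the 5th–95th
percentile range.

Under M1 the inference runs in two passes: the M0-inherited parameters use
only the 22 gene-order dimensions, the chromosome parameters only the 8
chromosome dimensions — each block of statistics is nearly uninformative
about the other group of parameters.

One reference pool is shared across the test datasets of an evaluation
configuration (and across the `m` candidates in the retention-size
optimization): the retained neighborhoods of distinct datasets barely
overlap at realistic pool sizes, and per-dataset pools would multiply the
cost by the number of test datasets.

## Synthetic data and scaled-down defaults

The fixture generator produces random bifurcating trees (uniform
sequential joining; i.i.d. exponential branch lengths rescaled to a target
total) and genomes simulated under the models themselves. The evaluation
defaults are deliberately desk-scale: a 10-leaf tree of total length 0.2,
`n_root = 1,000`, `s_abc = 10,000`, `m = 50`, 50 test datasets. Total
length 0.2 mirrors a closely related microbial core-genome phylogeny:
pairwise paths of a few hundredths of a substitution per site yield tens
to a few hundred rearrangement events at prior-typical rates — informative
but far from the saturation regime where unique blocks degenerate to
single genes. The M1 evaluation instead uses total length 1.5 with
`n_root = 500`: fission tops out at `0.03` per gene, so chromosome-number
events are vanishingly rare on short trees, and a deeper (yeast-like)
divergence is the regime the multi-chromosome model is meant for.

What scaled-down passing shows — and does not. Rate recovery (r² ≥ 0.8
for inversion and translocation rates) and near-nominal credible-interval
coverage at this scale demonstrate the estimator is consistent and
calibrated on data generated by its own model. They do not certify
accuracy on empirical genomes, where ortholog calls, tree error and
non-core genes add noise the generator does not emulate. Fusion and
fission r² at desk scale is intrinsically low: with ~10 chromosomes only
a handful of fusion events occur regardless of genome size, so the
all-statistics signal is weak; recovering the published accuracy for
those parameters requires the full-scale setting (hundreds of thousands
of simulations, larger genomes and deeper trees).

## Numerical choices and edge cases

* Chromosome canonicalization compares signed integers lexicographically;
  any total order works, one is fixed for reproducibility.
* Retention ties at the threshold break by pool row order (stable sort).
* `r_squared` returns 0 when either vector is constant (no-signal
  convention, used by the zero-branch-length control).
* Zero-length branches are legal and simulate zero events; multifurcating
  trees are accepted throughout (sibling definitions quantify over all
  siblings).
* A translocation of an entire chromosome empties its source; the empty
  chromosome is dropped (the move degenerates to a fusion-like event).
  Whole-genome blocks have no destination and are resampled.
* Blocks never span chromosome boundaries (the size redraw rule implies
  a block is confined to one chromosome).
* The exact-recovery contract (`m = 1` with the observed row present in
  the pool) returns the generating parameters up to ties between
  identical summary rows.

## Known limitations

* No gene gain/loss, duplication, transfer, or whole-genome duplication;
  content-altering events would need a richer genome format.
* No model choice between M0 and M1; the user selects the model.
* No regression adjustment or sequential ABC; plain rejection only.
* Branch lengths are taken from the input tree as substitutions per site;
  rearrangement clocks that decouple from the substitution clock violate
  the model's core assumption.
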