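# Methods

## The information model

A binding-site model over an alignment of `n` sites of width `L` assigns
base `b` at position `l` the weight, in bits,

    w(b,l) = 2 + log2 f'(b,l) − e(n),

with `f'(b,l) = (count(b,l) + 0.25) / (n + 1)` a lightly pseudocounted base
frequency, the 2-bit term the information of the uniform four-letter
background, and `e(n)` the small-sample correction. The uniform background
is deliberate: the weights model protein–DNA contacts, which do not depend
on the composition of the surrounding genome, so no relative-entropy
(composition-adjusted) variant is provided. The pseudocount is used only
inside the logarithm — it keeps zero-count weights finite (a zero count at
`n = 100` scores about −6.7 bits rather than −∞) while the per-position
entropies `H(l)` are computed from the raw frequencies.

A site's individual information is `Ri = Σ_l w(s_l, l)`; reverse-strand
sites are scored on the reverse complement of their window. `Rsequence` is
**defined** as the mean `Ri` of the training sites and computed as
`Σ_{b,l} f(b,l) w(b,l)`, which makes the identity "mean training-site Ri =
Rsequence" hold to machine precision for every constructed matrix; the
entropy form `Σ_l (2 − H(l) − e(n))` agrees to `O(L/n)` (the pseudocount
inside the log accounts for the difference) and is available from the
stored `entropies`. Ri differences convert to affinity fold changes as
`2^ΔRi`, which is also how substitution variants are assessed
(`ΔRi = w(alt,l) − w(ref,l)`).

### Small-sample correction

`e(n) = 2 − E[H_n]`, the expected shortfall of the plug-in entropy of `n`
draws from the uniform 4-letter distribution, is computed exactly for all
practical `n` through the binomial marginal:
`E[H_n] = 4·E[−(X/n)log2(X/n)]` with `X ~ Binomial(n, 1/4)`. This is an
O(n) sum, so no approximation is needed below `n = 100 000`; above that
the first-order asymptotic `3/(2 n ln 2)` is used, where the two agree to
better than 1e-9 bits. `e(1) = 2` (one site looks perfectly conserved),
`e(2) = 1.25`, and `e(n)` decreases monotonically to 0.

### Bipartite models

A bipartite model `l<a,b>r` is two half-site matrices separated by a
spacer of `a..b` nt whose length histogram is learned with the alignment.
A site's Ri is the sum of the two half-site Ri values; spacer positions
carry no weights. An optional spacer-length information term
`log2((b−a+1)·f_gap(g))` (pseudocount 0.25, so a uniform histogram
contributes exactly 0 bits) can be added via `include_gap_information`;
it is off by default so that Ri stays half-site-additive.

### Matrix comparison

The normalized Euclidean distance between two equal-width weight matrices
is `sqrt(Σ (w1 − w2)²) / L` in bits/nt, minimized over the reverse
complement of one matrix (alignment searches lock onto an arbitrary
strand; the symmetrized form is the quotient metric under that isometry,
so symmetry and the triangle inequality survive). Matrices of unequal
width are compared at the best full-overlap offset on either strand,
normalized by overlap length. Distances below ~1 bit/nt indicate
essentially the same motif; 1–2 bits/nt differ at one or two positions.

## Entropy-minimization alignment

Discovery seeks the placement of one site per sequence (offset, strand
and, for bipartite patterns, spacer length) minimizing the mean Shannon
entropy of the alignment columns; for bipartite patterns the entropy of
the spacer-length distribution, divided by the number of matrix columns,
is added so concentrating the spacers is rewarded. The optimizer is:

1. **Gibbs sampling** — sequences are swept in random order; each
   sequence's placement is resampled from the predictive distribution
   implied by the column (and spacer) counts with that sequence held out,
   at unit temperature. Candidate placements are precomputed per
   sequence; windows containing N and windows overlapping mask intervals
   are never candidates. Sequences with no legal placement are excluded
   (with a logged count).
2. **Phase-shift moves** — single-sequence updates cannot move the whole
   alignment between registers, and the sampler otherwise converges to
   phase-shifted optima (every site off by one, half-site boundaries slid
   into the spacer). After each restart the register moves
   `(dl, dr) ∈ {−1,0,1}² ∪ {±2 diagonal}` — sliding the left and right
   motif edges in motif orientation for every sequence where legal — are
   tried and the best adopted when it lowers the objective.
3. **Polish** — exact coordinate descent: each sequence is moved to its
   objectively best placement (per-column entropy tables make this an
   O(candidates × width) gather) until no single move helps, so every
   reported alignment is a local minimum of the true objective.

Defaults are 5 independent restarts, each run until 15 sweeps pass
without improvement (capped at 150 sweeps). On the synthetic conditions
used throughout the tests this converges in tens of sweeps; the heavier
classical prescription of hundreds of restarts buys nothing detectable on
these problems, and the restart count is a parameter (`cycles`) wherever
the search is invoked. All randomness flows from a single integer seed
through `numpy.random.SeedSequence`, so results are bit-reproducible.

On tiny instances (4 sequences of length 10, motif width 3) the search
provably attains the global minimum found by exhaustive enumeration of
all joint placements (tested over several seeds).

## Recursive masking

After a motif is derived, every site it detects with `Ri > 0` (the
threshold for a potentially functional site) is converted to a mask
interval; rediscovery under the accumulated masks surfaces the
next-lowest-entropy motif — the route to cofactor motifs sharing the same
peaks. No candidate placement may overlap a mask, so no round-k site
overlaps an earlier round's mask (a tested invariant). A consequence
worth knowing: because an informative matrix still calls ~1–2% of random
windows at `Ri > 0`, masks accumulate beyond the true sites, and a second
motif that cross-matches the first in any register is systematically
erased. Motif pairs without cross-register similarity (as with real
TF/cofactor pairs from different families) are recovered cleanly; the
discovery *order* follows entropy, not biological primacy — a G-rich
low-complexity-adjacent motif can surface before a more informative but
more degenerate one, since background windows reinforce it.

## Peak-strength thresholding

Weak peaks contribute low-complexity sequence that can dominate the
objective, so the pipeline finds the largest top-rank prefix still
yielding the motif by half-interval search: `G` (greater bound) starts at
the signal of the 200th peak, `S` at the weakest; the midpoint prefix
(rounded half-up to a multiple of 500 peaks, clamped inside the bracket
to guarantee progress) is tested by deriving its model and comparing
distances to the fixed endpoint models; the bracket narrows until it
holds ≤ 500 peaks and the final `G` is returned. Endpoint models are
derived once with a per-prefix seed and reused as the bracket moves. If
the top-200 model already fails classification the search reports
`no-motif-in-top-200`; datasets under 200 peaks skip the search. The
method's resolution is the 500-peak step: the returned prefix can sit up
to one step beyond the true carrier boundary when the mildly diluted
midpoint model still resembles the motif end.

## Motif vs noise classification

A model is accepted as a true motif when (i) its overall conservation
`Rsequence/L` reaches 0.5 bits/nt and (ii) the regression of the
binding-energy proxy `E = −log2(signal)` on training-site Ri has negative
slope with regression F (1, n−2 df) above 1000. Condition (ii) is the
discriminating one: a poly-A run is highly conserved yet shows no
Ri–signal relationship and is rejected. The log-signal proxy is a
pluggable transform; it encodes only that occupancy rises with signal and
falls with binding energy. At the default threshold, statistical power
requires a few hundred peaks (at 150 peaks a genuine signal-coupled motif
can sit just below F = 1000). A reference-matrix classifier (accept iff
distance to a supplied matrix < 1 bit/nt) is provided for benchmarking
against a known ground truth.

## Validation statistics

- **Null Ri distribution** — every window (both strands, all spacers) of
  a 10 000-nt random sequence generated by a first-order Markov chain
  fitted to the dataset (conserving mono- and dinucleotide composition)
  is scored, sub-zero scores included; a Gaussian is fitted by moments
  and the upper tail at 0 is the expected false-positive site rate.
- **Positional mutual information** — pairwise MI between site positions,
  bias-corrected by subtracting the mean MI of 100 column-wise permuted
  alignments (independent shuffles destroy correlation, keep marginals),
  clipped at 0, summed, and expressed as a percentage of Rsequence. Under
  10% means an additive model loses little.
- **F-distribution comparison** — motif vs noise F samples are compared
  by two-sided Mann–Whitney U (exact for small tie-free samples).
- **Intersite distances** — per peak containing at least one surviving
  primary and cofactor site (after an Ri ≥ Rsequence filter, relaxed to
  0.5·Rsequence when too few cofactor sites survive), the minimum
  edge-to-edge separation; enrichment below 20 nt supports co-binding,
  overlapping sites counting as distance 0.

## Synthetic data

The generator emulates the structure the pipeline assumes, not read-level
ChIP-seq: background is order-0 (or Markov) sequence; primary sites are
sampled i.i.d. per column from a generating frequency matrix
(`matrix_with_information` solves the per-column conservation for a
target total information) and planted at uniform positions and strands;
cofactor sites land a fixed distance from the primary site; non-carrier
peaks optionally carry a low-complexity decoy run (the weak-peak noise
the thresholding step exists for); signals follow
`s0 · 2^(β·Ri) · lognormal(σ)` so Ri and signal are positively associated
when β > 0. Defaults — 500 peaks of 200 nt, 12-bit motif, 90% carriers,
β = 1, σ = 0.5 — reflect a mid-size experiment. For rank-confined
constructions the carrier flag can be forced onto the top ranks with an
exact count. What passing tests on these data do **not** show: robustness
to peak-length variation, positional bias of sites within peaks,
overlapping/multiple true sites per peak, or genomic repeat structure.

## Problem sizes

Test and acceptance runs use desk-scale conditions chosen once: the
threshold-search construction uses 4000 × 100-nt peaks (12-bit motif in
the top 2000, poly-A decoys below); bipartite spacer recovery uses
2000 × 200-nt peaks with palindromic 9-bit half sites and spacer mode
3 nt over 0–5; two-motif recovery uses 500 × 200-nt peaks (12-bit and
11-bit motifs); F-test calibration uses 20 simulated datasets of 300
peaks per class plus 200 signal permutations at n ≈ 300–500.

## Known limitations

- One site per sequence is enforced during alignment; peaks lacking the
  motif contribute a junk row that dilutes the matrix (visible as matrix
  distance growing with the non-carrier fraction). A zero-or-one
  occurrence mode would need an occupancy prior and is not implemented.
- Masking at `Ri > 0` is aggressive by construction; cofactors that
  cross-match the primary motif in any register cannot be recovered.
- The Gibbs proposal uses the predictive (pseudocounted product)
  distribution, not the exact entropy change; the polish step closes the
  gap at convergence but mid-run trajectories are approximate.
- The threshold search assumes the distance comparison cleanly separates
  motif-end from noise-end models; datasets where dilution is gradual
  resolve the boundary only to the 500-peak step.
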