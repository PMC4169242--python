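# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open `[start, end)`. BED is read
and written natively in this convention; GFF3 (1-based, closed) is converted
at the boundary (`start − 1, end`). Strand is carried on gene models and
used only for labelling upstream/downstream flanks — never by overlap
arithmetic, because peak–gene association on tiling arrays is
strand-agnostic. A peak set is sorted and internally disjoint by
construction; overlapping intervals in an input BED are merged on read with
a warning. The one deliberate exception is the random-placement null, whose
draws may mutually overlap (below).

## ChIP-chip signal model and processing

The signal representation is one log2 IP/input value per probe of a fixed
probe map (strictly increasing centers per chromosome, ~300 bp apart).
Processing order is: per-track median-centering, quantile normalization
between replicate arrays, replicate pooling by the per-probe median,
running-median smoothing, mock subtraction.

- *Median-centering* stands in for within-array loess normalization: loess
  operates on the raw two-channel intensities, which are outside this
  package's inputs; on a log-ratio track a location shift is the defensible
  reduction.
- *Quantile normalization* maps every track onto the per-rank mean of the
  input order statistics; ties take the value interpolated at their average
  rank, so within-track ordering is preserved exactly (Spearman ρ = 1 with
  the input, asserted in tests).
- *Running median* uses an odd window (default 3 probes; 5 recommended for
  the broader AOP binding), never crosses a chromosome boundary, shrinks at
  chromosome edges rather than padding, and takes the mean of the central
  pair for even counts. These edge conventions are this package's choice;
  they are stated because upstream descriptions leave them open.
- *Mock subtraction* is direct per-probe subtraction of the pooled mock
  track. Both tracks are smoothed before subtracting; a `subtract_first`
  switch flips the order for sensitivity analysis, since the processing
  narrative does not fully determine it.

## Peak calling

A probe qualifies when its processed value reaches the threshold
(y0 = 0.97 on the absolute log2 scale by default; a quantile mode
interprets the threshold as a genome-wide signal quantile instead, since
the absolute reading of y0 cannot be fully disambiguated — both are
shipped, absolute is the default). Successive qualifying probes on one
chromosome belong to one cluster while their center-to-center distance is
*strictly less than* the 600 bp cut-off. With exact 300 bp spacing this
means a single non-qualifying probe (gap 600) breaks the run — the behaviour
the worked examples pin down. Clusters of ≥ `min_probes` (default 3)
probes become peaks spanning `[first center, last center + 1)` — probe
centers, not probe extents, which are unknown on a custom array — scored by
the cluster's maximum probe value. Raising the threshold never increases
total peak basepairs; raising `min_probes` never increases the peak count
(monotonicity is tested, and the caller is checked probe-for-probe against
an independent pure-Python run enumerator).

## Association, classification and the random-placement null

A gene is associated with a peak when the gap between their half-open
intervals is ≤ 1 kb, where the gap of `[a,b)` and `[c,d)` with `b ≤ c` is
`c − b` (0 when they overlap). "Within 1 kb" is read inclusively
(gap ≤ 1000); the boundary inequality is a package choice.

Feature classification counts a peak toward every category it intersects by
≥ 1 bp — gene bodies, strand-aware 1 kb upstream flanks, strand-aware 1 kb
downstream flanks — and toward intergenic when it touches none. Categories
are deliberately non-exclusive because they are reported independently.

The null draws peak sets of identical per-chromosome count and length
multiset, with each start uniform on `[0, L − length]`. Draws may overlap
each other: the null preserves size, length and chromosomal distribution,
not disjointness (a rejection-sampling `disjoint` mode exists). Per
category, `z = (obs − μ₀)/σ₀` over `n_sim` draws (default 1000) and the
one-sided empirical p gets the +1 correction, flooring it at
`1/(n_sim + 1)` — at 1000 draws, exactly the `p < 10⁻³` style floor. A
constant null (σ₀ = 0) is flagged degenerate and its z reported as 0.

## Overlap significance

*Gene sets*: one-sided hypergeometric tail `P(X ≥ k)` via the scipy
log-gamma implementation, cross-checked in tests against exhaustive
enumeration and an independent factorial-based tail for all universes ≤ 20.

*Peak sets*: the observed statistic is marginal basepair overlap. The null
resamples the second set per chromosome: destination slots tile the
chromosome in `block_length` pieces (default 100 kb — much longer than any
peak, much shorter than a chromosome), each filled from a uniformly drawn
source block, transplanting and edge-clipping the intervals it carries,
then merging. This is the tiled-resampling variant of the block bootstrap,
a documented choice among the family's segmented/circular variants; it
preserves local peak structure and density while destroying the cross-set
positional relationship, and preserves the resampled set's total basepairs
per chromosome in expectation (tested to 2%). Reported: z-score, the
+1-corrected one-sided empirical p (floor `1/(n_iterations + 1)`), and a
normal-approximation p. The first argument stays fixed; the CLI reports
both orientations.

## Differential expression

Presence filtering keeps genes at or above an intensity floor (default: the
matrix-wide 25th percentile, a stand-in for array present/absent calls) in
at least `min_samples` samples. Each gene is fitted by OLS of log2
intensity on an induced indicator plus fixed-effect batch dummies; the
effect is the condition coefficient and p is the two-sided t-test with the
residual degrees of freedom. Genes with zero residual variance (up to
accumulated rounding) and a nonzero effect get the machine-minimum positive
p and a degenerate flag. Selection converts FDR level q into the cutoff
`p₍ₖ₎` with `k = max{i : p₍ᵢ₎ ≤ (i/m)q}`.

Empirical-Bayes variance moderation is deliberately **not** implemented.
This matters quantitatively: at 4 vs 4 samples with a batch covariate the
t-test has 5 residual degrees of freedom, and for a planted 2-fold change
(1.0 log2) with per-sample noise SD 0.25 the per-gene noncentrality is
1/(0.25·√½) ≈ 5.66. The self-consistent BH solution at q = 0.05 over 2000
genes with 100 planted effects then recovers ≈ 33% of them — whereas a
(near-)known-variance statistic such as the moderated t recovers ≈ 99.6%.
Power comparisons against moderated-statistic pipelines must therefore not
be read off this module; its guarantees are the ones its own tests state:
uniform null p-values, unbiased effects under batch structure, realized FDP
at or below the nominal level, and near-zero selections under label
permutation.

## Boolean network simulation

Synchronous updates; clamped nodes are pinned (modelling constitutive
over-expression) and override rules; free nodes — no rule, no clamp — hold
their initial value, which is what keeps dFOXO's uniform initialisation
meaningful when only PNT is clamped. The probability that the target
("lifespan") is active after `n_transitions` (default 1000) averages over
initial states drawn uniformly from `{0,1}`^(unclamped): exactly, by
enumeration (default, feasible to ~20 free nodes), or by seeded
Monte-Carlo. Since the dynamics are deterministic, trajectories are
resolved by cycle detection, so 1000 transitions cost no more than the
transient plus one attractor period (≤ 2^n states); the probability at 1000
steps provably equals the probability at any step past the transient, and
tests assert this. The two built-in wirings (linear cascade; feed-forward
with `lifespan' = dFOXO NAND PNT`) are expressed in a one-line-per-node
rule text (`node <- EXPR` with NOT/AND/OR/NAND) so alternative wirings can
be simulated without code changes; the linear model's exact wiring is a
reconstruction from the circuit diagram and is config-overridable. The
`synergy` flag per model is true iff P(both clamped) is strictly below the
minimum of the single-clamp probabilities.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their arguments including the seed, and
always return the planted truth. The ChIP generator places probes on a
deterministic grid (spacing/2 + k·spacing) with optional Gaussian jitter
(kept strictly monotone), plants non-overlapping enriched regions with a
minimum separation (default 2 kb, so the caller's gap rule cannot fuse two
distinct truths), and emits per-replicate tracks
`amplitude·1[in peak] + N(0, σ)` plus a mock carrying only noise and any
shared artifact regions; optional per-replicate scale factors exercise
quantile normalization, and artifact regions demonstrate that mock
subtraction removes shared nonspecific enrichment. The expression generator
adds a per-gene baseline, a planted log2 effect for DE genes under
induction, a shared Gaussian batch effect (batches balanced across
conditions), and i.i.d. Gaussian noise.

Not emulated: probe GC/affinity bias, fragment-size convolution of ChIP
signal (planted peaks have sharp edges), heteroscedastic or
intensity-dependent expression noise, and correlated genes. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the stated model, not robustness to those real-data artifacts.

Default simulation conditions mirror the study's design where stated —
~300 bp probe spacing, three ChIP replicates, a 3-probe (or 5-probe)
smoothing window, y0 = 0.97 with 600 bp cut-off, 1 kb association flank,
1000 random sets / 10000 bootstrap iterations, FDR 5%, 4–5 samples per
condition with dissection batches — and otherwise use values a tiling-array
practitioner would call realistic: 2-fold planted changes, per-sample noise
SD 0.25, probe noise SD 0.3 against amplitude 2.0, 1–3 kb peaks. Test and
demonstration genomes are scaled to a few megabases so the full suite runs
in minutes; every statistical check is sample-size aware (CLT/SE bands,
binomial margins), so the scale is a cost choice, not a tuning one.

## Orchestration and reproducibility

A single global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence(seed).spawn` in a fixed documented stage order,
so any stage can be rerun in isolation. Run manifests record the config
hash, seed, stage parameters and artifact hashes — and no timestamps — so
identical config + seed yields byte-identical artifacts (asserted by
hashing in tests). Config files round-trip losslessly to YAML; relative
paths resolve against the config file's directory.

## Known limitations

- The peak caller reports probe-center extents; studies reporting probe
  extents will differ by up to one probe spacing at each peak edge.
- The block bootstrap is one variant of a family; block length defaults to
  100 kb and results should be checked for sensitivity to it.
- Hypergeometric and BH machinery assume exchangeable gene universes; no
  GC/mappability-aware or gene-length-aware nulls are provided.
- The DE module's power differs from moderated-statistic pipelines as
  quantified above; its gene lists are not comparable to published counts
  derived with moderation.
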