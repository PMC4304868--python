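# Methods

## Scope and model

`copyvar` quantifies within-individual heterogeneity among the copies of a
high-copy locus from shotgun reads. The underlying model is simple: an
individual carries *N* nearly identical copies (for plant nrDNA, on the
order of 10² – 10³; the default generator uses 960); at a polymorphic
position a fraction *f* of copies carries an alternative base. Reads sample
copies approximately uniformly, so the minor-allele read fraction at a
position is binomially distributed around *f*, and thresholding the
differing-read fraction at 2% (polymorphic) and 10% (highly polymorphic)
separates genuine copy variation from sequencing error, provided the
per-base error rate is well below 2%. Both cutoffs are inclusive.

## Pipeline stages and their conventions

**Preprocessing.** Duplicate collapsing treats reads with identical base
strings (N compares as a literal) as one molecule and keeps the copy with
the highest mean raw Phred score, ties to the first occurrence. Mean
quality is the arithmetic mean of Phred values, not of error
probabilities. Filtering drops reads with mean Q strictly below 20 and
masks bases strictly below 20 to N; masked bases carry no call and are
excluded from both the numerator and denominator of every downstream
fraction.

**Mapping.** The mapper is an exhaustive ungapped scan of every offset on
both strands, retaining the unique fewest-mismatch placement when it meets
a per-length mismatch cap: reads under 50 bp get 2 mismatches, 50–89 bp get
3 (standard) or 4 (relaxed), 90 bp and longer get 4 or 5. The anchors (3/80,
4/100 standard; 4/80, 5/100 relaxed) reproduce the defaults of short-read
mappers in the BWA family for those lengths; the piecewise-constant
interpolation avoids reimplementing a Poisson error model. Reads tied
between distinct placements are discarded rather than placed at random —
deterministic, unlike BWA, and a deliberate divergence. The gapped mode
allows a single indel of 1–5 bp on either side, scored as mismatches plus
one gap-open equivalent, with an ungapped placement preferred on ties;
within one placement, ties between split points resolve to the leftmost
split, deletions before insertions. Alignments can be exported to and
imported from SAM (pysam), so an external mapper can substitute for the
built-in one.

**Consensus and coordinates.** The consensus is an iterative majority call
(ties A < C < G < T; at most 5 rounds; zero-coverage columns marked
unassembled). This replaces a reference-guided assembler: the artifact
needs the position association, not de novo assembly, and the majority call
cannot change sequence length — length differences are absorbed by the
subsequent global alignment of consensus to group reference (match +1,
mismatch −1, gap open −4, gap extend −1). The first optimal alignment is
taken, which fixes a deterministic tie-break. Identity below 70% over
aligned columns triggers a non-homologous-assembly warning; the threshold
is a package decision with no exact analog in assembler identity settings.
All coordinates are 1-based and inclusive, including the BED-like region
TSVs (deliberately not UCSC half-open; files say so in a header comment).

**Classification.** Per-position tallies pool *all* non-consensus bases
(tri-allelic sites sum), matching the definition "reads differing from the
consensus". The consensus call at a column is the plurality base of the
column itself; an exact 50/50 tie resolves lexicographically and yields a
differing fraction of 0.5 — highly polymorphic. `min_coverage` defaults to
0 (no floor), because the original counting scheme states none; it is
exposed because at coverage ≤ 50 a single error read crosses 2%. Insertions
relative to the group reference are discarded when projecting; reference
positions deleted in a consensus are unassembled (no read calls a base
there). Percentages are over sequenced (assembled) positions only. The
indel-polymorphism rule — reads supporting an identical indel (start,
length, kind, inserted bases) at ≥ 2% of reads covering the position — is a
package decision; the counting scheme for indels was never specified
precisely in the tradition this follows.

## Statistics

**Logistic model.** Two factors (subunit vs spacer; unpaired vs paired) and
their interaction on a per-position binary response, fitted by maximum
likelihood with treatment coding; the reference level is a paired spacer
position. Odds-ratio CIs are Wald, exp(β ± 1.96·SE) — symmetric on the log
scale. Complete separation raises with advice to use exact methods; an
empty cell warns.

**ANOVA.** Type III sums of squares on √counts, computed under sum-to-zero
contrasts via statsmodels — the convention of `car::Anova(type = 3)` for
unbalanced designs. Type III is contrast-dependent; with any other coding
the factor SS differ, which is why the contrasts are pinned. An empty cell
is an error (type III undefined). In a balanced design type III and type I
coincide, which the tests exploit as an oracle.

## Phylogenetic signal

**Squared-change parsimony.** States minimizing Σ (Δstate)²/w over edges
are the solution of a linear system in the graph Laplacian; the minimized
length is the Schur-complement quadratic form t′St in the tip values. The
default is unweighted (w = 1); weighted (w = branch length) is available
but requires strictly positive lengths and errors otherwise, advising
collapse. Unweighted is the default because empirical trees routinely carry
zero-length branches.

**Permutation test.** The observed SCP length is compared to lengths under
uniform permutations of tip values; because the length is a fixed quadratic
form, each permutation is an O(n²) product and 10,000 permutations are
cheap. The p-value is the strictly-smaller fraction (no +1 correction), with
a relative tolerance of 1e−9 so permutations that tie the observed length
exactly are not counted as shorter through floating-point noise. With
constant tip values every permutation ties and the statistic degenerates to
0 — reported as such, not as evidence of signal; the CLI prints "< 1/n_perm"
when the count is zero.

**Pagel's λ.** V(λ) multiplies off-diagonal phylogenetic covariances by λ,
diagonal untouched; on the tree this is internal branches × λ with terminal
branches extended to preserve root-to-tip depth. σ² and the root state are
profiled out analytically (GLS mean, ML variance), leaving a 1-D bounded
maximization of λ on [0, 1] (tolerance 1e−8, endpoints evaluated
explicitly). λ is capped at 1 because larger values can break positive
definiteness off ultrametric trees. The LRT statistic 2(ln L_λ̂ − ln L_0)
is referred to χ² with 1 df; recomputing p from the published *Asclepias*
log-likelihood pairs (−594.192/−597.863 and −587.547/−590.765) returns the
printed 0.0067 and 0.0112, confirming the convention.

**BM fit and simulation.** The ML (σ̂², root) has a closed form; the
multi-start optimizer (default 100 starts, 10,000 available via
`n_starts`) always includes the analytic solution as a start, so it can
only improve on it. Simulation draws branchwise normal increments and
reflects (not truncates) at the bounds, default (0, ∞) — reflection keeps
counts non-negative without biasing trajectories far from the bound; tip
variance matches σ²·depth when the root is far from zero (checked by Monte
Carlo). Per-clade extremeness compares the observed SCP state at each
resolved (bifurcating) internal node with its simulated SCP distribution,
counting simulations strictly beyond the observed value in the direction of
the observed deviation from the simulation mean (a two-sided option
exists); significance uses the Bonferroni critical count
⌊n_sims·α/n_clades⌋.

**Tip preparation.** Samples not in the tree are dropped; multiple samples
per tip are averaged arithmetically; sibling tips separated by zero
patristic distance are collapsed to one tip carrying the mean of all
contributing samples (the collapse handles zero-length sibling leaves,
which is the empirical case; longer all-zero chains are not searched).

## The synthetic generator

Defaults mirror the study conditions the package is designed around: 960
copies, 97× locus coverage, 80 bp single-end reads, constant Q40 qualities
(so quality filtering is a no-op unless the two-level Q40/Q10 model is
requested — isolating pipeline stages in tests), substitution-only errors
with uniform per-base rate, uniform read starts without wrap-around (edges
get ramp-down coverage, as in real data). Copy-level indels (≤ 5 bp) are
planted only on request. Exactly round(f·N) copies carry each planted
variant, so realized frequencies are within 1/N of specification. Trees
are random bifurcating topologies from sequential random joins with
Exponential(1) branch lengths; traits evolve by bounded BM on the
λ-transformed tree. Everything is bit-reproducible under a fixed seed.

What the generator does *not* emulate: quality-dependent and
position-dependent error profiles, GC or PCR bias, paralog families beyond
a single pool, pseudogene divergence, plastid contamination, and
homogenization dynamics. Passing tests therefore demonstrate correctness of
the counting, mapping and inference machinery under the stated sampling
model, not robustness to every artifact of real sequencing.

## Problem sizes in the test suite

Desk-scale runs use a 300 bp five-region locus (the classification
arithmetic is length-free), 100–200 copies, coverage 100–500. Recovery
suites use 100 replicates of 200-tip trees for λ and σ², 500 replicates at
n_perm = 400 for permutation-p calibration, and 100 seeds for the
end-to-end planted-variant check (0.30-frequency variant, 0.1% error, 100×
coverage). These sizes were chosen to give stable averages while keeping
the default `pytest` run around a minute.

## Known limitations

* The mapper is exhaustive and O(reads × locus length); it is meant for a
  single locus of kilobase scale, not genomes. SAM import exists precisely
  so a production mapper can be used instead.
* The ambiguous-read discard policy slightly depresses coverage in exact
  repeats relative to random-placement mappers.
* The iterative majority consensus cannot recover length variants of the
  individual relative to the template; such variants surface only via the
  consensus↔reference alignment or the gapped mapper's indel counter.
* Only one indel per read is modelled in gapped mapping.
* Permutation p-values are reported without the +1 small-sample correction;
  at n_perm = 10,000 the difference is ≤ 1e−4.
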