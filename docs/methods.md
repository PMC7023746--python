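# Methods

## Model

The mutational profile of an experimental subclone is modelled as a
linear combination of two multinomial sources over a fixed channel
scheme: the background (intrinsic + culture) mutagenesis of the cell
model, and the signature generated by the perturbation under study.
Control subclones realise the background alone; their averaged
normalized profile **q** and averaged burden *B* define the background
model. For an experimental condition with subclone profiles
**p**₁…**p**ₖ and burdens *N*₁…*N*ₖ, the centroid expected counts are

    c = N̄ · mean_i(p_i)

and the experiment-associated signature is the normalized, non-negative
residual of `c − α·B·q`, with the background scale α ≤ 1 described
below. Averaging *normalized* profiles (rather than pooling counts)
weights subclones equally regardless of burden, treating them as
technical replicates of one founding event.

Assumptions worth stating: mutations are independent draws from a fixed
channel distribution (no clustering along the genome beyond context);
background and treatment processes are additive; control and
experimental subclones share the same background process; every
post-bottleneck mutation is clonal in its subclone.

## Quality control

**Clonality.** A clonal mutation present on *m* of *p* allele copies is
expected at VAF *m*/*p* (0.5 for heterozygous diploid, 1.0 haploid,
1/3 for single-copy triploid); read sampling spreads observed VAFs
binomially around that value. A subclone is flagged
`polyclonal_suspect` only when a one-sided one-sample t-test of mean
VAF below expectation rejects at α = 0.001 **and** the observed mean is
below 0.8× the expectation. The effect-size floor prevents very deep
sequencing from flagging biologically trivial deviations; the stringent
α keeps the false-flag rate per subclone negligible across a whole
experiment. At least 20 usable VAFs are required; fewer is reported as
inconclusive, not as a verdict. In the whole-experiment screen,
clonality is assessed on each subclone's *private* mutations (those not
in its declared parent): inherited mutations are clonal in every cell
even of a polyclonal subclone and would dilute the VAF shift.

**Relatedness.** All samples are compared by shared variant keys
(chrom, pos, ref, alt). Per declared family, three scenarios are
distinguished: `consistent` (every subclone contains ≥ θ_p = 0.90 of
its parent's mutations and has ≥ 1 private mutation), `wrong_parent`
(siblings form a single sharing group but none contains the sequenced
parent), and `mixed_parental` (siblings split into ≥ 2 groups under
single-linkage clustering at cut θ_s = 0.50). Sibling grouping uses
pairwise shared counts normalized by the family's **largest** pairwise
shared count. This relative metric was chosen over shared/min(burden)
deliberately: condition-private mutations (e.g. a strong treatment)
inflate subclone burdens and would push genuinely related treated
siblings below any absolute sharing fraction, whereas the relative
pattern — full parental sharing within a lineage, none across —
survives arbitrary private burden. The absolute fraction is still
reported per pair as a diagnostic. Both thresholds are configurable;
they are separation heuristics, not doctrine. Copy-number stability and
driver screening are outside this package's scope and are recorded as
"not assessed" in QC reports.

## Burden test

The expected background burden distribution is built by bootstrap
resampling of the control burdens (n_boot resamples with replacement,
resample size = number of controls); its quantiles are reported as the
null reference. The p-value for burden excess is a label-permutation
test on the difference of group means (one-sided for excess by default,
+1-corrected so p ≥ 1/(n_boot+1)). A permutation p-value was chosen
over comparing the observed mean to the bootstrap distribution because
the latter ignores the sampling variability of the experimental mean
and is markedly anti-conservative at realistic subclone counts
(simulations here measured ~9–19% type-I error at a nominal 1% for
3–8 subclones per arm); the permutation version is calibrated (~1.1%
at 6 vs 6 over 1000 null replicates). Note that the permutation
p-value is discrete: with *n_c* + *n_e* subclones its attainable
minimum is about (1 + n_boot/C(n_c+n_e, n_e))/(n_boot+1), so designs
smaller than ~5 vs 5 cannot reach p ≤ 0.01 at all — a real design
constraint, not an implementation artifact. When several conditions are
tested against one control set, Benjamini–Hochberg adjusted p-values
are reported alongside the raw ones.

## Signal-to-noise ratio

With per-channel means μ and standard deviations σ of the normalized
profiles in each group,

    SNR = ‖μ_Exp − μ_Control‖₂ / sqrt(‖σ_Control‖₂² + ‖σ_Exp‖₂²).

The numerator is the Euclidean separation of the group spectra; the
denominator combines the two within-group spreads across channels in
quadrature, treating them as independent noise sources. This
denominator is one reasonable aggregation of per-group, per-channel
spreads into a scalar — nothing canonical forces quadrature — and is
therefore this package's stated convention. SD is population (divide
by n) by default, reading σ as a descriptive spread over the observed
subclones; `ddof=1` switches to the sample SD. 0/0 is defined as 0 and
a positive signal over exactly zero noise is flagged infinite rather
than raised.

## Background subtraction

Each experimental subclone's counts are bootstrapped (multinomial
redraws of its own N mutations at its observed profile); per replicate,
profiles are averaged across subclones and rescaled to the mean burden,
giving a 99% percentile confidence interval for each channel of the
centroid counts. The background is bootstrapped likewise (multinomial
at its averaged burden and profile). The per-channel tolerance for
negative residuals is

    w_c = sqrt(w_exp,c² + w_bg,c²)

where each w is the distance from the bootstrap mean to the lower CI
bound. Combining both sources matters: channels with few or no observed
experimental counts have w_exp ≈ 0, and without the background term any
background mass there would force a drastic (and spurious) background
reduction. The background half-width is computed at full background and
not rescaled with α, which keeps the admissibility condition linear in
α and is conservative for α < 1.

"Reduce the background burden" is operationalised in closed form: the
largest α ≤ 1 with every residual ≥ −w_c is

    α* = min(1, min over channels with q_c > 0 of (c_c + w_c)/(B·q_c)).

Residuals at α* that remain negative are set to zero (each such
shortfall is within its channel's tolerance by construction) and
recorded. The normalized clamped residuals are the signature; their sum
is the burden attributed to the perturbation. α* at (or numerically
indistinguishable from) zero raises a degenerate-subtraction error: the
signal cannot be separated from background. Averaging replicates across
subclones *before* taking percentiles (per-replicate centroids) was
chosen over per-subclone percentiles because the subtraction operates
on the centroid; the alternative is available via the per-subclone
bootstrap primitive.

Because only negative residuals are clamped, attributed burden carries
a small positive bias of roughly half the summed per-channel noise
magnitude; in null simulations (experimental = background, burden 300,
4 subclones) this amounts to ~15–20% of the background burden, against
<4% relative error when a planted signature ≥ 2× background is present.

Stability of an extracted signature is the minimum pairwise cosine
similarity among per-subclone extractions; > 0.9 is called stable.
Cosine similarity is most informative for peaked signatures and is not
linear — 0.8 is not "almost 0.9" — which is why the full pairwise
matrix is returned, not only the summary.

## Synthetic data generator

The generator emulates exactly the structure the framework assumes:
a uniform-ACGT random reference (default 100 kb) indexed by
trinucleotide context so sampled substitutions can be placed at
context-matching loci (classification of generated data round-trips
exactly); parental clones with `parental_burden` background mutations
inherited by all their subclones; `private_burden` post-bottleneck
mutations per subclone (the interface for "number of doublings", which
is not modelled mechanistically); experimental subclones adding
`treatment_burden` draws from a treatment signature; VAFs as
Binomial(depth, cell_fraction·copies/ploidy)/depth. Defaults — 2
parents × 6 subclones, 100 parental + 60 private background mutations,
treatment 300, diploid, depth 30 — depict a realistic six-subclone
design with a clearly detectable treatment. Planted QC defects: a
sequenced unrelated clone declared as parent; siblings drawn from two
parents in the fixed pattern {1,4,6} vs {2,3,5}; a subclone with half
its private mutations at half cell fraction. Mutated loci are unique
per lineage (experimental burdens ≪ genome size; collisions are
re-drawn).

What the generator does **not** emulate: sequencing/alignment artifacts,
variant-calling error, copy-number change, mutation clustering
(kataegis-like), purity/contamination beyond the two-population
polyclonal model, and non-uniform genome composition. Passing tests
demonstrate correctness of the statistical machinery under the model's
own assumptions, not robustness to upstream calling error on real data.

Test and calibration problem sizes were chosen to make the suite
self-contained and quick: null calibration at 1000 replicates of 6 vs 6
subclones with n_boot = 2000; signature recovery over 20 seeds of 4 + 4
subclones (background 200, planted 600); QC scenario detection over
100 seeds × 4 scenarios; conservation round-trips up to 10⁴ mutations
on a 200 kb reference.

## Numerical and interface choices

- VCF positions are 1-based; all internal context lookups convert
  through a single audited function to 0-based half-open intervals.
- Doublets may arrive as one MNV row or as adjacent SNV rows; adjacent
  same-sample SNVs are merged into a doublet at read time (logged).
  Phase is not inspected; on dense catalogs a coincidental adjacency
  can merge two independent substitutions.
- Ambiguous reference context (N) makes a record unclassifiable — it is
  reported and excluded from the catalog, never silently dropped and
  never fatal.
- DBS canonicalization: of the two strand readings, the
  lexicographically smaller ref dinucleotide wins, ties broken by the
  smaller alt. Any fixed total order yields the same 78-label space.
  In the flank-extended space the doublet core is canonicalized the
  same way; for the 12 doublet pairs that read identically on both
  strands the flank orientation is kept as given, making the label
  space the full 4 × 78 × 4 = 1248 product.
- Indel channels default to {ins, del} × {1bp C/G, 1bp T/A, longer} ×
  {rep_2…rep_5+, mh (deletions ≥ 2 bp only), none}, with the repeat
  count including the event copy and capped at 5+. The granularity is
  deliberately coarse for experimental mutation yields and is
  configurable in spirit: the classifier exposes the raw ingredients.
- Rearrangements: five log-spaced size bins (<10 kb, 10–100 kb,
  100 kb–1 Mb, 1–10 Mb, >10 Mb) for tandem duplications, deletions and
  inversions, one sizeless translocation channel — 16 labels.
- All stochastic operations take an explicit seed and are reproducible
  bit-for-bit given (seed, n_boot); run records written next to CLI
  outputs capture both.

## Known limitations

- One signature per condition: the package extracts the aggregate
  experiment-associated signature and deliberately does no de novo
  multi-signature decomposition (NMF) or fitting of a-priori cancer
  signatures, which can attribute processes that are not present;
  external signatures can only be *collapsed* onto experimental
  channels for comparison.
- The burden test needs enough subclones for permutation resolution
  (see above); two or three controls give a valid but low-powered test.
- Subtraction assumes the control-derived background transfers
  unchanged to the experimental arm; a perturbation that modulates the
  background process itself (rather than adding to it) violates the
  linear model.
- The clonality test examines the mean VAF only; subtler multimodal
  VAF structure at the expected mean would pass.
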