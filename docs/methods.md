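# Methods

This note documents the models, estimators and design choices behind
`cageprom`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Promoter definition

The raw observation is a tag landscape: per-base, per-strand, per-sample
counts of CAGE tag 5′ ends (0-based coordinates; a CTSS position is the
5′-most base of the tag on its own strand). Promoters are defined in
three steps:

1. **Local maxima.** A site is an anchor candidate when its pooled count
   is strictly greater than every non-tied site within ±d on the same
   strand (d = 50 by default; 20, 100 and 200 are supported). Among sites
   tied for the maximum within ±d of each other, only the 5′-most
   (strand-aware) is kept — the strict-inequality reading plus a
   deterministic tie rule.
2. **Annotation filter.** Anchors farther than d from a same-strand
   annotated TSS (BED; start for +, end−1 for −) are discarded, because
   annotated starts are often slightly upstream of the main CAGE peak.
3. **Fixed-window collection.** Each tag within ±d of at least one anchor
   is assigned to exactly one promoter: the nearest anchor, with
   equidistant ties going to the anchor 5′ of the site. Unique assignment
   prevents double counting when two surviving anchors are 51..2d bases
   apart — a situation the fixed-window definition does not otherwise
   resolve; nearest-anchor is our choice and is the main place a
   different convention could change promoter tag counts slightly.

TSS spread is the IQR and population SD of the multiset of tag start
coordinates. Quantiles use linear interpolation on the expanded multiset
(the "type 7" rule). The choice matters: the narrow/wide class boundary
at IQR = 7 is sensitive to the quantile convention, which is why the rule
is fixed and documented here.

`distance_cluster` (single-linkage clustering of tag sites with spacing
≤ gap) is deliberately retained as the naive baseline: sampling one fixed
initiation profile at 10² versus 10⁴ tags multiplies its mean cluster
width while leaving the fixed-window IQR statistically unchanged — the
depth artifact the fixed-window definition exists to avoid.

## Expression and specificity

Expression is tags per million, e_gt = 10⁶·x_gt/N_t. Entropy is computed
on tpm-normalized shares so that unequal library sizes matter. The
pseudocount variant adds one tag to every promoter–sample cell, hence
e′_gt = (x_gt+1)/(N_t+N_g) with N_g the number of promoters; the original
formula behind this estimator is not available verbatim, so this
reconstruction (the unique simple form in which the per-sample
denominator absorbs one pseudotag per promoter) is used and flagged as a
reconstruction. Max/median returns a flagged infinity when the median
tpm is zero — necessarily the case when the tag count is below about half
the number of samples — and infinities are ranked above all finite values
in the rank statistics rather than dropped, which would bias against
specific promoters.

All three plug-in measures are depth-biased, and the bias experiment
quantifies this: promoters with ≥ 10⁵ tags are resampled (with
replacement) at 10⁴, 10³ and 10² tags; median entropy and pseudocount
entropy fall, and median max/median rises, as the sample shrinks, even
though the underlying expression pattern is fixed. The package therefore
measures breadth as `entropy_100`: the entropy of a multinomial sample of
exactly n = 100 tags (with replacement by default; a without-replacement
switch exists). Promoters with fewer than 100 tags get a missing value —
they cannot supply a comparable fixed-depth sample. Richness
R_n = Σ_t [1 − (1−p_t)ⁿ] is the closed-form companion measure.

The uniform-breadth calibration (`simulate_uniform_breadth`) rebuilds the
count matrix with each promoter uniformly expressed in a random fraction
f of samples, assigning its (exactly preserved) tag total to active
samples with probability proportional to N_t restricted to the active
set. Restricting and renormalizing is our resolution of an ambiguity —
without the restriction f would not control breadth.

## Sequence features

All features use the length-201 window centered on the anchor, on the
coding strand (reverse-complemented for − promoters); non-ACGT bases are
N and excluded from every composition denominator. CpG observed/expected
divides the overlapping count of CG dinucleotides by (L−1)(gc/2)² — the
"expected from %G+C" form — with the C×G product form available as an
option. The TATA scanner scores s_k(x) = log₂[(c_kx+1)/(Σ_y c_ky+4)] −
log₂(b_x) at every offset and reports the best match no matter how weak;
b is uniform (1/4) or the window's own base frequencies with one
pseudocount per base. Log base and pseudocount only rescale scores, and
every downstream statistic is rank-based, so these choices cannot affect
conclusions. N positions score the column minimum, a conservative choice
that prevents N runs from creating spurious best matches. The scan
window defaults to the same 201-base window as the composition features
and is configurable. The bundled position count matrix
(`make_tata_pcm`) is a constructed TBP-like matrix with the canonical
TATAWAWR core — a synthetic stand-in, not a database matrix.

Upstream conservation is the mean per-base identity over the 100 bases
immediately 5′ of the anchor (anchor base excluded, strand-aware), with
unaligned bases counted in the denominator, so wholly unaligned promoters
score 0%. Identity can come from a BED score track or from axt-style
alignment blocks.

## Correlation network

Associations use tie-corrected Kendall tau-b with asymptotic two-sided
p-values, pairwise-complete observations, and Bonferroni adjustment over
the 36 property pairs by default. First-order partial correlations use
T_xy·z = (T_xy − T_xz·T_yz)/√((1−T_xz²)(1−T_yz²)) with a normal
approximation on the reduced-n Kendall variance for p-values.

`reduce_to_direct` formalizes "discard associations explainable by
stronger ones". The default `triangle` rule marks an edge (x, y)
indirect when some third property z has significant associations with
both x and y that are strictly stronger than |T_xy| — the literal
"potentially explained" reading, which prunes shortcut edges across
longer causal chains as well. Two variants are provided:
`triangle_direct` additionally requires the covering pair to have been
decided direct (edges are decided in decreasing |tau|, so each cover is
decided before anything it covers and a single pass is a fixed point);
and `strongest_path`, which compares |T_xy| against the best bottleneck
|tau| over all other paths between x and y. No rule can mark the
globally strongest edge indirect. The `triangle` default is the most
aggressive and matches the intent of keeping only associations that no
pair of stronger associations could produce; the conservative variant is
preferable when measurement noise on the intermediate property is large,
because an imperfectly measured mediator leaves real partial correlation
behind.

The mosaic summary counts promoters in the four combinations of
narrow/wide spread (IQR threshold 7, the valley of the bimodal IQR
distribution) and low/high CpG (O/E threshold 0.5, which the generator
places in the valley of its bimodal CpG distribution; real cohorts should
set it from their own histogram).

## The synthetic cohort generator

The generator is the package's test bed: it produces CTSS files, a
genome, TSS annotations, an identity track and metadata with known
per-promoter truth. It emulates a deep multi-sample CAGE atlas at desk
scale; defaults are 120 samples and 2000 promoters.

Study conditions (defaults, with units):

- library sizes N_t: lognormal, median 10⁶ mapped tags, σ = 0.8 (about an
  order-of-magnitude spread, as in real atlases), floor 10⁴;
- germ-cell samples: 10% of the cohort (≥ 2);
- breadth fraction f ~ Uniform(0.1, 1); maximum level M: lognormal,
  median 250 ppm, σ = 1 — drawn independently of f. The 250 ppm median
  puts per-promoter tag totals at order 10⁴, typical of deeply sampled
  annotated promoters; at much lower totals the count matrix itself
  becomes a depth-limited sample and the fixed-depth entropy inherits a
  small residual depth bias;
- expression: the promoter's top active sample sits exactly at M, every
  other active sample at 0.7·M·exp(σz − max σz) with σ = 0.5. Pinning
  the maximum is deliberate: with i.i.d. multiplicative noise the
  expected maximum over k active samples grows with k, so breadth would
  leak into measured maximum expression; the pinned model expresses the
  hypothesis that a promoter's maximum output is near-fully achieved in
  however many cell types it is on in. Tag totals are Poisson around
  ppm·N_t/10⁶ and tag positions are multinomial draws from the
  initiation profile;
- initiation profiles: narrow = two-sided geometric decay (0.55 per
  base) around the anchor, IQR ≈ 2; broad = flat plateau of width 41
  with fast geometric shoulders, IQR ≈ 20 — matching the two observed
  TSS-spread classes;
- germ-line activity g is a noisy companion of f (sd 0.45); the CpG
  latent is log germ-line expression (activity × level) plus noise, so
  CpG content is caused by germ-line activity; %G+C follows the CpG
  latent with extra noise; TATA presence is planted preferentially in
  GC-poor windows at the canonical −31 position; narrow shape is made
  more likely by a TATA box and by high M; upstream identity increases
  with M. Window sequences come from a first-order Markov sampler whose
  CG-transition probability is tuned to the target CpG O/E, giving
  bimodal CpG (valley at 0.5) and realistic GC ranges (35–63%).

`PLANTED_DIRECT_EDGES` declares the nine directly coupled property pairs
this structural model implies, with signs; every other significant
association in a generated cohort is an indirect consequence. The
couplings were calibrated once, while designing the generator, so that
each declared direct edge is the strongest association between its
endpoints — the property the reduction rule needs to be able to recover
the truth. One deliberate divergence from the motivating real-data
analysis: here expression breadth connects to the expression block
through *average* expression (breadth raises expression in every sample
class equally, so its association with the germ-cell average is mediated
by the overall average), whereas germ-line causality is planted on CpG.

What the generator does **not** emulate: CAGE's first-base G bias,
multimapping, promoter-dense regions with overlapping windows, ontology
graphs (replicates are exact term-set duplicates), uncalibrated
cell-type redundancy (all samples count equally), and real chromosomal
sequence context. Tests passing on this cohort therefore validate the
estimators and the inference logic under a known truth; they do not
certify the biological conclusions on any real atlas.

## Numerical and degenerate-input conventions

- All-zero promoters: entropy, max/median, richness and spread raise
  errors rather than returning sentinel values; eligibility filters
  (≥ 100 tags for entropy_100) produce missing values, never zero fills.
- Quantiles: type-7 on weighted multisets, computed without expansion.
- Randomness: every stochastic operation takes a seed or Generator; the
  generator derives independent substreams from one master seed, so
  cohorts are byte-reproducible.
- Problem sizes used in the shipped analyses: 2000 promoters × 120
  samples for planted-network recovery (10 seeds), 200 promoters with
  1.5×10⁵ tags each for the depth-bias experiment (3 seeds), 100
  replicates per depth for the clustering artifact. These sizes give
  stable rank statistics (tau standard error ≈ 0.015 at n = 2000) while
  keeping any single analysis under a few seconds.

## Known limitations

- The pseudocount-entropy formula is a reconstruction (see above).
- The triangle reduction is a heuristic, not causal discovery; with an
  imperfectly measured mediator it can discard a genuinely direct weak
  association (or keep an indirect one), which is exactly why partial
  correlations are also reported.
- Per-promoter spread in the fast synthetic path is measured on a capped
  sample of 1000 profile draws; IQR/SD stabilize well before that, but
  extreme-tail SD is slightly underestimated for very deep promoters.
- `find_local_maxima` applies the tie rule pairwise; in pathological
  chains of equal counts spaced just under d apart, no site may survive
  within a run of ties whose 5′-most member is itself suppressed by a
  louder neighbor. Real landscapes with continuous counts are unaffected.
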