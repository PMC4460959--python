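# Methods

`enhancerlink` infers cancer-altered distal enhancers, their target
genes, and candidate upstream transcription factors (TFs) from two
matrices measured on the same samples: CpG methylation beta values
(probes × samples, as produced by methylation arrays) and normalized
gene-level expression (genes × samples, RSEM-like). This note records
the model, the parameter choices, and the numerical conventions.

## Probe universe

A probe is **distal** when its CpG lies strictly more than
`tss_min_dist` (default 2,000 bp) from every annotated TSS; the strict
inequality is a deliberate resolution of the 1-bp ambiguity between
"greater than 2 kb" and "less than 2 kb filtered out", and the flag is
configurable. Distance is unstranded absolute bp. Distal probes that
fall inside a merged enhancer annotation (chromatin-state segments
labeled EnhG1/EnhG2/EnhA1/EnhA2, plus eRNA regions) are **enhancer
probes**; the remaining distal probes form the permutation pool used
for empirical p-values. Probes are single 1-based coordinates;
interval files are BED (0-based half-open); conversion happens only
inside overlap tests. Region merging unions overlapping *and touching*
intervals.

## Differential methylation

Tumor-only subtypes motivate an extreme-quantile design: for each
enhancer probe the `extreme_fraction` (default 0.2) least methylated
tumors are compared with the least methylated normals (hypo; hyper
mirrors with the most methylated and the opposite tail) by an unpaired
one-tailed t-test. Group size is `max(1, floor(fraction * n))` with
ties in beta broken by sample id, so the selection is deterministic.
Welch (unequal-variance) t is the default because group sizes and
variances differ systematically between small normal sets and large
tumor sets; `pooled_var` restores the pooled-variance form. Two
identical constant groups give p = 0.5 by convention. Raw p-values are
Benjamini–Hochberg adjusted per cohort and per direction across
exactly the probes tested; calls require `p_adj < 0.01` and an
absolute extreme-group mean difference `|Δ| > 0.3` with the
direction-consistent sign. Missing betas are dropped per probe before
quantile selection.

## Probe–gene linking

Candidates are the 10 nearest TSSs on each side of the probe (ranks
1..20 by absolute distance, ties by gene id). Before testing, a probe
must pass a variability filter: for hypo, ≥5% of all samples (tumor +
normal combined) with beta > 0.3 — there must be methylation to lose;
the hyper rule is mirrored (≥5% below 0.3), since the filter's purpose
is directional headroom and the threshold is stated only once, in the
hypo context.

For each candidate pair, samples split into the M group (highest-beta
`extreme_fraction`) and U group (lowest); a one-sided Mann–Whitney U
test asks whether expression in M is lower than in U. Exact
enumeration is used when the combined group size is ≤ 12 and tie-free;
otherwise the normal approximation with midranks, tie correction, and
continuity correction. Rank-based testing makes the result invariant
to any monotone transform of expression, so matrices are stored
untransformed and log2(x+1) is a display-only choice.

The raw p is calibrated against a permutation null: the gene is held
constant and the probe replaced by random **distal non-enhancer**
probes (enhancer probes would import co-regulated structure), sampled
without replacement when the pool allows (with replacement, logged,
otherwise). With `nperm` permutation p-values P_p,

    p_e = (num(P_p <= P_r) + 1) / (nperm + 1)

— a pseudo-count of one, so the attainable floor is `1/(nperm+1)`.
Pairs with `p_e < 0.001` are reported. Permutation scope is per pair
by default (`perm_scope="pair"`); `"probe"` shares one drawn set
across the 20 genes of a probe. Permutation p-values are computed by a
vectorized implementation of the same tie-corrected normal
approximation (cross-checked against the scalar path in the tests).
Note the scaling constraint: `pe_max` must exceed the floor, so runs
with `nperm` scaled below ~1,000 must scale `pe_max` with it.

Called probes within `cluster_gap` (default 500 bp) of each other are
chained (single linkage) into enhancer regions. Characterization
follows the same randomization logic throughout: distance histograms
(50 kb and 200 kb bin schemes, final open bin, proportions summing
to 1) against 1,000 datasets of 1,000 random distal probes each paired
with one random candidate; the nearest-gene rank profile after
omitting probes linked to multiple genes and genes linked by multiple
probes; and loop-anchor overlap against 100 random pair sets that
preserve the per-probe link counts, with intervals reported as
mean ± 1.96·SD.

## Motif scanning and enrichment

Windows of ±100 bp around each enhancer probe are scanned on both
strands with position weight matrices. Scoring follows the standard
log-odds convention: probabilities are smoothed with a
background-proportional pseudocount, `p' = (p·nsites + 0.1·bg) /
(nsites + 0.1)` (nsites defaults to 20 when the motif file omits it),
and scored as log2(p'/bg) against a 0-order background (uniform by
default, configurable). The match p-value — the probability that an
i.i.d. background sequence scores at least as high — is computed
exactly by dynamic programming over scores quantized to 1/1000 of the
score range; positions containing N are unscorable and skipped.
Positions with p < 1e-4 count as occurrences.

Enrichment of the paired-probe set against the full enhancer-probe
background binarizes per probe (a probe counts once per motif no
matter how many occurrences):

    p = a/(a+b)   P = c/(c+d)
    OR = (p/(1-p)) / (P/(1-P))
    SD = sqrt(1/a + 1/b + 1/c + 1/d)
    lower CI = exp(ln(OR) - z·SD)

A motif is enriched when the lower CI exceeds 1.1 and a ≥ 10. The
default `z = 1.96` is the standard Wald 95% lower bound; `z = 1.0`
reproduces the alternative one-SD convention. Any zero cell renders
the motif unevaluable (reported, not flagged).

## Upstream TF ranking

For each enriched motif, the per-sample mean beta over the paired
probes carrying the motif (missing-aware mean) summarizes that
motif's enhancer activity. Samples split into the 20% most/least
methylated at this profile; every TF in a user-supplied census (the
reference census has 1,777 human TFs; a placeholder list ships with
the synthetic bundle) is tested for lower expression in the
methylated group, one-sided Mann–Whitney. TFs are ranked by
−log10(p), ties broken by gene id; the top set holds
`ceil(0.05 · n_tested)` TFs — ceiling for inclusivity, and the
denominator is the number of TFs actually measured in the expression
matrix (missing TFs are logged and skipped). The best-ranked member
of the motif's cognate binding family is flagged as the putative
driver iff it lands in the top set.

## Synthetic cohorts

The generator emulates the features the inference relies on, with
defaults fixed as the study conditions: 100 tumors, 20 normals, a
planted molecular subtype covering 40% of tumors, 2,000 probes (500
enhancer, 1,500 distal non-enhancer — a pool large enough for 1,000
permutations without replacement), 50 driver probes.

* **Methylation**: per-probe mean from Uniform(0.1, 0.9); samples drawn
  from mean-parameterized Beta distributions (concentration 50), which
  respects [0, 1] without clipping artifacts. Driver probes have mean
  0.8 in normals and non-subtype tumors, shifted down by 0.45 in
  subtype tumors.
* **Geometry**: probes every 6 kb on chromosomes of 1,000 probes; one
  gene TSS per inter-probe gap at +2.6 kb from its probe, so every
  probe is distal (min distance 2.6 kb) and candidate ranks are
  unique. The planted target sits at candidate rank 3 — deliberately
  not the nearest gene, mirroring the observation that the correlated
  gene is usually not the closest TSS. Driver probes are spaced 40
  probe slots (~240 kb) apart so one driver's target never enters
  another driver's 20-gene window; otherwise the shared subtype
  structure would create correct-but-unplanted links and ill-defined
  truth. TF genes live on a probe-free contig so they can never be
  linking candidates.
* **Expression**: target genes follow `baseline + 20·(1 − beta) +
  N(0, 2)`; decoys are baseline + noise. The driver TF follows
  `10 + 20·(1 − mean driver-probe beta) + N(0, 2)` among 200
  independent decoy TFs; effect sizes give group-separation
  signal-to-noise ratios of roughly 2 and above.
* **Motifs**: a 10-bp consensus (embedded at rate 0.9 in driver
  windows, 0.05 elsewhere, random strand and offset) plus two decoy
  motifs never embedded. Probe spacing far exceeds twice the scan
  window, so windows never overlap.

The generator does **not** model: co-methylation/LD structure between
probes, tumor purity or copy-number confounding, batch effects,
missing values, or realistic expression dispersion. Passing tests
therefore demonstrate correctness of the statistical machinery under
its stated assumptions, not robustness to those real-data
complications.

Null cohorts zero every planted effect (shift, link slope, TF slope,
and the motif embed rate drops to background), leaving the truth
tables empty.

## Problem sizes and numerical choices

The test suite and the acceptance script run the linking stage at
1,000 permutations (down from the 10,000 default) and the type-I
checks at 500; these keep single-CPU runtime in minutes while leaving
the empirical-p floor below the thresholds used with them. Type-I
tracking is checked at α = 0.01 with ±50% Monte-Carlo tolerance. All
randomness flows through explicitly seeded NumPy generators; output
tables carry the seed and a configuration hash, and identical inputs +
config reproduce byte-identical outputs.

Degenerate inputs are handled as follows: all-missing beta vectors are
an error; probes whose extreme groups are too small are skipped with a
logged reason; constant-and-equal t-test groups give p = 0.5;
fully-tied U tests give p = 1; zero-cell enrichment tables are
unevaluable; an empty loop set reports enrichment as not applicable.

## Known limitations

Linking is correlative and cis-only (same chromosome, 20 nearest
genes); trans effects and indirect co-regulation can masquerade as
links. The t-test operates on bounded beta values, a pragmatic
convention inherited from array practice rather than a distributional
claim. Motif scanning uses a 0-order background and procedure-level
equivalence with FIMO is intended, not hit-set identity. TF ranking is
expression-based and will miss post-transcriptionally regulated
factors.
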