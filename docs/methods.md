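# Methods

## The model

RRMP is modeled at the level of idealized sequence consequences. A library
molecule is one strand of one genomic fragment; wet-lab steps (adapters,
conversion chemistry, PCR, pooling) appear only through their effect on the
molecule's sequence. The chain is:

1. **Fragmentation.** cfDNA mode draws lengths from a normal distribution
   with mode 170 bp (sd 15), the mononucleosomal peak of plasma DNA; gDNA
   mode emulates mechanical shearing (mean 250, sd 80). Start positions are
   uniform; origin strand is Bernoulli(0.5). Lengths are clipped at 20 bp
   and resampled if no chromosome can hold them.
2. **Conversion.** For a Crick-origin molecule the reverse complement of
   the insert is taken first; then every cytosine of the molecule's own
   strand converts to T unless it is the cytosine of a CpG unit whose
   per-molecule state — a single Bernoulli(β) draw per unit — is methylated
   and protected. CpG context is decided from the reference, so units
   straddling an insert edge keep their genomic context. CH methylation is
   not modeled (all non-CpG cytosines are unmethylated); a retained CH
   cytosine is therefore a recorded conversion failure, and molecules with
   more than 3 of them are removed, matching the standard
   incomplete-conversion read filter. Conversion and protection
   efficiencies default to 1.0 — published enzymatic-conversion kits do not
   state them precisely — and are exposed as `ConversionParams`.
3. **Digestion.** A molecule is cut iff a complete recognition site lies
   within its insert (sites spanning the insert/adapter junction never cut,
   since the enzyme needs the full duplex site and adapters are unmodeled).
   Digestion is complete — the protocol's repeated digestion/amplification
   is modeled as certainty. Retained molecules are byte-identical to their
   inputs, so lengths and ends are preserved. Built-in panels: `one_cut`
   (MseI TTAA) and `four_cut` (MseI, MluCI AATT, SspI AATATT, PsiI TTATAA);
   all built-ins are AT-only palindromes, so scanning one strand suffices.
   Custom non-palindromic enzymes are scanned on both strands. N never
   matches.

Because the recognition strings contain no C or G, conversion can only
*create* sites (C→T makes new T runs), never destroy one; and lowering
methylation can only add sites. These monotonicity properties are asserted
in the test suite and anchor the enrichment logic: after conversion the
AT-rich background is dense with sites while islands — protected by their G
content, which conversion never touches — are mostly site-free.

## Deterministic site maps vs stochastic molecules

Genome-level site tracks use a consensus methylation rule: either
`all_unmethylated` (every C converts; the maximal site set) or
`threshold_0.5` (β ≥ 0.5 protects; the default). Library simulation instead
draws per-molecule CpG states, so two molecules over the same locus can be
cut differently. Both views are provided because a static track and a
molecule ensemble answer different questions (where *can* the enzyme cut
vs. what *fraction* of molecules survive). Crick-strand sites are reported
in the Watson frame at the leftmost base under the site.

## Coverage, capture and downsampling

Coverage accumulates each molecule's drawn CpG states onto Watson CpG
coordinates — simulation knows the origin coordinates, so there is no
alignment step. "Combined coverage" of an element is interpreted as the
SUM of per-CpG depths (an "accumulated to ≥ 100-fold" reading); a per-CpG
mean is available via `mode="mean"`. The capture threshold defaults to 100.

Saturation curves downsample by cumulative base pairs, not read count, and
use nested subsamples: molecules are permuted once and each grid target
takes the shortest prefix reaching it (the crossing molecule included).
Nesting makes curves exactly monotone rather than monotone in expectation.
A target beyond the total base count saturates at the full-data capture
count (logged), so the curve's right end equals full-data capture.

## Methylation statistics

- **Windows**: unweighted mean beta of qualifying CpGs per 100-kb tiling
  window; empty windows are missing, never zero.
- **Concordance**: restricted to CpGs at ≥ `min_depth` in both tracks
  (default 20); Pearson r plus the fraction of CpGs with |Δβ| > 0.5. With
  fewer than two shared CpGs, r is reported as NaN, not 0.
- **DMR caller**: candidate regions are maximal runs of CpGs with inter-CpG
  gap ≤ 100 bp, chunked to spans ≤ 300 bp (the gap value is this package's
  choice; the span cap is the standard one). A region is testable only if
  its summed depth reaches 10 in *every* sample. The test is a two-sided
  Fisher exact test on pooled group counts — exact, dependency-free and
  auditable; pooling ignores between-sample variance, a documented
  simplification, and the null calibration (false-positive rate at
  p < 0.05 within [0.03, 0.07] at depth ~100) is asserted in the
  acceptance tests. The three standard threshold configurations are
  exposed as `DMR_CONFIGS`; boundary comparisons are inclusive (≥) by
  default with a `strict` switch, since printed thresholds do not resolve
  the boundary.
- **Promoter comparisons**: one-vs-rest Fisher tests over TSS ± 4 kb
  regions, Benjamini–Hochberg q across all tested region × cell pairs,
  emitted at q ≤ 0.01 and |Δβ| ≥ 0.5.
- **Peak association**: regions with β < 0.10 count as hypomethylated. For
  two cells, one 2×2 table per peak set: rows are cell-1- vs
  cell-2-specific hypomethylated regions, columns split by containment
  (≥ 1 bp) of that peak set, each with a two-sided Fisher p. Conditioning
  the columns on a *fixed* cell's peaks is deliberate: a table whose
  columns meant "own-cell peak" would be symmetric under perfect
  co-location and could never detect the association. The own-cell
  diagonal percentages are reported alongside.

## The cohort generator and classifier

The synthetic cfDNA cohort mixes a shared normal methylome with a planted
tumor component: at `n_informative_cpgs` promoter CpGs (within TSS ± 2 kb),
BC samples shift to (1−f)·normal + f·(normal ± Δ), the shift directed away
from the nearer beta boundary; f is the tumor fraction (default 0.3,
Δ = 0.5). Every sample also receives per-CpG Gaussian jitter
(sd 0.10) — inter-individual biological variability — plus binomial
counting noise at sequencing depth (Poisson around 200×). The jitter scale
places typical promoter-CpG variance near 0.01, so the 0.009 variance
prefilter is genuinely discriminative rather than vacuous. What the
generator does **not** emulate: fragment-level features (the matrix is
site-level), batch effects, copy-number aberrations, age/cell-type
composition drift, and correlated methylation blocks — so passing tests
demonstrate the statistical machinery, not clinical performance on real
plasma.

QC order is fixed and idempotent: sites first (autosomal CpGs at depth
strictly > 100 in strictly > 80 % of samples), then samples (excluded when
strictly > 20 % of the kept sites fall below 100×). The variance prefilter
is computed on all samples before cross-validation — a known mild-leakage
choice that mirrors how a single global feature set is typically reported;
it is label-free, and the label-permutation guard in the acceptance suite
bounds its effect.

Leave-one-out classification re-selects features inside every fold: Welch t
ranking on training samples only, top 50 by |t| (both configurable), mean
imputation of missing betas from the training fold, then L2 logistic
regression (scikit-learn default C = 1, stable at p ≫ n). The held-out
predicted probability is the sample's tumor score. AUC uses the rank
formulation with ties ½; an operating threshold, where needed, is chosen by
Youden's J on the pooled scores (`ClassifierResult.youden_threshold`),
since no standard threshold rule exists for this design.

A note on the null-cohort check: individual LOO AUCs under the null are
highly variable (fold-correlated scores plus selection instability give a
per-seed sd around 0.2), so the no-signal and permuted-label guards are
asserted on seed-averaged AUC, which is what actually detects leakage.

## Numerical and I/O choices

- Coordinates are 0-based half-open everywhere internally; the
  bismark-coverage dialect (1-based, start = end) is converted only at I/O.
- Fisher exact p values come from `scipy.stats.fisher_exact` and are
  verified in tests against an exact hypergeometric enumeration oracle
  (rational arithmetic) to 1e-10 for tables up to N = 200.
- Per-molecule RNG streams derive from (seed, crc32(molecule id)), so a
  molecule's conversion is reproducible independent of batch order; batch
  APIs use one stream for speed.
- Degenerate inputs are reported as missing (NaN), never silently zero:
  fractions over zero molecules, r over < 2 CpGs, AUC with one class,
  Fisher p with an empty region set.

## Problem sizes

Tests and the acceptance script run on a ~150 kb synthetic genome
(30 islands of 0.6–1.4 kb, GC 0.65, in spacers of 3–6 kb, GC 0.30, CpG
seeding rate 0.06/bp inside islands), libraries of 6 000–40 000 fragments,
DMR calibrations of 2 000 regions × 5 seeds, and cohorts of 30 + 30 samples
at 200×. These sizes make every property measurable with comfortable
statistical margins while the full suite runs in about a minute; all
quantities scale with the same machinery if larger studies are wanted.

## Known limitations

- Complete digestion and ideal conversion are upper bounds on real
  enrichment; partial digestion kinetics, star activity and enzyme dosage
  are out of scope.
- No PCR duplicates, sequencing errors (an error-free molecule is the unit
  of analysis), adapter artifacts, or alignment ambiguity.
- DMR pooling across samples within groups understates between-sample
  variance; calls on real cohorts should be re-checked with a
  variance-aware model.
- The classifier is a single model family (logistic regression) by design;
  no fragmentomics or end-motif features.
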