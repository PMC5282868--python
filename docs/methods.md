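# Methods note

Statistical models, parameter choices and known limitations of the
`methylmark` pipeline. Nothing in this note makes an empirical claim that
is not computed by the test suite or `scripts/acceptance.py`.

## Discovery filter

A locus is a candidate marker when both hold:

- **Non-cancer constraint**: β strictly below `normal_beta_max` (default
  0.10) in *every* non-cancer sample — the maximum over all normal
  urothelium, blood and non-cancer urine samples is compared, with no
  outlier allowance. An optional per-group quantile (`noncancer_quantile`)
  relaxes this to a robust per-group summary.
- **Cancer constraint**: β strictly above `cancer_beta_min` (default
  0.50) in at least `cancer_fraction_min` (default 0.50) of cancers.

Strict inequalities make the boundary behaviour explicit (a sample at
exactly 10% fails the locus). Missing betas are excluded from both sides;
the per-locus audit table records how many samples were used. Relaxing
any criterion can only grow the candidate set (monotonicity), which the
property tests exercise directly.

The unmethylated-control threshold estimator is a plain quantile
(`numpy.quantile`, linear interpolation) of control betas, default 0.99.

## Classification protocol

Training runs `n_iterations` (default 100) independent iterations. Each
iteration draws a within-class 80/20 split (at least one held-out sample
per class), fits a `RandomForestClassifier` (500 trees, `sqrt` features,
per-iteration seed derived from the master seed via
`numpy.random.default_rng`), and records held-out AUC, sensitivity and
specificity. The model from the highest-AUC iteration (earliest under
ties) is fixed; per-locus training medians are stored with it.

Prediction imputes missing betas with those medians; samples missing more
than 20% of the signature loci are returned as `unclassifiable` (never
silently imputed into a call). The binary call is cancer-present iff the
forest probability is ≥ 0.5 (inclusive).

Signature reduction re-ranks loci by mean variable importance across the
iterations of the full run and retrains the protocol on the top
`target_size` loci. The reduction criterion (mean impurity-based
importance) is an implementation choice; alternatives such as permutation
importance would slot into the same interface.

Forests and logistic regressions are scikit-learn; the protocol, split
logic, AUC routines and evaluation metrics are implemented here.

## ROC and AUC

Two independent AUC routes are implemented and required to agree exactly:

- rank-based (Mann–Whitney with midrank tie handling via
  `scipy.stats.rankdata`), and
- trapezoidal integration (`numpy.trapezoid`) over an ROC curve built by
  grouping tied scores into single cut-points, anchored at (0,0) and
  (1,1).

With ties counted ½, both equal exhaustive pairwise concordance; the
tests verify all three against each other on randomized tie-heavy score
sets. Undefined ratios (no positives called, etc.) are reported as
missing, never as 0.

## Bisulfite reference frames and read assignment

Each amplicon top strand S yields four reference frames:

| frame | sequence            | read reduction | CpG call (raw base) |
|-------|---------------------|----------------|---------------------|
| OT    | S with C→T          | C→T            | C meth / T unmeth   |
| CTOT  | revcomp(OT)         | G→A            | G meth / A unmeth   |
| OB    | S with G→A          | G→A            | G meth / A unmeth   |
| CTOB  | revcomp(OB)         | C→T            | C meth / T unmeth   |

The per-frame reduction directions follow from the frame definitions: OT
contains no C and OB no G, so their reverse complements contain no G and
no C respectively, and a read can only match its frame after the
direction shown. The interrogated position is the CpG cytosine at
amplicon offset p (OT/CTOT) or the opposite-strand cytosine at top offset
p+1 (OB/CTOB); primer-span positions are excluded (primer bases are
synthetic).

Assignment is exhaustive ungapped scoring of every read against every
window of every frame — practical because the reference is a small
fixed-length panel, and free of heuristic mapping artifacts. Reads are
grouped by length and scored as one-hot float32 matrix products (BLAS); a
read is assigned to the unique best window with match fraction ≥ 0.9,
equal-best windows leave it ambiguous (e.g. a fully unconverted read
matches both strand routes and is correctly undecidable), and indels drop
reads below the floor. Adapter trimming (semi-global, 3′-partial overlap
≥ 5 bases, 10% mismatch) must precede assignment for templates shorter
than the read length.

Per-CpG counting consults the raw (unreduced) read base; mates of the
same fragment covering the same CpG are counted once (mate 1 wins). Loci
under `min_coverage` (default 10) report a missing beta, never 0.
Bisulfite conversion efficiency is estimated from non-CpG cytosines and
reported, not used to correct betas. `on_target_fraction` is assigned
reads / total reads: the aligner is panel-only, so "aligned" and "on
target" coincide and the informative denominator is all input reads.
Per-amplicon depth is fragment-fold coverage (union of mate intervals
over amplicon length), so overlapping mates are not double-counted.

## Synthetic-data models

**Cohort generator.** Marker loci draw a per-locus penetrance
p ~ U(0.5, 1.0); methylated states get Beta(6, 2) noise truncated at
≥ 0.55, unmethylated states Beta(1.5, 48.5) truncated at ≤ 0.08 (array-
like beta noise; `None` switches to noise-free constants 0.75 / 0.02).
With `enforce_filter_margin` (default) each marker's methylated-cancer
count is clamped to a strict majority, so the planted set satisfies the
discovery filter *by construction* and filter recall is deterministically
1 — the generator models the idealized discovery premise, and the
perfect classification results downstream are a property of these planted
margins, not evidence about real cohorts. Setting
`enforce_filter_margin=False` gives free Binomial penetrance draws for
heterogeneous-cohort experiments; the panel-ordering experiments use this
with p ~ U(0.2, 0.7), chosen a priori to model inter-tumour
heterogeneity, because under the margin-respecting default every small
panel saturates and the orderings are not exercised. Background loci get
per-locus Beta-distributed baselines. A low-grade tumour stratum retains
each methylation alteration independently with probability
`low_grade_marker_retention` (default 0.98). Default cohort sizes are 86
cancers / 30 normal urothelium / 20 blood / 10 non-cancer urine; blood
enters only the non-cancer maximum, so its size beyond a handful does not
change filter behaviour.

**Urine mixtures.** A case is w·tumour + (1−w)·normal plus Gaussian
noise (σ = 0.02), clipped to [0, 1]; controls are normal profiles plus
noise. The tumour-cell fraction w is a free simulation parameter (fixed,
interval-uniform, or per-case).

**Read simulator.** Per-amplicon depth ~ Gamma(shape 4, mean 1254)
clipped to [123, 2673]; 150 bp paired-end reads; the four frames in equal
proportion; each fragment draws independent per-CpG methylation states
from the locus beta; unmethylated (and non-CpG) cytosines convert with
probability 0.995; uniform substitution errors at 0.003 per base;
off-target read pairs are random sequence at 3% of the output; templates
shorter than the read length read through into the adapter. The
generator emits a full per-fragment truth table and is byte-deterministic
under its seed; RNG consumption is shaped so that runs restricted to
complementary frame subsets share methylation/conversion draws, which the
strand-symmetry tests exploit for exact-equality checks.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeds; derived
  seeds stay below 2³¹. Acceptance results derive both cohort seeds from
  a single CLI `--seed`.
- Beta matrices are written with `%.10g` formatting and `NA` for missing;
  round-trips are identity to ~1e-10.
- Read scoring uses float32 one-hot products with an integer-rounded
  match count and an epsilon-guarded score floor.
- Every CLI run writes a `manifest.json` with parameters and SHA-256
  output digests.

## Limitations

- No genomic realism: amplicon sequences are random, there are no SNPs,
  indels, repeats or mappability effects, and the aligner is panel-only
  (off-target material is rejected, not mapped elsewhere).
- No PCR or coverage bias models beyond the Gamma depth draw; no quality-
  score model (qualities are constant and unused).
- The clamped cohort generator makes discovery and classification succeed
  by construction; it validates the pipeline's correctness, not the
  clinical performance of any marker set. Heterogeneous settings exist
  but their penetrance range is itself a modelling choice.
- Urine tumour-cell fractions and the mixture form (two components plus
  optional blood) are stylized; no quantitative ground truth for sediment
  composition is modelled.
- Signature reduction uses impurity-based importances, which are known to
  favour high-variance features; the protocol interface admits other
  rankings but none are implemented.
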