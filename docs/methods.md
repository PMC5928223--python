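# Methods

## Study design being modelled

The package analyses a two-group human cohort: normal-weight (NW,
BMI < 25 kg/m²) and obese (O, BMI ≥ 30 kg/m²) adults whose orosensory
sensitivity to linoleic acid (LA) is measured psychophysically, whose
circumvallate-papillae microbiota is profiled by 16S family-level counts,
and whose resting and stimulated saliva is assayed biochemically. Subjects
split into tasters (T) and non-tasters (NT) at an LA detection threshold of
0.5% wt/wt, giving three comparisons of interest: NW vs O, T vs NT, and
obese tasters vs obese non-tasters.

## Psychophysics

The stimulus ladder is geometric: c_k = c_min · 10^(0.25·k), k = 0…17, from
0.00028% to ≈5% wt/wt (the 18th value is 4.979%, within 0.5% of 5%; the
series is constructed by step count, not by endpoint, because the endpoint
is only approximately a series member). Per 3-AFC set the subject must
identify the odd sample among three, so chance is 1/3.

**Stop rule.** The procedure ends when the LA sample is identified correctly
three times consecutively; that concentration is the threshold. Protocol
descriptions of this kind do not fully pin down what happens between sets,
so the package adopts one explicit convention: after a correct
identification the *same* concentration is presented again, after an
incorrect one the series advances one step. Under this rule three
consecutive corrects always sit at a single concentration, which is the only
reading under which "this concentration" is well defined. `detect_threshold`
therefore requires the streak to occur at one concentration and resets it on
an incorrect answer or a concentration change.

**Censoring.** A subject who never meets the criterion is assigned the
series maximum, flagged censored, and classified NT (thresholds at the top
of the range are observed in practice). Classification is NT iff
threshold ≥ cutoff or censored; the cutoff default is 0.5% wt/wt. Group
summaries use geometric means because thresholds span about five orders of
magnitude; for the same reason thresholds are log10-transformed before
regression against taxa, while BMI is used untransformed.

The simulated observer is a step function with a guess rate (default 1/3)
below the true threshold and 1 − lapse above it. This ignores the graded
psychometric slope of real subjects; it is sufficient to exercise the stop
rule and its censoring behaviour, and with guess rate 0 it provides exact
recovery oracles.

## Microbiome stages

- **Filtering:** features with total count < 3 across all samples are
  removed. The threshold is interpreted as a global (cohort-wide) total, not
  per sample; per-sample filtering would be a stricter rule than the
  pipeline wording supports.
- **Aggregation** sums counts over a lineage rank; unresolved assignments
  are pooled under "unclassified" and kept as their own taxon.
- **Shannon diversity** is −Σ p ln p over positive proportions, reported in
  nats by default with the log base configurable, since conventions differ
  between tools.
- **Ordination:** the dissimilarity is Bray-Curtis on relative abundances,
  embedded by classical PCoA (double-centred −D²/2, via scikit-bio);
  negative eigenvalues are excluded from the explained fractions. A
  compositional alternative (Euclidean distances of centred-log-ratio
  transformed proportions with a 0.5/p pseudofraction) is available via
  `metric="clr"`.
- **Effect-size screen:** the two-class, no-subclass reduction of the LEfSe
  procedure. Samples are rescaled to sum 10⁶; per taxon a Kruskal-Wallis
  test at α = 0.05 is followed, for significant taxa, by an effect size
  equal to the mean over 30 within-class bootstrap rounds of
  log10 |difference of class means|, floored at 0 after averaging (per-round
  differences are clipped at 10⁻¹² to keep the log finite). A taxon passes
  at a score ≥ 2.0. This deliberately replaces the one-against-all LDA of
  the Galaxy tool with the class-mean difference on the same per-million
  scale: for two classes with no subclasses the two quantities track each
  other closely, and the replacement is deterministic and dependency-free.
  It is an approximation of, not a byte-match to, the original.

## Multiblock PLS-DA

**Preprocessing.** Every variable is autoscaled (mean 0, unit variance,
ddof = 1); every block is then divided by √p_b. Each autoscaled column has
sum of squares n − 1, so each block's total is p_b(n−1)/p_b = n − 1: block
sums of squares are balanced exactly, by construction. This is the standard
construction achieving "equal sum-of-squares contribution per block"; the
scaling constant is parameterised through the preprocessing model should a
different convention be needed. Constant columns are an error (they carry no
scale), as are missing values — the analysis is complete-case, with dropped
subjects counted in the log; imputation is out of scope.

**Fitting.** NIPALS on the preprocessed concatenated matrix with Y a
centred class indicator, tolerance 1e-12, at most 1000 iterations
(single-column Y converges in one step; non-convergence raises with the
iteration count). The super-score identity — MB-PLS super scores equal
ordinary PLS scores on the concatenated matrix — is asserted against
scikit-learn's PLSRegression to |r| > 1 − 1e-8 in the tests, which keeps the
implementation and its oracle fully independent. Y coding is a single
centred indicator by default; a two-column dummy coding is provided and
verified to give identical first-component scores. The model is
deterministic: NIPALS is initialised from the first Y column and uses no
randomness.

**Component count.** Components are interpreted while each explains at
least 10% of Y variance (a prefix rule, minimum one component); in the
motivating analyses this yields two.

**Variable selection.** VIP is computed on the first component by default
(the number of components is a parameter). Selection is strict VIP > 1.
The display rule "loading > 0.3" is ambiguous between normalized weights and
correlation loadings; the package uses the absolute correlation of each
variable with the super scores of components 1–2 (correlation loadings),
with raw weights available on the results object. Thresholds are strict
inequalities throughout (VIP > 1, loading > 0.3, p < 0.05). The post-hoc
test is a two-sided Mann-Whitney per variable — exact for combined n ≤ 20
without ties, otherwise the normal approximation with tie and continuity
correction — with no multiplicity adjustment, and bands § (p < 0.1),
* (p < 0.05), ** (p < 0.01).

## Synthetic cohorts

The generator emulates the study's data structure with known ground truth:

- **Sizes:** default 21 NW + 17 O; non-taster fractions 4/21 (NW) and 8/17
  (O). Published legends disagree on the obese taster split (9/9 vs 9/8),
  so the split is an exposed parameter, not a claim.
- **Thresholds** are drawn uniformly over the series *indices* (log-uniform
  in concentration) below 0.5% for tasters and at/above it for non-tasters,
  with 25% of non-tasters censored at the maximum; labels and thresholds
  are therefore consistent by construction.
- **Microbiome:** per sample a Dirichlet-multinomial at depth 50,000 reads
  (the order of post-QC read counts in comparable 16S runs). Baseline
  Dirichlet means encode a Firmicutes/Bacteroidetes-dominated anaerobic
  oral community over the 18 canonical families, with rare families
  (including TM7) near 1%; the total concentration of 50 gives realistic
  subject-to-subject overdispersion. Planted family effects multiply the
  favoured class's concentration parameter by 2^magnitude.
- **Saliva and biology:** lognormal with unit-free baseline (log-sd 0.4,
  a typical biological coefficient of variation); planted effects shift the
  favoured class by magnitude × SD on the log scale, guaranteeing
  positivity. BMI is uniform on [19, 25) / [30, 45) by group with waist
  circumference linearly coupled to it; age uniform 20–60.
- **Default planted effects** encode the reported discriminants: TM7
  (+3 log2FC) and Lactobacillaceae (+1.5) plus resting lysozyme (+1.5 SD)
  and antioxidant capacity (+1.0 SD) up in tasters; stimulated flow and
  carbonic anhydrase VI (+1.5 SD each) up in non-tasters.

**What the generator does not emulate:** real covariance among saliva
variables, phylogenetic correlation among families, sequencing error, or
any BMI–taste interaction beyond the group-wise non-taster fractions.
Passing recovery tests therefore show the pipeline detects effects of the
planted kind and size at these sample sizes; they do not certify behaviour
under real-world correlation structure.

**Compositional closure.** Planting a large fold-change on an abundant
family (e.g. Bacteroidaceae ×8) necessarily depresses every other family's
relative abundance in that class. In recovery experiments the unplanted
families are therefore *not* statistically null; chance-level false-positive
calibration is assessed on unplanted saliva/biology variables and on
zero-effect cohorts.

## Problem sizes and numerical choices

Recovery and calibration experiments use 50 seeded cohorts of 20 + 20
subjects at depth 5,000 reads for multiblock recovery and depth 50,000 for
the effect-size screen, and 30–200 seeds for monotonicity and α-calibration
checks — sizes at which the binomial error of the measured rates is a few
percent. All generators run off numpy `SeedSequence` spawning, so a single
seed reproduces every table byte-for-byte. Ties at thresholds are broken by
strict inequality; degenerate inputs (empty cohorts, all-zero samples,
constant columns, one-sample classes) raise typed errors naming the
offending object rather than propagating NaNs.

## Known limitations

- Two-class discriminant analysis only; no >2-class extension, no
  permutation model-level p, no sparse PLS, no cross-validated prediction
  accuracy.
- The effect-size screen approximates the LDA step (see above).
- No OTU-level read processing (clustering, chimera removal, taxonomy
  assignment) — inputs begin at the count table.
- Complete-case handling of missing data only.
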