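# lipotaste

Tools for linking the orosensory detection of dietary fatty acids to the
lingual (circumvallate-papillae) microbiome and salivary biochemistry.

The package is written for sensory-physiology and microbiome researchers
studying fat-taste sensitivity in humans. It covers the full analysis chain
of such a study:

- **Psychophysics** — the ascending three-alternative forced-choice (3-AFC)
  staircase for linoleic-acid (LA) detection thresholds on an 18-solution
  geometric concentration ladder (0.00028% to 5% wt/wt, 0.25 log10 steps),
  with taster / non-taster classification at the 0.5% cutoff and censoring
  at the series maximum.
- **Microbiome stages** — count-table filtering, rank aggregation, relative
  abundance, Shannon diversity, rarefaction, Bray-Curtis PCoA,
  taxon-covariate regression, and a two-class LDA-effect-size screen
  (Kruskal-Wallis at α = 0.05, log10 LDA score cutoff 2.0).
- **Multiblock PLS discriminant analysis (MB-PLS-DA)** — the core model,
  built statsmodels-style: a model object fitted to four named predictor
  blocks, returning a results object with scores, block importances,
  explained variance, VIP-based variable selection and Mann-Whitney
  post-hoc tests.
- **A synthetic cohort generator** with planted, recoverable effects, so
  every stage is testable end-to-end without access to subject data.

## The model

Let X₁…X_B be predictor blocks (biological determinants, stimulated saliva,
resting saliva, microbiota families) over the same n subjects and y a
two-class outcome coded as a centred indicator. Every variable is
autoscaled and each block divided by √p_b (its variable count), so all
blocks contribute equal total sum of squares. NIPALS then extracts
components from the concatenated matrix X = [X₁ … X_B]: per component,

    w = X'u / ‖X'u‖ ,   t = Xw ,   q = Y't / t't ,   u = Yq / q'q ,

iterated to convergence, followed by deflation of X and Y by t. Block
importances are the partition ‖w_b‖² of the unit super weight (summing to 1
per component), and per-variable importance is the VIP

    VIP_j = √( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ) ,

with Σ_j VIP_j² = p. Variables with VIP > 1 on the first component are the
discriminant set; a two-sided Mann-Whitney test per variable gives the
significance bands § (p<0.1), * (p<0.05), ** (p<0.01).

## Worked example

```python
from lipotaste import CohortSpec, MBPLS, generate_cohort

cohort = generate_cohort(CohortSpec(seed=7))   # 21 NW + 17 O subjects
res = MBPLS(cohort.blocks, cohort.group_taste.to_numpy(), n_components=2).fit()
print(res.summary())
```

```
Multiblock PLS-DA results
============================================================
classes: T vs NT   n = 38   components = 2

component   explained Y   explained X
        1        0.765        0.130
        2        0.149        0.096

block importance (component 1):
  biological_determinants      0.211
  stimulated_saliva            0.299
  resting_saliva               0.176
  microbiota                   0.314

variables with VIP > 1 on component 1 (10):
  BMI                          VIP=1.72  p=0.1277 ns
  Waist                        VIP=1.97  p=0.0397 *
  Age                          VIP=1.23  p=0.1358 ns
  Flux_S                       VIP=2.26  p=0.0000 **
  CAVI_S                       VIP=2.43  p=0.0000 **
  Proteo_R                     VIP=1.10  p=0.0760 §
  Lyso_R                       VIP=1.88  p=0.0001 **
  Deferribacteraceae           VIP=1.22  p=0.0595 §
  Lactobacillaceae             VIP=1.84  p=0.0000 **
  TM7_family_incertae_sedis    VIP=1.96  p=0.0000 **
```

The first component separates tasters from non-tasters (76.5% of Y
variance); the microbiota block carries the largest share of its weight.
The variables the generator planted — TM7 and Lactobacillaceae enriched in
tasters, higher resting lysozyme in tasters, higher stimulated flow and
carbonic anhydrase VI in non-tasters — all exceed the VIP threshold with
significant post-hoc tests, while incidental hits (BMI, Age) carry
non-significant p values.

The same pipeline is available from a shell:

```sh
lipotaste simulate --seed 7 --out cohort/
lipotaste run --config run.yaml        # comparison: T_vs_NT, NW_vs_O, OT_vs_ONT
```

which writes `thresholds.tsv`, `diversity.tsv`, `lefse_results.tsv`,
`vip_report.tsv`, `mbpls_model.json` and `summary.json`.

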