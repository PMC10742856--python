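# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
`haplopheno`.

## Study design being modelled

A candidate-gene association study in a selfing crop: a panel of
~180 fully inbred accessions, targeted resequencing of ~42 cloned
genes (coding region plus 2000 bp upstream), grain-trait phenotypes
from two years with one pooled value per accession per year, and a
haplotype-based breeding question — which haplotype (and which
multi-gene haplotype combination) should be selected, and which small
marker set identifies it.

## Multi-environment trait statistics

**Variance components.** For each trait, a balanced two-way ANOVA
(accession × environment, r replicates) gives method-of-moments
estimates from expected mean squares:

* r > 1: `Ve = MS_err`, `Vge = (MS_GE − MS_err)/r`,
  `Vg = (MS_G − MS_GE)/(r·e)`;
* r = 1 (the pooled-plant design, the default): the interaction and
  residual are confounded; we report `Vg = (MS_G − MS_GE)/e`,
  `Ve = MS_GE`, `Vge = 0` and log the confounding. Heritability and
  BLUP shrinkage are unaffected because only the sum
  `Vge/e + Ve/(re)` enters them.

Negative moment estimates are truncated at 0 (standard EMS practice,
logged). Accessions without complete environment coverage are excluded
(logged); unequal replicate counts fall back to per-cell means with
r = 1.

**Heritability.** Broad-sense, entry-mean basis:
`h² = Vg / (Vg + Vge/e + Ve/(r·e))`; exactly 0.5 for
Vg = Vge = Ve = 1, e = 2, r = 1.

**BLUP.** With a balanced design and environments treated as fixed,
the mixed-model solution has the closed form
`BLUP_i = μ̂ + s·(ȳ_i − μ̂)` with `s = Vg/(Vg + Vge/e + Ve/(re))`,
where ȳ_i is the accession mean after per-environment centering. The
test suite checks this against Henderson's mixed-model equations
solved directly on a toy. We use the closed form rather than general
REML because the target design (2 environments × 1 pooled value) is
exactly balanced; the shrinkage map is monotone, so accession ranking
is preserved.

**Correlations** are Pearson r between per-accession BLUPs with the
t-transform p (n − 2 df), annotated `**`/`***` at p < 0.01 / 0.001.

## Association scan

Per variant, the exact single-marker LMM
`y = Wα + xβ + u + ε`, `u ~ N(0, λτ⁻¹K)`, `ε ~ N(0, τ⁻¹I)`:

* **Kinship** K = W·Wᵀ/p over column-centered dosages (the centered
  relatedness matrix), computed from the LD-pruned variant set by
  default; the scan itself uses the full QC'd set. Missing dosages are
  mean-imputed per variant (logged); negative eigenvalues of K are
  floored at 0 (logged).
* **λ optimization**: K is eigendecomposed once; per variant the REML
  log-likelihood in λ is evaluated on a 6-points-per-decade log grid
  over [1e−5, 1e5] and the bracketing interval refined by Brent. A
  fast mode (`per_variant_lambda=False`) estimates λ once under the
  null model and reuses it (EMMAX-style); the exact per-variant mode
  is the default.
* **Test**: GLS β at λ̂, Wald t = β/se referred to a t distribution
  with n − c df (c = 2: intercept + variant). With K = I this reduces
  *exactly* to the OLS t-test — the identity-kinship limit is checked
  to |Δlog₁₀p| < 1e−6. The p-value is exactly invariant to affine
  rescaling of y. No covariates are included by default (kinship-only
  correction); a covariate matrix can be supplied. No multiple-testing
  correction is applied: significance is the raw p < 0.01 rule below.
* **Consistency rule**: a variant is associated with a trait iff
  p < 0.01 (strict) in environment 1, environment 2 *and* the BLUP
  dataset. Variants are assigned to the gene whose
  [promoter, transcript-end] envelope contains them; others are
  reported intergenic. Monomorphic variants and variants below a MAF
  floor (default 1 %) are skipped with a reason.

## Haplo-pheno analysis

* **Haplotype calling**: dosage 0 → REF, 2 → ALT at each associated
  site of a gene; any missing or heterozygous site makes the
  accession's haplotype missing (no imputation — conservative for an
  inbred panel). Labels H1, H2, … by descending frequency, ties by
  lexicographic allele string.
* **Rare groups**: retained iff more than three accessions (count ≥ 4),
  the default; a percent mode (retain ≥ x %, default x = 1) is
  available because field practice states the threshold both ways.
  Excluded accessions still count in panel-percent denominators, so
  percent columns sum to ≤ 100 (equality only with no missing calls).
* **Group statistics** are computed on BLUP values by default
  (per-environment mode available). Two groups: pooled-variance
  Student's t (Welch behind a flag). More: Duncan's multiple range
  test — means sorted descending, critical range
  `R_p = q(1−α_p, p, df_err)·sqrt(MSE/n_h)` with protection level
  `α_p = 1−(1−α)^(p−1)` and n_h the harmonic mean group size; spans
  inside an already-homogeneous span are not retested; the compact
  letter display derives from maximal homogeneous spans. An
  independent recursive span-enumeration implementation is the test
  oracle.
* **Variance explained (R²)**: one-way ANOVA eta-squared,
  `100·SS_between/SS_total`, over retained accessions, with the F-test
  p alongside. This is a *descriptive* group-mean statistic: under
  population structure a stratified gene can show a large η² without
  any causal effect (see Limitations). For two equal groups with
  standardized mean gap d it converges to `100·d²/(d²+4)`.
* **Superior haplotype**: retained group with the maximal
  (direction = maximize) or minimal (minimize) mean; ties go to the
  larger group (logged).
* **Combinations**: per accession the tuple of per-gene labels
  (missing if any component is missing), labelled HC1, HC2, … by
  descending frequency, then filtered/analysed exactly like single
  genes. Refining a grouping can only increase SS_between, so the
  combination R² is ≥ each component gene's R².

## Marker panels

For a target haplotype (combination) among the retained groups, the
panel is a set cover: site i covers group g if g's allele at i differs
from the target's. Greedy selection (largest remaining coverage,
ties → earlier genomic position) is exchanged for exhaustive minimal
cover when there are ≤ 15 candidate sites ("auto"). A target sharing
its full allele string with another retained group is not
discriminable → error. Panel genotyping: `target` iff homozygous for
every diagnostic allele; a non-missing mismatch anywhere → `non-target`
(even if other sites are missing); otherwise `inconclusive`. Primer
chemistry (KASP/PARMS tails) is out of scope; the panel is the site
list plus diagnostic alleles such assays would interrogate.

## Synthetic data generator

`simulate_panel` builds, per gene: a gene model (1–4 exons, CDS a
multiple of 3, strand random, promoter = 2000 bp upstream,
strand-aware), a random CDS sequence, `sites_per_gene` polymorphic
sites across promoter + gene body (indels kept out of the CDS so REF
alleles stay consistent with the CDS sequence), and
`founders_per_gene` distinct founder haplotypes. Each accession draws
one founder per gene — no intra-gene recombination, which is what
makes haplotypes gene-local and trivially phased in inbred material.
Base founder frequencies come from a Dirichlet(2) with a 5 % floor
(every founder is present at panel scale, mirroring the ~5 % rarest
analyzable groups in real panels); subpopulation divergence perturbs
them Balding–Nichols-style: subpop frequencies ~
Dirichlet(base·(1−F)/F). QUAL/QD/FS/MQ are drawn from passing ranges
with a configurable fraction planted to fail each hard-filter
criterion.

`simulate_phenotypes` draws, per trait,
`y_ijk = μ + g_i + h_i + E_j + (gE)_ij + ε_ijk` with the polygenic
background g ~ N(0, Vg_bg·K_true) on the (unit-mean-diagonal
normalized) kinship of the simulated genotypes — this is what makes
the LMM correction testable — planted haplotype effects h from the
causal spec, fixed year effects, and iid interaction/error terms. The
truth table records founder strings, per-accession founders, causal
genes, the planted superior haplotype per causal gene and the realized
h² from the realized variance components.

Default study conditions: 180 accessions in 3 subpopulations
(39/58/83), 42 genes × 65 sites (≈ 2700 variants), divergence
F = 0.15, four grain traits (GL/GW/L-W/TGW with means 9 mm / 2.6 mm /
3.5 / 25 g) with variance components placing entry-mean h² near
0.94/0.86/0.91/0.80, r = 1 (pooled plants), e = 2 years, 1 % missing
genotypes, and 7 causal genes with per-haplotype effects a fraction of
a genetic SD (pleiotropy included: one gene feeds both grain-width and
weight, as single-gene contrasts of a few tenths of a mm / 2–3 g).

**What the generator does not emulate**: linkage between genes,
within-gene recombination and rare recombinant haplotypes, dominance
and epistasis, genotyping error beyond missingness, selection
footprints, and phenotype distributions beyond the Gaussian additive
model. Passing recovery tests therefore demonstrates that the
*pipeline machinery* is correct under its own model class, not that
the model captures every feature of a real panel.

## Calibration and recovery experiment designs

* **Type-I calibration** uses null panels (no planted effects,
  background and structure on) built from 350 single-site genes, so
  the kinship matrix has high effective rank and the LMM's model
  assumptions hold sharply; measured inclusion rate at α = 0.01 sits
  inside the 95 % binomial band over >10⁴ variant-dataset pairs.
* **Recovery** plants one causal gene (two founders, 50/50, effect =
  1 phenotypic SD) among 60 background genes at h² = 0.85; 100 panels
  are pushed through the full pipeline. With few background genes the
  kinship-drawn background covaries with the causal founder split and
  both power and the R² comparison degrade — see Limitations.

Problem sizes in the test suite (panel sizes, seed counts) were chosen
so the full suite and the acceptance script each complete in a few
minutes on one CPU.

## Known limitations

* **Low-rank kinship**: with only ~40 founder-block genes, K has low
  effective rank. Two consequences, both visible in experiments and
  faithful to real candidate-gene panels: (i) *proximal
  contamination* — the tested variant contributes to K, deflating its
  own signal (conservative); (ii) when the trait's polygenic
  background truly follows that low-rank K, the 1 %-tail of the Wald
  test inflates mildly (≈1.4× in our experiments). With a high-rank
  kinship the test is exactly calibrated.
* **η² under structure**: the reported R² is a raw group-mean
  statistic; population stratification can make non-causal genes
  "explain" sizeable variance. The association scan (kinship-corrected)
  decides *which* genes are analysed; R² is descriptive.
* **r = 1 confounding**: with one value per environment, Vge and Ve
  cannot be separated; reported Ve is their sum.
* The consistency rule (three correlated datasets at p < 0.01) has no
  formal family-wise guarantee; it is the field's screening heuristic,
  reproduced as specified.
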