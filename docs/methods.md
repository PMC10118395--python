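# Methods

## The model

`ssblup` implements a multi-trait genomic evaluation for beef-cattle
carcass traits — carcass weight (CW), eye muscle area (EMA), backfat
thickness (BF) and marbling score (MS) — in which pedigree, genotype
and phenotype information are used jointly ("single step"). Each
slaughtered animal contributes one record of all four traits:

    y = X_f f + X_b b + u + e

with class fixed effects f (herd-year, year-season, sex), a linear
regression b on age at slaughter, breeding values u with
Var(u) = A ⊗ G0 (A the numerator relationship matrix, G0 the 4x4
additive genetic covariance), and residuals e with Var(e) = I ⊗ R0.
All-or-none recording is assumed: carcass traits are measured once, at
slaughter, so per-trait missingness is rejected rather than modelled.

For genotyped animals the breeding value is decomposed into marker and
residual polygenic (RPG) parts:

    u_g = Z g + a

where Z holds centered allele dosages (code − 2p), g are SNP effects
with per-marker covariance

    Σ_SNP = (1 − k) · G0 / D,      D = Σ_j 2 p_j (1 − p_j)

and a is the RPG term with Var(a) = k · A22 ⊗ G0 (A22 the pedigree
relationship block among genotyped animals). The RPG fraction defaults
to k = 0.2, i.e. markers carry 80% of the additive variance.

Three model kinds share one design:

* **conventional** — pedigree prior A⁻¹ ⊗ G0⁻¹ only;
* **ssnpblup** — the marker-effect single-step model: unknowns
  (f, b, u_all, g) with prior precision (per trait, scaled by G0⁻¹)

      u,u   : A⁻¹  +  (1/k − 1)·A22⁻¹ on the genotyped block
      u_g,g : −A22⁻¹ Z / k
      g,g   : Zᵀ A22⁻¹ Z / k  +  (D/(1−k))·I

  which is the joint density of p(u_ng | u_g) · p(a) · p(g) after the
  substitution a = u_g − Z g;
* **ssgblup** — the equivalent H-matrix form,
  H⁻¹ = A⁻¹ + blockdiag(0, Gw⁻¹ − A22⁻¹) with G = ZZᵀ/D and
  Gw = (1−k) G + k A22.

The two single-step forms are algebraically identical for u (a
Woodbury identity connects the Schur complement of the g block to
Gw⁻¹ − A22⁻¹), which the test suite exploits: each is the other's
oracle, and both must collapse to conventional BLUP at k = 1. At k = 0
the marker-effect form has no finite RPG precision and is rejected;
ssgblup covers that corner.

## Pedigree algebra

A⁻¹ is assembled by Henderson's rules with inbreeding; inbreeding
coefficients come from the Meuwissen–Luo recursion (no dense A is ever
formed for that). Missing parents are absorbed by phantom parent
groups following Westell/Quaas: a missing slot is replaced by the
group column and the Mendelian-variance coefficient treats the group
parent as unknown (group inbreeding 0). Groups are the cross product
of selection paths (by default: parent role × offspring sex, the four
classical paths) and birth-year bins; the group count is configuration,
not a constant.

**Random genetic groups.** Purely fixed group equations are confounded
with the general mean, and when missingness is concentrated in the
founder cohort the groups are also mutually confounded. The resulting
equations are singular (or, with a cosmetic ridge, conditioned at
~1e10), which makes iterative and direct solutions drift apart along
the near-null directions. We therefore put a proper prior on the
groups — a unit diagonal on the group rows of A*, i.e. group effects
~ N(0, G0) — the standard stabilization for unknown-parent groups.
`group_prior=0` restores the fixed-group treatment for users who want
it. In the synthetic populations the generative group effects are
exactly zero, so the shrinkage prior is also the correctly specified
choice there.

A22 is computed by the tabular method on the pedigree restricted to
genotyped animals and their ancestors — exact and adequate at desk
scale (its cost is quadratic in the restricted pedigree size). For
millions of animals one would instead use Colleau's indirect method;
that is a scalability note, not a feature of this package.

## Mixed-model equations and solvers

Equations are ordered block-major: the t traits of one effect level
are adjacent, so every prior contribution is a Kronecker product of a
scalar structure matrix with G0⁻¹ and the data part is
(WᵀW) ⊗ R0⁻¹ for scalar incidence matrix W. The coefficient matrix is
stored as a block-sparse (BSR) matrix with t×t blocks.

Identifiability of fixed effects uses reference coding: the first
class effect keeps all its levels (it carries the cell means); every
later class effect has its first (sorted) level constrained to zero by
equation fixing (unit diagonal, zero right-hand side), so level counts
— and therefore equation counts — are preserved. Covariates are
centered for conditioning.

`solve_pcg` is preconditioned conjugate gradients with an exact t×t
block-Jacobi preconditioner, plus — for the marker-effect model — the
exact dense marker block (Zᵀ A22⁻¹ Z / k + D/(1−k) I) ⊗ G0⁻¹, whose
Cholesky factor is formed once. Without the marker-block term the
marker equations dominate the iteration count. Convergence is declared
at relative residual ‖Cx − rhs‖/‖rhs‖ < 1e-10 (default); iteration
counts at desk scale (~150–250) are not comparable to production
systems with tens of millions of equations. `solve_direct` (dense
Cholesky/LU below ~6,000 equations, sparse LU up to 20,000) is the
oracle for the iterative path. Solver agreement is asserted in
genetic-standard-deviation units, the scale-free metric appropriate
when traits differ by orders of magnitude in raw units.

RPG effects of genotyped animals are recovered as â = û_g − Z ĝ, which
makes the decomposition identity exact by construction; the test
suite still asserts it end to end as a guard against index errors.

## Post-processing and forward validation

All four evaluations (single-step and conventional, full and truncated
data) are rebased to a common base cohort — by default the last cohort
born before the truncation cutoff that has carcass records — and
divided by the per-trait genetic standard deviation √G0_ii. Rebasing
is affine, so rankings and differences are base-invariant (tested).

SNP-effect scans divide each estimated effect by the per-trait marker
genetic standard deviation √Σ_SNP,ii (the multi-trait Σ_SNP is used
through its diagonal), giving effects comparable across traits. No P
values are attached to the scan: approximating significance of
single-step marker effects is an open problem and deliberately out of
scope.

Forward validation removes the phenotypes of animals born after a
cutoff year (pedigree and genotypes are never truncated). Validation
cohorts are genotyped cows/steers with a record in the full data, born
after the cutoff; bulls are excluded. The LR regression test fits
full = b0 + b1 · truncated over the cohort (in common-base genetic-SD
units); b0 measures bias, b1 inflation (the regression direction is
full-on-truncated; the LR literature also uses the reverse), and R² is
the raw squared Pearson correlation. Identical inputs return exactly
(0, 1, 1) because numerator and denominator share the same centered
sums.

## The synthetic population generator

The generator mirrors the evaluation model generatively, so both
single-step and conventional models are correctly specified on its
output:

* **Pedigree**: founder males and females (one cohort), then
  `n_generations` discrete cohorts; each generation `n_sires` sires ×
  `dams_per_sire` dams. Sires are truncation-selected on an index of
  true breeding values (CW + MS on the genetic-SD scale by default)
  observed with accuracy 0.8 — emulating progeny-test selection — and
  promoted to `bull`; other males are steers. Dams are drawn at
  random. Defaults give ~2,040 animals over 5 cohorts two years apart.
* **Genotypes**: founder haplotypes are mosaics of a pool of 20
  ancestral haplotypes per chromosome (switch probability 0.05 per
  marker), which creates the local linkage disequilibrium of a real
  SNP panel; descendants receive gametes with one crossover per
  chromosome per meiosis. Without founder LD the marker-QTL
  association comes only from family co-segregation and smears over
  whole chromosomes, so scans cannot localize — an early version of
  the generator had exactly that defect. 1,000 markers on 10
  chromosomes by default; ~500 animals genotyped with probabilities
  rising from 2% (founders) to 55% (last cohort), bulls at 90%.
* **True effects**: g_true rows are N(0, Σ_SNP) at realized founder
  frequencies. Three "major gene" markers (one per region on three
  chromosomes, minor allele frequency ≥ 0.2) are planted for CW at
  ±16 σ_SNP — each explaining roughly 15% of the CW genetic variance,
  the scale reported for major carcass-weight QTL in beef cattle —
  and each trait column is rescaled so the realized founder marker
  variance is exactly (1 − k) G0_ii. The planted markers are the
  top-|effect| markers of g_true by construction. RPG effects a_true
  follow the pedigree gene-flow recursion (parent average plus
  Mendelian sampling with the exact inbreeding-adjusted variance)
  scaled to k·G0, for all animals, genotyped or not. tbv = Z g + a.
* **Phenotypes**: every cow and steer gets one slaughter record
  y = herd-year + year-season + sex + β·(age − μ_age) + tbv + e with
  e ~ N(0, R0); bulls get none. Herd-year and season effects are
  drawn per level with SDs of 0.4 and 0.15 phenotypic SD; the sex
  (steer − cow) shift is 0.5 phenotypic SD; age ~ N(30, 2) months.
* **Variance components** (defaults): phenotypic SDs 30 kg, 8 cm²,
  4 mm, 2 score; heritabilities 0.40/0.35/0.28/0.48 (inside the
  0.28–0.48 range typical of routine carcass evaluations); genetic
  correlations moderate positive (0.30–0.45) except BF–EMA = −0.10
  and BF–MS = −0.15; mild positive residual correlations. These are
  plausible values, not estimates from any particular dataset.

What the generator does **not** emulate: genotyping error and
haplotype-phasing structure beyond the mosaic approximation, multiple
SNP chips and imputation across panels, heterogeneous residual
variances, non-random mating beyond sire selection, and production
scale (millions of records). Passing tests therefore demonstrate the
correctness and internal consistency of the estimation machinery and
the qualitative validation patterns — not that real-data headline
numbers would be reproduced.

## Numerical and design choices

* Allele frequencies are observed frequencies among genotyped animals,
  clamped to [0.5/2n, 1 − 0.5/2n] so monomorphic markers keep nonzero
  variance; centering by base-generation frequencies is a config
  switch away (the estimable quantities are unaffected by the choice).
* Missing genotypes are mean-dosage imputed (2p_j). This is a
  documented fidelity limitation relative to haplotype imputation; it
  preserves column means and is irrelevant to the estimation algebra
  under test.
* Parentage verification counts opposing homozygotes per duo; a duo is
  flagged above a 1% conflict rate, and duos with fewer than 100
  jointly called markers are skipped.
* Mean age centering is computed per assembled dataset (full vs
  truncated differ slightly); the difference is absorbed by the fixed
  effects.
* Singleton class levels are allowed but logged; a completely
  confounded first effect (single level) degenerates gracefully to an
  intercept.
* Problem sizes in the test suite (pedigrees ≤ 1,000; equivalence
  batteries of 250 animals × 300 markers; ten studies of ~2,040
  animals × 1,000 markers) were chosen so the full suite and the
  acceptance script each run on a single CPU in minutes while leaving
  every statistical property measurable.
* Desk-scale calibration of the "stability" check: with ~1,900 records
  total, removing the last cohort's phenotypes perceptibly shifts the
  parents' EBV, so pre-cutoff cohort correlations between full and
  truncated runs sit at 0.97–0.999 rather than at the ~1.000 seen when
  millions of records are shared. The acceptance tolerance for
  "correlation ≈ 1" is therefore 0.95.
* Scan-localization checks use a dedicated, more densely genotyped and
  unselected simulation (~1,250 genotyped of ~1,850 animals, 600
  markers on 6 chromosomes, no sire selection — a mapping population
  is not selected on the scanned trait, since selection drives major
  QTL toward fixation and induces cross-chromosome disequilibrium)
  rather than the forward-validation scenario: placing
  three ~15%-variance major genes among the top three of all marker
  estimates needs a reference population of about a thousand genotyped
  animals, while ~500 suffice for prediction but not for localization.
  Localization is judged at chromosome level — the resolution at which
  genome scans of this kind identify large genes — because linkage
  disequilibrium legitimately spreads a major gene's signal onto
  neighbouring markers of the same chromosome.

## Known limitations

* Explicit A22⁻¹ and a dense marker block limit the implementation to
  desk scale (tens of thousands of equations); the production-scale
  reformulations that avoid these inverses are documented in the
  literature and out of scope here.
* Prediction error variances come from a dense inverse and are only
  available for small systems.
* The LR slope under selection on (noisily observed) true breeding
  values is mildly deflated relative to 1 — selection information not
  contained in the data is invisible to BLUP — which is the expected
  behaviour, not a defect; the acceptance band [0.9, 1.1] on the mean
  slope accounts for it.
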