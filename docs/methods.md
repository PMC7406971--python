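# Methods

This note records the models, numerical choices and known limitations of
hexagwas, in the order the pipeline runs them.

## Genotype representations

All genotyping starts from per-genotype allele depths (ref, alt) at
biallelic SNPs. Three representations are derived:

* **Quantitative genotype** — the alt-read fraction r = alt/(ref+alt),
  defined only where total coverage strictly exceeds 20 reads (default
  `min_genotype_depth`). The fraction is used directly as an additive
  predictor; in a hexaploid its expectation is d/6 for dosage d.
* **Dosage class** — argmin_k |r − k/6|, computed as ceil(6r − 1/2), which
  breaks exact midpoint ties toward the lower class. There are exactly
  seven classes (nulliplex … hexaplex). At fixed depth 100 and sequencing
  error 0.001 the exact binomial misclassification analysis gives per-class
  recovery 1.00/.98/.91/.91/.93/.97/1.00 — about 94% overall for a
  uniform parental-dosage mix, limited by the middle classes whose
  boundaries sit 1/12 away; the unit tests check simulation against this
  oracle rather than a flat figure.
* **Diploidized genotype** — reference-allele copies x ∈ {0, 1, 2}: 2 when
  r < 0.05, 0 when r > 0.95, 1 otherwise (both thresholds inclusive on the
  heterozygous side). This is the coding used by the GRM and the mixed
  model. Marker filters: MAF > 0.05 (strict) computed from the diploidized
  codes, and non-missing data for at least half the individuals. The
  correlation scan additionally requires intermediate (duplex–pentaplex)
  dosage in at least 23/83 of individuals, scaled as ceil(23n/83) for other
  population sizes, so that the allele ratio actually varies.

Missing genotypes propagate through every representation; the only
imputation in the package is the GRM's mean imputation (below). p_i is the
*reference*-allele frequency: the 2p_i centering term is only coherent for
the frequency of the counted allele, even though such frequencies are often
loosely called "minor allele frequencies".

## Transmission-ratio distortion

Markers enter the screen only under stringent conditions: mean progeny
coverage in [60, 200], both parents' coverage strictly above 60, MAF >
0.01 and no missing progeny genotype. The statistic is

    log10( F1 allele ratio / mean parental allele ratio )

where the F1 ratio averages per-progeny alt fractions (a pooled-read mode
exists) and the parental ratio averages the two per-parent fractions —
never pooled parental reads. Markers where either ratio is zero are
excluded (the log is undefined there).

**Standardization.** Scores are z-standardized empirically (genome-wide
mean and SD) and tested two-sided against the normal, flagging P < 1e-10
(the threshold is configurable; the method is sometimes quoted with 1e-11).
Before standardization each log ratio is divided by its delta-method
sampling SE — empirical progeny-ratio variance for the F1 term, binomial
read-sampling variance *evaluated at the F1 ratio* for the parental term.
This weighting matters: the raw log ratio's variance is dominated by
parental read sampling and scales like (1−p)/p, so markers with a low
parental ratio have several times the genome-wide SD, and an ordinary 2–3σ
parental fluctuation would cross |z| = 6.5 and mimic distortion (parents
are sequenced once, without replicates — precisely the failure mode that
produces isolated "distorted" markers in real data). With the weighting, a
5,000-marker Mendelian-null population yields zero flags and the |z| > 1.96
fraction sits at 5%. Evaluating the parental binomial variance at the null
(F1) ratio rather than the observed parental ratio keeps the SE from
collapsing when a parental count fluctuates toward zero.

## Kinship and heritability

The additive relationship between individuals j and k is the standard
per-marker-standardized form

    A_jk = Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / [2 p_i (1 − p_i)],

with missing genotypes mean-imputed at 2p_i (the sum needs complete
columns; association scans never impute). The raw sum is available
(`literal_sum=True`); by default it is rescaled to unit mean diagonal. In a
Hardy–Weinberg population that equals dividing by the marker count m, but
in a full-sib F1 the within-family genotype variance is far below
2p(1−p) — the raw-sum diagonal averages ≈ 0.14/m here — and without the
rescaling σ²_g absorbs the deficit and h² is badly inflated (≈ 0.88
measured for a trait simulated at 0.3). With it, recovery is unbiased
(mean ĥ² = 0.30 over 20 seeds at n = 300, ~2,000 markers).

REML maximizes the restricted likelihood of y ~ N(Xb, A σ²_g + I σ²_e)
through one eigendecomposition of A and a bounded scalar search over the
log variance ratio λ = σ²_g/σ²_e on [1e-5, 1e5] (profiled σ²_e in closed
form). Numerical guards: 1e-6 diagonal jitter when the smallest eigenvalue
is negative; a flat-likelihood flag when A is proportional to I
(components unidentifiable); a boundary flag when the pure-noise limit is
as good as the interior optimum; constant phenotypes return zero components
with a warning. The solution matches a 200-point dense grid search of the
same restricted likelihood within grid resolution on random instances.
h² = σ²_g/(σ²_g + σ²_e) and is invariant to shifting or scaling y.

Heritability is fitted on a single phenotype vector per individual
(intercept-only fixed effect); repeated yearly records would need a
repeatability model that is out of scope.

## Association scans

**Correlation scan.** Pearson r of the alt-read fraction against the
phenotype, pairwise-complete per marker (minimum 10 individuals; zero
variance skips the marker). P-values come from empirically standardizing
the coefficients genome-wide — centered at the observed mean by default
(a zero-centered and a Fisher arctanh·√(n−3) mode are selectable). The
empirical route is self-calibrating: under a simulated null the fraction of
markers past |z| = 1.96 is 5% by construction.

**Partial correlation.** Per marker, on individuals where the marker, the
phenotype and the covariate O are all observed,

    r_partial = (r_by − r_ay r_ab) / √[(1 − r²_ay)(1 − r²_ab)],

which equals the correlation of O-residualized phenotype and genotype (the
identity is asserted to 1e-10 in the tests). Markers collinear with O
(|r_ab| = 1) are skipped. O is either a measured dosage vector (e.g.
qPCR-derived) or the called dosage at a named proxy marker.

**Mixed model.** y = β_o O + g + sτ + ε with Var[g] = K σ²_g and an
identity incidence structure (one record per individual). Variance
components are fitted once under the null (P3D/EMMAX) and reused as the GLS
covariance for every marker; the Wald t-test re-estimates the residual
scale per marker with n − q − 1 degrees of freedom. Markers with missing
genotypes are tested on their complete cases, grouped by missingness
pattern (no imputation); constant or covariate-collinear markers are
skipped. An exact per-marker REML refit is available as a cross-check and
agrees with P3D within 0.2 −log10 units on test populations. With K = εI
and no covariate the scan reproduces simple-regression coefficients to
1e-8. Effects are reported signed, so recessive "nulliplex higher" claims
can be sign-checked rather than assumed. All tests are two-sided.

Significance in every scan is Bonferroni: −log10(α/n_tests) with α = 0.1
by default and n_tests the number of markers actually tested.

**Group test and multi-locus r².** A Welch t-test compares the phenotype
between two rounded dosage classes of O (default simplex vs duplex), and
ordinary least squares of the phenotype on up to 10 loci (plus O when
compensating) reports the coefficient of determination, with a
pseudo-inverse fallback and a flag under rank deficiency.

## LD

r² is the squared Pearson correlation of diploidized genotype codes —
haplotype-based LD is out of reach in a hexaploid, where phasing is
unresolved. The haploblock span around a peak is the min–max position of
markers with r² > 0.15 (configurable) within a 5 Mb window; contiguity is
deliberately not required, since multi-haplotype regions produce LD
patterns inconsistent with marker order. The window default is a judgment
call: it comfortably contains the 2–5 Mb spans typical of F1 haploblocks
at this marker density.

## Simulator

The generator mirrors the study design the analysis assumes:

* **Cross** — 83 progeny by default from a nulliplex × duplex sex-locus
  cross; five 20 Mb chromosomes with uniformly placed markers; parental
  dosages uniform on 0..6 per marker (so all 7 progeny dosage classes and
  all 13 F1 frequency classes (d₁+d₂)/12 are realized); modifier loci
  forced to simplex × simplex so nulliplex progeny segregate at 25%.
* **Meiosis** — the six homologs pair randomly into three bivalents each
  meiosis; one recombinant chromatid per bivalent is transmitted, with
  Poisson crossovers at 2.5 cM/Mb (configurable). Alt alleles are assigned
  to a random homolog subset per marker, so linked markers co-inherit
  through shared homolog segments. Double reduction is off by default —
  whether persimmon meiosis permits it is unknown — and when enabled
  replaces a transmitted chromatid with a second copy from another
  bivalent with the given probability per slot.
* **Reads** — negative-binomial total depth (mean 80, size 8 by default;
  ddRAD depths are overdispersed) and binomial alt counts at
  (d/6)(1−e) + (1−d/6)e with e = 0.001.
* **Phenotypes** — latent = intercept + β_ogi·d_sex + Σ effect·1[d = 0] +
  polygenic + noise, where the polygenic term is linear in true dosages and
  scaled so its share of the non-major-locus variance is exactly h2_poly.
  The "logistic" link is max(0, 2σ(x) − 1): a plain sigmoid never returns
  zero, but real populations contain individuals that never convert, and
  ability must be exactly 1[rate > 0]. A clamped-linear link is available.
  Yearly rates add fixed year shifts plus year noise; the cumulative rate
  is their mean. Defaults (intercept −2.4, β_ogi 1.7, noise SD 0.55, year
  shifts −0.30…+0.35) were calibrated once against the marginals the
  design implies — ~64% of progeny never converting and yearly mean rates
  rising from ~0.07 toward ~0.15 — and then frozen.
* **Seeding** — one seed expands into independent substreams for meiosis,
  reads and phenotypes, so each stage is separately reproducible.

What the simulator does **not** emulate: branch architecture (rates are
latent-link values, not branch-count proportions), aneuploidy, epigenetic
dynamics, reference-genome artifacts (paralogous mapping), and sharing of
parental haplotypes along chromosomes (homolog subsets are independent
across markers, which makes marker-marker LD weaker than in real data at
equal distance). Passing tests therefore demonstrate correctness of the
statistical machinery under hexasomic inheritance, not performance on any
particular real dataset.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale, chosen to make
Monte-Carlo summaries stable: heritability recovery at n = 300 with ~2,000
markers; scan calibration at n = 100 with ~2,000 markers; compensation and
modifier-recovery studies at n = 150–200 with 1,500–2,000 markers; the
distortion null at n = 91 with 5,000 markers; 20 Monte-Carlo seeds in the
test suite and 10 in the acceptance script.
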