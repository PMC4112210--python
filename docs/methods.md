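# Methods

## Model

The core model is the centred animal model for genomic evaluation:
y = X beta + N a + e with a ~ N(0, G sigma2_a) and e ~ N(0, I sigma2_e).
N maps phenotype records to animals, so animals that are genotyped but
unphenotyped (founders and F1 in a resource cross) stay in G and receive
predictions through relationships.  G = ZZ' with z_ij = (m_ij - 2 p_j) /
sqrt(m * 2 p_j (1 - p_j)); p are reference-allele frequencies taken from
the founder generation (falling back to all samples, with a warning, when
no founders are flagged).  With this scaling the animal model is exactly
equivalent to the ridge regression y = X beta + N Z g + e with
g ~ N(0, I sigma2_g), sigma2_g = sigma2_a, which is why the marker effects
can be recovered as g_hat = Z' G^-1 a_hat and why diag Var(g_hat) =
diag(Z' G^-1 Var(a_hat) G^-1 Z) is the correct per-marker estimation
variance.  Both identities are asserted in the test suite against an
independently coded ridge fit, and the reconstruction Z g_hat = a_hat is
asserted on every scan.

Assumptions worth stating: purely additive gene action; a single variance
for all marker effects (strong shrinkage — large-effect loci are shrunk
like any other); complete dosages after mean imputation (a missing call
becomes 2 p_j, which contributes exactly zero to its standardized column);
and a normal reference for the standardized statistics (no
degrees-of-freedom correction).

## Data editing

Rules are applied in a fixed order: markers with unknown position, samples
with more than 10% missing calls, markers with more than 10% missing calls
(fractions recomputed on the remaining samples), markers with minor allele
frequency strictly below 0.01 (monomorphic markers fall under this rule).
Comparisons are strict, matching "more than" / "below" wording.  The QC
report tallies every rule so the counts balance by construction.  With
mean imputation a post-imputation MAF re-filter cannot change anything and
is therefore not implemented.

## REML

The restricted log-likelihood is lR = -1/2[(n-p) log 2 pi + log|V| +
log|X'V^-1 X| + y'Py]; the 2 pi constant is included, so printed values are
comparable only within a run — only likelihood differences (LRTs) are
meaningful across software.

Single-GRM fits eigendecompose N G N' once and profile both beta and
sigma2_e out, leaving a one-dimensional optimization in log(sigma2_a /
sigma2_e) on [-25, 25], solved by a coarse grid plus bounded Brent
refinement.  Two-GRM (segment) fits use L-BFGS-B on log-variances with the
analytic gradient -1/2[tr(P V_k) - y'P V_k P y], initialized from the
single-GRM fit with a 10/90 split of the additive variance between segment
and complement.  Where the two routes overlap they agree to 1e-6 in
log-likelihood (tested).  Components are bounded below at 1e-10 var(y);
estimates landing on that floor are reported as zero, which is why the
segment LRT is floored at zero.

Variance-component standard errors come from the average-information
matrix AI_kl = 1/2 y'P V_k P V_l P y at the optimum.

## Numerical choices

GRMs built from centred dosages are routinely rank-deficient: with
in-sample frequencies the ones vector is in the null space exactly, and an
F2 design's small founder pool limits the rank further.  A Cholesky
factorization can still "succeed" on such matrices and silently lose
several digits.  `GRM.solve` therefore uses a cached symmetric
eigendecomposition and truncates eigenvalues below 1e-12 of the largest —
a pseudoinverse that is exact for right-hand sides in the column space of
G, which a_hat = sigma2_a G N'Py and Var(a_hat) always are, and identical
to the Cholesky solve when G has full rank.  Var(a_hat) itself is computed
by the projection route sigma2_a^2 G N'PN G, which needs no inverse; the
Henderson mixed-model-equations route (PEV = C^aa sigma2_e) is kept as an
explicit function and verified against the projection route on full-rank
problems.  Diagonal regularization (G + eps I) remains available but is
not used by the default pipeline, because it biases the reconstruction
Z g_hat = a_hat by O(eps).

Degenerate markers are flagged rather than dropped silently: a marker
whose estimation variance is below 1e-12 sigma2_g is reported untestable
with a reason code, so downstream multiple-testing counts stay explicit.

## Segment testing

Peaks are the per-chromosome argmax of -log10 p, ties broken by smaller
position then lexicographic id.  Windows are closed intervals of +-1 Mb
around the peak at full floating precision.  G1 rescales the segment
markers by their own count; G2 = G - Z_s Z_s' keeps the full-m scaling —
the two scalings are linked by Z_s Z_s' = (m_seg / m) G1, exposed as
`segment_bridge` and tested.  The reduced model is fitted once per dataset
and reused for every segment, since its likelihood does not depend on the
segment.

The LRT null is the chi-square distribution with 0.5 degrees of freedom,
evaluated as the regularized upper incomplete gamma (shape 0.25, scale 2).
A fractional df is an unusual choice for a boundary test — the more common
null is the 50:50 mixture of a point mass and chi-square(1) — but the
half-df reading reproduces all three published tail probabilities to
better than 1%, so it is implemented literally; the mixture is available
behind `lrt_pvalue(..., mixture=True)` for sensitivity analysis.  The
Bonferroni denominator defaults to genome_length_mb / (2 half_width), i.e.
1400 segments for a 2800 Mb genome with 1 Mb half-width; both knobs are
configurable.

## Synthetic data

The generator emulates a two-line F2 resource cross at reduced scale.
Defaults: 4 + 15 founders, 40 F1, 300 F2; two 100 Mb chromosomes with 400
evenly spaced markers each; founder haplotypes from a first-order Markov
chain with Beta(2, 2) stationary frequencies (clipped to [0.02, 0.98]) and
adjacent-marker correlation ld_rho = 0.6, drawn separately per line so the
lines diverge; Haldane meiosis at one expected crossover per 100 Mb; 30
additive QTL with N(0, 1) effects; a Bernoulli(0.5) sex covariate with
effect 1.0; residual variance set so the realized F2 heritability equals
h2_target = 0.42 exactly.  These defaults are the fixed study conditions
used by the stochastic tests and the acceptance script.

What the generator does not emulate: realistic demographic history (LD
decays geometrically with marker lag rather than following a coalescent
pattern), genotyping or imputation error, multiple chips, or pedigree
errors.  Passing tests therefore show that the machinery is correct and
calibrated under an idealized cross, not that any particular real
population will behave identically.

## Plasmode harness and its scale

Each replicate derives an independent RNG substream from (seed, replicate
index), permutes the target chromosome's block (rows jointly for the LD
scenario, per column for LE), recomputes allele frequencies from all
samples of the permuted matrix, rebuilds G, refits the model by REML, and
records both statistics' p-values for the block SNPs.  Founder-based
frequencies are not used inside the harness because a row permutation
mixes founder and non-founder genotypes within the block, making "founder
frequency" ill-defined there.  The phenotype is never permuted.

The scale of the harness matters scientifically.  With a single
genome-wide variance multiplying the whole kernel, the permuted (null)
block still receives a share of the fitted additive variance proportional
to its marker fraction, which deflates the variance-based statistics.
Measured at n = 300: the LE empirical size of SNP_ej at alpha = 0.05 is
0.029 when the block is 19% of the genome, 0.043 at 4.8%, and 0.048 at
2.4% — the source design's fraction (one chromosome of 1018 SNPs among
44055, 2.3%).  The default reduced-scale study therefore uses three
chromosomes of 3000 + 3000 + 150 markers with the 150-marker chromosome as
the permuted block, preserving that fraction.  At this scale the 0.05-level
calibration of SNP_ej under LE sits inside the 95% binomial interval, the
LD scenario is conservative, and the PEV standardization is far more
conservative still (empirical size ~0 at alpha = 0.05) — the qualitative
ordering the method predicts.  In the far tail (alpha = 0.01) a residual
conservatism remains (size ~0.008), a finite-scale effect that is
direction-safe: the test under-rejects, never over-rejects.

## Single-marker oracle

The cross-check scan fits one marker at a time by GLS after rotating y, X
and the dosages by the eigenvectors of N G N'.  The default p3d mode
estimates variance components once under the null model (the EMMAX
approximation); exact mode re-optimizes the variance ratio per marker.
The tested marker stays in G.  On simulated data the -log10 p profiles of
SNP_ej and the single-marker scan correlate at r > 0.999, and p3d vs exact
agree at r > 0.999.

## Known limitations

* Two random terms at most; no multi-trait models, no repeated records
  beyond what the record-to-animal incidence expresses.
* The plasmode harness recomputes G per replicate (correctness over
  speed); at full chip scale (tens of thousands of markers) this is the
  dominant cost.
* SNP_epj is provided for comparison only; it is conservative by a wide
  margin and should not be used for discovery.
* Dosage formats supported are dosage-TSV, PLINK raw and PLINK .bed; VCF
  input should be converted upstream.
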