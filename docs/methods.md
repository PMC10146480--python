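# Methods

## The model

Disease liability is a latent variable ℓ with population variance 1. An
individual is (or will become) a case once ℓ exceeds an age-varying
threshold t(a) = Φ⁻¹(1 − K(a)), where K(a) is the cumulative prevalence by
age a. Liability decomposes as

    ℓ = g + e,   g = Σ_j z_j β_j,

with z_j the allele-frequency-standardized dosage of SNP j, so the
liability-scale SNP heritability is h²_l = Var(g). Estimation proceeds on
the observed scale: the 0/1 disease indicator y is fitted with the linear
mixed model y = Xb + Σ_k g_k + e, g_k ~ N(0, A_k σ²_k), where A_k is a
genetic relatedness matrix, giving h²_o = Σσ²_k/(Σσ²_k + σ²_e); h²_o is
then converted to the liability scale with

    h²_l = h²_o · [K(1−K)/z²] · [K(1−K)/(P(1−P))]

(z the standard normal density at the threshold, P the sample case
proportion). When controls are unscreened for a late-onset disease, a
fraction f of them are latent cases and the conversion uses the uplifted
proportion P_actual = P + f(1−P).

## Age–prevalence curve

K(a) is interpolated log-linearly between anchor points, by default
(65, 2%), (75, 5%), (85, 15%) — the three prevalence thresholds used
throughout the analyses. Log-linear interpolation was chosen because
late-onset incidence grows roughly exponentially over this age range and it
keeps K(a) positive and monotone; outside the anchors the curve is clamped
(with a warning) since the anchors are the only empirical constraint. No
generative hazard model links liability to onset age in the source
analyses; the threshold-crossing construction used here (onset at the
youngest age where ℓ ≥ t(a)) is a stand-in with two deliberate properties:
cumulative prevalence by age a is exactly K(a), and risk-allele frequency
declines with age among the still-unaffected.

## Synthetic cohorts

`simulate_genotypes` draws biallelic haplotypes by thresholding latent
Gaussians with first-order autoregressive correlation ρ inside blocks of
consecutive SNPs (independent across blocks); dosage = sum of two
haplotypes. This is the simplest mechanism that yields a non-degenerate
segment-LD-score distribution for LDMS binning. SNPs sit at 20 kb spacing
on one simulated chromosome, centred on the APOE-analog window
(chr19:44.4–46.5 Mb). Defaults: MAF ~ U(0.05, 0.5), block 20 SNPs, ρ = 0.5
in the pipeline (0 where a test needs independence).

`draw_effects` realizes an architecture with exact variance shares: one
major locus at the window midpoint (default 25% of genetic variance — a
window exclusion then drops h² by ≈ 12 percentage points at h²_l = 0.5,
matching the reported average drop), a gene-set of 3% of SNPs jointly
carrying 70% (the reported range is 69–84% on ~3% of SNPs), and a causal
background drawn outside the window so the window's variance equals the
major-locus share exactly. Group effects are Gaussian, rescaled so each
group share — and Σ β²·2p(1−p) = h²_l — holds to machine precision.

`simulate_liability_onset` standardizes the polygenic score and the
environmental noise to exact sample mean 0/variance 1, residualizes the
noise against the score, and mixes with weights √h², √(1−h²): the realized
variance decomposition is exact, at the cost of a global rescaling of the
drawn effects. Sex is a balanced Bernoulli covariate with zero true effect.

`ascertain` draws labelled cases (onset ≤ assigned study age) and controls
(never-onsetting when `screened`, not-yet-onset otherwise) with
configurable age distributions, and can relabel a fraction of cases with
never-onsetting individuals (misdiagnosis). It reports the latent-case
fraction among controls — the quantity the uplift corrects for.

What the simulator does **not** emulate: population structure and
relatedness (individuals are exchangeable; the `n_pcs` machinery is
exercised but PCs carry no confounding signal by default), genotyping
error/missingness, X chromosome, dominance/epistasis, age-dependent
genetic architecture, and competing mortality. Tests passing on these
cohorts therefore validate the estimation machinery and the qualitative
ascertainment phenomena, not cohort-specific published values — the real
cohorts are controlled-access and not reproducible at desk scale.

## GRM, LD scores, strata

The relatedness kernel is the standard allele-frequency-standardized
estimator with p from the analysed sample (cases+controls jointly, the
GCTA default; switching to population frequencies changes estimates by
< 1e-3 in our regimes) and monomorphic SNPs dropped. Segment LD scores sum
r² over a ±100 kb sliding window (total 200 kb) around each SNP — sliding
rather than tiled windows for translation invariance. LDMS strata split at
MAF 0.05, then at LD-score quartiles computed *within* each MAF group
(matching common GREML-LDMS practice; the alternative, quartiles across
groups, is not implemented), with linear-interpolation quantiles and
right-closed bins; strata are recomputed within each SNP subset because
quartiles are defined on the analysed SNPs. Coordinates are 1-based
inclusive internally; BED input is converted at the parser.

## REML

AI-REML with 3 initial EM iterations, log-likelihood convergence tolerance
1e-6, at most 100 iterations. Constrained mode clamps components to a small
floor (1e-8 × phenotypic variance) rather than zero so the
average-information matrix stays invertible; components pinned at the floor
with a downhill score are frozen out of the AI update (an active-set step),
which keeps the AI direction an ascent direction. Step halving guards each
AI update with an EM fallback. Non-convergence is flagged on the fit, not
raised. Singular designs raise; a near-singular AI matrix (e.g. an identity
GRM, where σ²_g and σ²_e are jointly unidentifiable) is reported via a
message on the fit.

Single-GRM fits run in the kernel's eigenbasis: with the stored
standardized-genotype factor Z (A = ZZ'/M), the spectrum comes from the
M × M SNP Gram matrix when M < N; the kernel's null space enters the
likelihood only through the complement Gram of [y X], reduced exactly to
p+1 pseudo-observations, and pure-noise dimensions are handled
analytically. The spectral and dense paths agree to ~1e-8 in tests; the
spectral path makes repeated fits on a fixed kernel (and N = 3000 fits)
cheap. Multi-GRM (LDMS, joint gene-set) fits use the dense path.

The LRT against σ²_g = 0 uses the boundary mixture ½χ²₀ + ½χ²₁ for one
component and a conservative χ²_k for k components (the exact multi-
component boundary mixture depends on the kernel geometry and is not
asserted as equivalent to any particular tool's choice). SEs come from the
inverse AI matrix with the delta method for h²_o. Binary phenotypes are
analysed as 0/1 on the observed scale, the standard case-control GREML
practice. N is intended for desk scale (dense algebra, roughly N ≤ 15,000).

## Pipeline choices

The gene-set cell fits the gene-set GRM alone (the ratio to the all-SNP fit
is the proportion-of-h²); a joint two-GRM partition is available through
`reml_fit([grm_set, grm_rest], ...)` + `h2_partition` as an extension.
Because the liability transform is a multiplicative factor shared by
numerator and denominator, the proportion-of-h² is constant across
prevalences — which is why published per-prevalence ranges of this quantity
are narrow. Liability conversions are reported with both the raw and the
uplifted case proportion where an uplift fraction is given. No
multiple-testing correction is applied (raw LRT p-values are reported).
Whether gene-set fits should exclude APOE-window SNPs is configurable:
the default synthetic gene-set is drawn outside the window.

## Problem sizes used in the test suite

Estimator calibration and the ascertainment study run at n = 3000
(1500/1500) with m = 2000 SNPs over 50 replicates, the LRT type-I study at
n = 1000 with 200 phenotype replicates on a fixed kernel; the
region-exclusion, age-covariate and gene-set phenomena use 12–50 replicates
of cohorts with 700–1200 individuals and 600–2000 SNPs — sizes at which the
directional phenomena are decisively resolved on a single CPU.

## Known limitations

- **Transform attenuation under strong ascertainment.** Observed-scale
  GREML estimates the variance in the 0/1 labels actually explainable in
  the ascertained sample; the first-order liability transform maps that
  quantity back to the population scale exactly only in the small-h²
  limit. At h²_l = 0.5, K = 0.05, P = 0.5 the model itself (verified with
  the true genetic score on 8M simulated individuals, no REML involved)
  yields a transformed value of ≈ 0.38–0.42, not 0.5. This attenuation is
  a property of the estimand, not an implementation artifact — it is the
  motivation for moment-based alternatives such as PCGC regression, which
  are out of scope here. The package reports what the method reports.
- The multi-component LRT null is conservative (χ²_k).
- The onset model is a stand-in (see above); onset ages below the youngest
  anchor are clamped to it.
- No relatedness pruning: simulated individuals are unrelated by
  construction; real-data users should prune relatives upstream.
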