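# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the design decisions behind `alleleprime`.

## The scientific problem

VRC01-class broadly-neutralizing-antibody precursors require an IGHV1-2
heavy chain from allele *02 or *04. In a dose-escalation trial of a
germline-targeting immunogen the dose groups can end up imbalanced in
allele content, so the response difference between groups confounds dose
with genotype. The package's core question is: given per-participant
genotypes, naive-repertoire allele usage, and post-vaccination VRC01-class
B cell counts, does allele content or dose better explain the response?

## Response count model

For a sample with V VRC01-class cells among N sampled IgG B cells, the
four candidate mean structures are identity-link linear combinations of N,
the high-dose indicator, and the zygosity counts n02, n04 ∈ {0, 1, 2}
(see README). Counts are over-dispersed: Var(V) = φ·E(V) with φ estimated
by the Pearson statistic over rows with positive fitted mean,
ĉ = X²/(n_active − K_mean).

**Estimation.** The coefficients solve the quasi-score equations
Σ xᵢ (Vᵢ − μᵢ)/μᵢ = 0, by iteratively reweighted least squares with
weights 1/μ. Updates that would drive any fitted mean non-positive are
step-halved (up to 60 halvings); μ is floored at 1e-8 inside the weights;
convergence is max relative coefficient change < 1e-12 (200 iterations
cap). The identity link is deliberate — the means are additive in allele
copies, not multiplicative — so no log link or offset is used. Coefficients
are unconstrained beyond μ > 0 feasibility; a negative dose delta is
allowed. Rows with a structurally zero mean (e.g. an *05/*06 genotype
under the Allele model) are retained if V = 0, contributing nothing to the
score, Pearson statistic, or likelihood; V > 0 on such a row is an
infeasibility error. Placebo recipients are excluded from all fits.
Degenerate one- and two-group designs (Null, Dose) reduce to pooled
ΣV/ΣN ratios exactly, which the tests verify to 1e-10.

**Model ranking.** QAICc = −2 lnL/ĉ + 2K + 2K(K+1)/(n−K−1), where lnL is
the Poisson log-likelihood at the fitted means, and K counts mean
parameters plus one for ĉ (the standard QAICc convention; rankings are
then interpretable across models). By default ĉ is taken from the most
general (Full) model and shared across all four candidates — standard
QAIC practice — with a per-model option, since either convention is
defensible. Exact QAICc ties break toward fewer parameters.

**Inference.** Coefficient confidence intervals use t quantiles with
df = n_active − K_mean, the quasi-family convention in standard GLM
software. Linear-combination genotype means and allele differences use
normal theory with the quadratic-form variance. The *02:*04 coefficient
ratio uses the delta method with gradient (1/β₀₄, −β₀₂/β₀₄²) and a lower
CI bound truncated at zero; a non-positive β₀₄ leaves the ratio undefined
(flagged).

**V as an input.** When V must be reconstructed from sorting data, it is
round(freq_epitope × freq_VRC01-among-sequenced × N), half-up. The
upstream description of this quantity is ambiguous about the final
multiplicand; the product of the two frequencies with the total sampled
IgG count is the only dimensionally consistent reading and is what is
implemented.

## Repertoire quantification

mRNA molecules are counted as unique UMIs per allele among records with
zero mismatches to the personal germline (records with missing mismatch
annotation are conservatively treated as mutated; missing UMIs are skipped
with a logged count). Unique B cell clones are counted as distinct HCDR3
amino-acid strings (exact equality; no clustering, since the underlying
quantity is "unique HCDR3s" without a similarity threshold). Frequencies
divide by the whole-library totals over all IGHV genes; a per-gene
denominator is available for relative *02:*04 usage. Whether the HCDR3
denominator should be all-IGHV or per-gene is not fully settled; all-IGHV
is the documented default. The two primer-set libraries are combined by
averaging their frequencies per allele (an allele absent in one library
contributes zero), and the non-coding *02_S4953 variant is folded into
*02 by summing frequencies — these two operations commute, which a
property test verifies.

## Mixed models for affinity

K_D values are analyzed as log10 molar: affinities span picomolar to
~100 µM, and multiplicative effects (fold-changes) are the natural scale.
The raw scale is exposed as an option since the choice is a documented
package decision. The random-intercept model y_ij = x_ij'β + b_i + e_ij is
fitted by REML, profiling over λ = σ_b²/σ_e²: the profiled criterion is
evaluated on {0} ∪ logspace(−8, 8, 81) and refined by bounded scalar
minimization (xatol 1e-10), with an explicit boundary comparison at λ = 0.
Satterthwaite degrees of freedom use the analytic gradient of the contrast
variance and the inverse *expected* REML information ½ tr(P V_j P V_k);
against lmerTest (observed information) this agrees to ~3% in df on test
cases, and the package's own tests pin the structural behaviour instead
(df tracks participant count under strong clustering). When every
participant contributes one observation, or λ̂ = 0, the variance
components are unidentifiable or boundary-valued and the fit collapses to
OLS with residual df — making the between-group test exactly the pooled
two-sample t-test and the paired test exactly the paired t-test, which the
tests assert to 1e-9. Censored non-binders are excluded from model fits;
summaries count them and flag a median that falls among censored values as
a lower bound. A parametric-bootstrap p-value is available as a
cross-check.

## BCR allele assignment

Each read is compared to the participant's personal germline templates
over a fixed, equal-length V-region window by Hamming distance; the call
is the unique minimum, and exact ties are "ambiguous". For equal-length
ungapped candidates this ordering coincides with ranking by alignment
e-value, so mismatch distance is used as the documented surrogate; a full
alignment engine (and indel handling — reads are assumed indel-corrected
upstream) is out of scope. *02/*04-ambiguous reads are equiprobable for
either allele and count 0.5 to each; ties involving any other allele go to
a separate bucket excluded from the *02:*04 ratio. Per-participant usage
ratios with zero or infinite values are reported but flagged out of the
t-interval. Tie detection uses exact distance equality.

## Synthetic-trial generator

The generator reproduces the statistical structure the analysis assumes;
its defaults are the study conditions used throughout the tests.

- **Genotypes.** Two alleles drawn independently (Hardy–Weinberg) from
  frequencies (0.29, 0.02, 0.48, 0.05, 0.16) over
  (*02, *02_S4953, *04, *05, *06) — *04 most common, then *02, with the
  S4953 variant rare — for 18 participants per dose group. The published
  genotype table reports counts but no sampling model; HWE is the simplest
  exchangeable choice, and a stratified `dose_imbalance` mode instead
  fixes 13/18 high-dose and 5/18 low-dose *02 carriers to regenerate the
  confounded scenario.
- **Repertoires.** Per-allele UMI counts are marginally
  Binomial(n_total_umis, zygosity × rate), drawn jointly with the
  other-IGHV background via one multinomial so frequencies sum to one
  exactly. Default per-copy usage rates: *02 and *02_S4953 3.1%, *04 0.9%,
  *05 0.09%, *06 2.4%. The default library size of 20,000 unique UMIs is a
  realistic UMI depth for an IgM library of a few hundred thousand merged
  reads. Unique-HCDR3 counts are a Binomial(n_umi, 0.23) thinning of the
  UMI counts — reproducing the count-ratio statistic without modeling the
  clone-size distribution — floored at one string when an allele has any
  UMIs (every record needs a CDR3; the floor's bias is negligible except
  at very small allele counts). No somatic hypermutation, class switching,
  or light chains are modeled.
- **Responses.** μ = (β₀₂·n02 + β₀₄·n04 + δ·1[high])·N with defaults
  β₀₂ = 8e-4, β₀₄ = 2e-4 (the observed ≈4:1 per-allele ratio at
  trial-like response magnitude), δ = 0, φ = 2, drawn as NB1
  (gamma-Poisson with size μ/(φ−1), success probability 1/φ), which has
  variance φμ exactly — matching the quasi-Poisson variance function in
  its first two moments — and reduces to Poisson at φ = 1. Placebo means
  are structurally zero. The per-sample IgG total N is not reported
  upstream; the default N = 30,000 is a configurable stand-in that yields
  realistic count magnitudes (tens per sample).
- **BCR reads.** Synthetic 294-nt templates (not database sequences)
  differ between *02 and *04 at a single diagnostic position (T/A,
  mirroring the real single-nucleotide difference); *05/*06 share a
  codon-50 substitution plus private differences; *02_S4953 is
  coding-identical to *02. Reads pick a chromosome uniformly (origin
  proportional to zygosity) and mutate each base independently at rate
  0.005 by default.

All generators consume a `numpy` Generator derived from the config seed
and are bit-reproducible.

What passing tests on these data do **not** show: robustness to primer
bias between libraries, PCR/UMI collision artifacts, clonal expansion in
the naive compartment, somatic hypermutation near the diagnostic site
beyond the uniform substitution model, or dose-genotype interactions —
none of which the generator emulates.

## Study sizes used in the verification suites

- Parameter recovery: 500 simulated trials of 36 vaccine recipients at
  one timepoint (trial-scale), β₀₂ = 4β₀₄, φ = 2; checks coefficient bias
  < 5% and t-interval coverage within [90%, 98%].
- Model selection: 200 replicates at 36 → 360 → 3600 samples with nested
  rosters (common random numbers across sizes). This study uses a
  weak-signal scenario (β₀₂ = 2e-4, β₀₄ = 5e-5, same 4:1 ratio): at the
  trial-like signal strength the misspecified models essentially always
  lose already at n = 36, so the selection rate is flat in n and governed
  solely by the χ²(1)-versus-penalty race between Allele and Full — a
  regime in which consistency-with-n is unobservable. An effect an order
  of magnitude weaker keeps the smallest size informative but
  unsaturated, so the expected monotone improvement is actually
  exercised.
- Delta-method ratio CIs are compared against 100,000-draw parametric
  bootstrap quantiles on fixed fits (tolerance 5% of the ratio, covering
  Monte-Carlo error plus the second-order delta-method mismatch).
- Bootstrap coverage: 500 simulations at n = 10 per group with B = 2,000
  (scaled down from the B = 10,000 production default).

## Known limitations

- The quasi-likelihood covariance is asymptotic; at n = 36 the t-based
  intervals give ≈95% empirical coverage in the recovery study, but very
  sparse counts (many zero samples) would degrade it.
- The Satterthwaite implementation uses expected rather than observed
  information; df can differ by a few percent from lmerTest in small
  samples.
- The Hamming-window assignment requires equal-length, indel-free reads
  over the window.
- The exact Wilcoxon path enumerates only tie-free samples up to combined
  n = 20; ties fall back to the corrected normal approximation.
- Exact permutation p-values for correlations are limited to n ≤ 8
  (seeded Monte-Carlo beyond).
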