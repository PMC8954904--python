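# Methods

## Demographic models

Time runs backward from sampling in generations; epochs are half-open
intervals `[t_start, t_end)` tiling `[0, ∞)`, and within an epoch
`Ne(t) = size_start · exp(rate · (t − t_start))`. Samples collected over a
few calendar years are treated as contemporaneous (the sampling window is
far below one generation of drift at these sizes). The generation time
(10 years) never enters any computation; it exists only to annotate
reports in calendar units.

The bottleneck model fixes the decline window to 22–11 generations before
sampling and estimates three diploid sizes: `Ne_pre` (t ≥ 22), `Ne_bot`
(11 ≤ t < 22) and `Ne_post` (t = 0). The recovery epoch is exponential
with rate `GR = log(Ne_bot / Ne_post) / 11`; `log` is the natural
logarithm, a self-consistent choice because only `exp(GR · t)` is ever
evaluated. The null model is a single constant size. Replicate starting
values are drawn from the protocol's search ranges — `Ne_post`
log-uniform on [5 000, 50 000], `Ne_pre` uniform on [5 000, 50 000],
`Ne_bot` uniform on [10, 250] — which constrain only initialisation;
estimates may exceed the upper limits. The lower limits bound the
search (with an absolute backstop of 2 diploids): this mirrors how
ECM-style SFS fitters treat search ranges, and it matters here because
the model family is near-degenerate (see *Identifiability*, below).

## Expected SFS by Monte Carlo coalescent

With `k` lineages the pairwise merger rate is `k(k−1)/(4 Ne(t))`.
Waiting times are sampled by exact time rescaling: a unit-exponential
draw is inverted through the integrated rate, which has a closed form in
both constant and exponential epochs (no Euler stepping). Under infinite
sites with `μ · E[tree length] ≪ 1`, the unfolded class probabilities are
`p_i = μ E[t_i]` and `p_0 = 1 − Σ p_i`; folding adds mirror classes.

Rather than averaging `t_i` over explicitly simulated topologies, the
engine marginalises the topology analytically: given `k` ancestral
lineages, one of them subtends `i` of the `n` leaves with probability
`C(n−i−1, k−2) / C(n−1, k−1)` (exchangeable-coalescent identity), so

    E[t_i] = Σ_k  k · E[W_k] · C(n−i−1, k−2) / C(n−1, k−1)

and only the inter-coalescence times `W_k` are Monte Carlo. This is the
same estimand with substantially lower variance, and it lets a single
stream of exponential draws drive several candidate trajectories at once
(common random numbers). The fully explicit simulator
(`simulate_genealogy`, random pair merging included) is retained and
cross-checked against msprime in the tests. Monte Carlo class
probabilities of exactly zero are floored at `1/(10 · n_sims ·
n_classes)` before any log-likelihood use; the structurally empty
fixed-derived class of an unfolded spectrum is left at zero.

## Composite likelihood, optimisation, model choice

`ln CL = Σ_i m_i ln p̃_i` over unmasked classes, with `p̃` renormalised
over those classes; reported in log10 units. The monomorphic class is
retained: with μ fixed, the monomorphic fraction is what identifies
absolute Ne from a folded spectrum. Singletons are masked by default
(error-prone at low coverage); a flag disables this.

Each replicate draws a start from the search ranges and runs
coordinate-wise refinement in log-parameter space: per coordinate a
geometric bracket `x·e^±w` is evaluated against the incumbent with a
shared draw stream, the move is accepted only on improvement, and the
bracket shrinks by the golden ratio on failure (initial width 1 log unit,
floor 0.01). Fresh draws are used for every comparison; sharing them
*within* a comparison removes most of the Monte Carlo noise from the
accept decision.

Selection among replicates — and between model families — is a separate
numerical problem: the surface along `Ne_post` is nearly flat once the
recovery epoch is large (a few generations of drift cannot erase the
long-term signal), and independently evaluated likelihoods at tens of
millions of sites carry noise of order 10³ nats, dwarfing both the AIC
parameter penalty and genuine ridge-height differences of a few nats.
All final likelihoods are therefore computed against one shared draw
stream with at least 10⁵ simulations, regardless of the per-comparison
`n_sims`. AIC = −2 ln L + 2K; ties break toward fewer parameters. The
delta likelihood (saturated-multinomial maximum minus fitted composite
likelihood, log10) is reported with every fit.

## Genotype-likelihood SFS estimation

Per-site SAF likelihoods `P(data | X = x)` for sample minor-allele count
`x = 0..2n` are computed by sequential convolution over individuals of
`(gl_0, 2·gl_1, gl_2)` followed by division by `C(2n, x)`, with running
per-site rescaling (141-class products underflow otherwise). A missing
individual is a flat likelihood vector and counts toward filter failure
through its zero depth. Site filters: ≥ `min_ind` individuals at ≥ 5
reads and pooled depth within `[315, 3600]` (defaults for 70
individuals; `min_ind` defaults to 90% of the sample). The SFS is the
EM-fitted mixture over `x` (E-step posteriors ∝ η_x · SAF; M-step mean
posterior), with the observed-data log-likelihood checked non-decreasing,
relative tolerance 10⁻⁸ and a hard cap of 1000 iterations. The folded
estimate is fractional by nature and is carried as fractional counts.

## Synthetic data

The generator reproduces the statistical structure the inference assumes,
at the study design conditions: 70 diploid individuals, μ = 2.5 × 10⁻⁸,
truth trajectory (12 506 → 534 → 29 319), and for read-level data mean
depth 10 (within the 5–58× acceptance window), symmetric per-read error
0.5%, and dropout 0.02 — chosen so that the ≥ 90%-presence depth filter
retains the large majority of sites. Default 5 × 10⁴ sites for tests;
the full-scale 31 328 941 is a constant in the package. Sites are
independent (no linkage and no RAD-locus block structure — the composite
likelihood assumes exactly this, so passing tests validate the estimator,
not robustness to linkage). Genotypes are built by scattering the drawn
minor-allele count over chromosomes and pairing them, giving sample-level
Hardy–Weinberg proportions; the GL model is the same symmetric-error
binomial the estimator assumes, which makes the estimator's consistency
analytically checkable but does not probe GL-model misspecification, BAQ
or mapping artefacts. Real data additionally violate the fixed-μ and
unlinked-sites idealisations; bootstrap CIs on real data inherit those
caveats.

## Identifiability of the recovery

After folding and singleton masking, the bottleneck family is
near-degenerate at the study conditions: the trajectory
(Ne_bot = 620, Ne_post ≈ 3600–5000) produces a spectrum within ~0.03
log10 composite-likelihood units (expected over datasets, ±0.17 SD from
31.3M-site multinomial sampling alone) of the reference truth
(534, 29 319); the per-class contrasts are 2 × 10⁻³ and below, confirmed
against msprime at 2n = 140. Consequently a large minority of synthetic
datasets drawn *at* the truth genuinely prefer a fitted recovery ratio
below one, and no correct maximum-likelihood procedure can recover
ratio > 1 on ~90% of such datasets. `Ne_bot` and `Ne_pre` are sharply
identified throughout; only the (Ne_bot, Ne_post) compensation direction
is flat. Real datasets are not draws from the fitted model and need not
sit on this degenerate ridge. The end-to-end recovery tests assert the
ratio property anyway and document the observed shortfall rather than
weakening the check.

## Validation scales

The test suite runs the complete method end-to-end at sizes chosen for a
single CPU; these scales are package choices, fixed up front:

- parameter recovery and model-selection specificity: 10 seeded runs
  each, 31.3M sites drawn from a 10⁶-simulation generating spectrum
  (so simulator noise does not masquerade as data signal), fits at 6
  replicates × 20 loops × 10⁴ simulations with a 2 × 10⁵-simulation
  final evaluation (full-scale protocol: 100 × 100 × 10⁵);
- bootstrap validity: 3 seeded runs at 16 resamples × 2 replicates × 12
  loops × 8 × 10³ simulations (full-scale: 600 × 100 × 100 × 10⁵);
- GL estimator: 70 individuals × 5 × 10⁴ sites at 10× (error 0.5%), with
  the spectrum compared in bins matching the estimator's ~±4-chromosome
  frequency resolution at that depth (the ML mixture concentrates mass
  on scattered support points within its resolution — classic NPMLE
  behaviour — and tail classes have expected counts below one, so
  single-class normal checks are invalid at this size); plus a
  noise-free deep-coverage run that must reduce exactly to genotype
  counting;
- engine correctness: constant-size spectra against the `θ/i` law and
  the bottleneck spectrum against msprime at 2n = 20, both within 3
  Monte Carlo standard errors.

`scripts/acceptance.py` reruns the same pipeline from a single seed and
writes the headline numbers (estimates, AICs, bootstrap ratio
distribution, GL-estimation error) as JSON.

## Known limitations

- Single population only: no migration, admixture or multi-deme spectra.
- `Ne_post` is weakly identified by design of the scenario (the recovery
  spans ~2 generations of drift); its point estimate wanders along a
  flat likelihood ridge above ~25 000 and the compensation direction
  described under *Identifiability* lies within ~1 nat of the optimum.
  The bootstrap ratio distribution is the honest uncertainty statement;
  bootstrap ratio *means* can be inflated by the flat upper tail and the
  median is the more stable summary.
- The `.obs` format cannot encode foldedness or masks; the TSV sidecar
  format is lossless.
- Expected-SFS accuracy is Monte Carlo limited; there is no analytic SFS
  solver in the package (analytic results appear only as test oracles).
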