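# sfsdemog

SFS-based reconstruction of recent demographic history for a single
diploid population, built around the textbook conservation-genomics
scenario of the Antarctic fur seal: a severe sealing-era bottleneck
followed by rapid recovery. The package is for population geneticists who
have (or can estimate) a folded site frequency spectrum from
reduced-representation sequencing data and want maximum composite
likelihood estimates of effective population size before, during and
after a dated decline — together with honest uncertainty.

## The method

Two single-population models of the diploid effective size trajectory
Ne(t), with t in generations before sampling, are compared:

- **Bottleneck model** (3 free parameters): constant `Ne_pre` for
  t ≥ 22, constant `Ne_bot` on [11, 22), and exponential recovery on
  [0, 11) ending at `Ne_post` at sampling. The recovery rate is the
  complex parameter `GR = log(Ne_bot / Ne_post) / 11` (natural log), so
  the trajectory is continuous at t = 11. The 22- and 11-generation
  boundaries are fixed from historical sealing records at a ten-year
  generation time.
- **Null model** (1 free parameter): constant `Ne_post`.

For a candidate model the expected folded SFS for 2n sampled chromosomes
is computed by Monte Carlo coalescent simulation: with k lineages,
mergers occur at rate k(k−1)/(4 Ne(t)), and under infinite sites with
fixed mutation rate μ = 2.5 × 10⁻⁸ the probability of a site carrying a
variant subtended by i chromosomes is p_i = μ E[t_i], with t_i the branch
length subtending i leaves. The fit maximises the composite likelihood
`ln CL = Σ_i m_i ln p_i` over unmasked classes (singletons are masked by
default — they are unreliable at low coverage), with many replicate runs
started from the published search ranges; models are compared with
AIC = −2 ln L + 2K. Uncertainty comes from a nonparametric bootstrap of
the SFS (site-level multinomial resampling, refit per resample,
percentile CIs), including the distribution of the recovery ratio
`Ne_post / Ne_pre`.

When only genotype likelihoods are available (low-coverage RAD-seq), the
`gl` module estimates the folded SFS the way ANGSD-style pipelines do:
per-site sample-allele-frequency likelihoods by convolution over
individuals assuming Hardy–Weinberg proportions, depth-based site filters
(≥ 63 of 70 individuals at ≥ 5×, pooled depth in [315, 3600]), and EM
over frequency-class mixture weights (≤ 1000 iterations).

## Worked example

```python
import numpy as np
from sfsdemog import (build_bottleneck_model, expected_sfs, draw_sfs,
                      fit_models)

rng = np.random.default_rng(7)
truth = build_bottleneck_model(12_506, 534, 29_319)   # diploid sizes
exp = expected_sfs(truth, n_lineages=140, mu=2.5e-8, n_sims=100_000, rng=rng)
obs = draw_sfs(exp, n_sites=31_328_941, rng=rng)      # synthetic "observed" SFS

comp = fit_models(obs, n_replicates=6, n_loops=20, n_sims=10_000, rng=rng)
for f in comp.fits:
    print(f.model_name, {k: round(v, 1) for k, v in f.estimates.items()},
          "log10CL", round(f.log10_cl, 1), "AIC", round(f.aic))
print("preferred:", comp.preferred)
```

Output from this exact session:

```
bottleneck {'Ne_pre': 12460.6, 'Ne_bot': 514.4, 'Ne_post': 325040.0} log10CL -745977.1 AIC 3435358
null {'Ne_post': 12035.4} log10CL -746156.7 AIC 3436181
preferred: bottleneck
```

The bottleneck fit recovers the generating pre-decline size (12,461 vs
12,506) and bottleneck size (514 vs 534) closely, and beats the null
model by 823 AIC units. The post-recovery size is the least identifiable
parameter — the boom spans only ~2 generations of drift, so the
likelihood is nearly flat above `Ne_post ≈ 25,000` and its point estimate
wanders along that ridge (here 325,040); the recovery ratio
`Ne_post / Ne_pre` > 1 is the robust statement, quantified properly by
the bootstrap distribution rather than the point estimate.

The same pipeline is scriptable from the shell:

```bash
sfsdemog simulate --n-sites 50000 --gl --out-dir sim/
sfsdemog estimate-sfs --gl-file sim/genotype_likelihoods.tsv --out-dir est/
sfsdemog fit --obs sim/observed_MAF.obs --preset desk --out-dir fit/
sfsdemog bootstrap --obs sim/observed_MAF.obs --preset desk --out-dir boot/
sfsdemog report --fit-dir fit/ --out-dir report/
```

The `paper` preset runs the full-scale protocol (100 replicates × 100
estimation loops × 100,000 simulations; 600 bootstrap resamples); `desk`
is a workstation-scale configuration for validation.

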