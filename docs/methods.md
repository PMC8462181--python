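# Methods

## The problem

Repeated-count surveys of ecological communities never detect every
individual: a species' count at a site is a thinned sample of the number of
individuals actually present, and the thinning rate differs among species and
along environmental gradients. Diversity metrics computed from raw counts
therefore inherit a detection artefact. `hiddendiv` (i) fits a hierarchical
model that separates true abundance from detectability, (ii) pushes the
posterior uncertainty about true abundance through taxonomic, phylogenetic
and functional diversity metrics, and (iii) summarises, per site and metric,
how far the observed diversity deviates from its detection-corrected
counterpart and whether that deviation merely rescales the observed pattern
(noise) or inverts it (critical bias).

## The abundance model

For species *k* at site *i*, true abundance is latent and Poisson,

    N_ik ~ Poisson(lambda_ik)
    log lambda_ik = beta.can_k (1 - Strata_i) + beta.und_k Strata_i
                    + beta1_k Temp_i + s_su(i) + m_sm(i)

and counts on occasion *j* are a Binomial thinning,

    y_ijk ~ Binomial(N_ik, p_ijk)
    logit p_ijk = alpha.can_k (1 - Strata_i) + alpha.und_k Strata_i
                  + alpha1_k Date_ij + alpha2_k Temp_ij.

`Strata` is a binary vertical-stratification indicator (0 = canopy,
1 = understory), so each species has separate abundance and detection
intercepts per stratum; `Temp`, `Date` are z-scored covariates; `s` and `m`
are zero-mean normal random effects for sampling units and sampling months.
Abundance is assumed closed across the repeated occasions at a site, and
species are exchangeable given community-level hyperdistributions:

    theta_k ~ Normal(mu_theta, sd_theta)   for each coefficient block theta,

with vague Normal(0, variance 1000) hyperpriors on the community means,
except the two detection intercepts whose community mean has a Uniform(0, 1)
prior on the probability scale (equivalently a standard-logistic density on
the logit scale). Every standard deviation — the seven community sds and the
two random-effect sds — has a Uniform(0, 10) prior.

The model corrects false negatives only: no draw of `N_ik` can fall below
the maximum count observed at that site, so detection-corrected richness and
abundance are never below their observed values.

### Random-effect wiring

The month effect can be read either as attached to site-month replicate
abundance states or as a per-site grouping. Both wirings are expressible
through `SiteDesign.group_sm`; the default simulated design indexes the 12
sites into 6 sampling-unit pairs (`group_su = site // 2`) and cycles the
month index over sites (`group_sm = site mod n_sm`). Neither wiring is
asserted as canonical; readers supply an explicit site→month map for real
designs.

## Posterior computation

`fit_model` runs a Metropolis-within-Gibbs sampler. One sweep performs:

1. **Latent abundances.** A symmetric integer random walk (steps
   ±1, ±2, ±5) on each `N_ik` within `[max_j y_ijk, Nmax]`, with
   `Nmax = max_j y + Nmax_buffer` (default buffer 100). Every fifth sweep
   the random walk is replaced by an **exact enumeration Gibbs draw**: the
   full conditional of `N_ik` is a finite categorical over at most
   `Nmax_buffer + 1` values, and the gammaln tables it needs depend only on
   the data, so they are precomputed once.
2. **Species coefficients.** Per-block vectorised random-walk Metropolis
   with an independent accept/reject per species (valid because species are
   conditionally independent given hyperparameters and random effects).
3. **Random effects.** Per-group random-walk accepts for `s` and `m`,
   followed by an **exact recentering Gibbs move** along the translation
   ridge: the likelihood is invariant to adding a constant to both abundance
   intercept blocks (and their community means) while subtracting it from a
   random-effect block, so the conditional for that constant is Gaussian and
   can be sampled directly. Without this move the intercepts and random
   effects drift jointly and chains take thousands of sweeps to agree.
4. **Hyperparameters.** Conjugate normal draws for the five non-detection
   community means; random-walk Metropolis with the exact logistic prior for
   the two detection-intercept means; **exact truncated inverse-gamma Gibbs**
   on every variance (the Uniform(0, 10) sd prior makes the conditional of
   the variance inverse-gamma truncated at sd = 10; rejection sampling with
   an inverse-CDF fallback).
5. **Funnel interweaving.** For each coefficient block, a non-centered
   update: holding `z_k = (theta_k - mu)/sd` fixed, `(mu, sd)` are proposed
   jointly and accepted against the likelihood of `mu + sd z` — in these
   coordinates the Jacobian cancels exactly. This crosses the hierarchical
   funnel that traps centered updates when a block is weakly informed (run
   twice per sweep; the second pass measurably shortens autocorrelation
   times for the sds).
6. **Collapsed (marginalised) block moves.** Two families of moves are
   accepted against the likelihood with **N summed out** (enumerated over
   the truncated support, using the same precomputed tables as the Gibbs
   draw): a *translation* of each intercept block (species vector plus its
   community mean shifted together), and a *rescaling* of every block's
   spread (`sd' = c sd`, `theta' = mu + c(theta - mu)`, a log-random-walk on
   the block sd in non-centered coordinates with its `sd'/sd` Hastings
   factor). Because the marginal acceptance ratio does not involve N, the
   moves compose as a Metropolis chain on the N-marginalised posterior; N
   is then redrawn once from its exact conditional whenever any of them
   accepted, before the next sweep's N-conditional updates. The marginal
   surface is far flatter than the conditional given N along both the
   abundance/detection trade-off and the hierarchical-sd funnel, and these
   moves are what let chains agree within a few thousand sweeps.

Proposal scales adapt per element during burn-in only (multiplicative update
every 50 sweeps toward ~0.35 acceptance) and are frozen afterwards, keeping
the retained portion a valid Markov chain. Each chain draws from its own
`numpy` generator spawned from the configured seed, so identical inputs and
seeds give bit-identical draws. Initial species intercepts are data-informed
(log mean counts) with per-chain jitter; initial `N` is the observed maximum
plus one; a non-finite log posterior at initialisation raises immediately.

Convergence is diagnosed with the classic Gelman–Rubin potential scale
reduction factor, `sqrt(((n-1)/n W + B/n)/W)`; exact inter-chain agreement
reports 1.0 by convention, and a split-chain variant is available via
`rhat(..., split=True)`. Note the classic factor can fall slightly below 1
(by O(1/n)) when chains agree.

The default configuration is 3 chains × 150,000 iterations, 50,000 burn-in,
thinning 100 (3,000 retained draws). Tests and the validation scripts use
reduced configurations — 3 chains × 5,000 iterations with 2,500 burn-in and
thinning 3 for the recovery study, shorter still for unit tests — chosen so
the whole study runs on a single desk CPU while leaving the Monte Carlo
error well below the widths of the intervals being checked.

An exact truncated-sum marginal likelihood (`marginal_loglik_truncated`)
exists alongside the sampler purely as a brute-force oracle: tests require
the sampler's posterior for a one-species toy to agree with a grid posterior
built from it to within three Monte Carlo standard errors (batch-means).

## Diversity metrics and null models

`CommunityMatrix` holds site × species abundances. Metrics:

* **TD / abundance** — species richness and summed abundance (always
  computed).
* **Faith PD** — summed branch lengths of the minimal subtree spanning the
  site's species, *including the path to the root of the supplied (pruned)
  tree*; a single-species site has PD equal to its root-to-tip path, an
  empty site has PD 0. Conventions differ across software, so this one is
  pinned by tests against an edge-enumeration oracle.
* **MPD / MFD** — mean pairwise distance among co-occurring species on the
  phylogenetic (patristic) or functional (Gower) distance matrix;
  abundance-weighted form `sum_{k<l} n_k n_l d_kl / sum_{k<l} n_k n_l`
  (diagonal excluded), incidence variants (MPDi/MFDi) always reported
  alongside. Sites with fewer than two species are flagged undefined (NaN),
  never coerced to 0.
* **Functional dendrogram** — UPGMA (average linkage) on the Gower matrix,
  each internal node at half its merge height, so cophenetic distances
  reproduce merge heights and ultrametric inputs are fixed points. Ties
  follow scipy's deterministic ordering.
* **Gower distance** — range-normalised absolute differences for continuous
  traits, simple mismatch for binary ones, averaged over traits; zero-range
  traits are dropped with a warning. Range normalisation makes prior
  z-scoring of continuous traits immaterial.

Standardized effect sizes use `SES = (obs - mean_null)/sd_null` with the
sample sd over `n_perm` randomizations (default 999, tip shuffle). Null
models: `tip_shuffle` permutes species positions on the tree/distance
matrix; `site_shuffle` permutes the sampling-unit rows of the community
matrix; `species_shuffle` permutes species identities (columns). After the
tree is pruned to the community's species, tip and species shuffles induce
the same null distribution; both are kept for interface fidelity. A zero
null sd flags the SES undefined rather than reporting 0.

## Hidden diversity

For each site and metric,

    HD_i = (div.obs_i - mean(div.est_i)) / sd(div.est_i)

where `div.est_i` are the metric values on each posterior draw of the
detection-corrected abundance matrix and the sd is the sample (n−1) sd over
draws (the denominator convention is not dictated by the statistic; the
sample sd is used and tested). Positive HD = the observed data overestimate
the corrected diversity, negative = underestimate. The raw difference
`div.obs - mean(div.est)` is exported as an auxiliary column since the
standardized and raw views answer different questions. A zero sd over draws
(e.g. degenerate posteriors) flags HD undefined — never 0.

For SES metrics the pair (observed SES, mean estimated SES) is classified:
same sign → `noise` (the qualitative pattern survives correction); observed
positive with estimated negative → `bias_overestimation`; the reverse →
`bias_underestimation`. An exact zero on either axis carries no directional
pattern and is classified noise with a warning.

By default the null randomization is **re-drawn per posterior draw** from a
draw-indexed seed stream, so sd(div.est) carries both detection and
null-model uncertainty; `reuse_null=True` freezes a single permutation
stream for the observed matrix and every draw, isolating detection
uncertainty. Both behaviours are exposed because either reading of
"mean diversity over the posterior sample" is defensible.

The pipeline always outputs TD and abundance rows; requesting `"pd"` adds
SES.PD and SES.FD (Faith PD on the phylogeny and on the functional
dendrogram — PD is incidence-based, so abundance weighting applies only to
the MPD-family metrics); requesting `"mpd"` adds SES.MPD/SES.MFD (weighted
per the flag) and SES.MPDi/SES.MFDi (incidence). Species present in the
community but absent from the tree or trait table abort with an error
listing the offenders.

## Synthetic metacommunities

The validation grid varies one hyperparameter at a time — canopy or
understory abundance mean, canopy or understory detection mean — over
low/intermediate/high levels with everything else at constants, giving 12
settings coded A–L. Defaults: abundance-mean levels `ln 0.5 / ln 2 / ln 8`
(mean site abundance 0.5, 2, 8 on the natural scale), detection-mean levels
`logit 0.1 / 0.3 / 0.6`; constants hold both abundance means at `ln 2`, both
detection means at `logit 0.3`, a mild community temperature effect
(`mu_beta1 = 0.25`), community sds 0.5 (intercepts) and 0.25 (slopes), and
random-effect sds 0.25. These are plausible magnitudes for a
moderate-abundance, hard-to-detect insect assemblage with modest
species heterogeneity; they are configurable and not claimed to reproduce
any published grid. The default design mirrors the motivating study: 35
species, 12 sites as 6 canopy/understory pairs, 5 occasions; site and
occasion temperatures are drawn standard-normal, occasion dates are an
evenly spaced z-scored grid.

What the generator emulates: the exact generative process of the fitted
model (hyperdistributions → species coefficients → Poisson abundance →
Binomial counts). What it does not: overdispersion beyond Poisson,
abundance-detection correlations, open populations, spatial or temporal
autocorrelation, misidentification (false positives). Passing recovery
checks therefore demonstrate the estimator is consistent with its own
assumptions — not that those assumptions hold for any particular field
dataset.

`recovery_check` compares the truth with central credible intervals from the
pooled draws (plain quantiles); the desk-scale study (15 species × 12 sites
× 5 occasions, 3 chains × 5,000 iterations, 10 simulation seeds) is
reproduced by `scripts/acceptance.py` and the acceptance test, reporting
aggregate hyperparameter coverage at the 95% level and the worst community
R-hat.

## Numerical choices and degenerate inputs

* Binomial pmfs are evaluated from the logit (`y*eta - n*softplus(eta)`), so
  detection probabilities arbitrarily close to 0 or 1 stay finite.
* The truncated marginal and the enumeration Gibbs draw share one support
  convention (`[max_j y, max_j y + buffer]`); the truncation error is
  monitored by a convergence test (buffer vs buffer + 50).
* The classic R-hat with zero within-chain variance reports 1.0 when the
  between-chain variance is also zero and +inf otherwise.
* Counts files are validated row-by-row (negative counts, duplicate keys,
  unknown columns abort with the offending row); masked occasions arise only
  from wholly absent (site, occasion) pairs and only when the reader is told
  the file is allowed to be incomplete.
* Tree pruning collapses pass-through nodes summing branch lengths, so PD
  conventions survive pruning; pruning to a single tip is allowed and PD of
  that tip is its remaining root path.

## Known limitations

* The sampler is a desk-scale research implementation: it mixes well at the
  study's dimensions (tens of species, a dozen sites) but is not tuned for
  hundreds of sites or species.
* `TreeIndex` packs tip memberships into 64-bit masks, capping communities
  at 63 species on the fast PD path (the surrounding pipeline prunes trees
  to the community, so this binds only for larger communities than the
  intended use).
* Only closed-population, Poisson-Binomial N-mixture models are supported —
  no zero inflation, negative-binomial abundance, or open populations.
* The linear mixed model relating HD to strata in downstream analyses is out
  of scope; the HD table this package exports is that model's input.
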