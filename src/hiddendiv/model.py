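"""Stratified multispecies N-mixture model: data containers and probability functions.

The biological process is a latent Poisson abundance per site and species,

    N_ik ~ Poisson(lambda_ik)
    log lambda_ik = beta_can_k (1 - Strata_i) + beta_und_k Strata_i
                    + beta1_k Temp_i + s[su(i)] + m[sm(i)]

and the observation process is a Binomial thinning of that abundance on each
survey occasion,

    y_ijk ~ Binomial(N_ik, p_ijk)
    logit p_ijk = alpha_can_k (1 - Strata_i) + alpha_und_k Strata_i
                  + alpha1_k Date_ij + alpha2_k Temp_ij

with species-specific coefficients drawn from community-level normal
hyperdistributions.  ``Strata`` is 0 for canopy and 1 for understory sites;
``s`` and ``m`` are zero-mean normal random effects for sampling units and
sampling months.  Everything here is sampler-agnostic: likelihood, priors and
a brute-force truncated marginal likelihood used as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "PARAM_NAMES",
    "DETECTION_INTERCEPTS",
    "DetectionHistory",
    "SiteDesign",
    "SpeciesParams",
    "RandomEffects",
    "CommunityHyperparams",
    "LatentAbundance",
    "expected_abundance",
    "expected_abundance_matrix",
    "detection_prob",
    "detection_logit_matrix",
    "joint_loglik",
    "marginal_loglik_truncated",
    "log_prior",
    "poisson_logpmf",
    "binomial_logpmf",
]

#: species-parameter blocks, in canonical order
PARAM_NAMES = ("beta_can", "beta_und", "beta1", "alpha_can", "alpha_und", "alpha1", "alpha2")

#: hyper-means with a Uniform(0, 1) prior on their inverse-logit (detection intercepts)
DETECTION_INTERCEPTS = ("alpha_can", "alpha_und")

#: variance of the vague Normal(0, precision 0.001) hyperprior on community means
HYPERMEAN_PRIOR_VAR = 1000.0

#: upper bound of the Uniform(0, 10) prior on every standard deviation
SD_UPPER = 10.0


def _softplus(x):
    return np.logaddexp(0.0, x)


def poisson_logpmf(n, lam):
    """log Poisson pmf, vectorised; lam must be strictly positive."""
    n = np.asarray(n, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return n * np.log(lam) - lam - gammaln(n + 1.0)


def binomial_logpmf(y, n, eta):
    """log Binomial pmf parameterised by the logit ``eta`` of the success probability.

    Using the logit directly keeps y*log(p) + (n-y)*log(1-p) stable for
    extreme detection probabilities.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = np.asarray(eta, dtype=float)
    comb = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)
    return comb + y * eta - n * _softplus(eta)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionHistory:
    """Repeated-count detection histories ``y[site, occasion, species]``.

    ``mask[i, j]`` is True for surveyed occasions; unsurveyed cells are
    excluded from every likelihood sum.
    """

    y: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        y = np.asarray(self.y)
        if y.ndim != 3:
            raise ValueError(f"y must be 3-d (site, occasion, species); got shape {y.shape}")
        if not np.issubdtype(y.dtype, np.integer):
            if not np.all(np.equal(np.mod(y, 1), 0)):
                raise ValueError("counts must be integers")
            y = y.astype(np.int64)
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "y", y.astype(np.int64))
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != y.shape[:2]:
                raise ValueError("mask must have shape (n_sites, n_occasions)")
            object.__setattr__(self, "mask", mask)

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def n_species(self) -> int:
        return self.y.shape[2]

    def occasion_mask(self) -> np.ndarray:
        """(n_sites, n_occasions) boolean; all-True when no mask was given."""
        if self.mask is None:
            return np.ones(self.y.shape[:2], dtype=bool)
        return self.mask

    def max_counts(self) -> np.ndarray:
        """Per-(site, species) maximum count over surveyed occasions (lower bound for N)."""
        m = self.occasion_mask()
        y = np.where(m[:, :, None], self.y, 0)
        return y.max(axis=1)


@dataclass(frozen=True)
class SiteDesign:
    """Site- and occasion-level covariates and random-effect grouping.

    Covariates are assumed standardized (z-scored); ``standardization``
    records the means/sds applied by the reader, or is empty when the data
    arrived pre-standardized.
    """

    strata: np.ndarray          # (I,) in {0, 1}; 0 = canopy, 1 = understory
    temp_site: np.ndarray       # (I,) standardized site temperature
    group_su: np.ndarray        # (I,) index into sampling-unit random effects
    group_sm: np.ndarray        # (I,) index into sampling-month random effects
    date_obs: np.ndarray        # (I, J) standardized Julian date per occasion
    temp_obs: np.ndarray        # (I, J) standardized occasion temperature
    n_su: int = 0
    n_sm: int = 0
    standardization: dict = field(default_factory=dict)

    def __post_init__(self):
        strata = np.asarray(self.strata, dtype=np.int64)
        if not np.isin(strata, (0, 1)).all():
            raise ValueError("strata values must be 0 (canopy) or 1 (understory)")
        object.__setattr__(self, "strata", strata)
        for name in ("temp_site", "group_su", "group_sm"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != strata.shape:
                raise ValueError(f"{name} must be per-site, shape {strata.shape}")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "group_su", self.group_su.astype(np.int64))
        object.__setattr__(self, "group_sm", self.group_sm.astype(np.int64))
        if self.n_su == 0:
            object.__setattr__(self, "n_su", int(self.group_su.max()) + 1)
        if self.n_sm == 0:
            object.__setattr__(self, "n_sm", int(self.group_sm.max()) + 1)
        if self.group_su.min() < 0 or self.group_su.max() >= self.n_su:
            raise ValueError("group_su indices outside declared n_su")
        if self.group_sm.min() < 0 or self.group_sm.max() >= self.n_sm:
            raise ValueError("group_sm indices outside declared n_sm")
        for name in ("date_obs", "temp_obs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[0] != strata.shape[0]:
                raise ValueError(f"{name} must have shape (n_sites, n_occasions)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        if not np.all(np.isfinite(self.temp_site)):
            raise ValueError("temp_site contains non-finite values")

    @property
    def n_sites(self) -> int:
        return self.strata.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.date_obs.shape[1]

    def flipped(self) -> "SiteDesign":
        """Design with all strata labels flipped (for the symmetry property)."""
        return replace(self, strata=1 - self.strata)


@dataclass(frozen=True)
class SpeciesParams:
    """Species-specific coefficients, one vector of length n_species per block."""

    beta_can: np.ndarray
    beta_und: np.ndarray
    beta1: np.ndarray
    alpha_can: np.ndarray
    alpha_und: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray

    def __post_init__(self):
        k = None
        for name in PARAM_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be a vector")
            if k is None:
                k = arr.shape[0]
            elif arr.shape[0] != k:
                raise ValueError("all species-parameter vectors must share a length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)

    @property
    def n_species(self) -> int:
        return self.beta_can.shape[0]

    @classmethod
    def zeros(cls, n_species: int) -> "SpeciesParams":
        return cls(*(np.zeros(n_species) for _ in PARAM_NAMES))

    def get(self, name: str) -> np.ndarray:
        if name not in PARAM_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class RandomEffects:
    """Sampling-unit (s) and sampling-month (m) random effects and their sds."""

    s: np.ndarray
    m: np.ndarray
    sigma_s: float = 1.0
    sigma_m: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        if not (self.sigma_s > 0 and self.sigma_m > 0):
            raise ValueError("sigma_s and sigma_m must be positive")

    @classmethod
    def zeros(cls, n_su: int, n_sm: int, sigma_s: float = 1.0, sigma_m: float = 1.0):
        return cls(np.zeros(n_su), np.zeros(n_sm), sigma_s, sigma_m)


@dataclass(frozen=True)
class CommunityHyperparams:
    """Community-level means and sds of the species-parameter hyperdistributions.

    Detection-intercept means (``mu_alpha_can``, ``mu_alpha_und``) are stored on
    the logit scale; their prior is Uniform(0, 1) on the inverse-logit.  All sds
    have a Uniform(0, 10) prior.
    """

    mu_beta_can: float = 0.0
    mu_beta_und: float = 0.0
    mu_beta1: float = 0.0
    mu_alpha_can: float = 0.0
    mu_alpha_und: float = 0.0
    mu_alpha1: float = 0.0
    mu_alpha2: float = 0.0
    sd_beta_can: float = 1.0
    sd_beta_und: float = 1.0
    sd_beta1: float = 1.0
    sd_alpha_can: float = 1.0
    sd_alpha_und: float = 1.0
    sd_alpha1: float = 1.0
    sd_alpha2: float = 1.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            sd = self.sd(name)
            if not (0.0 < sd <= SD_UPPER):
                raise ValueError(f"sd_{name} must lie in (0, {SD_UPPER}]")
            if not math.isfinite(self.mu(name)):
                raise ValueError(f"mu_{name} must be finite")

    def mu(self, name: str) -> float:
        return getattr(self, f"mu_{name}")

    def sd(self, name: str) -> float:
        return getattr(self, f"sd_{name}")

    def detection_prob_mean(self, name: str) -> float:
        """Community mean detection intercept on the probability scale."""
        if name not in DETECTION_INTERCEPTS:
            raise KeyError(name)
        return float(expit(self.mu(name)))


@dataclass(frozen=True)
class LatentAbundance:
    """Latent true abundance N[site, species]."""

    N: np.ndarray

    def __post_init__(self):
        N = np.asarray(self.N)
        if N.ndim != 2:
            raise ValueError("N must be 2-d (site, species)")
        if not np.issubdtype(N.dtype, np.integer):
            if not np.all(np.equal(np.mod(N, 1), 0)):
                raise ValueError("N must be integer")
        object.__setattr__(self, "N", N.astype(np.int64))
        if np.any(self.N < 0):
            raise ValueError("N must be non-negative")

    def check_support(self, y: DetectionHistory) -> None:
        if np.any(self.N < y.max_counts()):
            raise ValueError("N below the maximum observed count (outside binomial support)")


# ---------------------------------------------------------------------------
# probability functions
# ---------------------------------------------------------------------------


def expected_abundance_matrix(params: SpeciesParams, re: RandomEffects, design: SiteDesign) -> np.ndarray:
    """lambda[i, k] = exp(log-linear predictor); shape (n_sites, n_species)."""
    strata = design.strata[:, None].astype(float)
    loglam = (
        params.beta_can[None, :] * (1.0 - strata)
        + params.beta_und[None, :] * strata
        + params.beta1[None, :] * design.temp_site[:, None]
        + re.s[design.group_su][:, None]
        + re.m[design.group_sm][:, None]
    )
    lam = np.exp(loglam)
    if not np.all(np.isfinite(lam)):
        raise ValueError("expected abundance overflowed; invalid parameter state")
    return lam


def expected_abundance(params: SpeciesParams, re: RandomEffects, design: SiteDesign, i: int, k: int) -> float:
    """Expected abundance lambda_ik for one site and species."""
    if not (0 <= i < design.n_sites):
        raise IndexError(f"site index {i} out of range")
    if not (0 <= k < params.n_species):
        raise IndexError(f"species index {k} out of range")
    strata = float(design.strata[i])
    loglam = (
        params.beta_can[k] * (1.0 - strata)
        + params.beta_und[k] * strata
        + params.beta1[k] * design.temp_site[i]
        + re.s[design.group_su[i]]
        + re.m[design.group_sm[i]]
    )
    lam = math.exp(loglam)
    if not math.isfinite(lam):
        raise ValueError("expected abundance overflowed; invalid parameter state")
    return lam


def detection_logit_matrix(params: SpeciesParams, design: SiteDesign) -> np.ndarray:
    """logit p[i, j, k]; shape (n_sites, n_occasions, n_species)."""
    strata = design.strata[:, None, None].astype(float)
    return (
        params.alpha_can[None, None, :] * (1.0 - strata)
        + params.alpha_und[None, None, :] * strata
        + params.alpha1[None, None, :] * design.date_obs[:, :, None]
        + params.alpha2[None, None, :] * design.temp_obs[:, :, None]
    )


def detection_prob(params: SpeciesParams, design: SiteDesign, i: int, j: int, k: int) -> float:
    """Detection probability p_ijk, strictly inside (0, 1)."""
    if not (0 <= i < design.n_sites):
        raise IndexError(f"site index {i} out of range")
    if not (0 <= j < design.n_occasions):
        raise IndexError(f"occasion index {j} out of range")
    if not (0 <= k < params.n_species):
        raise IndexError(f"species index {k} out of range")
    strata = float(design.strata[i])
    eta = (
        params.alpha_can[k] * (1.0 - strata)
        + params.alpha_und[k] * strata
        + params.alpha1[k] * design.date_obs[i, j]
        + params.alpha2[k] * design.temp_obs[i, j]
    )
    return float(expit(eta))


def joint_loglik(
    y: DetectionHistory,
    N: LatentAbundance | np.ndarray,
    params: SpeciesParams,
    re: RandomEffects,
    design: SiteDesign,
) -> float:
    """Joint log-likelihood of counts and latent abundance.

    Sum over (i, k) of the Poisson log-pmf of N at lambda plus, over surveyed
    (i, j, k), the Binomial log-pmf of y given size N and detection p.
    Returns -inf exactly when some surveyed y_ijk exceeds N_ik.
    """
    Nmat = N.N if isinstance(N, LatentAbundance) else np.asarray(N, dtype=np.int64)
    if Nmat.shape != (y.n_sites, y.n_species):
        raise ValueError("N must have shape (n_sites, n_species)")
    if design.n_sites != y.n_sites or design.n_occasions != y.n_occasions:
        raise ValueError("design and detection history dimensions disagree")
    mask = y.occasion_mask()
    if np.any((y.y > Nmat[:, None, :]) & mask[:, :, None]):
        return -np.inf
    lam = expected_abundance_matrix(params, re, design)
    eta = detection_logit_matrix(params, design)
    ll = poisson_logpmf(Nmat, lam).sum()
    lb = binomial_logpmf(y.y, Nmat[:, None, :], eta)
    ll += lb[mask[:, :, None] & np.ones_like(lb, dtype=bool)].sum()
    return float(ll)


def marginal_loglik_truncated(
    y: DetectionHistory,
    params: SpeciesParams,
    re: RandomEffects,
    design: SiteDesign,
    Nmax: int | np.ndarray,
) -> float:
    """Log-likelihood with the latent N summed out over [max_j y, Nmax] per cell.

    Brute-force reference for the sampler; monotonically non-decreasing in
    Nmax and exact once the Poisson tail above Nmax is negligible.
    """
    maxy = y.max_counts()
    Nmax_arr = np.broadcast_to(np.asarray(Nmax, dtype=np.int64), maxy.shape)
    if np.any(Nmax_arr < maxy):
        raise ValueError("Nmax below the maximum observed count")
    lam = expected_abundance_matrix(params, re, design)
    eta = detection_logit_matrix(params, design)
    mask = y.occasion_mask()
    total = 0.0
    for i in range(y.n_sites):
        for k in range(y.n_species):
            lo, hi = int(maxy[i, k]), int(Nmax_arr[i, k])
            grid = np.arange(lo, hi + 1)
            terms = poisson_logpmf(grid, lam[i, k])
            for j in range(y.n_occasions):
                if mask[i, j]:
                    terms = terms + binomial_logpmf(y.y[i, j, k], grid, eta[i, j, k])
            mx = terms.max()
            total += mx + math.log(np.exp(terms - mx).sum())
    return float(total)


def _normal_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * math.log(2 * math.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def logistic_logpdf(x: float) -> float:
    """Log density of logit(U) for U ~ Uniform(0, 1) (standard logistic)."""
    return float(-x - 2.0 * np.logaddexp(0.0, -x))


def log_prior(params: SpeciesParams, re: RandomEffects, hyper: CommunityHyperparams) -> float:
    """Log prior of species parameters, random effects and hyperparameters.

    Species coefficients are Normal(mu, sd) given the community hyperparameters;
    random effects are Normal(0, sigma).  Hyperpriors: Normal(0, variance 1000)
    on non-detection community means, Uniform(0, 1) on the inverse-logit of
    detection-intercept means (a standard-logistic density on the logit scale),
    and Uniform(0, 10) on every sd.  Returns -inf outside the support.
    """
    for name in PARAM_NAMES:
        if not (0.0 < hyper.sd(name) <= SD_UPPER):
            return -np.inf
    if not (0.0 < re.sigma_s <= SD_UPPER and 0.0 < re.sigma_m <= SD_UPPER):
        return -np.inf
    lp = 0.0
    for name in PARAM_NAMES:
        lp += _normal_logpdf(params.get(name), hyper.mu(name), hyper.sd(name)).sum()
        if name in DETECTION_INTERCEPTS:
            pre = expit(hyper.mu(name))
            if not (0.0 < pre < 1.0):
                return -np.inf
            lp += logistic_logpdf(hyper.mu(name))
        else:
            lp += float(_normal_logpdf(hyper.mu(name), 0.0, math.sqrt(HYPERMEAN_PRIOR_VAR)))
    lp += _normal_logpdf(re.s, 0.0, re.sigma_s).sum()
    lp += _normal_logpdf(re.m, 0.0, re.sigma_m).sum()
    # Uniform(0, 10) on the 7 community sds and the 2 random-effect sds
    lp += -9.0 * math.log(SD_UPPER)
    return float(lp)
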