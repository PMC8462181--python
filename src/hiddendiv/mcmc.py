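"""Metropolis-within-Gibbs sampler for the multispecies N-mixture model.

Each sweep updates, in fixed order: the latent abundances ``N_ik`` (symmetric
integer random walk on the truncated support), the seven species-coefficient
vectors (vectorised random-walk Metropolis, one independent accept/reject per
species, valid because species are conditionally independent given the
community hyperparameters and random effects), the sampling-unit and
sampling-month random effects (per-group accepts), and the community
hyperparameters.  Community means of non-detection blocks are conjugate
normal draws; detection-intercept means carry the exact logistic prior
implied by a Uniform(0, 1) prior on their inverse-logit and use a random
walk; every standard deviation has a Uniform(0, 10) prior and is drawn by
exact truncated inverse-gamma Gibbs on the variance.

Proposal scales adapt during burn-in only (target acceptance 0.2-0.5) and are
frozen afterwards, keeping the retained chain a valid Markov chain.  A fixed
seed fully determines the draw sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import gamma as _gamma_dist

from .model import (
    DETECTION_INTERCEPTS,
    HYPERMEAN_PRIOR_VAR,
    PARAM_NAMES,
    SD_UPPER,
    CommunityHyperparams,
    DetectionHistory,
    RandomEffects,
    SiteDesign,
    SpeciesParams,
    joint_loglik,
    log_prior,
    logistic_logpdf,
)

__all__ = ["MCMCConfig", "PosteriorDraws", "retained_samples", "fit_model", "rhat",
           "posterior_abundance_matrices"]

_NON_DETECTION_MEANS = tuple(n for n in PARAM_NAMES if n not in DETECTION_INTERCEPTS)
_N_STEPS = np.array([1, 2, 5, -1, -2, -5])


@dataclass(frozen=True)
class MCMCConfig:
    """Chain bookkeeping and proposal configuration.

    ``fixed`` names blocks held at their initial values and never updated
    (any of the seven species-parameter names, ``"s"``, ``"m"``,
    ``"sigma_s"``, ``"sigma_m"``, ``"mu"``, ``"sd"``).  ``init`` optionally
    overrides initial values by the same names (plus ``"mu_<block>"``,
    ``"sd_<block>"`` and ``"N"``).
    """

    n_chains: int = 3
    n_iter: int = 150_000
    n_burn: int = 50_000
    thin: int = 100
    seed: int = 0
    proposal_scale: float = 0.1
    Nmax_buffer: int = 100
    adapt: bool = True
    fixed: frozenset = frozenset()
    init: dict | None = None

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("n_chains, n_iter and thin must be positive")
        if self.n_burn < 0 or self.n_burn >= self.n_iter:
            raise ValueError("n_burn must satisfy 0 <= n_burn < n_iter")
        if self.Nmax_buffer < 1:
            raise ValueError("Nmax_buffer must be positive")
        object.__setattr__(self, "fixed", frozenset(self.fixed))


def retained_samples(config: MCMCConfig) -> int:
    """Total retained draws: n_chains * floor((n_iter - n_burn) / thin)."""
    return config.n_chains * ((config.n_iter - config.n_burn) // config.thin)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (n_chains, n_retained, ...) per block."""

    species: dict            # name -> (C, R, K)
    s: np.ndarray            # (C, R, n_su)
    m: np.ndarray            # (C, R, n_sm)
    sigma_s: np.ndarray      # (C, R)
    sigma_m: np.ndarray      # (C, R)
    mu: dict                 # name -> (C, R)
    sd: dict                 # name -> (C, R)
    N: np.ndarray            # (C, R, I, K) int
    config: MCMCConfig
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.N.shape[0]

    @property
    def n_retained_per_chain(self) -> int:
        return self.N.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_retained_per_chain

    def community_names(self) -> list[str]:
        names = [f"mu_{n}" for n in PARAM_NAMES] + [f"sd_{n}" for n in PARAM_NAMES]
        return names + ["sigma_s", "sigma_m"]

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_retained) trace for a scalar parameter name.

        Accepts ``mu_*``/``sd_*``/``sigma_*``, ``beta_can[3]``-style species
        entries, ``s[0]``/``m[2]`` random effects and ``N[i,k]`` cells.
        """
        if name in ("sigma_s", "sigma_m"):
            return getattr(self, name)
        if name.startswith("mu_"):
            return self.mu[name[3:]]
        if name.startswith("sd_"):
            return self.sd[name[3:]]
        if "[" in name and name.endswith("]"):
            base, idx = name[:-1].split("[", 1)
            if base == "N":
                i, k = (int(v) for v in idx.split(","))
                return self.N[:, :, i, k]
            ix = int(idx)
            if base in ("s", "m"):
                return getattr(self, base)[:, :, ix]
            return self.species[base][:, :, ix]
        raise KeyError(f"unknown parameter name {name!r}")

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, 1-d."""
        return self.get(name).reshape(-1)

    def summary(self, names=None, level: float = 0.95):
        """Posterior mean/sd/credible interval (and R-hat when >= 2 chains)."""
        import pandas as pd

        names = list(names) if names is not None else self.community_names()
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        rows = []
        for name in names:
            tr = self.get(name)
            pooled = tr.reshape(-1)
            row = {
                "parameter": name,
                "mean": pooled.mean(),
                "sd": pooled.std(ddof=1),
                "lo": np.quantile(pooled, lo_q),
                "hi": np.quantile(pooled, hi_q),
            }
            if self.n_chains >= 2 and tr.shape[1] >= 2:
                row["rhat"] = rhat(self, name)
            rows.append(row)
        return pd.DataFrame(rows)


def rhat(draws: PosteriorDraws, name: str, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    Classic (non-split) form by default: with m chains of length n,
    W = mean within-chain variance, B/n = variance of chain means, and
    R-hat = sqrt(((n-1)/n W + B/n) / W).  ``split=True`` halves each chain
    first.  Chains that agree exactly (zero variance everywhere) report 1.0.
    """
    tr = draws.get(name) if isinstance(draws, PosteriorDraws) else np.asarray(draws, dtype=float)
    return rhat_from_chains(tr, split=split)


def rhat_from_chains(chains: np.ndarray, split: bool = False) -> float:
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-d (chain, draw)")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 2:
        raise ValueError("R-hat requires at least 2 draws per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else math.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(math.sqrt(var_hat / W))


def posterior_abundance_matrices(draws: PosteriorDraws) -> np.ndarray:
    """All retained latent-abundance matrices, shape (n_draws, n_sites, n_species).

    Order is chain-major and stable: chain 0 draws first, in retained order.
    """
    c, r, i, k = draws.N.shape
    return draws.N.reshape(c * r, i, k)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _truncated_invgamma_sd(rng, shape_a: float, scale_b: float, current: float) -> float:
    """Draw sd with p(sd^2) = InvGamma(a, b) truncated to sd < SD_UPPER.

    Exact Gibbs step for a Uniform(0, SD_UPPER) sd prior with normal
    observations.  Rejection sampling with an inverse-CDF fallback for the
    (rare) heavy-truncation case; degenerate inputs keep the current value.
    """
    if scale_b < 1e-12 or shape_a <= 0:
        return current
    lo = scale_b / SD_UPPER**2  # need Gamma draw g > lo so that sd = sqrt(b/g) < upper
    for _ in range(50):
        g = rng.standard_gamma(shape_a)
        if g > lo:
            return math.sqrt(scale_b / g)
    cdf_lo = _gamma_dist.cdf(lo, shape_a)
    u = cdf_lo + (1.0 - cdf_lo) * rng.random()
    g = _gamma_dist.ppf(min(u, 1.0 - 1e-16), shape_a)
    return math.sqrt(scale_b / g)


class _ChainState:
    """Mutable per-chain state with cached linear predictors."""

    def __init__(self, y: DetectionHistory, design: SiteDesign, config: MCMCConfig, rng):
        self.y = y
        self.design = design
        self.config = config
        self.rng = rng
        I, J, K = y.n_sites, y.n_occasions, y.n_species
        self.I, self.J, self.K = I, J, K
        self.mask = y.occasion_mask()
        self.mask3 = self.mask[:, :, None]
        self.nj = self.mask.sum(axis=1)  # surveyed occasions per site
        self.maxy = y.max_counts()
        self.Nmax = self.maxy + config.Nmax_buffer

        # covariates per block
        strata = design.strata.astype(float)
        self.x_beta = {
            "beta_can": 1.0 - strata,
            "beta_und": strata,
            "beta1": design.temp_site.astype(float),
        }
        self.x_alpha = {
            "alpha_can": np.broadcast_to((1.0 - strata)[:, None], (I, J)).copy(),
            "alpha_und": np.broadcast_to(strata[:, None], (I, J)).copy(),
            "alpha1": design.date_obs,
            "alpha2": design.temp_obs,
        }
        # constant: sum over surveyed (i, j) of y * x, per alpha block
        self.yx = {
            b: np.einsum("ijk,ij->k", y.y * self.mask3, x) for b, x in self.x_alpha.items()
        }

        # constant enumeration grids over the truncated latent support, reused
        # by the exact N Gibbs draw and the collapsed (marginalised) moves
        B = config.Nmax_buffer
        self.Ngrid = self.maxy[:, :, None] + np.arange(B + 1)        # (I, K, B+1)
        self.glg_grid = gammaln(self.Ngrid + 1.0)
        diff = self.Ngrid[:, None, :, :] - y.y[:, :, :, None]        # (I, J, K, B+1)
        self.glgy_grid = np.einsum("ijkb,ij->ikb", gammaln(diff + 1.0),
                                   self.mask.astype(float))
        del diff
        self.const_y = np.einsum("ijk,ij->ik", gammaln(y.y + 1.0),
                                 self.mask.astype(float))

        self._init_state()
        self._refresh_caches()

        # proposal scales (elementwise) and acceptance bookkeeping
        ps = config.proposal_scale
        self.scales = {b: np.full(K, ps) for b in PARAM_NAMES}
        self.scales["s"] = np.full(design.n_su, ps * 2)
        self.scales["m"] = np.full(design.n_sm, ps * 2)
        self.scales["mu_alpha_can"] = np.full(1, ps * 2)
        self.scales["mu_alpha_und"] = np.full(1, ps * 2)
        for b in PARAM_NAMES:
            self.scales[f"nc_{b}"] = np.full(1, ps * 2)
        for b in ("beta_can", "beta_und", "alpha_can", "alpha_und"):
            self.scales[f"cs_{b}"] = np.full(1, ps * 3)
        for b in PARAM_NAMES:
            self.scales[f"sc_{b}"] = np.full(1, ps * 3)
        self.acc = {k: np.zeros_like(v) for k, v in self.scales.items()}
        self.block_tries = {k: 0 for k in self.scales}
        self.tries = 0

    # -- initialisation ----------------------------------------------------

    def _init_state(self):
        rng, K = self.rng, self.K
        mean_count = np.where(self.mask3, self.y.y, 0).sum(axis=(0, 1)) / np.maximum(
            self.nj.sum(), 1
        )
        b0 = np.log(np.maximum(mean_count, 0.1))
        self.params = {
            "beta_can": b0 + 0.3 * rng.standard_normal(K),
            "beta_und": b0 + 0.3 * rng.standard_normal(K),
            "beta1": 0.2 * rng.standard_normal(K),
            "alpha_can": 0.3 * rng.standard_normal(K) - 0.5,
            "alpha_und": 0.3 * rng.standard_normal(K) - 0.5,
            "alpha1": 0.2 * rng.standard_normal(K),
            "alpha2": 0.2 * rng.standard_normal(K),
        }
        self.s = 0.1 * rng.standard_normal(self.design.n_su)
        self.m = 0.1 * rng.standard_normal(self.design.n_sm)
        self.sigma_s = float(np.clip(math.exp(0.3 * rng.standard_normal()), 0.05, 5.0))
        self.sigma_m = float(np.clip(math.exp(0.3 * rng.standard_normal()), 0.05, 5.0))
        self.mu = {b: float(self.params[b].mean()) for b in PARAM_NAMES}
        self.sd = {b: 1.0 for b in PARAM_NAMES}
        self.N = self.maxy + 1

        init = self.config.init or {}
        for key, val in init.items():
            if key in PARAM_NAMES:
                self.params[key] = np.asarray(val, dtype=float).copy()
            elif key in ("s", "m"):
                setattr(self, key, np.asarray(val, dtype=float).copy())
            elif key in ("sigma_s", "sigma_m"):
                setattr(self, key, float(val))
            elif key.startswith("mu_"):
                self.mu[key[3:]] = float(val)
            elif key.startswith("sd_"):
                self.sd[key[3:]] = float(val)
            elif key == "N":
                N = np.asarray(val, dtype=np.int64).copy()
                if np.any(N < self.maxy):
                    raise ValueError("initial N below observed maximum counts")
                self.N = N
            else:
                raise KeyError(f"unknown init key {key!r}")

    def _refresh_caches(self):
        d = self.design
        self.loglam = (
            np.outer(self.x_beta["beta_can"], self.params["beta_can"])
            + np.outer(self.x_beta["beta_und"], self.params["beta_und"])
            + np.outer(self.x_beta["beta1"], self.params["beta1"])
            + (self.s[d.group_su] + self.m[d.group_sm])[:, None]
        )
        self.lam = np.exp(self.loglam)
        self.eta = (
            self.x_alpha["alpha_can"][:, :, None] * self.params["alpha_can"]
            + self.x_alpha["alpha_und"][:, :, None] * self.params["alpha_und"]
            + self.x_alpha["alpha1"][:, :, None] * self.params["alpha1"]
            + self.x_alpha["alpha2"][:, :, None] * self.params["alpha2"]
        )
        self.sp = np.logaddexp(0.0, self.eta)
        self.spsum = np.einsum("ijk,ij->ik", self.sp, self.mask.astype(float))
        self.glN = gammaln(self.N + 1.0)
        self.glNy = np.einsum(
            "ijk,ij->ik", gammaln(np.maximum(self.N[:, None, :] - self.y.y, 0) + 1.0),
            self.mask.astype(float),
        )

    # -- snapshot helpers --------------------------------------------------

    def species_params(self) -> SpeciesParams:
        return SpeciesParams(**{b: self.params[b].copy() for b in PARAM_NAMES})

    def random_effects(self) -> RandomEffects:
        return RandomEffects(self.s.copy(), self.m.copy(), self.sigma_s, self.sigma_m)

    def hyper(self) -> CommunityHyperparams:
        kw = {f"mu_{b}": self.mu[b] for b in PARAM_NAMES}
        kw.update({f"sd_{b}": min(self.sd[b], SD_UPPER) for b in PARAM_NAMES})
        return CommunityHyperparams(**kw)

    # -- update blocks -----------------------------------------------------

    def update_N(self):
        rng = self.rng
        steps = _N_STEPS[rng.integers(0, len(_N_STEPS), size=(self.I, self.K))]
        prop = self.N + steps
        valid = (prop >= self.maxy) & (prop <= self.Nmax)
        prop_safe = np.where(valid, prop, self.N)
        glP = gammaln(prop_safe + 1.0)
        glPy = np.einsum(
            "ijk,ij->ik",
            gammaln(np.maximum(prop_safe[:, None, :] - self.y.y, 0) + 1.0),
            self.mask.astype(float),
        )
        d = (prop_safe - self.N).astype(float)
        dgl = glP - self.glN
        delta = (
            d * self.loglam - dgl                       # Poisson
            + self.nj[:, None] * dgl - (glPy - self.glNy) - d * self.spsum  # Binomial
        )
        accept = valid & (np.log(rng.random(size=delta.shape)) < delta)
        if accept.any():
            self.N = np.where(accept, prop_safe, self.N)
            self.glN = np.where(accept, glP, self.glN)
            self.glNy = np.where(accept, glPy, self.glNy)

    def _latent_logweights(self, loglam, spsum):
        """Unnormalised log conditional of N over the support grid, (I, K, B+1)."""
        return (
            self.Ngrid * (loglam - spsum)[:, :, None]
            + (self.nj[:, None, None] - 1.0) * self.glg_grid
            - self.glgy_grid
        )

    def _marginal_loglik(self, loglam, lam, spsum, yeta) -> float:
        """Log-likelihood with N summed out over the truncated support (all cells)."""
        logw = self._latent_logweights(loglam, spsum)
        m = logw.max(axis=2)
        logz = m + np.log(np.exp(logw - m[:, :, None]).sum(axis=2))
        return float((logz - lam - self.const_y + yeta).sum())

    def update_N_gibbs(self):
        """Exact draw of every N_ik from its enumerated full conditional.

        The conditional over the truncated support [max_j y, Nmax] is a
        finite categorical with log-weights
        N (loglam - sum_j softplus(eta)) + (n_j - 1) lgamma(N+1)
        - sum_j lgamma(N - y_j + 1); enumerating it decorrelates the latent
        abundances from the abundance/detection coefficients far faster than
        the random walk alone.
        """
        logw = self._latent_logweights(self.loglam, self.spsum)
        logw -= logw.max(axis=2, keepdims=True)
        w = np.exp(logw)
        cum = np.cumsum(w, axis=2)
        u = self.rng.random(size=self.maxy.shape)[:, :, None] * cum[:, :, -1:]
        idx = (cum < u).sum(axis=2)
        self.N = self.maxy + idx
        self.glN = gammaln(self.N + 1.0)
        self.glNy = np.einsum(
            "ijk,ij->ik",
            gammaln(np.maximum(self.N[:, None, :] - self.y.y, 0) + 1.0),
            self.mask.astype(float),
        )

    def update_beta_block(self, name: str):
        rng = self.rng
        d = self.scales[name] * rng.standard_normal(self.K)
        x = self.x_beta[name]
        shift = np.outer(x, d)
        E = np.exp(shift)
        Nx = (self.N * x[:, None]).sum(axis=0)
        dll = Nx * d - (self.lam * (E - 1.0)).sum(axis=0)
        p, mu, sd = self.params[name], self.mu[name], self.sd[name]
        dpr = -(((p + d - mu) ** 2) - ((p - mu) ** 2)) / (2.0 * sd * sd)
        accept = np.log(rng.random(self.K)) < dll + dpr
        if accept.any():
            self.params[name] = np.where(accept, p + d, p)
            self.loglam[:, accept] += shift[:, accept]
            self.lam[:, accept] *= E[:, accept]
        self.acc[name] += accept
        self.block_tries[name] += 1

    def update_alpha_block(self, name: str):
        rng = self.rng
        d = self.scales[name] * rng.standard_normal(self.K)
        x = self.x_alpha[name]
        eta_new = self.eta + x[:, :, None] * d
        sp_new = np.logaddexp(0.0, eta_new)
        dll = self.yx[name] * d - np.einsum(
            "ijk,ij->k", (sp_new - self.sp) * self.N[:, None, :], self.mask.astype(float)
        )
        p, mu, sd = self.params[name], self.mu[name], self.sd[name]
        dpr = -(((p + d - mu) ** 2) - ((p - mu) ** 2)) / (2.0 * sd * sd)
        accept = np.log(rng.random(self.K)) < dll + dpr
        if accept.any():
            self.params[name] = np.where(accept, p + d, p)
            self.eta[:, :, accept] = eta_new[:, :, accept]
            self.sp[:, :, accept] = sp_new[:, :, accept]
            self.spsum[:, accept] = np.einsum(
                "ijk,ij->ik", self.sp[:, :, accept], self.mask.astype(float)
            )
        self.acc[name] += accept
        self.block_tries[name] += 1

    def _update_random_effect(self, which: str):
        rng = self.rng
        vals = getattr(self, which)
        group = self.design.group_su if which == "s" else self.design.group_sm
        sigma = self.sigma_s if which == "s" else self.sigma_m
        n_groups = vals.shape[0]
        d = self.scales[which] * rng.standard_normal(n_groups)
        delta_site = d[group]
        Nrow = self.N.sum(axis=1)
        lamrow = self.lam.sum(axis=1)
        dll_site = Nrow * delta_site - lamrow * np.expm1(delta_site)
        dll = np.bincount(group, weights=dll_site, minlength=n_groups)
        dpr = -(((vals + d) ** 2) - vals**2) / (2.0 * sigma * sigma)
        accept = np.log(rng.random(n_groups)) < dll + dpr
        if accept.any():
            setattr(self, which, np.where(accept, vals + d, vals))
            acc_site = accept[group]
            self.loglam[acc_site] += delta_site[acc_site][:, None]
            self.lam[acc_site] *= np.exp(delta_site[acc_site])[:, None]
        self.acc[which] += accept
        self.block_tries[which] += 1

    def update_random_effect_sds(self):
        fixed = self.config.fixed
        if "sigma_s" not in fixed:
            self.sigma_s = _truncated_invgamma_sd(
                self.rng, (self.s.shape[0] - 1) / 2.0, (self.s**2).sum() / 2.0, self.sigma_s
            )
        if "sigma_m" not in fixed:
            self.sigma_m = _truncated_invgamma_sd(
                self.rng, (self.m.shape[0] - 1) / 2.0, (self.m**2).sum() / 2.0, self.sigma_m
            )

    def update_recenter(self, which: str):
        """Exact Gibbs move along the intercept / random-effect translation ridge.

        The likelihood is invariant to adding d to both abundance intercepts
        (and their community means) while subtracting d from every random
        effect in one block, so the conditional of d involves only the
        random-effect prior and the vague hypermean prior and is Gaussian.
        Fixed linear bijection with unit Jacobian; a standard
        non-centered/centered interchange that removes the slow ridge walk.
        """
        rng = self.rng
        vals = getattr(self, which)
        sigma = self.sigma_s if which == "s" else self.sigma_m
        G = vals.shape[0]
        prec = G / sigma**2 + 2.0 / HYPERMEAN_PRIOR_VAR
        mean = (vals.sum() / sigma**2
                - (self.mu["beta_can"] + self.mu["beta_und"]) / HYPERMEAN_PRIOR_VAR) / prec
        d = mean + math.sqrt(1.0 / prec) * rng.standard_normal()
        self.params["beta_can"] = self.params["beta_can"] + d
        self.params["beta_und"] = self.params["beta_und"] + d
        self.mu["beta_can"] += d
        self.mu["beta_und"] += d
        setattr(self, which, vals - d)
        # loglam and lam are exactly invariant under this move

    def update_hyper_means(self):
        rng, K = self.rng, self.K
        for name in _NON_DETECTION_MEANS:
            x, sd = self.params[name], self.sd[name]
            v = 1.0 / (K / sd**2 + 1.0 / HYPERMEAN_PRIOR_VAR)
            mean = v * x.sum() / sd**2
            self.mu[name] = mean + math.sqrt(v) * rng.standard_normal()
        for name in DETECTION_INTERCEPTS:
            key = f"mu_{name}"
            x, mu, sd = self.params[name], self.mu[name], self.sd[name]
            d = float(self.scales[key][0] * rng.standard_normal())
            mu_new = mu + d
            dll = -(((x - mu_new) ** 2).sum() - ((x - mu) ** 2).sum()) / (2.0 * sd * sd)
            dpr = logistic_logpdf(mu_new) - logistic_logpdf(mu)
            if math.log(rng.random()) < dll + dpr:
                self.mu[name] = mu_new
                self.acc[key] += 1
            self.block_tries[key] += 1

    def update_hyper_sds(self):
        rng, K = self.rng, self.K
        for name in PARAM_NAMES:
            x, mu = self.params[name], self.mu[name]
            b = ((x - mu) ** 2).sum() / 2.0
            self.sd[name] = min(
                _truncated_invgamma_sd(rng, (K - 1) / 2.0, b, self.sd[name]), SD_UPPER
            )

    def update_collapsed_shift(self, name: str, cur: float, yeta):
        """Marginalised translation of one intercept block plus its community mean.

        Proposes theta_k += d for every species together with mu += d, accepts
        against the likelihood with N summed out (the N proposal drawn from
        its exact conditional under the shifted parameters cancels from the
        ratio), then redraws N by enumeration Gibbs.  This crosses the
        abundance/detection trade-off ridge that conditional-on-N updates walk
        slowly, because the marginal likelihood is far flatter than the
        conditional.
        """
        rng = self.rng
        self.block_tries[f"cs_{name}"] += 1
        d = float(self.scales[f"cs_{name}"][0] * rng.standard_normal())
        mu_new = self.mu[name] + d
        if name in DETECTION_INTERCEPTS:
            dpr = logistic_logpdf(mu_new) - logistic_logpdf(self.mu[name])
        else:
            dpr = -(mu_new**2 - self.mu[name]**2) / (2.0 * HYPERMEAN_PRIOR_VAR)
        if name.startswith("beta"):
            x = self.x_beta[name]
            loglam_new = self.loglam + x[:, None] * d
            lam_new = np.exp(loglam_new)
            new = self._marginal_loglik(loglam_new, lam_new, self.spsum, yeta)
            if math.log(rng.random()) < new - cur + dpr:
                self.params[name] = self.params[name] + d
                self.mu[name] = mu_new
                self.loglam, self.lam = loglam_new, lam_new
                self.acc[f"cs_{name}"] += 1
                return new, yeta, True
        else:
            x = self.x_alpha[name]
            eta_new = self.eta + x[:, :, None] * d
            sp_new = np.logaddexp(0.0, eta_new)
            spsum_new = np.einsum("ijk,ij->ik", sp_new, self.mask.astype(float))
            yeta_new = np.einsum("ijk,ijk->ik", (self.y.y * self.mask3).astype(float),
                                 eta_new)
            new = self._marginal_loglik(self.loglam, self.lam, spsum_new, yeta_new)
            if math.log(rng.random()) < new - cur + dpr:
                self.params[name] = self.params[name] + d
                self.mu[name] = mu_new
                self.eta, self.sp, self.spsum = eta_new, sp_new, spsum_new
                self.acc[f"cs_{name}"] += 1
                return new, yeta_new, True
        return cur, yeta, False

    def update_collapsed_scale(self, name: str, cur: float, yeta):
        """Marginalised rescaling of one block's spread: sd' = c sd, theta' = mu + c(theta - mu).

        A log-random-walk on the block sd in non-centered coordinates
        (z fixed), accepted against the likelihood with N summed out and with
        the log-scale Hastings factor sd'/sd; N is redrawn exactly on
        acceptance.  Complements the translation move: together they let the
        chain traverse the hierarchical funnel of weakly-informed blocks
        without waiting on per-species random walks.
        """
        rng = self.rng
        self.block_tries[f"sc_{name}"] += 1
        c = math.exp(float(self.scales[f"sc_{name}"][0] * rng.standard_normal()))
        sd_new = self.sd[name] * c
        if not (0.0 < sd_new <= SD_UPPER):
            return cur, yeta, False
        p, mu = self.params[name], self.mu[name]
        d = (c - 1.0) * (p - mu)
        dpr = math.log(c)  # Hastings factor for the log-scale random walk
        if name.startswith("beta"):
            x = self.x_beta[name]
            loglam_new = self.loglam + x[:, None] * d
            lam_new = np.exp(loglam_new)
            new = self._marginal_loglik(loglam_new, lam_new, self.spsum, yeta)
            if math.log(rng.random()) < new - cur + dpr:
                self.params[name] = p + d
                self.sd[name] = sd_new
                self.loglam, self.lam = loglam_new, lam_new
                self.acc[f"sc_{name}"] += 1
                return new, yeta, True
        else:
            x = self.x_alpha[name]
            eta_new = self.eta + x[:, :, None] * d
            sp_new = np.logaddexp(0.0, eta_new)
            spsum_new = np.einsum("ijk,ij->ik", sp_new, self.mask.astype(float))
            yeta_new = np.einsum("ijk,ijk->ik", (self.y.y * self.mask3).astype(float),
                                 eta_new)
            new = self._marginal_loglik(self.loglam, self.lam, spsum_new, yeta_new)
            if math.log(rng.random()) < new - cur + dpr:
                self.params[name] = p + d
                self.sd[name] = sd_new
                self.eta, self.sp, self.spsum = eta_new, sp_new, spsum_new
                self.acc[f"sc_{name}"] += 1
                return new, yeta_new, True
        return cur, yeta, False

    def update_noncentered(self, name: str):
        """Interweaved non-centered update of (mu, sd) for one species block.

        With z_k = (theta_k - mu)/sd held fixed, the target in (mu, sd, z)
        coordinates is prior(mu) prior(sd) prod phi(z_k) L(mu + sd z), so a
        joint random-walk proposal on (mu, sd) rescales the whole species
        vector and crosses the hierarchical funnel that blocks centered
        updates when species-level information is weak.
        """
        rng = self.rng
        p, mu, sd = self.params[name], self.mu[name], self.sd[name]
        scale = float(self.scales[f"nc_{name}"][0])
        self.block_tries[f"nc_{name}"] += 1
        mu_new = mu + scale * rng.standard_normal()
        sd_new = sd + 0.5 * scale * rng.standard_normal()
        if not (0.0 < sd_new <= SD_UPPER):
            return
        z = (p - mu) / sd
        p_new = mu_new + sd_new * z
        d = p_new - p
        if name in DETECTION_INTERCEPTS:
            dpr = logistic_logpdf(mu_new) - logistic_logpdf(mu)
        else:
            dpr = -(mu_new**2 - mu**2) / (2.0 * HYPERMEAN_PRIOR_VAR)
        if name.startswith("beta"):
            x = self.x_beta[name]
            shift = np.outer(x, d)
            E = np.exp(shift)
            dll = float((self.N * shift).sum() - (self.lam * (E - 1.0)).sum())
            if math.log(rng.random()) < dll + dpr:
                self.params[name] = p_new
                self.mu[name], self.sd[name] = mu_new, sd_new
                self.loglam += shift
                self.lam *= E
                self.acc[f"nc_{name}"] += 1
        else:
            x = self.x_alpha[name]
            eta_new = self.eta + x[:, :, None] * d
            sp_new = np.logaddexp(0.0, eta_new)
            dll = float((self.yx[name] * d).sum() - np.einsum(
                "ijk,ij->", (sp_new - self.sp) * self.N[:, None, :], self.mask.astype(float)
            ))
            if math.log(rng.random()) < dll + dpr:
                self.params[name] = p_new
                self.mu[name], self.sd[name] = mu_new, sd_new
                self.eta = eta_new
                self.sp = sp_new
                self.spsum = np.einsum("ijk,ij->ik", sp_new, self.mask.astype(float))
                self.acc[f"nc_{name}"] += 1

    # -- one sweep ---------------------------------------------------------

    def sweep(self):
        fixed = self.config.fixed
        if self.tries % 5 == 4:
            self.update_N_gibbs()
        else:
            self.update_N()
        for name in ("beta_can", "beta_und", "beta1"):
            if name not in fixed:
                self.update_beta_block(name)
        for name in ("alpha_can", "alpha_und", "alpha1", "alpha2"):
            if name not in fixed:
                self.update_alpha_block(name)
        if "s" not in fixed:
            self._update_random_effect("s")
        if "m" not in fixed:
            self._update_random_effect("m")
        recenter_ok = not ({"beta_can", "beta_und", "mu"} & fixed)
        if recenter_ok and "s" not in fixed:
            self.update_recenter("s")
        if recenter_ok and "m" not in fixed:
            self.update_recenter("m")
        if not {"sigma_s", "sigma_m"} <= fixed:
            self.update_random_effect_sds()
        if "mu" not in fixed:
            self.update_hyper_means()
        if "sd" not in fixed:
            self.update_hyper_sds()
        if not {"mu", "sd"} & fixed:
            for _ in range(2):
                for name in PARAM_NAMES:
                    if name not in fixed:
                        self.update_noncentered(name)
        # collapsed (marginalised) moves share one running marginal loglik;
        # the marginal does not involve N, so N is redrawn once at the end
        do_shift = "mu" not in fixed
        do_scale = "sd" not in fixed
        if do_shift or do_scale:
            yeta = np.einsum("ijk,ijk->ik", (self.y.y * self.mask3).astype(float),
                             self.eta)
            cur = self._marginal_loglik(self.loglam, self.lam, self.spsum, yeta)
            any_accept = False
            if do_shift:
                for name in ("beta_can", "beta_und", "alpha_can", "alpha_und"):
                    if name not in fixed:
                        cur, yeta, acc = self.update_collapsed_shift(name, cur, yeta)
                        any_accept |= acc
            if do_scale:
                for name in PARAM_NAMES:
                    if name not in fixed:
                        cur, yeta, acc = self.update_collapsed_scale(name, cur, yeta)
                        any_accept |= acc
            if any_accept:
                self.update_N_gibbs()
        self.tries += 1

    def adapt_scales(self, window: int):
        for key, counts in self.acc.items():
            tries = self.block_tries[key]
            if tries == 0:
                continue
            rate = counts / tries
            self.scales[key] *= np.exp(0.4 * (rate - 0.35))
            np.clip(self.scales[key], 1e-3, 10.0, out=self.scales[key])
            counts[:] = 0.0
            self.block_tries[key] = 0


def fit_model(y: DetectionHistory, design: SiteDesign, config: MCMCConfig) -> PosteriorDraws:
    """Fit the N-mixture model by MCMC and return retained draws only.

    Raises if the log posterior is non-finite at initialisation.
    """
    if design.n_sites != y.n_sites or design.n_occasions != y.n_occasions:
        raise ValueError("design and detection history dimensions disagree")
    n_ret = (config.n_iter - config.n_burn) // config.thin
    if n_ret < 1:
        raise ValueError("configuration retains no draws; increase n_iter or lower thin")
    C, I, J, K = config.n_chains, y.n_sites, y.n_occasions, y.n_species

    species = {b: np.empty((C, n_ret, K)) for b in PARAM_NAMES}
    s_draws = np.empty((C, n_ret, 0))
    m_draws = np.empty((C, n_ret, 0))
    sigma_s = np.empty((C, n_ret))
    sigma_m = np.empty((C, n_ret))
    mu = {b: np.empty((C, n_ret)) for b in PARAM_NAMES}
    sd = {b: np.empty((C, n_ret)) for b in PARAM_NAMES}
    N_draws = np.empty((C, n_ret, I, K), dtype=np.int32)

    child_seeds = np.random.SeedSequence(config.seed).spawn(C)
    accept_rates = {}
    window = 50
    for c in range(C):
        rng = np.random.default_rng(child_seeds[c])
        state = _ChainState(y, design, config, rng)
        if c == 0:
            s_draws = np.empty((C, n_ret, design.n_su))
            m_draws = np.empty((C, n_ret, design.n_sm))
        lp0 = joint_loglik(y, state.N, state.species_params(), state.random_effects(), design)
        lp0 += log_prior(state.species_params(), state.random_effects(), state.hyper())
        if not math.isfinite(lp0):
            raise ValueError("non-finite log posterior at initialisation")
        r = 0
        for it in range(1, config.n_iter + 1):
            state.sweep()
            if config.adapt and it <= config.n_burn and it % window == 0:
                state.adapt_scales(window)
            if it > config.n_burn and (it - config.n_burn) % config.thin == 0:
                for b in PARAM_NAMES:
                    species[b][c, r] = state.params[b]
                    mu[b][c, r] = state.mu[b]
                    sd[b][c, r] = state.sd[b]
                s_draws[c, r] = state.s
                m_draws[c, r] = state.m
                sigma_s[c, r] = state.sigma_s
                sigma_m[c, r] = state.sigma_m
                N_draws[c, r] = state.N
                r += 1
        accept_rates[f"chain{c}"] = {
            k: float(np.mean(v)) / max(state.block_tries[k], 1)
            for k, v in state.acc.items()
        }
    return PosteriorDraws(
        species=species, s=s_draws, m=m_draws, sigma_s=sigma_s, sigma_m=sigma_m,
        mu=mu, sd=sd, N=N_draws, config=config, accept_rates=accept_rates,
    )
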