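"""Metacommunity simulation under the N-mixture model and parameter recovery.

The validation design varies one community hyperparameter at a time — the
canopy or understory abundance mean, or the canopy or understory detection
mean — over three levels (low, intermediate, high) while all other
hyperparameters stay at their constants, giving a 4 x 3 grid of 12 simulated
metacommunities coded A to L.  Each simulation draws species coefficients
from the community hyperdistributions, assembles expected abundance and
detection probability exactly as the model does, draws true abundances
N ~ Poisson(lambda) and observed counts y ~ Binomial(N, p), and keeps the
truth alongside the observed detection history for recovery checks.

The default grid levels are ln(0.5)/ln(2)/ln(8) for abundance means and
logit(0.1)/logit(0.3)/logit(0.6) for detection means; they are configurable
and not claimed to reproduce any particular published grid.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .model import (
    PARAM_NAMES,
    CommunityHyperparams,
    DetectionHistory,
    RandomEffects,
    SiteDesign,
    SpeciesParams,
    detection_logit_matrix,
    expected_abundance_matrix,
)

__all__ = [
    "SimulationSetting",
    "SimulatedMetacommunity",
    "DEFAULT_LEVELS",
    "DEFAULT_CONSTANTS",
    "build_setting_grid",
    "default_design",
    "simulate_metacommunity",
    "recovery_check",
    "coverage",
    "sampling_effort",
]

#: hyperparameters varied in the validation grid, in canonical (code) order
VARIED_PARAMETERS = ("mu_beta_can", "mu_beta_und", "mu_alpha_can", "mu_alpha_und")
LEVEL_NAMES = ("low", "intermediate", "high")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


DEFAULT_LEVELS = {
    "mu_beta_can": (math.log(0.5), math.log(2.0), math.log(8.0)),
    "mu_beta_und": (math.log(0.5), math.log(2.0), math.log(8.0)),
    "mu_alpha_can": (_logit(0.1), _logit(0.3), _logit(0.6)),
    "mu_alpha_und": (_logit(0.1), _logit(0.3), _logit(0.6)),
}

#: hyperparameters held constant when not varied: intermediate means, modest
#: species heterogeneity, no community-mean covariate effects
DEFAULT_CONSTANTS = CommunityHyperparams(
    mu_beta_can=math.log(2.0),
    mu_beta_und=math.log(2.0),
    mu_beta1=0.25,
    mu_alpha_can=_logit(0.3),
    mu_alpha_und=_logit(0.3),
    mu_alpha1=0.0,
    mu_alpha2=0.0,
    sd_beta_can=0.5,
    sd_beta_und=0.5,
    sd_beta1=0.25,
    sd_alpha_can=0.5,
    sd_alpha_und=0.5,
    sd_alpha1=0.25,
    sd_alpha2=0.25,
)

#: true random-effect sds used by the default simulations
DEFAULT_SIGMA_S = 0.25
DEFAULT_SIGMA_M = 0.25


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of the validation grid: which hyperparameter varies, at what level."""

    code: str
    varied: str
    level: str
    hyper: CommunityHyperparams
    n_species: int = 35
    n_sites: int = 12
    n_occasions: int = 5
    sigma_s: float = DEFAULT_SIGMA_S
    sigma_m: float = DEFAULT_SIGMA_M
    seed: int = 0

    def __post_init__(self):
        if self.varied not in VARIED_PARAMETERS:
            raise ValueError(f"unknown varied parameter {self.varied!r}")
        if self.level not in LEVEL_NAMES:
            raise ValueError(f"unknown level {self.level!r}")


@dataclass(frozen=True)
class SimulatedMetacommunity:
    """Ground truth plus the imperfectly observed detection history."""

    setting: SimulationSetting
    params: SpeciesParams
    re: RandomEffects
    design: SiteDesign
    N: np.ndarray          # true abundance (site, species)
    y: DetectionHistory    # observed counts

    def __post_init__(self):
        if np.any(self.y.y > self.N[:, None, :]):
            raise ValueError("observed counts exceed true abundance")


def build_setting_grid(
    levels: dict | None = None,
    constants: CommunityHyperparams = DEFAULT_CONSTANTS,
    n_species: int = 35,
    n_sites: int = 12,
    n_occasions: int = 5,
    seed: int = 0,
) -> list[SimulationSetting]:
    """The 12-setting validation grid, codes A..L in deterministic order.

    One varied hyperparameter per setting, three levels each; settings that
    share a varied parameter differ only in its level.
    """
    levels = dict(DEFAULT_LEVELS if levels is None else levels)
    for p in VARIED_PARAMETERS:
        if p not in levels or len(levels[p]) != 3:
            raise ValueError(f"exactly 3 levels required for {p}")
    settings = []
    codes = iter(string.ascii_uppercase)
    for p_idx, param in enumerate(VARIED_PARAMETERS):
        for l_idx, level in enumerate(LEVEL_NAMES):
            hyper = replace(constants, **{param: float(levels[param][l_idx])})
            settings.append(SimulationSetting(
                code=next(codes), varied=param, level=level, hyper=hyper,
                n_species=n_species, n_sites=n_sites, n_occasions=n_occasions,
                seed=seed + 100 * p_idx + l_idx,
            ))
    return settings


def default_design(n_sites: int = 12, n_occasions: int = 5, n_su: int | None = None,
                   n_sm: int = 5, rng=None) -> SiteDesign:
    """Paired-strata study design: sites come in pairs (canopy, understory).

    Consecutive site pairs share a sampling unit; the month effect is wired
    as a per-site group cycling over the ``n_sm`` months (one of the two
    readings the model admits; see the methods note).  Covariates are drawn
    standardized: site and occasion temperatures N(0, 1), occasion dates an
    evenly spaced z-scored grid shared across sites.
    """
    if n_sites % 2 != 0:
        raise ValueError("paired-strata design needs an even number of sites")
    if rng is None:
        rng = np.random.default_rng(0)
    strata = np.tile([0, 1], n_sites // 2)
    group_su = np.arange(n_sites) // 2
    if n_su is None:
        n_su = n_sites // 2
    group_sm = np.arange(n_sites) % n_sm
    temp_site = rng.standard_normal(n_sites)
    dates = np.arange(n_occasions, dtype=float)
    dates = (dates - dates.mean()) / dates.std(ddof=0) if n_occasions > 1 else dates * 0.0
    date_obs = np.tile(dates, (n_sites, 1))
    temp_obs = rng.standard_normal((n_sites, n_occasions))
    return SiteDesign(
        strata=strata, temp_site=temp_site, group_su=group_su, group_sm=group_sm,
        date_obs=date_obs, temp_obs=temp_obs, n_su=n_su, n_sm=n_sm,
        standardization={"simulated": True},
    )


def simulate_metacommunity(setting: SimulationSetting) -> SimulatedMetacommunity:
    """Draw one metacommunity and its imperfect observation, seed-reproducibly."""
    rng = np.random.default_rng(setting.seed)
    design = default_design(setting.n_sites, setting.n_occasions, rng=rng)
    hyper = setting.hyper
    params = SpeciesParams(**{
        name: rng.normal(hyper.mu(name), hyper.sd(name), size=setting.n_species)
        for name in PARAM_NAMES
    })
    re = RandomEffects(
        s=rng.normal(0.0, setting.sigma_s, size=design.n_su),
        m=rng.normal(0.0, setting.sigma_m, size=design.n_sm),
        sigma_s=setting.sigma_s,
        sigma_m=setting.sigma_m,
    )
    lam = expected_abundance_matrix(params, re, design)
    p = 1.0 / (1.0 + np.exp(-detection_logit_matrix(params, design)))
    N = rng.poisson(lam)
    y = rng.binomial(N[:, None, :], p)
    return SimulatedMetacommunity(
        setting=setting, params=params, re=re, design=design,
        N=N, y=DetectionHistory(y),
    )


def _truth_value(truth: SimulatedMetacommunity, name: str) -> float:
    if name == "sigma_s":
        return truth.re.sigma_s
    if name == "sigma_m":
        return truth.re.sigma_m
    if name.startswith("mu_"):
        return truth.setting.hyper.mu(name[3:])
    if name.startswith("sd_"):
        return truth.setting.hyper.sd(name[3:])
    if "[" in name:
        base, idx = name[:-1].split("[", 1)
        return float(truth.params.get(base)[int(idx)])
    raise KeyError(name)


def recovery_check(truth: SimulatedMetacommunity, draws: PosteriorDraws,
                   level: float = 0.95, include_species: bool = True) -> pd.DataFrame:
    """Central credible intervals versus the simulation truth.

    One row per hyperparameter (and, optionally, per species coefficient)
    with the true value, the central ``level`` credible interval from the
    pooled draws, and an inside/outside flag.  Aggregate coverage fractions
    come from :func:`coverage`.
    """
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    names = [(n, "hyper") for n in draws.community_names()]
    if include_species:
        K = truth.params.n_species
        names += [(f"{b}[{k}]", "species") for b in PARAM_NAMES for k in range(K)]
    rows = []
    for name, group in names:
        pooled = draws.pooled(name)
        lo, hi = np.quantile(pooled, [lo_q, hi_q])
        tv = _truth_value(truth, name)
        rows.append({
            "parameter": name, "group": group, "truth": tv,
            "lo": float(lo), "hi": float(hi),
            "inside": bool(lo <= tv <= hi),
        })
    return pd.DataFrame(rows)


def coverage(report: pd.DataFrame, group: str | None = None) -> float:
    """Fraction of parameters whose truth lies inside the credible interval."""
    if group is not None:
        report = report[report["group"] == group]
    if len(report) == 0:
        raise ValueError("empty recovery report")
    return float(report["inside"].mean())


def sampling_effort(traps_per_unit: int, n_units: int, n_days: int) -> int:
    """Total trap-days of a bait-trap design: traps/unit x units x days."""
    if min(traps_per_unit, n_units, n_days) <= 0:
        raise ValueError("all design constants must be positive")
    return traps_per_unit * n_units * n_days
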