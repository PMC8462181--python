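"""The hidden-diversity statistic and the noise/bias quadrant classification.

For each site and diversity metric, hidden diversity is

    HD_i = (div_obs_i - mean(div_est_i)) / sd(div_est_i)

where ``div_est_i`` are the metric values computed on each posterior draw of
the detection-corrected abundance matrix.  Positive HD means the observed
data overestimate the detection-corrected diversity; negative HD an
underestimation.  For SES-type metrics the pair (observed SES, mean estimated
SES) is classified into quadrants: same sign = "noise" (the observed pattern
holds), opposite signs = critical bias ("bias_overestimation" when the
observed SES is positive and the estimated negative, "bias_underestimation"
in the reverse case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import (
    CommunityMatrix,
    NullModelSpec,
    TraitMatrix,
    TreeIndex,
    faith_pd,
    gower_distance,
    functional_dendrogram,
    mpd,
    patristic_distance_matrix,
    richness,
    ses,
    total_abundance,
)

__all__ = [
    "HDValue",
    "HiddenDiversityRecord",
    "NOISE",
    "BIAS_OVERESTIMATION",
    "BIAS_UNDERESTIMATION",
    "hidden_diversity_value",
    "classify_quadrant",
    "hidden_diversity_pipeline",
]

NOISE = "noise"
BIAS_OVERESTIMATION = "bias_overestimation"
BIAS_UNDERESTIMATION = "bias_underestimation"

#: metrics reported per requested family
PD_METRICS = ("SES.PD", "SES.FD")
MPD_METRICS = ("SES.MPD", "SES.MFD", "SES.MPDi", "SES.MFDi")
ALWAYS_METRICS = ("TD", "abundance")


@dataclass(frozen=True)
class HDValue:
    """Hidden diversity for one site/metric: hd, draw mean and (sample) sd."""

    hd: float
    mean: float
    sd: float
    undefined: bool = False


@dataclass(frozen=True)
class HiddenDiversityRecord:
    site: str
    metric: str
    div_obs: float
    div_est_mean: float
    div_est_sd: float
    hd: float
    raw_difference: float
    quadrant: str | None


def hidden_diversity_value(div_obs: float, div_est_draws) -> HDValue:
    """HD = (observed - mean of draws) / sample sd of draws.

    Requires at least two draws; a zero (or NaN) sd is flagged undefined and
    hd is NaN, never 0.
    """
    draws = np.asarray(div_est_draws, dtype=float)
    if draws.size < 2:
        raise ValueError("hidden diversity needs at least two posterior draws")
    finite = draws[np.isfinite(draws)]
    if finite.size < 2:
        return HDValue(float("nan"), float("nan"), float("nan"), undefined=True)
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        return HDValue(float("nan"), mean, sd, undefined=True)
    return HDValue(float((div_obs - mean) / sd), mean, sd)


def classify_quadrant(obs_ses: float, est_ses_mean: float) -> str:
    """Quadrant of the (observed SES, estimated SES) plane.

    Same sign: noise (the observed pattern holds).  Observed positive with
    estimated negative: bias_overestimation.  Observed negative with
    estimated positive: bias_underestimation.  An exact zero on either axis
    carries no directional pattern and is classified noise, with a warning.
    """
    if not (np.isfinite(obs_ses) and np.isfinite(est_ses_mean)):
        raise ValueError("quadrant classification needs finite SES values")
    if obs_ses == 0.0 or est_ses_mean == 0.0:
        warnings.warn("zero SES on one axis; classified as noise by convention")
        return NOISE
    if obs_ses > 0 and est_ses_mean < 0:
        return BIAS_OVERESTIMATION
    if obs_ses < 0 and est_ses_mean > 0:
        return BIAS_UNDERESTIMATION
    return NOISE


def _reconcile(obs: CommunityMatrix, tree, traits, need_tree: bool, need_traits: bool):
    """Check that tree tips and trait rows cover the community's species."""
    problems = []
    if need_tree:
        if tree is None:
            raise ValueError("a phylogenetic tree is required for the requested metrics")
        tips = set(TreeIndex(tree).tip_labels) if not isinstance(tree, TreeIndex) else set(tree.tip_labels)
        missing = sorted(set(obs.species) - tips)
        if missing:
            problems.append(f"species absent from tree: {missing}")
    if need_traits:
        if traits is None:
            raise ValueError("a trait table is required for the requested metrics")
        missing = sorted(set(obs.species) - set(traits.species))
        if missing:
            problems.append(f"species absent from trait table: {missing}")
    if problems:
        raise ValueError("; ".join(problems))


def hidden_diversity_pipeline(
    obs: CommunityMatrix,
    draws,
    tree=None,
    traits: TraitMatrix | None = None,
    metrics=("pd", "mpd"),
    abundance_weighted: bool = True,
    null: NullModelSpec = NullModelSpec(),
    reuse_null: bool = False,
) -> pd.DataFrame:
    """Propagate posterior abundance draws into diversity metrics and HD.

    ``draws`` is a sequence of site x species abundance matrices (numpy
    arrays or :class:`CommunityMatrix`), one per retained posterior draw,
    with species in the same order as ``obs``.  Taxonomic diversity (TD,
    species richness) and total abundance are always computed; ``"pd"`` adds
    SES.PD and SES.FD (Faith PD on the phylogeny and on the UPGMA functional
    dendrogram), ``"mpd"`` adds SES.MPD/SES.MFD (mean pairwise distances,
    abundance-weighted when requested) plus their incidence-based variants
    SES.MPDi/SES.MFDi.

    By default the null-model randomization is re-drawn for every posterior
    draw from a draw-indexed seed stream, so null-model and detection
    uncertainty both propagate into sd(div_est); ``reuse_null=True`` freezes
    one permutation stream for the observed matrix and all draws.

    Returns one row per site x metric with columns site, metric, div_obs,
    div_est_mean, div_est_sd, hd, raw_difference, quadrant.
    """
    metrics = tuple(metrics)
    unknown = set(metrics) - {"pd", "mpd"}
    if unknown:
        raise ValueError(f"unknown metric families: {sorted(unknown)}")
    draw_mats = [d.abundance if isinstance(d, CommunityMatrix) else np.asarray(d) for d in draws]
    if len(draw_mats) == 0:
        raise ValueError("no posterior draws supplied")
    for d in draw_mats:
        if d.shape != obs.abundance.shape:
            raise ValueError("posterior draw shape does not match the observed matrix")

    need_struct = bool(metrics)
    _reconcile(obs, tree, traits, need_tree=need_struct, need_traits=need_struct)

    records: list[HiddenDiversityRecord] = []
    comms = [CommunityMatrix(d, obs.sites, obs.species) for d in draw_mats]

    # --- raw metrics, always computed ---
    for name, fn in (("TD", richness), ("abundance", total_abundance)):
        obs_vals = [fn(obs, i) for i in range(obs.n_sites)]
        est_vals = np.array([[fn(c, i) for i in range(obs.n_sites)] for c in comms])
        for i, site in enumerate(obs.sites):
            hv = hidden_diversity_value(obs_vals[i], est_vals[:, i])
            records.append(HiddenDiversityRecord(
                site, name, float(obs_vals[i]), hv.mean, hv.sd, hv.hd,
                float(obs_vals[i]) - hv.mean, None))

    # --- SES metrics ---
    ses_specs = []
    if "pd" in metrics or "mpd" in metrics:
        phylo_index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
        gower = gower_distance(traits.subset(obs.species))
        func_index = TreeIndex(functional_dendrogram(gower))
    if "pd" in metrics:
        ses_specs.append(("SES.PD", faith_pd, phylo_index))
        ses_specs.append(("SES.FD", faith_pd, func_index))
    if "mpd" in metrics:
        phylo_dist = patristic_distance_matrix(
            tree.as_tree() if hasattr(tree, "as_tree") else tree, obs.species
        ) if not isinstance(tree, TreeIndex) else None
        if phylo_dist is None:
            raise TypeError("mpd metrics need a dendropy tree, not a TreeIndex")
        wfn = lambda c, i, d, w=abundance_weighted: mpd(c, i, d, weighted=w)  # noqa: E731
        ifn = lambda c, i, d: mpd(c, i, d, weighted=False)  # noqa: E731
        ses_specs.append(("SES.MPD", wfn, phylo_dist))
        ses_specs.append(("SES.MFD", wfn, gower))
        ses_specs.append(("SES.MPDi", ifn, phylo_dist))
        ses_specs.append(("SES.MFDi", ifn, gower))

    if ses_specs:
        seed_seq = np.random.SeedSequence(null.seed)
        children = seed_seq.spawn(1 + len(draw_mats))
        for name, fn, structure in ses_specs:
            comm_for = obs if name not in ("SES.MPDi", "SES.MFDi") else obs.incidence()
            rng_obs = np.random.default_rng(children[0])
            obs_ses = ses(fn, comm_for, structure, null, rng=rng_obs)
            est = np.empty((len(comms), obs.n_sites))
            for d_idx, c in enumerate(comms):
                child = children[0] if reuse_null else children[1 + d_idx]
                rng_d = np.random.default_rng(child)
                c_for = c if name not in ("SES.MPDi", "SES.MFDi") else c.incidence()
                res = ses(fn, c_for, structure, null, rng=rng_d)
                est[d_idx] = [r.ses for r in res]
            for i, site in enumerate(obs.sites):
                hv = hidden_diversity_value(obs_ses[i].ses, est[:, i])
                quadrant = None
                if np.isfinite(obs_ses[i].ses) and np.isfinite(hv.mean):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        quadrant = classify_quadrant(obs_ses[i].ses, hv.mean)
                records.append(HiddenDiversityRecord(
                    site, name, obs_ses[i].ses, hv.mean, hv.sd, hv.hd,
                    obs_ses[i].ses - hv.mean, quadrant))

    df = pd.DataFrame([r.__dict__ for r in records])
    order = {m: i for i, m in enumerate(ALWAYS_METRICS + PD_METRICS + MPD_METRICS)}
    df["__o"] = df["metric"].map(order)
    df = df.sort_values(["__o", "site"], kind="stable").drop(columns="__o").reset_index(drop=True)
    return df
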