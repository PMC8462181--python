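"""Readers and writers: long-format counts, traits, Newick trees, run configs.

The counts schema is tidy/long: one row per (site, occasion, species) with
columns ``site, occasion, species, count`` plus site-level covariates
(``strata, temp_site, su, sm`` — constant within a site) and occasion-level
covariates (``date, temp_occ`` — constant within a site x occasion).  A
``# hiddendiv-counts v1`` comment on the first line versions the schema.
Continuous covariates are z-scored on read (means/sds recorded) unless the
caller asks for the values as-is.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .diversity import CommunityMatrix, NullModelSpec, TraitMatrix
from .mcmc import MCMCConfig
from .model import DetectionHistory, SiteDesign

__all__ = [
    "COUNTS_SCHEMA_VERSION",
    "read_counts",
    "write_counts",
    "read_traits",
    "read_tree",
    "write_tree",
    "prune_tree",
    "observed_community",
    "RunConfig",
]

COUNTS_SCHEMA_VERSION = "hiddendiv-counts v1"
_REQUIRED = ["site", "occasion", "species", "count"]
_SITE_COVS = ["strata", "temp_site", "su", "sm"]
_OCC_COVS = ["date", "temp_occ"]


def _zscore(x: np.ndarray):
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=0))
    if sd == 0.0:
        return x - mean, mean, sd
    return (x - mean) / sd, mean, sd


def read_counts(path, complete: bool = True, standardize: bool = True):
    """Parse a long-format counts file into (DetectionHistory, SiteDesign, labels).

    With ``complete=True`` every (site, occasion, species) combination must
    be present; with ``complete=False``, (site, occasion) pairs wholly absent
    from the file are treated as unsurveyed (masked) occasions.  Validation
    failures name the offending data row (1-based, excluding header lines).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    unknown = set(df.columns) - set(_REQUIRED + _SITE_COVS + _OCC_COVS)
    if unknown:
        raise ValueError(f"unknown columns in {path.name}: {sorted(unknown)}")
    missing = [c for c in _REQUIRED + _SITE_COVS + _OCC_COVS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns in {path.name}: {missing}")
    bad = df.index[(df["count"] < 0) | (df["count"] % 1 != 0)]
    if len(bad):
        raise ValueError(f"invalid count at data row {int(bad[0]) + 1} of {path.name}")
    dup = df.duplicated(subset=["site", "occasion", "species"])
    if dup.any():
        raise ValueError(
            f"duplicate (site, occasion, species) at data row {int(df.index[dup][0]) + 1}"
        )

    sites = sorted(df["site"].astype(str).unique())
    species = sorted(df["species"].astype(str).unique())
    occasions = sorted(df["occasion"].unique())
    I, J, K = len(sites), len(occasions), len(species)
    site_ix = {s: i for i, s in enumerate(sites)}
    occ_ix = {o: j for j, o in enumerate(occasions)}
    sp_ix = {s: k for k, s in enumerate(species)}

    y = np.zeros((I, J, K), dtype=np.int64)
    seen_pair = np.zeros((I, J), dtype=bool)
    for row in df.itertuples(index=False):
        i, j, k = site_ix[str(row.site)], occ_ix[row.occasion], sp_ix[str(row.species)]
        y[i, j, k] = int(row.count)
        seen_pair[i, j] = True
    if complete and not seen_pair.all():
        ij = np.argwhere(~seen_pair)[0]
        raise ValueError(
            f"missing rows for site {sites[ij[0]]!r} occasion {occasions[ij[1]]!r}; "
            "pass complete=False to treat absent occasions as unsurveyed"
        )
    mask = None if seen_pair.all() else seen_pair

    per_site = df.drop_duplicates("site").set_index(df.drop_duplicates("site")["site"].astype(str))
    for cov in _SITE_COVS:
        if df.groupby("site")[cov].nunique().max() > 1:
            raise ValueError(f"site covariate {cov!r} varies within a site")
    strata = np.array([per_site.loc[s, "strata"] for s in sites], dtype=np.int64)
    temp_site = np.array([per_site.loc[s, "temp_site"] for s in sites], dtype=float)
    su = np.array([per_site.loc[s, "su"] for s in sites])
    sm = np.array([per_site.loc[s, "sm"] for s in sites])
    su = np.searchsorted(np.unique(su), su)
    sm = np.searchsorted(np.unique(sm), sm)

    date_obs = np.zeros((I, J))
    temp_obs = np.zeros((I, J))
    per_occ = df.drop_duplicates(["site", "occasion"])
    for row in per_occ.itertuples(index=False):
        i, j = site_ix[str(row.site)], occ_ix[row.occasion]
        date_obs[i, j] = float(row.date)
        temp_obs[i, j] = float(row.temp_occ)

    standardization = {}
    if standardize:
        temp_site, mn, sd = _zscore(temp_site)
        standardization["temp_site"] = (mn, sd)
        m2 = mask if mask is not None else np.ones((I, J), dtype=bool)
        for name, arr in (("date", date_obs), ("temp_occ", temp_obs)):
            vals = arr[m2]
            mn, sd = float(vals.mean()), float(vals.std(ddof=0))
            if sd > 0:
                arr -= mn
                arr /= sd
            standardization[name] = (mn, sd)

    design = SiteDesign(
        strata=strata, temp_site=temp_site, group_su=su, group_sm=sm,
        date_obs=date_obs, temp_obs=temp_obs, standardization=standardization,
    )
    return DetectionHistory(y, mask=mask), design, {"sites": sites, "species": species,
                                                    "occasions": [str(o) for o in occasions]}


def write_counts(path, y: DetectionHistory, design: SiteDesign, sites=None, species=None,
                 occasions=None) -> None:
    """Write a detection history and design in the long counts schema."""
    I, J, K = y.n_sites, y.n_occasions, y.n_species
    sites = [f"site_{i:02d}" for i in range(I)] if sites is None else list(sites)
    species = [f"sp_{k:02d}" for k in range(K)] if species is None else list(species)
    occasions = list(range(1, J + 1)) if occasions is None else list(occasions)
    mask = y.occasion_mask()
    rows = []
    for i in range(I):
        for j in range(J):
            if not mask[i, j]:
                continue
            for k in range(K):
                rows.append({
                    "site": sites[i], "occasion": occasions[j], "species": species[k],
                    "count": int(y.y[i, j, k]), "strata": int(design.strata[i]),
                    "temp_site": float(design.temp_site[i]),
                    "su": int(design.group_su[i]), "sm": int(design.group_sm[i]),
                    "date": float(design.date_obs[i, j]),
                    "temp_occ": float(design.temp_obs[i, j]),
                })
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {COUNTS_SCHEMA_VERSION}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def observed_community(y: DetectionHistory, sites=None, species=None) -> CommunityMatrix:
    """Observed site x species matrix: the per-site maximum count over occasions.

    The maximum over repeated occasions is the tightest lower bound on true
    abundance the data provide, and is the quantity the latent-abundance
    support is anchored to.
    """
    maxy = y.max_counts()
    I, K = maxy.shape
    sites = [f"site_{i:02d}" for i in range(I)] if sites is None else list(sites)
    species = [f"sp_{k:02d}" for k in range(K)] if species is None else list(species)
    return CommunityMatrix(maxy, tuple(sites), tuple(species))


def read_traits(path, binary=None) -> TraitMatrix:
    """Species x trait table from delimited text (first column = species)."""
    df = pd.read_csv(path, comment="#", index_col=0)
    df.index = df.index.astype(str)
    binary = tuple(binary) if binary is not None else ()
    return TraitMatrix(df, binary)


def read_tree(path) -> dendropy.Tree:
    """Rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True, rooting="default-rooted")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def prune_tree(tree: dendropy.Tree, species) -> dendropy.Tree:
    """Prune a tree to a species set, collapsing pass-through nodes.

    Retains exactly the requested tips; errors on species absent from the
    tree.  Unifurcations created by pruning are suppressed with their branch
    lengths summed, so total retained branch length never exceeds the
    original tree's.
    """
    species = [str(s) for s in species]
    available = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(species) - available)
    if missing:
        raise KeyError(f"species missing from tree: {missing}")
    pruned = tree.clone(depth=1)
    if set(species) == available:
        return pruned
    pruned.retain_taxa_with_labels(species)
    return pruned


@dataclass
class RunConfig:
    """Plain-text (YAML) configuration for a full pipeline run; round-trippable."""

    counts: str = "counts.csv"
    tree: str = "tree.nwk"
    traits: str = "traits.csv"
    out_dir: str = "out"
    binary_traits: list = field(default_factory=list)
    metrics: list = field(default_factory=lambda: ["pd", "mpd"])
    abundance_weighted: bool = True
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    null: NullModelSpec = field(default_factory=NullModelSpec)
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["mcmc"]["fixed"] = sorted(data["mcmc"]["fixed"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        mcmc = data.pop("mcmc", {})
        mcmc["fixed"] = frozenset(mcmc.get("fixed", ()))
        null = data.pop("null", {})
        return cls(mcmc=MCMCConfig(**mcmc), null=NullModelSpec(**null), **data)
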