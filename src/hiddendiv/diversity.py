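"""Taxonomic, phylogenetic and functional diversity metrics with null-model SES.

Provides Faith's PD (branch-length based), mean pairwise distance (MPD, with
optional abundance-product weighting), Gower distances for mixed
continuous/binary trait tables, UPGMA functional dendrograms, and a generic
standardized-effect-size routine under three randomization nulls:

* ``tip_shuffle``   - permute species positions on the tree / distance matrix
* ``site_shuffle``  - permute the sampling-unit rows of the community matrix
* ``species_shuffle`` - permute species identities (columns) of the matrix

Faith's PD follows the convention that the path to the root of the (pruned)
tree is included, so a single-species community has PD equal to its
root-to-tip path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CommunityMatrix",
    "TraitMatrix",
    "DistanceMatrix",
    "NullModelSpec",
    "SESResult",
    "TreeIndex",
    "richness",
    "total_abundance",
    "gower_distance",
    "functional_dendrogram",
    "faith_pd",
    "mpd",
    "ses",
    "patristic_distance_matrix",
]


@dataclass(frozen=True)
class CommunityMatrix:
    """Site x species abundance matrix with labels."""

    abundance: np.ndarray
    sites: tuple
    species: tuple

    def __post_init__(self):
        a = np.asarray(self.abundance)
        if a.ndim != 2:
            raise ValueError("abundance must be 2-d (site, species)")
        if np.any(a < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "abundance", a.astype(np.int64))
        object.__setattr__(self, "sites", tuple(str(x) for x in self.sites))
        object.__setattr__(self, "species", tuple(str(x) for x in self.species))
        if len(self.sites) != a.shape[0] or len(self.species) != a.shape[1]:
            raise ValueError("label lengths do not match the abundance matrix")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")

    @property
    def n_sites(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(df.to_numpy(), tuple(df.index), tuple(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=list(self.sites), columns=list(self.species))

    def incidence(self) -> "CommunityMatrix":
        return CommunityMatrix((self.abundance > 0).astype(np.int64), self.sites, self.species)


@dataclass(frozen=True)
class TraitMatrix:
    """Species x trait table; ``binary`` names the 0/1 columns, the rest are continuous."""

    data: pd.DataFrame
    binary: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "binary", tuple(self.binary))
        unknown = set(self.binary) - set(self.data.columns)
        if unknown:
            raise ValueError(f"binary trait columns not in table: {sorted(unknown)}")
        for col in self.binary:
            vals = self.data[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"binary trait {col!r} contains values outside {{0, 1}}")

    @property
    def species(self) -> tuple:
        return tuple(str(s) for s in self.data.index)

    def subset(self, species) -> "TraitMatrix":
        missing = [s for s in species if s not in set(self.species)]
        if missing:
            raise KeyError(f"species missing from trait table: {missing}")
        return TraitMatrix(self.data.loc[list(species)], self.binary)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric species-by-species dissimilarity with zero diagonal."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) != v.shape[0]:
            raise ValueError("labels do not match matrix size")

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(str(l)) for l in labels]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], tuple(labels))


@dataclass(frozen=True)
class NullModelSpec:
    """Randomization null: kind, number of permutations and seed."""

    kind: str = "tip_shuffle"
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("tip_shuffle", "site_shuffle", "species_shuffle"):
            raise ValueError(f"unknown null model kind {self.kind!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass(frozen=True)
class SESResult:
    """Observed metric, null mean/sd and standardized effect size for one site."""

    site: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    undefined: bool = False


# ---------------------------------------------------------------------------
# tree indexing and Faith PD
# ---------------------------------------------------------------------------


class TreeIndex:
    """Edge table of a rooted tree with per-edge tip bitmasks, for fast PD.

    Supports up to 63 tips (a community matrix side, not a limitation of the
    surrounding pipeline, which prunes trees to the community's species).
    """

    def __init__(self, tree: dendropy.Tree):
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(tips) > 63:
            raise ValueError("TreeIndex supports at most 63 tips")
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")
        self.tip_labels = tuple(tips)
        self._tip_bit = {lab: 1 << i for i, lab in enumerate(tips)}
        masks, lengths = [], []
        node_mask = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                mask = self._tip_bit[node.taxon.label]
            else:
                mask = 0
                for ch in node.child_nodes():
                    mask |= node_mask[ch]
            node_mask[node] = mask
            if node.parent_node is not None:
                masks.append(mask)
                lengths.append(node.edge.length if node.edge.length is not None else 0.0)
        self.edge_masks = np.array(masks, dtype=np.uint64)
        self.edge_lengths = np.array(lengths, dtype=float)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def pd(self, species) -> float:
        """Faith PD of a species set: summed lengths of edges on root-to-tip paths."""
        mask = 0
        for sp in species:
            try:
                mask |= self._tip_bit[str(sp)]
            except KeyError:
                raise KeyError(f"species {sp!r} not a tip of the tree") from None
        if mask == 0:
            return 0.0
        hit = (self.edge_masks & np.uint64(mask)) != 0
        return float(self.edge_lengths[hit].sum())

    def relabelled(self, mapping: dict) -> "TreeIndex":
        """Copy with tip labels permuted according to ``mapping`` (old -> new)."""
        new = TreeIndex.__new__(TreeIndex)
        new.tip_labels = tuple(mapping.get(l, l) for l in self.tip_labels)
        new._tip_bit = {mapping.get(l, l): b for l, b in self._tip_bit.items()}
        new.edge_masks = self.edge_masks
        new.edge_lengths = self.edge_lengths
        return new


def _as_index(tree) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree)


def faith_pd(comm: CommunityMatrix, site: int, tree) -> float:
    """Faith's phylogenetic diversity of the species present at one site.

    ``tree`` may be a ``dendropy.Tree`` or a prebuilt :class:`TreeIndex`.
    Includes the path to the root; an empty site has PD 0.
    """
    idx = _as_index(tree)
    present = [sp for sp, a in zip(comm.species, comm.abundance[site]) if a > 0]
    return idx.pd(present)


def patristic_distance_matrix(tree: dendropy.Tree, species=None) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances, ordered by ``species``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label is not None}
    labels = [str(s) for s in species] if species is not None else sorted(taxa)
    missing = [l for l in labels if l not in taxa]
    if missing:
        raise KeyError(f"species missing from tree: {missing}")
    n = len(labels)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]])
            out[a, b] = out[b, a] = d
    return DistanceMatrix(out, tuple(labels))


# ---------------------------------------------------------------------------
# simple metrics
# ---------------------------------------------------------------------------


def richness(comm: CommunityMatrix, site: int) -> int:
    """Number of species with abundance > 0 at a site."""
    return int((comm.abundance[site] > 0).sum())


def total_abundance(comm: CommunityMatrix, site: int) -> int:
    """Summed abundance at a site."""
    return int(comm.abundance[site].sum())


def mpd(comm: CommunityMatrix, site: int, dist: DistanceMatrix, weighted: bool = False) -> float:
    """Mean pairwise distance among species present at a site.

    Unweighted: plain mean over distinct pairs.  Weighted: abundance-product
    weighting sum(n_k n_l d_kl) / sum(n_k n_l) over pairs k < l (diagonal
    excluded).  Returns NaN when fewer than two species are present.
    """
    if dist.labels != comm.species:
        dist = dist.reorder(comm.species)
    row = comm.abundance[site]
    present = np.flatnonzero(row > 0)
    if present.size < 2:
        return float("nan")
    sub = dist.values[np.ix_(present, present)]
    iu = np.triu_indices(present.size, k=1)
    if not weighted:
        return float(sub[iu].mean())
    n = row[present].astype(float)
    w = np.outer(n, n)[iu]
    return float((w * sub[iu]).sum() / w.sum())


# ---------------------------------------------------------------------------
# Gower distance and UPGMA dendrogram
# ---------------------------------------------------------------------------


def gower_distance(traits: TraitMatrix) -> DistanceMatrix:
    """Gower dissimilarity over mixed continuous/binary traits, in [0, 1].

    Continuous traits contribute range-normalised absolute differences,
    binary traits a simple mismatch; the distance is the mean over retained
    traits.  Zero-range continuous traits are dropped with a warning.
    """
    df = traits.data
    parts = []
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        if col in traits.binary:
            parts.append((x[:, None] != x[None, :]).astype(float))
        else:
            rng = np.ptp(x)
            if rng == 0:
                warnings.warn(f"trait {col!r} has zero range; dropped from Gower distance")
                continue
            parts.append(np.abs(x[:, None] - x[None, :]) / rng)
    if not parts:
        raise ValueError("no usable traits for Gower distance")
    d = np.mean(parts, axis=0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, traits.species)


def functional_dendrogram(dist: DistanceMatrix) -> dendropy.Tree:
    """UPGMA dendrogram from a distance matrix, as a rooted dendropy tree.

    Tip-to-tip path lengths reproduce the cophenetic merge heights (each
    internal node sits at half its merge height from the leaves).  Ties in
    the agglomeration are resolved by scipy's deterministic ordering, which
    follows the label order of the input.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two species")
    Z = linkage(squareform(dist.values, checks=False), method="average")
    taxa = dendropy.TaxonNamespace(list(dist.labels))
    nodes = []
    for lab in dist.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.height = 0.0
        nodes.append(node)
    for a, b, h, _ in Z:
        parent = dendropy.Node()
        parent.height = h / 2.0
        for childidx in (int(a), int(b)):
            child = nodes[childidx]
            child.edge.length = parent.height - child.height
            parent.add_child(child)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[-1]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# null models and SES
# ---------------------------------------------------------------------------


def _permuted_inputs(comm: CommunityMatrix, structure, kind: str, rng):
    """One randomization of (community, structure) under the chosen null."""
    if kind == "tip_shuffle":
        perm = rng.permutation(len(comm.species))
        if isinstance(structure, DistanceMatrix):
            newlabs = tuple(structure.labels[i] for i in perm)
            return comm, DistanceMatrix(structure.values, newlabs).reorder(comm.species)
        if isinstance(structure, TreeIndex):
            labs = structure.tip_labels
            mapping = {labs[i]: labs[perm[i]] for i in range(len(labs))}
            return comm, structure.relabelled(mapping)
        raise TypeError("tip_shuffle needs a tree or distance matrix")
    if kind == "site_shuffle":
        perm = rng.permutation(comm.n_sites)
        return CommunityMatrix(comm.abundance[perm], comm.sites, comm.species), structure
    if kind == "species_shuffle":
        perm = rng.permutation(comm.n_species)
        shuffled = CommunityMatrix(comm.abundance[:, perm], comm.sites, comm.species)
        return shuffled, structure
    raise ValueError(kind)


def ses(metric, comm: CommunityMatrix, structure, null: NullModelSpec,
        rng=None) -> list[SESResult]:
    """Standardized effect sizes of a per-site metric under a randomization null.

    ``metric(comm, site, structure) -> float``.  SES = (observed - null mean)
    / null sd with the sample (n-1) sd; a zero null sd is flagged undefined
    rather than reported as 0.  Positive SES means the observed value exceeds
    the null expectation (overdispersion).
    """
    if rng is None:
        rng = np.random.default_rng(null.seed)
    observed = np.array([metric(comm, i, structure) for i in range(comm.n_sites)])
    null_vals = np.empty((null.n_perm, comm.n_sites))
    for p in range(null.n_perm):
        comm_p, structure_p = _permuted_inputs(comm, structure, null.kind, rng)
        null_vals[p] = [metric(comm_p, i, structure_p) for i in range(comm_p.n_sites)]
    means = null_vals.mean(axis=0)
    sds = null_vals.std(axis=0, ddof=1) if null.n_perm > 1 else np.zeros(comm.n_sites)
    out = []
    for i, site in enumerate(comm.sites):
        if sds[i] > 0:
            out.append(SESResult(site, float(observed[i]), float(means[i]), float(sds[i]),
                                 float((observed[i] - means[i]) / sds[i])))
        else:
            out.append(SESResult(site, float(observed[i]), float(means[i]), float(sds[i]),
                                 float("nan"), undefined=True))
    return out
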