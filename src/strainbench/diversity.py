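"""Strain-level alpha and beta diversity.

Alpha diversity is the effective number of strains (ENS), the exponential
of Shannon entropy (natural log) of a sample's strain abundances: the
number of equally abundant strains that would give the same entropy.

Beta diversity is weighted UniFrac computed on a strain tree built by
UPGMA (average linkage) from pairwise Jaccard *distances* (1 - Jaccard
similarity) between binary strain genotypes — a genotype-space tree, not
a sequence phylogeny. The raw (unnormalized) weighted UniFrac of two
compositions is the sum over branches of branch length times the absolute
difference in total abundance descending through that branch; identical
compositions score 0 and identical genotypes coalesce at height 0, so
collapsing zero-distance strains never changes the metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

from .cohort_simulator import SampleComposition
from .strain_matching import discretize_genotype, jaccard_matrix

__all__ = [
    "StrainTree",
    "effective_number_of_strains",
    "build_strain_tree",
    "weighted_unifrac",
    "pairwise_weighted_unifrac",
    "self_vs_other_dissimilarity",
]


def effective_number_of_strains(
    composition: SampleComposition | dict[str, float] | pd.Series,
) -> float:
    """ENS = exp(Shannon entropy) over positive abundance fractions."""
    if isinstance(composition, SampleComposition):
        vals = np.fromiter(composition.abundances.values(), dtype=float)
    elif isinstance(composition, pd.Series):
        vals = composition.to_numpy(dtype=float)
    else:
        vals = np.fromiter(composition.values(), dtype=float)
    if (vals < -1e-12).any():
        raise ValueError("abundances must be non-negative")
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("composition has no positive abundance")
    p = pos / pos.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


@dataclass
class StrainTree:
    """Rooted ultrametric tree over strain genotypes.

    Stored as a branch table: ``branch_lengths[b]`` is the length of the
    branch above node ``b`` and ``leaf_membership[b, l]`` marks whether
    leaf ``l`` descends through that branch. This form makes weighted
    UniFrac a single sparse-ish matrix product. The root branch (length 0,
    all leaves) is excluded.
    """

    leaf_ids: list[str]
    branch_lengths: np.ndarray  # (n_branches,)
    leaf_membership: np.ndarray  # (n_branches, n_leaves) boolean
    linkage: np.ndarray  # scipy linkage matrix, kept for export

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_index(self, strain_id: str) -> int:
        return self.leaf_ids.index(strain_id)

    def to_newick(self) -> str:
        """Newick string with branch lengths in Jaccard-distance units."""
        tree_root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            height = node.dist / 2.0
            length = parent_height - height
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.10g}"
            left = render(node.left, height)
            right = render(node.right, height)
            return f"({left},{right}):{length:.10g}"

        root_height = tree_root.dist / 2.0
        if tree_root.is_leaf():
            return f"{self.leaf_ids[tree_root.id]}:0;"
        left = render(tree_root.left, root_height)
        right = render(tree_root.right, root_height)
        return f"({left},{right}):0;"


def build_strain_tree(genotypes: pd.DataFrame) -> StrainTree:
    """UPGMA tree on 1 - Jaccard distances between binary genotypes.

    ``genotypes``: strains x sites, binary or fractional (discretized at
    0.5). The resulting tree is ultrametric: each node sits at half its
    cophenetic distance, so two leaves at Jaccard distance d hang d/2
    below their common ancestor. Identical genotypes coalesce at height 0.
    """
    if genotypes.shape[0] < 2:
        raise ValueError("need at least 2 genotypes to build a tree")
    leaf_ids = [str(s) for s in genotypes.index]
    if len(set(leaf_ids)) != len(leaf_ids):
        raise ValueError("duplicate strain ids")
    disc = np.apply_along_axis(discretize_genotype, 1, genotypes.to_numpy(float))
    dist = 1.0 - jaccard_matrix(disc, disc)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")

    n = len(leaf_ids)
    heights = np.zeros(2 * n - 1)
    heights[n:] = z[:, 2] / 2.0
    members = np.zeros((2 * n - 1, n), dtype=bool)
    members[np.arange(n), np.arange(n)] = True
    parent_height = np.zeros(2 * n - 1)
    for i in range(n - 1):
        a, b = int(z[i, 0]), int(z[i, 1])
        members[n + i] = members[a] | members[b]
        parent_height[a] = heights[n + i]
        parent_height[b] = heights[n + i]
    # every node except the root contributes one branch
    nodes = np.arange(2 * n - 2)
    lengths = parent_height[nodes] - heights[nodes]
    lengths = np.maximum(lengths, 0.0)  # guard tiny negatives from fp noise
    return StrainTree(
        leaf_ids=leaf_ids,
        branch_lengths=lengths,
        leaf_membership=members[nodes],
        linkage=z,
    )


def _mass_vector(
    composition: SampleComposition | dict[str, float] | pd.Series, tree: StrainTree
) -> np.ndarray:
    if isinstance(composition, SampleComposition):
        items = composition.abundances.items()
    elif isinstance(composition, pd.Series):
        items = composition.items()
    else:
        items = composition.items()
    m = np.zeros(tree.n_leaves)
    index = {s: j for j, s in enumerate(tree.leaf_ids)}
    for sid, ab in items:
        if ab == 0:
            continue
        if sid not in index:
            raise KeyError(f"strain {sid!r} is not a leaf of the tree")
        m[index[sid]] += ab
    return m


def weighted_unifrac(
    comp_a: SampleComposition | dict[str, float] | pd.Series,
    comp_b: SampleComposition | dict[str, float] | pd.Series,
    tree: StrainTree,
    normalized: bool = False,
) -> float:
    """Raw weighted UniFrac between two compositions on one strain tree.

    Sum over branches of length x |mass_a below - mass_b below|. With
    ``normalized=True`` the value is divided by the same sum with the
    absolute difference replaced by the total mass below each branch.
    """
    ma = _mass_vector(comp_a, tree)
    mb = _mass_vector(comp_b, tree)
    below_a = tree.leaf_membership @ ma
    below_b = tree.leaf_membership @ mb
    raw = float(tree.branch_lengths @ np.abs(below_a - below_b))
    if not normalized:
        return raw
    denom = float(tree.branch_lengths @ (below_a + below_b))
    return raw / denom if denom > 0 else 0.0


def pairwise_weighted_unifrac(
    compositions: pd.DataFrame, tree: StrainTree
) -> pd.DataFrame:
    """All-pairs raw weighted UniFrac for a samples x strains abundance frame."""
    cols = [str(c) for c in compositions.columns]
    unknown = set(cols) - set(tree.leaf_ids)
    if unknown:
        raise KeyError(f"strains not in tree: {sorted(unknown)[:5]}")
    order = [tree.leaf_index(c) for c in cols]
    mass = np.zeros((len(compositions), tree.n_leaves))
    mass[:, order] = compositions.to_numpy(dtype=float)
    below = mass @ tree.leaf_membership.T  # samples x branches
    # cityblock on length-scaled branch masses == sum_b len_b |below_a - below_b|
    scaled = below * tree.branch_lengths[None, :]
    d = cdist(scaled, scaled, metric="cityblock")
    return pd.DataFrame(d, index=compositions.index, columns=compositions.index)


def self_vs_other_dissimilarity(
    true_compositions: pd.DataFrame,
    inferred_compositions: pd.DataFrame,
    tree: StrainTree,
    lbp_level_per_sample: pd.Series,
) -> pd.DataFrame:
    """Fig-style self-vs-other comparison of inferred vs true compositions.

    For every sample s: the weighted UniFrac between its inferred and its
    true composition ("self"), and the median dissimilarity between its
    inferred composition and the true compositions of all other samples
    ("other"), grouped by the sample's spike-in level. Both frames are
    samples x strains over leaves of ``tree``.
    """
    samples = list(true_compositions.index)
    if list(inferred_compositions.index) != samples:
        raise ValueError("sample sets of true and inferred compositions disagree")

    def mass_matrix(frame: pd.DataFrame) -> np.ndarray:
        cols = [str(c) for c in frame.columns]
        order = [tree.leaf_index(c) for c in cols]
        m = np.zeros((len(frame), tree.n_leaves))
        m[:, order] = frame.to_numpy(dtype=float)
        return m

    below_t = mass_matrix(true_compositions) @ tree.leaf_membership.T
    below_i = mass_matrix(inferred_compositions) @ tree.leaf_membership.T
    lt = below_t * tree.branch_lengths[None, :]
    li = below_i * tree.branch_lengths[None, :]
    cross = cdist(li, lt, metric="cityblock")  # inferred_s vs true_t
    n = len(samples)
    self_d = np.diag(cross)
    other = np.where(np.eye(n, dtype=bool), np.nan, cross)
    rows = []
    for j, sid in enumerate(samples):
        rows.append(
            {
                "sample_id": sid,
                "lbp_level": float(lbp_level_per_sample[sid]),
                "self_unifrac": float(self_d[j]),
                "median_other_unifrac": float(np.nanmedian(other[j])),
            }
        )
    return pd.DataFrame(rows)
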