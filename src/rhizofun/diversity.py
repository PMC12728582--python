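"""Rarefaction, alpha diversity, community composition, and PERMANOVA.

Alpha diversity is observed ASV richness plus (when a phylogeny is supplied)
Faith's phylogenetic diversity; the combined microbial diversity index is the
mean of the min–max standardised bacterial and fungal richness. Beta
diversity is Bray–Curtis with principal-coordinate ordination, and treatment
effects on community composition are tested with one-way PERMANOVA
(permutation of sample labels, pseudo-F on the distance partition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .multifun import standardize_minmax
from .ordination import bray_curtis_matrix, pcoa
from .tables import AsvTable, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy", "richness", "faith_pd", "microbial_diversity_index",
    "genus_abundance", "bray_curtis", "community_pcoa", "permanova",
    "PermanovaResult", "anova_lsd",
]


def rarefy(table: AsvTable, depth: int, seed: int | None = None) -> AsvTable:
    """Subsample every sample without replacement to exactly ``depth`` reads
    (one seeded multivariate-hypergeometric draw per sample)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_sums()
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValueError(
            f"depth {depth} exceeds total reads of sample(s) {list(shallow.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[sample].to_numpy()
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return AsvTable(
        counts=pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns),
        kingdom=table.kingdom,
        taxonomy=table.taxonomy,
    )


def richness(table: AsvTable) -> pd.Series:
    """Observed richness: number of ASVs with nonzero count per sample."""
    r = (table.counts > 0).sum(axis=0)
    r.name = f"richness_{table.kingdom}"
    return r


def _root_of(tree: TreeNode) -> TreeNode:
    return tree.root()


def faith_pd(table: AsvTable, tree) -> pd.Series:
    """Faith's phylogenetic diversity per sample: total branch length of the
    minimal rooted subtree spanning the sample's present ASVs and the root."""
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    tree = _root_of(tree)
    tips = {t.name for t in tree.tips()}
    pd_values = {}
    # cache the tip set under every node once
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node._tipset = frozenset([node.name])
        else:
            node._tipset = frozenset().union(*(c._tipset for c in node.children))
    for sample in table.sample_ids:
        present = set(table.counts.index[(table.counts[sample] > 0).to_numpy()])
        missing = present - tips
        if missing:
            raise KeyError(f"ASV(s) {sorted(missing)[:5]} present in sample "
                           f"{sample!r} but absent from the tree")
        total = 0.0
        for node in tree.postorder(include_self=False):
            if node._tipset & present:
                total += node.length or 0.0
        pd_values[sample] = total
    return pd.Series(pd_values, name=f"faith_pd_{table.kingdom}")


def microbial_diversity_index(bact_richness: pd.Series, fung_richness: pd.Series) -> pd.Series:
    """Combined microbial diversity: mean of the two standardised richnesses."""
    if not bact_richness.index.equals(fung_richness.index):
        fung_richness = fung_richness.reindex(bact_richness.index)
        if fung_richness.isna().any():
            raise ValueError("richness vectors cover different samples")
    b = standardize_minmax(bact_richness.to_numpy())
    f = standardize_minmax(fung_richness.to_numpy())
    out = pd.Series((b + f) / 2.0, index=bact_richness.index, name="microbial_diversity")
    return out


def genus_abundance(table: AsvTable) -> pd.DataFrame:
    """Genus x sample relative abundance (columns sum to 1). ASVs whose
    lineage stops above genus are pooled as ``unclassified_<parent>``."""
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    totals = table.sample_sums()
    zero = totals[totals == 0]
    if len(zero):
        raise FormatError(f"sample(s) with zero total count: {list(zero.index)}")
    genus_of = {}
    for asv in table.asv_ids:
        lineage = table.taxonomy.get(asv, [])
        if len(lineage) >= 6:
            genus_of[asv] = lineage[5]
        else:
            parent = lineage[-1] if lineage else "root"
            genus_of[asv] = f"unclassified_{parent}"
    grouped = table.counts.groupby([genus_of[a] for a in table.asv_ids]).sum()
    return grouped / totals


def bray_curtis(profiles: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis distance between rows (samples) of a non-negative matrix."""
    d = bray_curtis_matrix(profiles.to_numpy(dtype=float))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def community_pcoa(distance: pd.DataFrame, n_axes: int = 2):
    """PCoA of a sample distance matrix -> (coords DataFrame, eigenvalues)."""
    coords, eigvals = pcoa(distance.to_numpy(), n_axes=n_axes)
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=distance.index, columns=cols), eigvals


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    R2: float
    n_perm: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    return ss_total, ss_within


def permanova(distance, groups, n_perm: int = 999, seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from the among/within partition of squared
    distances, p-value from whole-label permutations,
    ``p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)``.
    """
    if isinstance(distance, pd.DataFrame):
        if hasattr(groups, "reindex"):
            groups = groups.reindex(distance.index)
        distance = distance.to_numpy()
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        singles = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {singles}")
    a = len(uniq)
    d2 = d**2

    def pseudo_f(lab: np.ndarray) -> float:
        ss_total, ss_within = _permanova_ss(d2, lab, uniq)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    ss_total, ss_within = _permanova_ss(d2, labels, uniq)
    r2 = (ss_total - ss_within) / ss_total
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        if pseudo_f(labels[rng.permutation(n)]) >= f_obs:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return PermanovaResult(pseudo_F=float(f_obs), p=float(p), R2=float(r2), n_perm=n_perm)


def anova_lsd(values: pd.Series, groups: pd.Series, alpha: float = 0.05) -> dict:
    """One-way ANOVA with least-significant-difference pairwise comparisons.

    Routine utility: returns the F statistic, its p-value, and for every
    treatment pair the mean difference and LSD t-test p-value using the
    pooled within-group mean square.
    """
    groups = groups.reindex(values.index)
    arrays = [values[groups == g].to_numpy() for g in groups.unique()]
    f_stat, p = stats.f_oneway(*arrays)
    n = len(values)
    k = len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (n - k)
    pairs = {}
    labels = list(groups.unique())
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(arrays[i]), len(arrays[j])
            diff = arrays[i].mean() - arrays[j].mean()
            se = np.sqrt(mse * (1 / ni + 1 / nj))
            t = diff / se if se > 0 else np.inf
            p_pair = 2 * stats.t.sf(abs(t), n - k)
            pairs[(labels[i], labels[j])] = {
                "diff": float(diff),
                "p": float(p_pair),
                "significant": bool(p_pair < alpha),
            }
    return {"F": float(f_stat), "p": float(p), "pairs": pairs}
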