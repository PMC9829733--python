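"""Post-hoc analyses on fitted species-level sensitivities.

Blomberg's K measures phylogenetic signal in a continuous trait: the ratio of
the observed mean squared error of tip values around the phylogenetic mean
(MSE0) to the GLS error under the tree's variance-covariance structure (MSE),
scaled by its Brownian-motion expectation. K ~ 1 under Brownian evolution and
well below 1 when values are independent of phylogeny. The diel comparison is
a Welch (unequal-variance) two-sample t-test between nocturnal- and
diurnal-migrant sensitivities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import dendropy


def phylo_vcv(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic variance-covariance matrix: V[i, j] = root-to-MRCA depth."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    # root-to-node depths
    depth: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    pdm = tree.phylogenetic_distance_matrix()
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depth[leaves[i]]
        for j in range(i + 1, n):
            patristic = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            V[i, j] = V[j, i] = 0.5 * (depth[leaves[i]] + depth[leaves[j]] - patristic)
    return V, labels


def blombergs_K(values: dict[str, float] | pd.Series, tree: dendropy.Tree) -> float:
    """Blomberg's K for tip values on a tree.

    K = (MSE0 / MSE) / E_BM[MSE0 / MSE], where MSE0 is the mean squared
    deviation of the values from the phylogenetically corrected mean and MSE
    is the GLS mean squared error under the tree's VCV. Invariant to affine
    transforms of the values.
    """
    V, labels = phylo_vcv(tree)
    values = pd.Series(values)
    missing = set(labels) ^ set(values.index)
    if missing:
        raise ValueError(f"tip/value label mismatch: {sorted(missing)}")
    x = values.loc[labels].to_numpy(float)
    n = len(x)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    ahat = float(ones @ Vinv @ x) / float(ones @ Vinv @ ones)
    resid = x - ahat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ Vinv @ resid) / (n - 1)
    expected = (np.trace(V) - n / float(ones @ Vinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


def K_over_tree_set(
    values: dict[str, float] | pd.Series, trees: list[dendropy.Tree]
) -> dict:
    """K per tree plus median and range across the tree set."""
    if not trees:
        raise ValueError("empty tree list")
    ks = []
    for idx, tree in enumerate(trees):
        try:
            ks.append(blombergs_K(values, tree))
        except Exception as exc:
            raise ValueError(f"tree {idx}: {exc}") from exc
    ks = np.asarray(ks)
    return {
        "K": ks,
        "median": float(np.median(ks)),
        "min": float(ks.min()),
        "max": float(ks.max()),
    }


def welch_t_test(group_a, group_b) -> dict:
    """Welch two-sample t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_difference": float(a.mean() - b.mean()),
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
    }


def diel_sensitivity_comparison(sensitivities: pd.DataFrame) -> dict:
    """Compare species sensitivities between nocturnal and diurnal migrants.

    ``sensitivities`` needs columns species_code, sensitivity, diel; species
    labelled both/unknown are excluded from the two-group comparison.
    """
    noc = sensitivities.loc[sensitivities["diel"] == "nocturnal", "sensitivity"]
    diu = sensitivities.loc[sensitivities["diel"] == "diurnal", "sensitivity"]
    out = welch_t_test(noc.to_numpy(), diu.to_numpy())
    out.update(n_nocturnal=int(len(noc)), n_diurnal=int(len(diu)))
    return out
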