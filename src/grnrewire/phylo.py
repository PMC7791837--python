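"""Phylogenetic independent contrasts (PICs) and contrast regression.

The standard construction: at each internal node joining tips i and j with
branch lengths b_i and b_j, the contrast is (x_i - x_j) / sqrt(b_i + b_j),
the node's value is the branch-length-weighted average, and the node's
parent branch is extended by b_i * b_j / (b_i + b_j). Contrast regression is
through the origin; the naive tip regression (with intercept) is returned
alongside so the effect of fitting the phylogeny can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import SpeciesTree, TreeNode

#: default dosage coding of segregation classes for contrast analysis
GENOTYPE_CODING = {"conserved": 0.0, "het_segregating": 0.5, "hom_segregated": 1.0}


def code_genotypes(classes: pd.Series, coding: Optional[Dict[str, float]] = None) -> pd.Series:
    coding = coding or GENOTYPE_CODING
    if len(set(coding.values())) != len(coding):
        raise ValueError("coding map must be injective")
    return classes.map(coding)


def pic(tree: SpeciesTree, trait: Dict[str, float]) -> np.ndarray:
    """Independent contrasts (n_tips - 1 values) for one trait.

    Requires a fully bifurcating tree with strictly positive branch lengths
    and a trait value at every tip; polytomies and zero branch lengths are
    errors rather than silently resolved.
    """
    for leaf in tree.leaf_names:
        if leaf not in trait:
            raise ValueError(f"no trait value for tip {leaf!r}")
    values: Dict[str, float] = {}
    lengths: Dict[str, float] = {}
    contrasts = []
    for node in tree.root.postorder():
        if node is not tree.root and node.length <= 0:
            raise ValueError(f"non-positive branch length above {node.name!r}")
        if node.is_leaf:
            values[node.name] = float(trait[node.name])
            lengths[node.name] = node.length
            continue
        if len(node.children) != 2:
            raise ValueError(f"polytomy at {node.name!r}")
        ci, cj = node.children
        xi, xj = values[ci.name], values[cj.name]
        bi, bj = lengths[ci.name], lengths[cj.name]
        contrasts.append((xi - xj) / np.sqrt(bi + bj))
        values[node.name] = (xi / bi + xj / bj) / (1 / bi + 1 / bj)
        lengths[node.name] = (node.length if node is not tree.root else 0.0) + (
            bi * bj / (bi + bj)
        )
    return np.asarray(contrasts)


@dataclass
class PicRegression:
    slope: float
    r2_adj: float
    p: float
    naive_slope: float
    naive_r2: float
    naive_p: float
    n_contrasts: int


def pic_regression(
    tree: SpeciesTree, x: Dict[str, float], y: Dict[str, float]
) -> PicRegression:
    """Through-origin regression of y contrasts on x contrasts, side by side
    with the naive tip regression (with intercept, ignoring the phylogeny)."""
    if len(tree.leaf_names) < 4:
        raise ValueError("need at least 4 tips")
    cx = pic(tree, x)
    cy = pic(tree, y)
    if np.allclose(cx, 0):
        raise ValueError("zero-variance contrasts in x: slope undefined")
    pic_fit = sm.OLS(cy, cx[:, None]).fit()
    tips = tree.leaf_names
    xv = np.array([x[t] for t in tips])
    yv = np.array([y[t] for t in tips])
    naive_fit = sm.OLS(yv, sm.add_constant(xv)).fit()
    return PicRegression(
        slope=float(pic_fit.params[0]),
        r2_adj=float(pic_fit.rsquared_adj),
        p=float(pic_fit.pvalues[0]),
        naive_slope=float(naive_fit.params[1]),
        naive_r2=float(naive_fit.rsquared),
        naive_p=float(naive_fit.pvalues[1]),
        n_contrasts=cx.size,
    )


def brownian_tips(
    tree: SpeciesTree, rate: float = 1.0, seed: int = 0
) -> Dict[str, float]:
    """Simulate one Brownian-motion trait along the tree (rate = variance
    per unit branch length); used for calibration checks."""
    rng = np.random.default_rng(seed)
    values = {tree.root.name: 0.0}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        values[node.name] = values[node.parent.name] + rng.normal(
            0.0, np.sqrt(rate * node.length)
        )
    return {leaf: values[leaf] for leaf in tree.leaf_names}
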