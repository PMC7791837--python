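"""Three metrics of cross-species regulatory-network rewiring.

1. Focal state-change rewiring: a TF is rewired for one focal species when
   it owns an edge present only in that species, its co-expression module
   label there differs from all other extant species, and the TF still
   appears in different edges in every other species.
2. A degree-corrected per-node rewiring score: the summed per-edge deviation
   of cross-species presence vectors from their centroid, divided by the
   node's degree in the union network, with a two-sample Kolmogorov-Smirnov
   comparison of candidate scores against a background.
3. Gain/loss rates of a TF's edges under a two-state continuous-time Markov
   process on the species tree, maximized over the grid {0, 5, ..., 400}^2
   with the published acceptance rule (both rates < 100, at least 25 edges).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModuleAssignment
from .core import SpeciesTree, TreeNode
from .network import ABSENT, EdgeMatrix, INELIGIBLE, PRESENT
from .simulate import ctmc_transition

RATE_GRID = np.arange(0, 401, 5)
RATE_ACCEPT_MAX = 100.0
MIN_EDGES = 25


# -- metric 1: focal state-change rewiring ------------------------------------


@dataclass
class FocalRewiring:
    focal: str
    rewired_tfs: List[str]
    rewired_edges: List[Tuple[str, str]]


def focal_rewired(
    matrix: EdgeMatrix, modules: ModuleAssignment, focal: str
) -> FocalRewiring:
    """Rewired TFs and edges for one focal species (metric 1).

    A qualifying ("focal-unique") edge is one whose presence pattern is
    unique to the focal species: present only in focal, or absent only in
    focal (the signature a lineage-specific binding-site disruption leaves
    on an otherwise conserved edge). A TF is rewired for the focal species
    when it owns such an edge, its module label in focal differs from every
    other extant species, and it still participates in other edges in every
    comparison species.
    """
    if focal not in matrix.species:
        raise ValueError(f"{focal!r} not in the edge matrix species")
    others = [s for s in matrix.species if s != focal]
    tf_edges: Dict[str, Dict[str, set]] = {}
    unique_by_tf: Dict[str, set] = {}
    for (tf, tg), row in matrix.cells.iterrows():
        for sp in matrix.species:
            if row[sp] == PRESENT:
                tf_edges.setdefault(tf, {}).setdefault(sp, set()).add((tf, tg))
        focal_present = row[focal] == PRESENT
        others_state = [row[sp] for sp in others]
        gain = focal_present and all(v == ABSENT for v in others_state)
        loss = row[focal] == ABSENT and all(v == PRESENT for v in others_state)
        if gain or loss:
            unique_by_tf.setdefault(tf, set()).add((tf, tg))

    rewired_tfs: List[str] = []
    rewired_edges: List[Tuple[str, str]] = []
    for tf, unique_edges in unique_by_tf.items():
        per_sp = tf_edges.get(tf, {})
        # condition 1: module state change in the focal species vs all others
        focal_label = modules.of(focal, tf)
        other_labels = [modules.of(sp, tf) for sp in others]
        known = [l for l in other_labels if l is not None]
        if focal_label is None or not known or any(l == focal_label for l in known):
            continue
        # condition 2: the TF participates in other (non-qualifying) edges
        # in every comparison species
        if not all(per_sp.get(sp, set()) - unique_edges for sp in others):
            continue
        rewired_tfs.append(tf)
        rewired_edges.extend(sorted(unique_edges))
    return FocalRewiring(focal, sorted(rewired_tfs), rewired_edges)


# -- metric 2: degree-corrected rewiring score --------------------------------


def dn_score(matrix: EdgeMatrix, node: str) -> Dict[str, float]:
    """Raw and degree-corrected rewiring score of one orthogroup node.

    Every incident edge contributes the sum of squared deviations of its
    cross-species presence vector (1 present / 0 absent; ineligible species
    excluded) from the vector's centroid, divided by (S - 1). The corrected
    score divides by the node's degree in the union (any-species) network.
    """
    rows = matrix.cells[
        (matrix.cells.index.get_level_values("tf") == node)
        | (matrix.cells.index.get_level_values("tg") == node)
    ]
    if rows.empty:
        raise ValueError(f"isolated node {node!r}: score undefined")
    raw = 0.0
    degree = 0
    for _, row in rows.iterrows():
        w = np.array([1.0 if v == PRESENT else 0.0 for v in row.values if v != INELIGIBLE])
        if w.size < 2 or w.sum() == 0:
            if w.sum() > 0:
                degree += 1
            continue
        centroid = w.mean()
        raw += float(((w - centroid) ** 2).sum() / (w.size - 1))
        degree += 1
    if degree == 0:
        raise ValueError(f"isolated node {node!r}: score undefined")
    return {"node": node, "raw": raw, "dn": raw / degree, "degree": degree}


def dn_scores(matrix: EdgeMatrix) -> pd.DataFrame:
    nodes = sorted(
        set(matrix.cells.index.get_level_values("tf"))
        | set(matrix.cells.index.get_level_values("tg"))
    )
    rows = []
    for node in nodes:
        try:
            rows.append(dn_score(matrix, node))
        except ValueError:
            continue
    return pd.DataFrame(rows).set_index("node")


def ks_compare(candidate: Sequence[float], background: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison (D statistic, asymptotic p)."""
    candidate = np.asarray(candidate, dtype=float)
    background = np.asarray(background, dtype=float)
    if candidate.size == 0 or background.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(candidate, background, method="asymp")
    return float(res.statistic), float(res.pvalue)


# -- metric 3: CTMC edge gain/loss rates --------------------------------------


def pattern_loglik(
    pattern: Sequence[Optional[int]],
    tree: SpeciesTree,
    g: float,
    l: float,
) -> float:
    """Log-likelihood of a leaf presence pattern under the gain/loss CTMC.

    Two-state pruning with the exact transition probabilities and the
    stationary root prior (l/(g+l), g/(g+l)). A ``None`` leaf state
    (ineligible species) is marginalized.
    """
    if g < 0 or l < 0:
        raise ValueError("rates must be non-negative")
    if g + l <= 0:
        raise ValueError("g + l must be positive")
    leaf_state = dict(zip(tree.leaf_names, pattern))

    def partial(node: TreeNode) -> np.ndarray:
        if node.is_leaf:
            s = leaf_state[node.name]
            if s is None:
                return np.ones(2)
            out = np.zeros(2)
            out[int(s)] = 1.0
            return out
        result = np.ones(2)
        for child in node.children:
            P = ctmc_transition(g, l, child.length)
            result = result * (P @ partial(child))
        return result

    prior = np.array([l / (g + l), g / (g + l)])
    lik = float(prior @ partial(tree.root))
    if lik <= 0:
        return -np.inf
    return float(np.log(lik))


def _pattern_likelihoods(
    patterns: np.ndarray, tree: SpeciesTree, g: float, l: float
) -> np.ndarray:
    """Vectorized pruning over many patterns (rows; -1 marks a marginalized
    leaf) for one (g, l) pair."""
    leaves = tree.leaf_names
    col = {name: i for i, name in enumerate(leaves)}
    n = patterns.shape[0]

    def partial(node: TreeNode) -> np.ndarray:
        if node.is_leaf:
            s = patterns[:, col[node.name]]
            out = np.zeros((n, 2))
            out[s == -1] = 1.0
            out[s == 0, 0] = 1.0
            out[s == 1, 1] = 1.0
            return out
        result = np.ones((n, 2))
        for child in node.children:
            P = ctmc_transition(g, l, child.length)
            result = result * (partial(child) @ P.T)
        return result

    prior = np.array([l / (g + l), g / (g + l)])
    return partial(tree.root) @ prior


@dataclass
class GainLossEstimate:
    tf_id: str
    n_edges: int
    gain: Optional[float]
    loss: Optional[float]
    loglik: Optional[float]
    accepted: bool
    direction: Optional[str]  # "gain-biased" | "loss-biased" | "balanced"
    uninformative: bool = False
    rejected_reason: Optional[str] = None
    surface: Optional[np.ndarray] = None  # grid log-likelihoods (gain x loss)


def estimate_gain_loss(
    patterns: np.ndarray,
    tree: SpeciesTree,
    tf_id: str = "",
    min_edges: int = MIN_EDGES,
    grid: np.ndarray = RATE_GRID,
    keep_surface: bool = False,
) -> GainLossEstimate:
    """Grid-search maximum likelihood over the published gain/loss lattice.

    The joint log-likelihood of the TF's edge patterns is evaluated for
    every rate pair in {0, 5, ..., 400}^2 (excluding the degenerate (0, 0));
    ties break toward smaller g+l and then smaller gain. An estimate is
    accepted only when both argmax rates are below 100. TFs with fewer than
    ``min_edges`` patterns are rejected outright.
    """
    patterns = np.asarray(patterns)
    n = patterns.shape[0]
    if n < min_edges:
        return GainLossEstimate(
            tf_id, n, None, None, None, False, None,
            rejected_reason=f"fewer than {min_edges} edges",
        )
    # collapse identical patterns for speed
    uniq, counts = np.unique(patterns, axis=0, return_counts=True)
    informative = not (
        (patterns[patterns >= 0] == 1).all() or (patterns[patterns >= 0] == 0).all()
    )
    best = None  # (loglik, g+l, g, l)
    surface = np.full((grid.size, grid.size), -np.inf) if keep_surface else None
    for i, g in enumerate(grid):
        for j, l in enumerate(grid):
            if g == 0 and l == 0:
                continue
            liks = _pattern_likelihoods(uniq, tree, float(g), float(l))
            with np.errstate(divide="ignore"):
                ll = float((counts * np.log(np.maximum(liks, 1e-300))).sum())
            if surface is not None:
                surface[i, j] = ll
            key = (-ll, g + l, g)
            if best is None or key < best[0]:
                best = (key, float(g), float(l), ll)
    _, g_hat, l_hat, ll = best
    accepted = max(g_hat, l_hat) < RATE_ACCEPT_MAX
    if g_hat > l_hat:
        direction = "gain-biased"
    elif l_hat > g_hat:
        direction = "loss-biased"
    else:
        direction = "balanced"
    return GainLossEstimate(
        tf_id, n, g_hat, l_hat, ll, accepted, direction,
        uninformative=not informative, surface=surface,
    )


def patterns_from_matrix(matrix: EdgeMatrix, tf: str) -> np.ndarray:
    """Leaf presence patterns (rows) for one TF's edges; ineligible cells
    become -1 (marginalized leaves)."""
    rows = matrix.cells[matrix.cells.index.get_level_values("tf") == tf]
    code = {PRESENT: 1, ABSENT: 0, INELIGIBLE: -1}
    return np.array([[code[v] for v in row.values] for _, row in rows.iterrows()], dtype=int)
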