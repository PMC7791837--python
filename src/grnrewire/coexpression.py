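"""Tissue specificity, tree-aware co-expression modules, and state changes.

Module assignment is a simplified, deterministic stand-in for probabilistic
tree-mixture clustering: module means are learned once on the concatenated
multi-species centered profiles (so labels are directly comparable across
species) and each species is then clustered from those shared means.
Ancestral labels are reconstructed by Sankoff parsimony with unit cost
between distinct modules; ties resolve toward the parent's label, then the
lowest module index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core import SpeciesTree
from .motifs import bh_qvalues

TAU_BROAD_MAX = 0.5
TAU_NARROW_MIN = 0.9


def tau(profile: Sequence[float]) -> Tuple[Optional[float], str]:
    """Tissue-specificity index on a non-negative (log-scale) profile.

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1), in [0, 1]; 0 for uniform
    expression and 1 for single-tissue expression. Categories follow the
    standard cutoffs: broad (tau <= 0.5), intermediate, narrow (tau >= 0.9).
    An all-zero profile has no defined specificity and is flagged.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least two tissues")
    if (x < 0).any():
        raise ValueError("tau requires non-negative values")
    m = x.max()
    if m == 0:
        return None, "undefined"
    t = float((1 - x / m).sum() / (x.size - 1))
    if t <= TAU_BROAD_MAX:
        cat = "broad"
    elif t >= TAU_NARROW_MIN:
        cat = "narrow"
    else:
        cat = "intermediate"
    return t, cat


def tau_table(tensor, species: str) -> pd.DataFrame:
    """Per-gene tau on the log layer of one species."""
    log = tensor.log_layer(species)
    rows = []
    for gene, profile in log.iterrows():
        t, cat = tau(profile.values)
        rows.append((gene, t, cat))
    return pd.DataFrame(rows, columns=["gene", "tau", "category"]).set_index("gene")


# -- module assignment -------------------------------------------------------


@dataclass
class ModuleAssignment:
    """node (species or ancestor) -> orthogroup -> module label."""

    labels: Dict[str, Dict[str, int]]
    k: int

    def of(self, node: str, orthogroup: str) -> Optional[int]:
        return self.labels.get(node, {}).get(orthogroup)


def _canonical_order(centers: np.ndarray) -> np.ndarray:
    """Deterministic module numbering: sort centers lexicographically."""
    return np.lexsort(centers.T[::-1])


def assign_modules(
    tensor, orthology, tree: SpeciesTree, k: int = 10, seed: int = 0
) -> ModuleAssignment:
    """Cluster centered expression profiles into k cross-species modules.

    A single k-means fit on the concatenated (gene, species) profiles yields
    shared module means; each species' genes are then assigned from those
    means, making labels comparable across species. Output is keyed by
    orthogroup.
    """
    species = [s for s in tree.leaf_names if s in tensor.raw]
    blocks = []
    keys = []  # (species, orthogroup)
    gene_to_og = {}
    for og in orthology:
        for sp in species:
            for gid in orthology.genes(og, sp):
                gene_to_og[(sp, gid)] = og
    for sp in species:
        centered = tensor.centered_layer(sp)
        blocks.append(centered.values)
        keys.extend((sp, g) for g in centered.index)
    X = np.vstack(blocks)
    if k > np.unique(X, axis=0).shape[0]:
        raise ValueError("k exceeds the number of distinct profiles")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(X)
    order = _canonical_order(km.cluster_centers_)
    centers = km.cluster_centers_[order]

    labels: Dict[str, Dict[str, int]] = {sp: {} for sp in species}
    start = 0
    for sp, block in zip(species, blocks):
        # per-species assignment from the shared canonical means
        d = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assigned = d.argmin(axis=1)
        genes = [key[1] for key in keys[start : start + block.shape[0]]]
        for g, lab in zip(genes, assigned):
            og = gene_to_og.get((sp, g), g)
            labels[sp][og] = int(lab)
        start += block.shape[0]
    return ModuleAssignment(labels, k)


def ancestral_modules(
    assignment: ModuleAssignment, tree: SpeciesTree
) -> ModuleAssignment:
    """Sankoff parsimony reconstruction of module labels at internal nodes.

    Unit substitution cost between distinct modules; leaves lacking a label
    (gene absent) are uninformative. Top-down ties break toward the parent's
    label, then the lowest module index.
    """
    k = assignment.k
    labels = {node: dict(d) for node, d in assignment.labels.items()}
    ogs = sorted({og for d in assignment.labels.values() for og in d})
    for og in ogs:
        # bottom-up minimal costs
        cost: Dict[str, np.ndarray] = {}
        informative = False
        for node in tree.root.postorder():
            if node.is_leaf:
                lab = assignment.of(node.name, og)
                c = np.zeros(k)
                if lab is not None:
                    c = np.full(k, np.inf)
                    c[lab] = 0.0
                    informative = True
                cost[node.name] = c
            else:
                c = np.zeros(k)
                for child in node.children:
                    child_c = cost[child.name]
                    # min over child state of child cost + substitution cost
                    trans = np.minimum(child_c, child_c.min() + 1.0)
                    c = c + trans
                cost[node.name] = c
        if not informative:
            continue
        # top-down assignment
        for node in tree.root.preorder():
            if node.is_leaf:
                continue
            c = cost[node.name]
            if node is tree.root:
                best = c.min()
                choice = int(np.flatnonzero(c == best)[0])
            else:
                parent_lab = labels[node.parent.name][og]
                total = c + (np.arange(k) != parent_lab)
                best = total.min()
                cands = np.flatnonzero(total == best)
                choice = int(parent_lab) if parent_lab in cands else int(cands[0])
            labels.setdefault(node.name, {})[og] = choice
    return ModuleAssignment(labels, k)


@dataclass
class StateChangeSummary:
    per_node: pd.DataFrame  # node x (assigned, changed_vs_root, changed_vs_lca)
    focal_unique: Dict[str, List[str]]  # focal species -> orthogroups
    convergent: Dict[str, List[str]]  # focal species -> orthogroups


def state_changes(assignment: ModuleAssignment, tree: SpeciesTree) -> StateChangeSummary:
    """Per-node state-change accounting along the tree.

    For every node: how many genes have a label, how many differ from the
    deepest common ancestor (root), and how many differ from their last
    common ancestor (the parent node). Per focal species: genes whose label
    differs from all other extant species (focal-unique), and genes sharing
    a derived label (different from the focal LCA's) with at least one other
    species (convergent).
    """
    root = tree.root.name
    species = tree.leaf_names
    ogs = sorted({og for d in assignment.labels.values() for og in d})
    rows = []
    for node in tree.root.postorder():
        name = node.name
        assigned = changed_root = changed_lca = 0
        for og in ogs:
            lab = assignment.of(name, og)
            if lab is None:
                continue
            assigned += 1
            root_lab = assignment.of(root, og)
            if root_lab is not None and lab != root_lab:
                changed_root += 1
            if node.parent is not None:
                lca_lab = assignment.of(node.parent.name, og)
                if lca_lab is not None and lab != lca_lab:
                    changed_lca += 1
        rows.append((name, assigned, changed_root, changed_lca))
    per_node = pd.DataFrame(
        rows, columns=["node", "assigned", "changed_vs_root", "changed_vs_lca"]
    ).set_index("node")

    focal_unique: Dict[str, List[str]] = {sp: [] for sp in species}
    convergent: Dict[str, List[str]] = {sp: [] for sp in species}
    for focal in species:
        parent = tree.node(focal).parent
        for og in ogs:
            lab = assignment.of(focal, og)
            if lab is None:
                continue
            others = [assignment.of(sp, og) for sp in species if sp != focal]
            present_others = [o for o in others if o is not None]
            if present_others and all(o != lab for o in present_others):
                focal_unique[focal].append(og)
            lca_lab = assignment.of(parent.name, og) if parent is not None else None
            if lca_lab is not None and lab != lca_lab and any(o == lab for o in present_others):
                convergent[focal].append(og)
    return StateChangeSummary(per_node, focal_unique, convergent)


# -- enrichment and correlation ----------------------------------------------


def hypergeom_enrich(
    candidate: Iterable[str],
    annotation_sets: Dict[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH correction across terms.

    fold = (k/n) / (K/N) with N the background size, K the term size in the
    background, n the candidate size, and k the overlap.
    """
    bg = set(background)
    cand = set(candidate)
    if not cand <= bg:
        raise ValueError("candidate set must be a subset of the background")
    N, n = len(bg), len(cand)
    rows = []
    for term, members in annotation_sets.items():
        K = len(set(members) & bg)
        if K == 0:
            continue
        k = len(set(members) & cand)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else np.nan
        rows.append((term, k, K, n, N, fold, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "fold", "p"])
    if len(df):
        df["q"] = bh_qvalues(df["p"].values)
    else:
        df["q"] = []
    return df.set_index("term")


CORRELATION_BANDS = [
    (0.0, 0.01, "none"),
    (0.1, 0.3, "small"),
    (0.3, 0.5, "medium"),
    (0.5, 1.0, "large"),
]


def correlation_band(r: float) -> str:
    """Published correlation bands: none [0, 0.01], small [0.1, 0.3],
    medium (0.3, 0.5], large (0.5, 1]."""
    if 0.0 <= r <= 0.01:
        return "none"
    if 0.1 <= r <= 0.3:
        return "small"
    if 0.3 < r <= 0.5:
        return "medium"
    if 0.5 < r <= 1.0:
        return "large"
    return "unbanded"


def motif_expr_correlation(
    enrichment: Sequence[float], expression: Sequence[float]
) -> dict:
    """Pearson r between per-species motif enrichment (-log q) and TF
    expression, with its two-sided p-value and the published band label."""
    x = np.asarray(enrichment, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired species values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {"r": None, "p": None, "band": "degenerate"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "band": correlation_band(float(r))}


def variance_tails(
    enrichments: pd.DataFrame, tail_frac: float = 0.10
) -> pd.Series:
    """Label TFs by the tails of the cross-species enrichment variance.

    The lowest ``tail_frac`` of variances are 'similar' (comparable motif
    enrichment across species), the highest are 'dissimilar', the rest
    'middle'.
    """
    if len(enrichments) < 10:
        raise ValueError("need at least 10 TFs")
    var = enrichments.var(axis=1, ddof=1)
    labels = pd.Series("middle", index=var.index)
    if tail_frac > 0:
        n_tail = max(1, int(np.floor(tail_frac * len(var))))
        order = var.sort_values(kind="stable")
        labels[order.index[:n_tail]] = "similar"
        labels[order.index[-n_tail:]] = "dissimilar"
    return labels


def alignment_occupancy_filter(
    msa: Dict[str, str], min_frac: float = 0.10, min_nt: int = 100
) -> bool:
    """Require every aligned species row to contain at least ``min_frac`` of
    the alignment as nucleotides and at least ``min_nt`` nucleotides (gaps
    excluded); both thresholds inclusive."""
    if not msa:
        return False
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("aligned rows must be equal length")
    ncols = lengths.pop()
    if ncols == 0:
        return False
    for row in msa.values():
        nt = sum(c not in "-." for c in row)
        if nt < min_nt or nt / ncols < min_frac:
            return False
    return True
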