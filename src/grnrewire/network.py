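"""TF->target-gene network construction, integration, and pruning.

Expression edges come from a per-gene greedy (PGG) regression on the merged
multi-species profile (five species x six tissues = one 30-dimensional
vector per gene): for each target, TFs are added by forward selection on
residual-sum-of-squares reduction with a partial-F entry test. Motif edges
come from significant promoter hits. The integrated cross-species edge
matrix is then pruned by three rules: an edge must be present in at least
two species, must not be absent anywhere because of gene loss or
mis-annotation, and both nodes must belong to co-expression modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModuleAssignment
from .core import OrthologyMap
from .motifs import MotifHit, bh_qvalues

PRESENT, ABSENT, INELIGIBLE = "P", "A", "I"


@dataclass
class EdgeMatrix:
    """(TF orthogroup, TG orthogroup) x species presence matrix.

    Cells are "P" (present), "A" (absent), or "I" (ineligible: the TF or TG
    gene is missing or mis-annotated in that species). ``meta`` carries the
    per-edge max confidence score, min q-value, and evidence source.
    """

    cells: pd.DataFrame  # MultiIndex (tf, tg) x species
    meta: pd.DataFrame  # same index: confidence, q, evidence

    @property
    def species(self) -> List[str]:
        return list(self.cells.columns)

    def __len__(self) -> int:
        return len(self.cells)

    def present_count(self) -> pd.Series:
        return (self.cells == PRESENT).sum(axis=1)


# -- expression-based network (PGG) ------------------------------------------


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


@dataclass
class PggEdge:
    tf: str
    target: str
    step: int
    p_value: float
    q_value: Optional[float] = None


def pgg_network(
    merged: pd.DataFrame,
    tf_list: Sequence[str],
    fdr: float = 0.05,
    p_enter: float = 0.05,
    max_regulators: int = 10,
    targets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene greedy forward selection of TF regulators.

    ``merged`` is genes x merged dimensions (NaN where a species lacks the
    gene). At each step the TF giving the largest residual-sum-of-squares
    reduction is added if its partial-F p-value is <= ``p_enter``; edge
    significance is that partial-F p-value, BH-corrected across all selected
    edges, retaining q < ``fdr``. Fitting is masked least squares on the
    dimensions observed for the target and every fitted TF.
    """
    tf_set = [t for t in tf_list if t in merged.index]
    target_rows = list(targets) if targets is not None else list(merged.index)
    edges: List[PggEdge] = []
    n_candidate_edges = 0
    for target in target_rows:
        y_full = merged.loc[target].values.astype(float)
        candidates = sorted(t for t in tf_set if t != target)
        if not candidates:
            continue
        obs_y = ~np.isnan(y_full)
        if obs_y.sum() < 3 or np.nanvar(y_full) == 0:
            continue  # zero-variance or unusable target: no edges
        n_candidate_edges += len(candidates)
        selected: List[str] = []
        while len(selected) < max_regulators:
            best: Optional[Tuple[float, str, float]] = None  # (rss, tf, p)
            for tf in candidates:
                if tf in selected:
                    continue
                cols = selected + [tf]
                prof = merged.loc[cols].values.astype(float)
                mask = obs_y & ~np.isnan(prof).any(axis=0)
                n = int(mask.sum())
                p_params = len(cols) + 1  # with intercept
                if n <= p_params:
                    continue
                y = y_full[mask]
                X_new = np.column_stack([np.ones(n)] + [p[mask] for p in prof])
                X_old = X_new[:, :-1]
                rss_old = _ols_rss(X_old, y)
                rss_new = _ols_rss(X_new, y)
                df_resid = n - p_params
                if rss_new <= 0:
                    pval = 0.0
                else:
                    f = max(rss_old - rss_new, 0.0) / (rss_new / df_resid)
                    pval = float(stats.f.sf(f, 1, df_resid))
                # deterministic tie-break: larger reduction, then TF id
                key = (round(rss_new, 12), tf)
                if best is None or key < (round(best[0], 12), best[1]):
                    best = (rss_new, tf, pval)
            if best is None or best[2] > p_enter:
                break
            selected.append(best[1])
            edges.append(PggEdge(best[1], target, len(selected), best[2]))
    df = pd.DataFrame(
        [(e.tf, e.target, e.step, e.p_value) for e in edges],
        columns=["tf", "target", "step", "p"],
    )
    if len(df):
        # BH across all candidate (TF, target) pairs tested, not merely the
        # selected ones: unselected candidates count toward m
        df["q"] = _bh_with_total(df["p"].values, n_candidate_edges)
        df = df[df["q"] < fdr].reset_index(drop=True)
    else:
        df["q"] = []
    return df


def _bh_with_total(pvals: np.ndarray, m: int) -> np.ndarray:
    """BH step-up q-values when only the k smallest of m tests are reported."""
    pvals = np.asarray(pvals, dtype=float)
    m = max(m, pvals.size)
    order = np.argsort(pvals, kind="stable")
    ranks = np.arange(1, pvals.size + 1)
    q_sorted = pvals[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# -- motif-based edges --------------------------------------------------------


def motif_edges(
    hits: Iterable[MotifHit],
    orthology: Optional[OrthologyMap] = None,
    tf_orthogroup: Optional[Dict[str, str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One edge per (TF, TG, species) from significant hits (q < alpha),
    with the max confidence and min q across supporting hits."""
    rows: Dict[Tuple[str, str, str], List[MotifHit]] = {}
    for hit in hits:
        if hit.q_value is None or hit.q_value >= alpha:
            continue
        tg = hit.target_gene_id
        if orthology is not None:
            og = orthology.orthogroup_of(tg)
            tg = og if og is not None else tg
        tf = hit.tf_id
        if tf_orthogroup:
            tf = tf_orthogroup.get(tf, tf)
        rows.setdefault((tf, tg, hit.species_id), []).append(hit)
    out = []
    for (tf, tg, sp), group in rows.items():
        confs = [h.confidence_score for h in group if h.confidence_score is not None]
        out.append(
            (
                tf,
                tg,
                sp,
                max(confs) if confs else None,
                min(h.q_value for h in group),
            )
        )
    return pd.DataFrame(out, columns=["tf", "tg", "species", "confidence", "q"])


# -- integration and pruning --------------------------------------------------


def project_eligibility(
    tf_og: str,
    tg_og: str,
    species: Sequence[str],
    orthology: OrthologyMap,
    flagged_missing: Optional[Dict[str, Set[str]]] = None,
) -> Dict[str, Optional[str]]:
    """Species -> ineligibility reason (None when both nodes are usable).

    A species lacking the TF or TG gene makes the edge ineligible there
    ("gene loss"); a gene flagged as present in the genome but missing from
    the annotation makes it ineligible with reason "mis-annotation".
    """
    flagged_missing = flagged_missing or {}
    out: Dict[str, Optional[str]] = {}
    for sp in species:
        reason = None
        for og in (tf_og, tg_og):
            genes = orthology.genes(og, sp) if og in orthology.groups else []
            flagged = flagged_missing.get(sp, set())
            # the flag table may name either gene ids or the orthogroup itself
            if og in flagged or any(g in flagged for g in genes):
                reason = "mis-annotation"
                break
            if not genes:
                reason = "gene loss"
        out[sp] = reason
    return out


def integrate_and_prune(
    expr_edges: pd.DataFrame,
    motif_edge_df: pd.DataFrame,
    modules: ModuleAssignment,
    orthology: OrthologyMap,
    species: Sequence[str],
    flagged_missing: Optional[Dict[str, Set[str]]] = None,
    require_both: bool = False,
) -> EdgeMatrix:
    """Union (or intersection with ``require_both``) of expression and motif
    evidence per edge, followed by the three pruning rules.

    Orthogroups whose many-to-many members include a flagged-missing gene in
    any species are removed entirely before the per-row rules.
    """
    flagged_missing = flagged_missing or {}
    presence: Dict[Tuple[str, str], Dict[str, Set[str]]] = {}

    def add(tf, tg, sp, source):
        presence.setdefault((tf, tg), {}).setdefault(sp, set()).add(source)

    if len(expr_edges):
        for _, row in expr_edges.iterrows():
            for sp in row.get("species", ",".join(species)).split(","):
                add(row["tf"], row["target"] if "target" in row else row["tg"], sp, "expression")
    if len(motif_edge_df):
        for _, row in motif_edge_df.iterrows():
            add(row["tf"], row["tg"], row["species"], "motif")

    # flagged many-to-many orthogroups are dropped wholesale
    bad_ogs = set()
    for og in orthology:
        if orthology.cardinality(og) != "many-to-many":
            continue
        for sp, flagged in flagged_missing.items():
            genes = set(orthology.genes(og, sp))
            others = {
                g
                for s2, flg in flagged_missing.items()
                for g in flg
                if orthology.orthogroup_of(g) == og
            }
            if genes & flagged or others:
                bad_ogs.add(og)
                break

    conf_lookup: Dict[Tuple[str, str], Tuple[Optional[float], Optional[float]]] = {}
    if len(motif_edge_df):
        for (tf, tg), grp in motif_edge_df.groupby(["tf", "tg"]):
            confs = grp["confidence"].dropna()
            conf_lookup[(tf, tg)] = (
                float(confs.max()) if len(confs) else None,
                float(grp["q"].min()),
            )

    module_ogs = {
        og for node, d in modules.labels.items() for og in d
    }

    cells_rows, meta_rows, index = [], [], []
    for (tf, tg), per_sp in sorted(presence.items()):
        if tf in bad_ogs or tg in bad_ogs:
            continue
        eligibility = project_eligibility(tf, tg, species, orthology, flagged_missing)
        row = {}
        for sp in species:
            if eligibility[sp] is not None:
                row[sp] = INELIGIBLE
            elif sp in per_sp and (
                not require_both or per_sp[sp] >= {"expression", "motif"}
            ):
                row[sp] = PRESENT
            else:
                row[sp] = ABSENT
        # rule 2: absence caused by node loss / mis-annotation removes the row
        if INELIGIBLE in row.values():
            continue
        # rule 1: present in at least two species
        if sum(v == PRESENT for v in row.values()) < 2:
            continue
        # rule 3: both nodes belong to co-expression modules
        if tf not in module_ogs or tg not in module_ogs:
            continue
        conf, q = conf_lookup.get((tf, tg), (None, None))
        sources = {s for srcs in per_sp.values() for s in srcs}
        evidence = "both" if len(sources) == 2 else next(iter(sources))
        index.append((tf, tg))
        cells_rows.append(row)
        meta_rows.append({"confidence": conf, "q": q, "evidence": evidence})

    idx = pd.MultiIndex.from_tuples(index, names=["tf", "tg"]) if index else pd.MultiIndex.from_arrays([[], []], names=["tf", "tg"])
    cells = pd.DataFrame(cells_rows, index=idx, columns=list(species))
    meta = pd.DataFrame(meta_rows, index=idx, columns=["confidence", "q", "evidence"])
    return EdgeMatrix(cells, meta)


def prune(matrix: EdgeMatrix, modules: ModuleAssignment) -> EdgeMatrix:
    """Apply the three pruning rules to an existing edge matrix (idempotent)."""
    module_ogs = {og for d in modules.labels.values() for og in d}
    keep = []
    for (tf, tg), row in matrix.cells.iterrows():
        if INELIGIBLE in row.values:
            keep.append(False)
        elif (row == PRESENT).sum() < 2:
            keep.append(False)
        elif tf not in module_ogs or tg not in module_ogs:
            keep.append(False)
        else:
            keep.append(True)
    mask = np.array(keep, dtype=bool) if keep else np.array([], dtype=bool)
    return EdgeMatrix(matrix.cells[mask], matrix.meta[mask])


def write_edge_matrix(matrix: EdgeMatrix, path) -> None:
    df = matrix.cells.join(matrix.meta)
    df.to_csv(path, sep="\t")


def read_edge_matrix(path, species: Sequence[str]) -> EdgeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=[0, 1])
    cells = df[list(species)]
    meta = df[["confidence", "q", "evidence"]]
    return EdgeMatrix(cells, meta)
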