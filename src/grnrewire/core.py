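"""Shared data model for the comparative regulatory-network pipeline.

All genomic coordinates are 0-based half-open internally; conversion to and
from 1-based (GFF3, VCF) happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene with a strand-aware TSS and orthology membership.

    ``annotated_but_flagged_missing`` marks genes absent from a species'
    annotation but present in its genome per upstream homology evidence;
    downstream edge pruning treats such absences as mis-annotation, not loss.
    """

    gene_id: str
    species_id: str
    interval: GenomicInterval
    orthogroup_id: Optional[str] = None
    is_tf: bool = False
    annotated_but_flagged_missing: bool = False

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class TreeNode:
    """Node of a rooted tree with branch lengths (length = edge to parent)."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterable["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()


class SpeciesTree:
    """Rooted binary species tree with labeled internal (ancestor) nodes."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._autolabel()
        names = [n.name for n in root.postorder()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node labels in tree")
        for node in root.postorder():
            if node.children and len(node.children) != 2:
                raise ValueError(
                    f"node {node.name!r} is not binary ({len(node.children)} children)"
                )
            if node is not root and node.length is None:
                raise ValueError(f"missing branch length above {node.name!r}")
            if node is not root and node.length < 0:
                raise ValueError(f"negative branch length above {node.name!r}")

    def _autolabel(self) -> None:
        # unlabeled internal nodes get Anc1..AncK in post-order
        k = 0
        for node in self.root.postorder():
            if not node.is_leaf and not node.name:
                k += 1
                node.name = f"Anc{k}"

    @property
    def leaves(self) -> List[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves]

    def node(self, name: str) -> TreeNode:
        for n in self.root.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + (
                    node.name or ""
                )
            if node.parent is not None:
                core += f":{node.length:g}"
            return core

        return fmt(self.root) + ";"


class OrthologyMap:
    """orthogroup_id -> {species_id: [gene_ids]} with cardinality classes."""

    def __init__(self, groups: Dict[str, Dict[str, List[str]]]):
        self.groups = groups
        seen: Dict[str, str] = {}
        for og, per_sp in groups.items():
            for genes in per_sp.values():
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g} in both {seen[g]} and {og}"
                        )
                    seen[g] = og
        self._gene_to_og = seen

    def cardinality(self, orthogroup_id: str) -> str:
        per_sp = self.groups[orthogroup_id]
        if all(len(genes) <= 1 for genes in per_sp.values()):
            return "one-to-one"
        return "many-to-many"

    def orthogroup_of(self, gene_id: str) -> Optional[str]:
        return self._gene_to_og.get(gene_id)

    def genes(self, orthogroup_id: str, species_id: str) -> List[str]:
        return self.groups.get(orthogroup_id, {}).get(species_id, [])

    def species_with_gene(self, orthogroup_id: str) -> List[str]:
        return [s for s, g in self.groups[orthogroup_id].items() if g]

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)


class ExpressionTensor:
    """Per-species gene x tissue expression with three layers.

    raw values are FPKM-like non-negative; log layer is log(x+1) with the
    natural logarithm; centered layer is the log layer made zero-mean per
    gene across tissues. Genes missing from a species are genuinely absent
    (no row), never imputed as zero.
    """

    def __init__(self, frames: Dict[str, pd.DataFrame], tissues: Sequence[str]):
        self.tissues = list(tissues)
        self.raw: Dict[str, pd.DataFrame] = {}
        for sp, df in frames.items():
            df = df.loc[:, self.tissues].astype(float)
            if (df.values < 0).any():
                raise ValueError(f"negative expression values for {sp}")
            if df.index.duplicated().any():
                dup = df.index[df.index.duplicated()][0]
                raise ValueError(f"duplicated gene row {dup!r} for {sp}")
            self.raw[sp] = df

    @property
    def species(self) -> List[str]:
        return list(self.raw)

    def log_layer(self, species: str) -> pd.DataFrame:
        return np.log(self.raw[species] + 1.0)

    def centered_layer(self, species: str) -> pd.DataFrame:
        log = self.log_layer(species)
        return log.sub(log.mean(axis=1), axis=0)

    def genes(self, species: str) -> pd.Index:
        return self.raw[species].index

    def merged_profiles(self, species_order: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Concatenate per-species centered profiles into one wide matrix.

        Columns are (species, tissue) pairs; genes are keyed by gene id and
        rows contain NaN for species where the gene is absent.
        """
        order = list(species_order or self.species)
        parts = []
        for sp in order:
            c = self.centered_layer(sp)
            c.columns = [f"{sp}:{t}" for t in self.tissues]
            parts.append(c)
        return pd.concat(parts, axis=1)


@dataclass
class VariantRecord:
    """A single-nucleotide variant, optionally with per-sample genotypes."""

    interval: GenomicInterval
    ref: str
    alt: str
    source: str = "pairwise"  # or "population"
    genotypes: Dict[str, tuple] = field(default_factory=dict)  # sample -> (a0, a1)
    phased: Dict[str, bool] = field(default_factory=dict)
    motif_hits: list = field(default_factory=list)
    concordant: Optional[bool] = None
    flank_conserved: Optional[bool] = None

    def __post_init__(self):
        for allele in (self.ref, self.alt):
            if allele not in ("A", "C", "G", "T"):
                raise ValueError(f"invalid allele {allele!r}")
        if len(self.interval) != 1:
            raise ValueError("variant records are single-nucleotide")

    @property
    def pos(self) -> int:
        return self.interval.start
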