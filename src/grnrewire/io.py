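"""Readers and writers for the standard formats the pipeline touches.

GFF3 is 1-based inclusive and converted to the internal 0-based half-open
convention on read; BED is passed through; VCF positions are converted from
1-based to 0-based. Newick trees are parsed with dendropy and converted to
the internal light-weight tree.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import dendropy
import pandas as pd

from .core import (
    ExpressionTensor,
    GeneModel,
    GenomicInterval,
    OrthologyMap,
    SpeciesTree,
    TreeNode,
    VariantRecord,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def _gff3_attributes(field: str) -> Dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path, species_id: str, feature_types=("gene",)) -> List[GeneModel]:
    """Read gene models from a GFF3 or BED file (dialect chosen by suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed6"):
        return _read_bed(path, species_id)
    return _read_gff3(path, species_id, feature_types)


def _read_gff3(path: Path, species_id: str, feature_types) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in feature_types:
                continue
            if strand not in ("+", "-"):
                logger.warning("%s:%d: unknown strand %r, record skipped", path, lineno, strand)
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attributes = _gff3_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene record without ID attribute")
            # GFF3 1-based inclusive -> 0-based half-open
            interval = GenomicInterval(contig, start_i - 1, end_i, strand)
            genes.append(GeneModel(gene_id=gene_id, species_id=species_id, interval=interval))
    return genes


def _read_bed(path: Path, species_id: str) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            contig, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                logger.warning("%s:%d: unknown strand %r, record skipped", path, lineno, strand)
                continue
            interval = GenomicInterval(contig, int(start), int(end), strand)
            genes.append(GeneModel(gene_id=name, species_id=species_id, interval=interval))
    return genes


def write_bed(records, path) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as fh:
        for interval, name, score in records:
            fh.write(
                f"{interval.contig}\t{interval.start}\t{interval.end}\t"
                f"{name}\t{score}\t{interval.strand}\n"
            )


def read_expression(paths: Dict[str, object], tissue_order: Sequence[str]) -> ExpressionTensor:
    """Read per-species gene x tissue TSVs into an ExpressionTensor."""
    frames = {}
    for species, path in paths.items():
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [t for t in tissue_order if t not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing tissue columns {missing}")
        frames[species] = df
    return ExpressionTensor(frames, tissue_order)


def write_expression(tensor: ExpressionTensor, directory, prefix="expr") -> Dict[str, Path]:
    out = {}
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sp in tensor.species:
        p = directory / f"{prefix}_{sp}.tsv"
        tensor.raw[sp].to_csv(p, sep="\t")
        out[sp] = p
    return out


def read_tree(path_or_str) -> SpeciesTree:
    """Read a rooted binary Newick tree with branch lengths."""
    text = str(path_or_str)
    if not text.strip().endswith(";") or "(" not in text:
        text = Path(path_or_str).read_text()
    dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(name=label, length=dnode.edge.length if dnode.edge.length is not None else None)
        for child in dnode.child_nodes():
            cnode = convert(child)
            if cnode.length is None:
                raise ParseError(f"missing branch length above node {cnode.name!r}")
            node.parent = None
            node.add_child(cnode)
        return node

    root = convert(dtree.seed_node)
    if root.length is None:
        root.length = 0.0
    if len(root.children) > 2:
        raise ParseError("unresolved polytomy at root; metrics require a rooted binary tree")
    return SpeciesTree(root)


def read_orthology(path) -> OrthologyMap:
    """Read a TSV orthogroup table: orthogroup, species, comma-joined genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups: Dict[str, Dict[str, List[str]]] = {}
    for _, row in df.iterrows():
        og = groups.setdefault(row.iloc[0], {})
        genes = [] if pd.isna(row.iloc[2]) or row.iloc[2] == "" else row.iloc[2].split(",")
        og[row.iloc[1]] = genes
    return OrthologyMap(groups)


def write_orthology(orthology: OrthologyMap, path) -> None:
    rows = []
    for og, per_sp in orthology.groups.items():
        for sp, genes in per_sp.items():
            rows.append((og, sp, ",".join(genes)))
    pd.DataFrame(rows, columns=["orthogroup", "species", "genes"]).to_csv(
        path, sep="\t", index=False
    )


def _parse_gt(token: str):
    """Parse a VCF GT field against ref/alt indices -> (alleles, phased)."""
    phased = "|" in token
    sep = "|" if phased else "/"
    parts = token.split(sep)
    alleles = []
    for p in parts:
        if p == ".":
            alleles.append(None)
        else:
            alleles.append(int(p))
    return tuple(alleles), phased


def read_variants(path, source: str = "pairwise") -> List[VariantRecord]:
    """Read single-nucleotide variants from VCF 4.x text or a 5-column TSV.

    VCF POS (1-based) is converted to the internal 0-based coordinate. Phased
    genotypes keep allele order.
    """
    path = Path(path)
    records: List[VariantRecord] = []
    with open(path) as fh:
        samples: List[str] = []
        is_vcf = path.suffix.lower() == ".vcf"
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                is_vcf = True
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_vcf:
                if len(fields) < 8:
                    raise ParseError(f"{path}:{lineno}: truncated VCF record")
                contig, pos, _vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
                sample_fields = fields[9:]
            else:
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: TSV requires contig, pos, ref, alt")
                contig, pos, ref, alt = fields[:4]
                sample_fields = fields[4:]
                samples = samples or [f"sample{i+1}" for i in range(len(sample_fields))]
            pos0 = int(pos) - 1
            interval = GenomicInterval(contig, pos0, pos0 + 1, "+")
            genotypes, phased = {}, {}
            alleles_by_index = [ref] + alt.split(",")
            for name, token in zip(samples, sample_fields):
                gt_token = token.split(":")[0]
                idx, ph = _parse_gt(gt_token)
                genotypes[name] = tuple(
                    None if i is None else alleles_by_index[i] for i in idx
                )
                phased[name] = ph
            records.append(
                VariantRecord(
                    interval=interval, ref=ref, alt=alt.split(",")[0],
                    source=source, genotypes=genotypes, phased=phased,
                )
            )
    return records


def read_module_assignment(path, k: int = 10):
    """Load externally computed module labels from a TSV with columns
    (node, orthogroup, module)."""
    from .coexpression import ModuleAssignment

    df = pd.read_csv(path, sep="\t", dtype={"module": int})
    labels: Dict[str, Dict[str, int]] = {}
    for _, row in df.iterrows():
        labels.setdefault(str(row.iloc[0]), {})[str(row.iloc[1])] = int(row.iloc[2])
    observed_k = max((lab for d in labels.values() for lab in d.values()), default=-1) + 1
    return ModuleAssignment(labels, max(k, observed_k))


def read_missing_flags(path) -> Dict[str, set]:
    """Read the (gene_id, species) table of genes present in the genome but
    absent from the annotation; returns species -> set of gene ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(row.iloc[1], set()).add(row.iloc[0])
    return out
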