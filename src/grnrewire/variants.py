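"""Overlap of variants with predicted binding sites and segregation classes.

Variants are intersected with motif hit intervals (half-open convention),
alleles are complemented into the motif frame for minus-strand motifs,
between-species variants are checked for concordance against orthologous
promoter alignments with flank conservation, and population genotypes are
classified relative to a reference species' allele as conserved,
heterozygous-segregating, or homozygous-segregated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .core import VariantRecord
from .motifs import MotifHit

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TfbsOverlap:
    hit: MotifHit
    motif_position: int  # 0-based position within the motif, motif frame
    ref_motif_frame: str
    alt_motif_frame: str


def intersect_tfbs(
    variants: Iterable[VariantRecord], hits: Sequence[MotifHit]
) -> List[VariantRecord]:
    """Annotate variants with every motif hit they fall inside.

    Intervals are half-open; a variant at motif position j (motif strand) is
    recorded at j after strand complementation. Returns the variants that
    overlap at least one hit.
    """
    by_contig: Dict[str, List[MotifHit]] = {}
    for h in hits:
        by_contig.setdefault(h.interval.contig, []).append(h)
    out = []
    for v in variants:
        v.motif_hits = []
        for h in by_contig.get(v.interval.contig, []):
            if h.interval.start <= v.pos < h.interval.end:
                pos_plus = v.pos - h.interval.start
                overlap = complement_context(v, h, pos_plus)
                v.motif_hits.append(overlap)
        if v.motif_hits:
            out.append(v)
    return out


def complement_context(
    record: VariantRecord, hit: MotifHit, genome_frame_position: int
) -> TfbsOverlap:
    """Express a variant's alleles and position in the motif frame.

    For a minus-strand motif the alleles are complemented and the position
    mirrored within the motif width; applying the transform twice restores
    the genome frame (involution).
    """
    width = len(hit.interval)
    for allele in (record.ref, record.alt):
        if allele not in _COMP:
            raise ValueError(f"ambiguous allele {allele!r}")
    if hit.strand == "+":
        return TfbsOverlap(hit, genome_frame_position, record.ref, record.alt)
    return TfbsOverlap(
        hit,
        width - 1 - genome_frame_position,
        _COMP[record.ref],
        _COMP[record.alt],
    )


def concordance_filter(
    record: VariantRecord,
    msa: Dict[str, str],
    reference_species: str,
    other_species: str,
    column: int,
    reference_revcomp: bool = False,
) -> Tuple[bool, Optional[str]]:
    """Check that an alignment column shows exactly ref in the reference
    species row and alt in the other species' row.

    ``column`` is the alignment column the variant lifts to;
    ``reference_revcomp`` signals that the promoter rows are stored on the
    opposite strand from the variant's genome frame, in which case alleles
    are complemented before comparison. Returns (concordant, reason).
    """
    ref_row = msa[reference_species]
    other_row = msa[other_species]
    a, b = ref_row[column].upper(), other_row[column].upper()
    if a in "-." or b in "-.":
        return False, "gap"
    ref, alt = record.ref, record.alt
    if reference_revcomp:
        ref, alt = _COMP[ref], _COMP[alt]
    if a == ref and b == alt:
        return True, None
    return False, "allele mismatch"


def flank_conservation(
    msa: Dict[str, str],
    reference_species: str,
    other_species: str,
    column: int,
    flank: int = 20,
    min_identity: float = 0.90,
    min_columns: int = 10,
) -> bool:
    """Identity over +-``flank`` alignment columns around the variant.

    Gaps count as mismatches. Each side is evaluated on the available
    columns (at least ``min_columns``); both sides must reach
    ``min_identity``.
    """
    ref_row = msa[reference_species].upper()
    other_row = msa[other_species].upper()

    def side_identity(cols: range) -> Optional[float]:
        cols = [c for c in cols if 0 <= c < len(ref_row)]
        if len(cols) < min_columns:
            return None
        matches = sum(
            ref_row[c] == other_row[c] and ref_row[c] not in "-." for c in cols
        )
        return matches / len(cols)

    left = side_identity(range(column - flank, column))
    right = side_identity(range(column + 1, column + 1 + flank))
    for ident in (left, right):
        if ident is None or ident < min_identity:
            return False
    return True


VALID_CLASSES = ("conserved", "het_segregating", "hom_segregated", "missing")


def classify_segregation(
    record: VariantRecord, reference_allele: str
) -> pd.Series:
    """Per-sample genotype class relative to the reference species' allele.

    conserved = homozygous for the reference allele; het_segregating =
    heterozygous (phase-independent); hom_segregated = homozygous for the
    other allele; samples with missing genotypes are classed "missing".
    """
    alleles = {record.ref, record.alt}
    if reference_allele not in alleles:
        raise ValueError("reference allele must be one of ref/alt")
    other = (alleles - {reference_allele}).pop()
    out = {}
    for sample, gt in record.genotypes.items():
        if any(a is None for a in gt):
            out[sample] = "missing"
            continue
        if set(gt) - alleles:
            raise ValueError(f"multi-allelic genotype {gt} at {record.pos}")
        a0, a1 = gt
        if a0 != a1:
            out[sample] = "het_segregating"
        elif a0 == reference_allele:
            out[sample] = "conserved"
        else:
            out[sample] = "hom_segregated"
    return pd.Series(out, name="class")


def classify_panel(
    variants: Sequence[VariantRecord], reference_sample: str
) -> pd.DataFrame:
    """Classify every site of a population panel against the genotype of
    one reference sample (which must be homozygous at each site)."""
    rows = {}
    for i, v in enumerate(variants):
        ref_gt = v.genotypes[reference_sample]
        if ref_gt[0] != ref_gt[1]:
            raise ValueError(
                f"reference sample heterozygous at site {i}; reference allele undefined"
            )
        rows[f"site{i}"] = classify_segregation(v, ref_gt[0])
    return pd.DataFrame(rows).T
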