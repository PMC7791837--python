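"""PSSM construction, promoter scanning, and exact score p-values.

Motif models are built either from binding sites extrapolated from vertebrate
(human/mouse) evidence into study-species promoters, or from JASPAR-style
count matrices. A species with at least ``min_cs_sites`` extrapolated sites
gets its own species-specific (CS) matrix; otherwise sites from all species
are pooled into a generic cross-species (CW) matrix.

Per-window p-values are exact under an i.i.d. background, computed by
dynamic-programming convolution of per-column score distributions on a
discretized log-odds lattice. Hits are filtered per window at a per-hit
p-value threshold (default 1e-4) and per scan family at FDR < 0.05 by
Benjamini-Hochberg over all tested windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import GeneModel, GenomicInterval, revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: published confidence tiers: evidence class -> (tier, score)
CONFIDENCE_TIERS = {
    "extrapolated_mouse_human": ("1a", 0.3),
    "extrapolated_mouse": ("1b", 0.2),
    "extrapolated_human": ("1c", 0.15),
    "scan_CS": ("2a", 0.125),
    "scan_CW": ("2b", 0.110),
    "scan_JASPAR": ("2c", 0.115),
}

DEFAULT_P_THRESHOLD = 1e-4
PROMOTER_RETAIN_BP = 5000
SCAN_SPAN_BP = 20000


class PSSM:
    """Position-specific scoring model with exact p-value support.

    Scores are natural-log odds of pseudocount-smoothed site frequencies
    against the background; a base whose frequency equals the background
    scores 0.
    """

    def __init__(
        self,
        tf_id: str,
        counts: np.ndarray,
        background: Optional[Sequence[float]] = None,
        pseudocount: float = 0.25,
        provenance: str = "JASPAR",
        p_threshold: float = DEFAULT_P_THRESHOLD,
        granularity: float = 1e-3,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("count matrix must be 4 x width")
        if counts.shape[1] < 4:
            raise ValueError("motif width must be >= 4")
        if provenance not in ("CS", "CW", "JASPAR"):
            raise ValueError(f"unknown provenance {provenance!r}")
        self.tf_id = tf_id
        self.counts = counts
        self.background = np.asarray(
            background if background is not None else [0.25] * 4, dtype=float
        )
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        self.pseudocount = float(pseudocount)
        self.provenance = provenance
        self.p_threshold = float(p_threshold)
        self.granularity = float(granularity)

        totals = counts.sum(axis=0)
        self.freq = (counts + self.pseudocount) / (totals + 4 * self.pseudocount)
        with np.errstate(divide="ignore"):
            # -inf entries are allowed (zero pseudocount); the exact p-value
            # machinery requires finite entries and checks separately
            self.log_odds = np.log(self.freq / self.background[:, None])
        self._sf_cache: Dict[bool, Tuple[int, np.ndarray]] = {}

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=0))

    def information_content(self) -> float:
        """Total information content in bits (uniform-background definition)."""
        f = self.freq
        return float((f * (np.log2(np.maximum(f, 1e-300)) + 2)).sum())

    def max_ic_column(self) -> int:
        f = self.freq
        ic = (f * (np.log2(np.maximum(f, 1e-300)) + 2)).sum(axis=0)
        return int(ic.argmax())

    def reverse_complement_matrix(self) -> np.ndarray:
        return self.log_odds[_COMP_IDX][:, ::-1]

    # -- exact p-values ----------------------------------------------------

    def _lattice(self, matrix: np.ndarray) -> np.ndarray:
        if not np.isfinite(matrix).all():
            raise ValueError("non-finite score entries; use a positive pseudocount")
        return np.round(matrix / self.granularity).astype(np.int64)

    def _score_distribution(self, rc: bool) -> Tuple[int, np.ndarray]:
        """Survival function of the lattice score under i.i.d. background.

        Returns (offset, sf) where sf[k - offset] = P(lattice score >= k).
        """
        if rc in self._sf_cache:
            return self._sf_cache[rc]
        matrix = self.reverse_complement_matrix() if rc else self.log_odds
        lat = self._lattice(matrix)
        lo = int(lat.min(axis=0).sum())
        hi = int(lat.max(axis=0).sum())
        pmf = np.zeros(hi - lo + 1)
        offset = 0  # current minimum achievable sum
        pmf[0] = 1.0
        cur_lo, cur_hi = 0, 0
        for col in range(lat.shape[1]):
            new_lo = cur_lo + int(lat[:, col].min())
            new_hi = cur_hi + int(lat[:, col].max())
            new = np.zeros(hi - lo + 1)
            for b in range(4):
                shift = int(lat[b, col])
                src = pmf[: cur_hi - cur_lo + 1]
                start = (cur_lo + shift) - new_lo
                new[start : start + src.size] += self.background[b] * src
            pmf = new
            cur_lo, cur_hi = new_lo, new_hi
        sf = np.cumsum(pmf[::-1])[::-1]
        # clamp accumulated float error
        sf = np.minimum(sf, 1.0)
        self._sf_cache[rc] = (cur_lo, sf)
        return self._sf_cache[rc]

    def exact_pvalue(self, score: float, rc: bool = False) -> float:
        """P(window score >= ``score``) under the i.i.d. background."""
        if not np.isfinite(score):
            raise ValueError("non-finite score")
        offset, sf = self._score_distribution(rc)
        k = int(round(score / self.granularity))
        idx = k - offset
        if idx <= 0:
            return 1.0
        if idx >= sf.size:
            return 0.0
        return float(sf[idx])

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


@dataclass
class MotifHit:
    tf_id: str
    target_gene_id: str
    species_id: str
    interval: GenomicInterval  # genome coordinates
    strand: str
    score: float
    p_value: float
    tss_offset: int  # distance (bp) of the hit start upstream of the TSS
    q_value: Optional[float] = None
    confidence_tier: Optional[str] = None
    confidence_score: Optional[float] = None


@dataclass
class ScanResult:
    """All retained hits for one (PSSM, promoter) scan plus the p-values of
    every tested window (needed for FDR correction over the full family)."""

    tf_id: str
    target_gene_id: str
    species_id: str
    hits: List[MotifHit]
    all_pvalues: np.ndarray
    n_windows: int


@dataclass
class SiteMatch:
    """A vertebrate site extrapolated into a study-species promoter."""

    tf_id: str
    species_id: str
    sequence: str  # motif-strand oriented
    identity: float
    start: int  # promoter-relative start
    strand: str
    source_organisms: frozenset = frozenset()


# -- promoter handling -----------------------------------------------------


def extract_promoter(
    gene: GeneModel, contig_seq: str, max_len: int = PROMOTER_RETAIN_BP
) -> Tuple[str, GenomicInterval]:
    """Return up to ``max_len`` bases upstream of the TSS on the gene strand.

    The returned sequence reads 5'->3' on the gene's strand with its last
    base immediately TSS-proximal; truncated at the contig boundary.
    """
    tss = gene.tss
    contig_len = len(contig_seq)
    if not (0 <= tss < contig_len):
        raise ValueError(f"TSS {tss} outside contig of length {contig_len}")
    if gene.interval.strand == "+":
        start = max(0, tss - max_len)
        seq = contig_seq[start:tss]
        iv_start, iv_end = start, tss
    else:
        start = tss + 1
        end = min(contig_len, start + max_len)
        seq = revcomp(contig_seq[start:end])
        iv_start, iv_end = start, end
    if not seq:
        return "", GenomicInterval(gene.interval.contig, max(iv_start, 0), max(iv_end, 1), gene.interval.strand)
    return seq.upper(), GenomicInterval(
        gene.interval.contig, iv_start, iv_end, gene.interval.strand
    )


def extrapolate_site(
    tf_id: str,
    species_id: str,
    source_site: str,
    promoter: str,
    min_identity: float = 0.70,
    source_organisms: Iterable[str] = (),
) -> Optional[SiteMatch]:
    """Best ungapped match of a vertebrate site within a promoter.

    Both strands are searched; ties are broken toward the most TSS-proximal
    position (promoters end at the TSS, so the largest start index) and then
    the + strand. Accepted iff identity >= ``min_identity`` (inclusive).
    """
    site = source_site.upper()
    w = len(site)
    if w > len(promoter):
        return None
    site_rc = revcomp(site)
    best = None  # (identity, start, strand_rank)
    n = len(promoter) - w + 1
    for i in range(n):
        window = promoter[i : i + w]
        for strand, probe in (("+", site), ("-", site_rc)):
            ident = sum(a == b for a, b in zip(window, probe)) / w
            key = (ident, i, 0 if strand == "+" else -1)
            if best is None or key > best[0]:
                best = (key, window, strand)
    (ident, start, _), window, strand = best
    if ident < min_identity:
        return None
    seq = window if strand == "+" else revcomp(window)
    return SiteMatch(
        tf_id=tf_id,
        species_id=species_id,
        sequence=seq,
        identity=ident,
        start=start,
        strand=strand,
        source_organisms=frozenset(source_organisms),
    )


# -- PSSM construction ------------------------------------------------------


def counts_from_sites(sites: Sequence[str]) -> np.ndarray:
    if not sites:
        raise ValueError("cannot build a matrix from zero sites")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("unequal site lengths")
    counts = np.zeros((4, w))
    for s in sites:
        for j, b in enumerate(s.upper()):
            counts[BASE_INDEX[b], j] += 1
    return counts


def build_pssms(
    tf_id: str,
    sites_by_species: Dict[str, Sequence[str]],
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.25,
    min_cs_sites: int = 3,
) -> Dict[str, PSSM]:
    """Per-species matrices: CS from a species' own sites when it has at
    least ``min_cs_sites``, otherwise a shared CW matrix pooled over all
    species' sites."""
    pooled = [s for sites in sites_by_species.values() for s in sites]
    if not pooled:
        raise ValueError(f"zero sites for {tf_id}")
    cw: Optional[PSSM] = None
    out: Dict[str, PSSM] = {}
    for species, sites in sites_by_species.items():
        if len(sites) >= min_cs_sites:
            out[species] = PSSM(
                tf_id, counts_from_sites(sites), background, pseudocount, "CS"
            )
        else:
            if cw is None:
                cw = PSSM(
                    tf_id, counts_from_sites(pooled), background, pseudocount, "CW"
                )
            out[species] = cw
    return out


def read_jaspar(path, background=None, pseudocount: float = 0.25) -> Dict[str, PSSM]:
    """Read JASPAR 2018 PFM text format into PSSMs (provenance JASPAR)."""
    from Bio import motifs as bio_motifs

    out = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            name = m.name or m.matrix_id
            out[name] = PSSM(name, counts, background, pseudocount, "JASPAR")
    return out


# -- scanning ---------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)  # 4 = N / other
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan(
    pssm: PSSM,
    promoter: str,
    gene: Optional[GeneModel] = None,
    species_id: str = "",
    target_gene_id: str = "",
    promoter_interval: Optional[GenomicInterval] = None,
    p_threshold: Optional[float] = None,
    max_n_frac: float = 0.20,
) -> ScanResult:
    """Score every window on both strands; retain windows with exact
    p <= per-hit threshold. Ambiguous bases contribute 0 to the score and
    windows with more than ``max_n_frac`` ambiguous bases are skipped."""
    if gene is not None:
        species_id = species_id or gene.species_id
        target_gene_id = target_gene_id or gene.gene_id
    w = pssm.width
    threshold = pssm.p_threshold if p_threshold is None else p_threshold
    enc = _encode(promoter)
    L = enc.size
    hits: List[MotifHit] = []
    all_p: List[float] = []
    n_windows = 0
    if L < w:
        return ScanResult(pssm.tf_id, target_gene_id, species_id, hits, np.array([]), 0)

    for rc, strand in ((False, "+"), (True, "-")):
        matrix = pssm.reverse_complement_matrix() if rc else pssm.log_odds
        lat = pssm._lattice(matrix)
        # pad with an all-zero row for N
        lo_pad = np.vstack([matrix, np.zeros(w)])
        lat_pad = np.vstack([lat, np.zeros(w, dtype=np.int64)])
        idx = np.lib.stride_tricks.sliding_window_view(enc, w)
        n_count = (idx == 4).sum(axis=1)
        ok = n_count <= max_n_frac * w
        cols = np.arange(w)
        scores = lo_pad[idx, cols].sum(axis=1)
        lat_scores = lat_pad[idx, cols].sum(axis=1)
        offset, sf = pssm._score_distribution(rc)
        ii = np.clip(lat_scores - offset, 0, sf.size - 1)
        pvals = np.where(lat_scores - offset <= 0, 1.0,
                         np.where(lat_scores - offset >= sf.size, 0.0, sf[ii]))
        for i in np.nonzero(ok)[0]:
            n_windows += 1
            p = float(pvals[i])
            all_p.append(p)
            if p <= threshold:
                tss_offset = L - int(i)
                if promoter_interval is not None:
                    if promoter_interval.strand == "+":
                        g_start = promoter_interval.start + int(i)
                    else:
                        g_start = promoter_interval.end - int(i) - w
                    iv = GenomicInterval(
                        promoter_interval.contig, g_start, g_start + w, strand
                    )
                else:
                    iv = GenomicInterval("promoter", int(i), int(i) + w, strand)
                hits.append(
                    MotifHit(
                        tf_id=pssm.tf_id,
                        target_gene_id=target_gene_id,
                        species_id=species_id,
                        interval=iv,
                        strand=strand,
                        score=float(scores[i]),
                        p_value=p,
                        tss_offset=tss_offset,
                    )
                )
    return ScanResult(
        pssm.tf_id, target_gene_id, species_id, hits, np.asarray(all_p), n_windows
    )


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def call_significant(
    scan_results: Iterable[ScanResult], alpha: float = 0.05
) -> List[MotifHit]:
    """BH-correct within each (species, motif) scan family over all tested
    windows and retain hits with q < alpha."""
    families: Dict[Tuple[str, str], List[ScanResult]] = {}
    for res in scan_results:
        families.setdefault((res.species_id, res.tf_id), []).append(res)
    retained: List[MotifHit] = []
    for results in families.values():
        all_p = np.concatenate([r.all_pvalues for r in results if r.all_pvalues.size])
        if all_p.size == 0:
            continue
        order = np.argsort(all_p, kind="stable")
        sorted_p = all_p[order]
        q_sorted = bh_qvalues(sorted_p)
        # q as a function of p (monotone): lookup by rightmost matching p
        for r in results:
            for hit in r.hits:
                j = np.searchsorted(sorted_p, hit.p_value, side="right") - 1
                hit.q_value = float(q_sorted[j])
                if hit.q_value < alpha:
                    retained.append(hit)
    return retained


def assign_confidence(
    source_organisms: Iterable[str] = (),
    provenance: Optional[str] = None,
) -> Tuple[str, float]:
    """Map hit evidence to the published confidence tier and score; when
    several tiers apply the highest score wins."""
    candidates = []
    orgs = set(source_organisms)
    if orgs - {"human", "mouse"}:
        raise ValueError(f"unknown source organisms {orgs}")
    if "mouse" in orgs and "human" in orgs:
        candidates.append(CONFIDENCE_TIERS["extrapolated_mouse_human"])
    elif "mouse" in orgs:
        candidates.append(CONFIDENCE_TIERS["extrapolated_mouse"])
    elif "human" in orgs:
        candidates.append(CONFIDENCE_TIERS["extrapolated_human"])
    if provenance is not None:
        key = f"scan_{provenance}"
        if key not in CONFIDENCE_TIERS:
            raise ValueError(f"unknown provenance {provenance!r}")
        candidates.append(CONFIDENCE_TIERS[key])
    if not candidates:
        raise ValueError("no evidence provided")
    return max(candidates, key=lambda t: t[1])


def window_density(
    hits: Iterable[MotifHit], window: int = 100, span: int = SCAN_SPAN_BP
) -> np.ndarray:
    """Hit counts per non-overlapping ``window``-nt bin of TSS-relative
    upstream distance, from the TSS out to ``span``."""
    counts = np.zeros(span // window, dtype=int)
    for hit in hits:
        if 0 < hit.tss_offset <= span:
            counts[(hit.tss_offset - 1) // window] += 1
    return counts


def retain_proximal(hits: Iterable[MotifHit], max_bp: int = PROMOTER_RETAIN_BP) -> List[MotifHit]:
    """Keep hits whose start lies within ``max_bp`` of the TSS."""
    return [h for h in hits if h.tss_offset <= max_bp]


# -- randomized-promoter controls -------------------------------------------


def shuffle_promoters(
    seqs: Sequence[str], mode: str = "dinucleotide", seed: int = 0
) -> List[str]:
    """Composition-preserving randomization of promoter sequences.

    ``mononucleotide`` permutes bases; ``dinucleotide`` preserves all 16
    dinucleotide counts via an Eulerian-path shuffle."""
    if mode not in ("mononucleotide", "dinucleotide"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = []
    for seq in seqs:
        if len(seq) < 2:
            out.append(seq)
        elif mode == "mononucleotide":
            chars = list(seq)
            rng.shuffle(chars)
            out.append("".join(chars))
        else:
            out.append(_dinucleotide_shuffle(seq, rng))
    return out


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson Eulerian shuffle preserving dinucleotide counts."""
    edges: Dict[str, List[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    if all(len(set(v)) <= 1 for v in edges.values()) and len(edges) <= 1:
        return seq  # homopolymer or trivial
    for _ in range(1000):
        # pick a random terminal edge for every vertex but the last symbol
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # connectivity check: every vertex must reach `last` via last_edge
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - retry bound
        return seq
    ordered: Dict[str, List[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        ordered[v] = pool
    # walk the Eulerian path
    result = [seq[0]]
    counters = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][counters[cur]]
        counters[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)
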