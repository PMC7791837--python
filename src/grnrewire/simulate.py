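"""Synthetic multi-species inputs with known ground truth.

The generator emulates the study design the pipeline targets: five species
related by a ladder phylogeny, six tissues, ten co-expression modules whose
labels evolve along the tree, promoters containing planted (and in chosen
lineages, broken) binding sites, binary edge-presence patterns evolved under
a two-state gain/loss Markov process, and a radiation panel of population
SNPs segregating by clade. Every latent quantity is returned as ground truth
so downstream stages can be tested end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ExpressionTensor, GenomicInterval, OrthologyMap, SpeciesTree, VariantRecord, revcomp
from .io import read_tree
from .motifs import BASES, BASE_INDEX, PSSM

#: five-species ladder with branch lengths; the root (deepest ancestor) is
#: auto-labeled Anc4 in post-order, its descendants Anc3..Anc1.
DEFAULT_TREE = "((((sp1:0.010,sp2:0.010):0.005,sp3:0.015):0.005,sp4:0.020):0.010,sp5:0.030);"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 5
    n_tissues: int = 6
    n_modules: int = 10
    n_genes: int = 200
    n_tfs: int = 20
    promoter_length: int = 5000
    expression_noise_sd: float = 0.5
    # per-branch probability of a module state change; over the 8 branches
    # of the default 5-species tree this yields ~40% state-changed genes
    state_change_rate: float = 0.0625
    gc_content: float = 0.4
    # radiation-panel settings
    n_clades: int = 3
    samples_per_clade: int = 8
    n_snp_sites: int = 30

    def __post_init__(self):
        for name in ("n_species", "n_tissues", "n_modules", "n_genes", "n_tfs",
                     "promoter_length", "n_clades", "samples_per_clade", "n_snp_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules must not exceed n_genes")


def default_tree() -> SpeciesTree:
    return read_tree(DEFAULT_TREE)


def module_means(config: SimulationConfig) -> np.ndarray:
    """Tissue-activation mean vectors (modules x tissues) in log space.

    Each module is strongly expressed in one (or, past the tissue count, two)
    tissues and near-baseline elsewhere; the separation between means is
    large relative to the default noise, mimicking tissue-specific modules.
    """
    k, nt = config.n_modules, config.n_tissues
    means = np.full((k, nt), 1.0)
    for m in range(k):
        means[m, m % nt] = 6.0
        if m >= nt:
            means[m, (m + 1) % nt] = 6.0
    return means


@dataclass
class ExpressionSim:
    tensor: ExpressionTensor
    labels: Dict[str, Dict[str, int]]  # node name -> orthogroup -> module
    means: np.ndarray
    orthology: OrthologyMap
    tree: SpeciesTree


def simulate_expression(
    config: SimulationConfig, tree: Optional[SpeciesTree] = None
) -> ExpressionSim:
    """Module-structured expression evolving along the tree.

    Ancestral module labels are drawn uniformly at the root and change with
    per-branch probability ``state_change_rate`` (new label uniform over the
    other modules); extant expression is the module mean plus Gaussian noise
    in log space, exponentiated back to an FPKM-like scale.
    """
    tree = tree or default_tree()
    rng = np.random.default_rng(config.seed)
    k = config.n_modules
    means = module_means(config)
    ogs = [f"og{i:04d}" for i in range(config.n_genes)]

    labels: Dict[str, Dict[str, int]] = {}
    root = tree.root
    labels[root.name] = {og: int(m) for og, m in zip(ogs, rng.integers(0, k, config.n_genes))}
    for node in root.preorder():
        if node is root:
            continue
        parent_labels = labels[node.parent.name]
        change = rng.random(config.n_genes) < config.state_change_rate
        shift = rng.integers(1, k, config.n_genes)
        node_labels = {}
        for i, og in enumerate(ogs):
            lab = parent_labels[og]
            if change[i]:
                lab = (lab + int(shift[i])) % k
            node_labels[og] = lab
        labels[node.name] = node_labels

    frames = {}
    groups: Dict[str, Dict[str, List[str]]] = {og: {} for og in ogs}
    tissues = [f"tissue{t+1}" for t in range(config.n_tissues)]
    for leaf in tree.leaf_names:
        gene_ids = [f"{leaf}_{og}" for og in ogs]
        mu = np.array([means[labels[leaf][og]] for og in ogs])
        log_vals = mu + rng.normal(0.0, config.expression_noise_sd, mu.shape)
        raw = np.clip(np.exp(np.clip(log_vals, 0.0, None)) - 1.0, 0.0, None)
        frames[leaf] = pd.DataFrame(raw, index=gene_ids, columns=tissues)
        for og, gid in zip(ogs, gene_ids):
            groups[og][leaf] = [gid]
    tensor = ExpressionTensor(frames, tissues)
    return ExpressionSim(tensor, labels, means, OrthologyMap(groups), tree)


# -- promoters ---------------------------------------------------------------


@dataclass
class PlantedSite:
    tf_id: str
    gene_id: str
    species_id: str
    start: int  # promoter-relative
    strand: str
    sequence: str  # motif-strand oriented, as embedded
    broken: bool


@dataclass
class PromoterSim:
    sequences: Dict[str, Dict[str, str]]  # species -> gene -> promoter
    truth: List[PlantedSite]


def _markov_background(length: int, gc: float, rng: np.random.Generator,
                       persistence: float = 0.25) -> str:
    stationary = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    trans = (1 - persistence) * np.tile(stationary, (4, 1)) + persistence * np.eye(4)
    out = np.empty(length, dtype=np.int8)
    out[0] = rng.choice(4, p=stationary)
    for i in range(1, length):
        out[i] = rng.choice(4, p=trans[out[i - 1]])
    return "".join(BASES[b] for b in out)


def _sample_site(pssm: PSSM, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=pssm.freq[:, j] / pssm.freq[:, j].sum())]
        for j in range(pssm.width)
    )


def _break_site(site: str, pssm: PSSM) -> str:
    """Substitute the maximum-information column with its least-favored base."""
    j = pssm.max_ic_column()
    worst = BASES[int(pssm.freq[:, j].argmin())]
    if worst == site[j]:  # degenerate column; fall back to any other base
        worst = next(b for b in BASES if b != site[j])
    return site[:j] + worst + site[j + 1 :]


def simulate_promoters(
    config: SimulationConfig,
    pssms: Dict[str, PSSM],
    plant_spec: Sequence[Tuple[str, str, Sequence[str], Sequence[str]]],
    genes_per_species: Dict[str, Sequence[str]],
) -> PromoterSim:
    """Per-species promoters with planted (and lineage-broken) motif sites.

    ``plant_spec`` rows are (tf, target gene, species with the site, species
    in which the site is broken). Background is an order-1 Markov chain with
    configurable GC content; planted sites are sampled from the motif's
    frequency matrix, and a broken site has its highest-information column
    substituted with the least-favored base.
    """
    rng = np.random.default_rng(config.seed + 1)
    seqs: Dict[str, Dict[str, str]] = {}
    occupied: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for sp, genes in genes_per_species.items():
        seqs[sp] = {
            g: _markov_background(config.promoter_length, config.gc_content, rng)
            for g in genes
        }
    truth: List[PlantedSite] = []
    for tf, gene, species_set, break_set in plant_spec:
        pssm = pssms[tf]
        if pssm.width >= config.promoter_length:
            raise ValueError("motif width must be below promoter length")
        base_site = _sample_site(pssm, rng)
        # one shared position across species keeps cross-species comparisons easy
        pos = None
        for _ in range(100):
            cand = int(rng.integers(0, config.promoter_length - pssm.width))
            window = (cand, cand + pssm.width)
            if all(
                window[1] <= s or window[0] >= e
                for s, e in occupied.get((gene, "any"), [])
            ):
                pos = cand
                break
        if pos is None:
            raise RuntimeError("could not place planted site without overlap")
        occupied.setdefault((gene, "any"), []).append((pos, pos + pssm.width))
        strand = "+" if rng.random() < 0.5 else "-"
        for sp in species_set:
            site = _break_site(base_site, pssm) if sp in break_set else base_site
            embedded = site if strand == "+" else revcomp(site)
            s = seqs[sp][gene]
            seqs[sp][gene] = s[:pos] + embedded + s[pos + pssm.width :]
            truth.append(
                PlantedSite(tf, gene, sp, pos, strand, site, sp in break_set)
            )
    return PromoterSim(seqs, truth)


# -- edge presence patterns ---------------------------------------------------


def ctmc_transition(g: float, l: float, t: float) -> np.ndarray:
    """Exact 2-state transition matrix for gain rate g, loss rate l, time t."""
    rate = g + l
    decay = np.exp(-rate * t)
    p01 = (g / rate) * (1 - decay)
    p10 = (l / rate) * (1 - decay)
    return np.array([[1 - p01, p01], [p10, 1 - p10]])


def simulate_edge_patterns(
    tree: SpeciesTree, g: float, l: float, n_edges: int, seed: int = 0
) -> np.ndarray:
    """Leaf presence/absence matrix (edges x leaves) under the gain/loss CTMC.

    The root state is drawn from the stationary distribution
    (P(present) = g/(g+l)) and evolved along each branch with the exact
    two-state transition probabilities.
    """
    if g < 0 or l < 0:
        raise ValueError("rates must be non-negative")
    if g == 0 and l == 0:
        raise ValueError("degenerate chain: g and l are both zero")
    rng = np.random.default_rng(seed)
    pi1 = g / (g + l)
    states: Dict[str, np.ndarray] = {}
    root = tree.root
    states[root.name] = (rng.random(n_edges) < pi1).astype(np.int8)
    for node in root.preorder():
        if node is root:
            continue
        P = ctmc_transition(g, l, node.length)
        parent = states[node.parent.name]
        u = rng.random(n_edges)
        # row of P given parent state, probability of child being present
        p_present = np.where(parent == 1, P[1, 1], P[0, 1])
        states[node.name] = (u < p_present).astype(np.int8)
    return np.column_stack([states[name] for name in tree.leaf_names])


# -- population SNP panel -----------------------------------------------------


@dataclass
class SnpPanelSim:
    variants: List[VariantRecord]
    truth: pd.DataFrame  # site x sample true class
    traits: pd.DataFrame  # sample -> diet, habitat, palette, clade
    reference_sample: str
    tree: SpeciesTree


_CLADE_TRAITS = [
    ("algae", "rock", "short"),
    ("zooplankton", "sand", "medium"),
    ("fish", "open_water", "long"),
]


def radiation_tree(config: SimulationConfig) -> SpeciesTree:
    """Balanced clade tree for the radiation panel (ladder of clades)."""

    def clade_newick(c: int) -> str:
        tips = [f"c{c+1}s{i+1}:0.05" for i in range(config.samples_per_clade)]
        # ladderized binary resolution inside the clade
        nwk = tips[0]
        for tip in tips[1:]:
            nwk = f"({nwk},{tip}):0.02"
        return nwk

    nwk = clade_newick(0)
    for c in range(1, config.n_clades):
        nwk = f"({nwk},{clade_newick(c)}):0.1"
    return read_tree(nwk + ";")


def simulate_population_snps(config: SimulationConfig) -> SnpPanelSim:
    """Genotypes at TFBS-overlapping positions segregating by clade.

    Each site assigns one genotype class per clade relative to the reference
    sample's clade: the reference clade is conserved (homozygous reference
    allele) and other clades are conserved, heterozygous-segregating, or
    homozygous-segregated as drawn. The trait table codes diet, habitat, and
    wavelength palette consistently within each clade.
    """
    if config.n_clades < 3:
        raise ValueError("the radiation panel needs at least 3 clades")
    rng = np.random.default_rng(config.seed + 2)
    tree = radiation_tree(config)
    samples = tree.leaf_names
    clade_of = {s: int(s[1 : s.index("s")]) - 1 for s in samples}
    reference_sample = "c1s1"

    variants: List[VariantRecord] = []
    truth_rows = []
    alleles = ["A", "C", "G", "T"]
    for i in range(config.n_snp_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_a, alt_a = alleles[ref], alleles[alt]
        clade_classes = {0: "conserved"}
        for c in range(1, config.n_clades):
            clade_classes[c] = ["conserved", "het_segregating", "hom_segregated"][
                int(rng.integers(0, 3))
            ]
        genotypes, phased = {}, {}
        row = {}
        for s in samples:
            cls = clade_classes[clade_of[s]]
            if cls == "conserved":
                gt = (ref_a, ref_a)
            elif cls == "het_segregating":
                gt = (ref_a, alt_a) if rng.random() < 0.5 else (alt_a, ref_a)
            else:
                gt = (alt_a, alt_a)
            genotypes[s] = gt
            phased[s] = True
            row[s] = cls
        variants.append(
            VariantRecord(
                interval=GenomicInterval("panel", 100 + i * 50, 101 + i * 50, "+"),
                ref=ref_a,
                alt=alt_a,
                source="population",
                genotypes=genotypes,
                phased=phased,
            )
        )
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows, index=[f"site{i}" for i in range(config.n_snp_sites)])
    traits = pd.DataFrame(
        {
            "sample": samples,
            "clade": [clade_of[s] for s in samples],
            "diet": [_CLADE_TRAITS[clade_of[s] % 3][0] for s in samples],
            "habitat": [_CLADE_TRAITS[clade_of[s] % 3][1] for s in samples],
            "palette": [_CLADE_TRAITS[clade_of[s] % 3][2] for s in samples],
        }
    ).set_index("sample")
    return SnpPanelSim(variants, truth, traits, reference_sample, tree)
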