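"""Synthetic data with known ground truth for every pipeline stage.

Abundance matrices come from a latent Gaussian copula: a sparse precision
matrix with planted modules defines the conditional-dependence structure, the
latent draws are pushed through an exponential (so marker families keep a
median of ~1), and optional zero-inflation emulates rare families.  Genomes
are simulated with planted cas operons and families colocated with them, so
the permutation tests have a planted signal and a calibrated null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .genes import GeneTable
from .profiles import AbundanceMatrix, Label

__all__ = [
    "SyntheticNetworkConfig",
    "GroundTruth",
    "SyntheticGenomeConfig",
    "make_precision",
    "sample_abundances",
    "planted_labels",
    "make_planted_graph",
    "simulate_genomes",
]

# A chain of pairwise partial correlation rho is positive definite for any
# module size as long as rho < 1/(2 cos(pi/(m+1))), i.e. just above 0.5; an
# equicorrelated clique would cap rho at 1/(m-1), far too small to plant a
# detectable signal, so modules are chains.
MAX_CHAIN_PARTIAL_CORR = 0.49


@dataclass(frozen=True)
class SyntheticNetworkConfig:
    p: int
    n: int
    module_sizes: Tuple[int, ...]
    within_module_partial_corr: float = 0.4
    zero_inflation: float = 0.0
    n_markers: int = 10
    cas_module_index: int = 0
    labeled_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        if self.p < sum(self.module_sizes) + self.n_markers:
            raise ValueError("p must cover all modules plus the markers")
        if not 0 <= self.within_module_partial_corr <= MAX_CHAIN_PARTIAL_CORR:
            raise ValueError(
                f"within_module_partial_corr must be in [0, {MAX_CHAIN_PARTIAL_CORR}] "
                "to keep the chain precision matrix positive definite"
            )
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.module_sizes and not (
            0 <= self.cas_module_index < len(self.module_sizes)
        ):
            raise ValueError("cas_module_index out of range")
        if not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in [0, 1]")

    @property
    def family_ids(self) -> Tuple[str, ...]:
        n_free = self.p - self.n_markers
        fams = tuple(f"F{i:05d}" for i in range(n_free))
        markers = tuple(f"M{i:03d}" for i in range(self.n_markers))
        return fams + markers

    @property
    def marker_ids(self) -> Tuple[str, ...]:
        return self.family_ids[self.p - self.n_markers:]

    def module_members(self, m: int) -> Tuple[str, ...]:
        start = sum(self.module_sizes[:m])
        return self.family_ids[start: start + self.module_sizes[m]]


@dataclass(frozen=True)
class GroundTruth:
    """Planted edges (precision off-diagonal support) and true cas families."""

    edge_set: FrozenSet[Tuple[str, str]]
    true_cas: FrozenSet[str]

    def __post_init__(self):
        object.__setattr__(
            self,
            "edge_set",
            frozenset(tuple(sorted(e)) for e in self.edge_set),
        )
        object.__setattr__(self, "true_cas", frozenset(self.true_cas))


def make_precision(cfg: SyntheticNetworkConfig) -> Tuple[np.ndarray, GroundTruth]:
    """Build the block-structured sparse precision matrix and its ground truth.

    Each planted module is a chain: consecutive members get an off-diagonal
    entry of -rho so every planted edge has partial correlation exactly
    ``within_module_partial_corr``.  Markers (and any leftover families) stay
    singleton blocks.
    """
    ids = cfg.family_ids
    p = cfg.p
    rho = cfg.within_module_partial_corr
    omega = np.eye(p)
    edges: Set[Tuple[str, str]] = set()
    if rho > 0:
        offset = 0
        for size in cfg.module_sizes:
            for k in range(size - 1):
                i, j = offset + k, offset + k + 1
                omega[i, j] = omega[j, i] = -rho
                edges.add(tuple(sorted((ids[i], ids[j]))))
            offset += size
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin <= 0:
        raise ValueError(f"precision matrix not positive definite (lambda_min={eigmin})")
    cas = cfg.module_members(cfg.cas_module_index) if cfg.module_sizes else ()
    return omega, GroundTruth(frozenset(edges), frozenset(cas))


def sample_abundances(
    omega: np.ndarray, cfg: SyntheticNetworkConfig
) -> AbundanceMatrix:
    """Draw an abundance matrix from the latent Gaussian copula.

    Latents are N(0, omega^-1); abundances are exp(latent), so each family's
    marginal is log-normal with median 1 (markers in particular).  Non-marker
    cells are zeroed independently with probability ``zero_inflation``.
    """
    p = omega.shape[0]
    if omega.shape != (p, p) or p != cfg.p:
        raise ValueError("precision matrix does not match config dimension")
    rng = np.random.default_rng(cfg.seed)
    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma)
    latent = chol @ rng.standard_normal((p, cfg.n))
    values = np.exp(latent)
    if cfg.zero_inflation > 0:
        n_free = cfg.p - cfg.n_markers
        mask = rng.random((n_free, cfg.n)) < cfg.zero_inflation
        values[:n_free][mask] = 0.0
    return AbundanceMatrix(cfg.family_ids, tuple(f"S{j:04d}" for j in range(cfg.n)), values)


def planted_labels(
    family_ids: Sequence[str],
    true_cas: Set[str],
    labeled_fraction: float,
    annotated_fraction: float = 1.0,
    seed: int = 0,
) -> dict:
    """Label a ``labeled_fraction`` of the true cas families POSITIVE.

    Remaining families are NEGATIVE with probability ``annotated_fraction``
    (emulating families with some pre-existing annotation) and UNANNOTATED
    otherwise.  Unlabeled cas families are left UNANNOTATED so they can be
    rediscovered.
    """
    rng = np.random.default_rng(seed)
    cas = [f for f in family_ids if f in true_cas]
    n_pos = int(round(labeled_fraction * len(cas)))
    pos = set(rng.choice(cas, size=n_pos, replace=False)) if n_pos else set()
    labels = {}
    for fam in family_ids:
        if fam in pos:
            labels[fam] = Label.POSITIVE
        elif fam in true_cas:
            labels[fam] = Label.UNANNOTATED
        elif rng.random() < annotated_fraction:
            labels[fam] = Label.NEGATIVE
        else:
            labels[fam] = Label.UNANNOTATED
    return labels


def make_planted_graph(
    n_nodes: int,
    module_size: int,
    p_within: float = 0.5,
    p_background: float = 0.01,
    seed: int = 0,
) -> Tuple[nx.Graph, FrozenSet[str]]:
    """Random graph with one dense planted module (the true cas community).

    Module members are wired with probability ``p_within``; all other pairs
    with ``p_background``.  Used to benchmark label propagation without going
    through network inference.
    """
    if module_size > n_nodes:
        raise ValueError("module_size exceeds n_nodes")
    rng = np.random.default_rng(seed)
    ids = [f"N{i:05d}" for i in range(n_nodes)]
    module = set(ids[:module_size])
    G = nx.Graph()
    G.add_nodes_from(ids)
    upper = np.triu_indices(n_nodes, k=1)
    probs = np.full(len(upper[0]), p_background)
    in_mod = (upper[0] < module_size) & (upper[1] < module_size)
    probs[in_mod] = p_within
    draw = rng.random(len(probs)) < probs
    for i, j in zip(upper[0][draw], upper[1][draw]):
        G.add_edge(ids[i], ids[j])
    return G, frozenset(module)


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_genomes: int = 20
    contigs_per_genome: int = 5
    genes_per_contig: int = 40
    mean_gene_len: int = 900
    mean_intergenic_len: int = 100
    colocated_families: Tuple[str, ...] = ()
    background_families: Tuple[str, ...] = ()
    pi_coloc: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "colocated_families", tuple(self.colocated_families))
        object.__setattr__(self, "background_families", tuple(self.background_families))
        if self.mean_gene_len <= 0 or self.mean_intergenic_len < 0:
            raise ValueError("lengths must be positive")
        if not 0 <= self.pi_coloc <= 1:
            raise ValueError("pi_coloc must be in [0, 1]")
        if self.genes_per_contig < 8:
            raise ValueError("genes_per_contig must be >= 8 to host a cas operon")
        n_special = len(self.colocated_families) + len(self.background_families)
        if self.contigs_per_genome * self.genes_per_contig < 8 + n_special + 4:
            raise ValueError("not enough gene slots for operon plus special families")


def _contig_coordinates(n_genes: int, cfg: SyntheticGenomeConfig, rng) -> List[Tuple[int, int]]:
    # Sequential non-overlapping genes; lengths/gaps uniform around their means.
    lengths = rng.integers(
        max(1, cfg.mean_gene_len // 2), cfg.mean_gene_len * 3 // 2 + 1, size=n_genes
    )
    gaps = rng.integers(0, max(1, cfg.mean_intergenic_len * 2 + 1), size=n_genes)
    coords = []
    pos = 0
    for L, gap in zip(lengths, gaps):
        start = pos + gap + 1
        end = start + int(L) - 1
        coords.append((start, end))
        pos = end
    return coords


def simulate_genomes(cfg: SyntheticGenomeConfig) -> List[GeneTable]:
    """Simulate genomes with a planted cas operon per genome.

    Each genome gets one operon (a run of 3-8 consecutive ``is_cas`` genes) on
    a random contig.  Every colocated family places one gene within 2 gene
    slots of the operon with probability ``pi_coloc`` and uniformly at random
    otherwise; background families always place uniformly.  Remaining slots
    are filled with unique filler families.
    """
    rng = np.random.default_rng(cfg.seed)
    tables = []
    for g in range(cfg.n_genomes):
        genome_id = f"G{g:04d}"
        slots = []  # (contig_id, slot_index, start, end)
        for c in range(cfg.contigs_per_genome):
            contig_id = f"{genome_id}_c{c:02d}"
            for k, (start, end) in enumerate(
                _contig_coordinates(cfg.genes_per_contig, cfg, rng)
            ):
                slots.append([contig_id, k, start, end])

        op_len = int(rng.integers(3, min(8, cfg.genes_per_contig) + 1))
        op_contig = int(rng.integers(cfg.contigs_per_genome))
        op_start = int(rng.integers(cfg.genes_per_contig - op_len + 1))
        op_contig_id = f"{genome_id}_c{op_contig:02d}"
        operon = set(
            op_contig * cfg.genes_per_contig + op_start + i for i in range(op_len)
        )

        family = [None] * len(slots)
        is_cas = [False] * len(slots)
        for i, s in enumerate(sorted(operon)):
            family[s] = f"cas{chr(ord('A') + i)}"
            is_cas[s] = True

        free = [i for i in range(len(slots)) if family[i] is None]
        near = [
            op_contig * cfg.genes_per_contig + j
            for j in range(op_start - 2, op_start + op_len + 2)
            if 0 <= j < cfg.genes_per_contig
        ]
        near_free = [i for i in near if not is_cas[i]]

        for fam in cfg.colocated_families:
            if rng.random() < cfg.pi_coloc and near_free:
                pick = near_free[int(rng.integers(len(near_free)))]
            else:
                candidates = [i for i in free if family[i] is None]
                pick = candidates[int(rng.integers(len(candidates)))]
            family[pick] = fam
            if pick in near_free:
                near_free.remove(pick)
        for fam in cfg.background_families:
            candidates = [i for i in free if family[i] is None]
            pick = candidates[int(rng.integers(len(candidates)))]
            family[pick] = fam

        filler = 0
        for i in range(len(slots)):
            if family[i] is None:
                family[i] = f"{genome_id}_orf{filler:04d}"
                filler += 1

        strands = rng.choice(["+", "-"], size=len(slots))
        df = pd.DataFrame(
            {
                "contig_id": [s[0] for s in slots],
                "start": [s[2] for s in slots],
                "end": [s[3] for s in slots],
                "strand": strands,
                "family_id": family,
                "is_cas": is_cas,
            }
        )
        tables.append(GeneTable(genome_id, df))
    return tables
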