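"""Genomic-proximity validation of predicted families.

Two permutation tests: (1) how often a family shares a contig with a known
cas gene, against a null that reassigns the family's genes to random ORF
locations within each genome; (2) the minimum base-pair distance from the
family to any cas gene, against null distributions from uniformly drawn
genome positions.  Plus the tabular-hit filters applied upstream of both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import GeneTable

logger = logging.getLogger(__name__)

__all__ = [
    "PermTestResult",
    "read_tblout",
    "filter_hits",
    "contig_cooccurrence",
    "orf_reassignment_test",
    "min_distance_to_cas",
    "random_location_null",
    "hhsuite_filter",
    "tm_flag",
    "format_p",
]


@dataclass(frozen=True)
class PermTestResult:
    family_id: str
    observed: float
    null_draws: np.ndarray
    p_value: float
    n_perm: int

    def formatted_p(self) -> str:
        return format_p(self.p_value, self.n_perm)


def format_p(p: float, n_perm: int) -> str:
    """Report "< 1/n_perm" when the observed value beat every null draw."""
    min_attainable = 1.0 / (n_perm + 1)
    if p <= min_attainable:
        return f"< {1.0 / n_perm:g}"
    return f"{p:g}"


# ---------------------------------------------------------------- hit tables

_TBLOUT_FIELDS = [
    "target_name", "target_accession", "query_name", "query_accession",
    "full_evalue", "full_score", "full_bias",
    "dom_evalue", "dom_score", "dom_bias",
    "exp", "reg", "clu", "ov", "env", "dom", "rep", "inc",
]


def read_tblout(path) -> pd.DataFrame:
    """Parse an hmmscan/hmmsearch ``--tblout`` table (whitespace-delimited)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split(None, len(_TBLOUT_FIELDS))
            if len(parts) < len(_TBLOUT_FIELDS):
                raise ValueError(f"malformed tblout line: {line!r}")
            rec = dict(zip(_TBLOUT_FIELDS, parts[: len(_TBLOUT_FIELDS)]))
            rec["description"] = (
                parts[len(_TBLOUT_FIELDS)].rstrip("\n")
                if len(parts) > len(_TBLOUT_FIELDS)
                else ""
            )
            rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df):
        for col in ["full_evalue", "full_score", "full_bias",
                    "dom_evalue", "dom_score", "dom_bias", "exp"]:
            df[col] = pd.to_numeric(df[col])
    return df


def filter_hits(
    hits: pd.DataFrame,
    n_targets: int,
    base_cutoff: float = 0.01,
    evalue_col: str = "evalue",
    gene_key: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Keep hits below the per-target E-value cutoff; one best call per gene.

    The cutoff is ``base_cutoff / n_targets`` (a Bonferroni-style correction
    over the searched genomes); among retained hits sharing a gene key the
    smallest E-value wins.
    """
    if evalue_col not in hits.columns:
        raise ValueError(f"hit table lacks E-value column {evalue_col!r}")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    cutoff = base_cutoff / n_targets
    kept = hits[hits[evalue_col] <= cutoff].copy()  # boundary E-value retained
    if gene_key is None:
        gene_key = [c for c in ("genome_id", "contig_id", "start", "end")
                    if c in kept.columns]
    if gene_key and len(kept):
        kept = kept.sort_values(evalue_col, kind="stable")
        kept = kept.drop_duplicates(subset=list(gene_key), keep="first")
        kept = kept.sort_index()
    return kept.reset_index(drop=True)


def hhsuite_filter(hits: pd.DataFrame, min_probability: float = 90.0,
                   prob_col: str = "probability") -> pd.DataFrame:
    """Keep HHsuite hits with probability score >= ``min_probability`` (percent)."""
    if prob_col not in hits.columns:
        raise ValueError(f"hit table lacks probability column {prob_col!r}")
    return hits[hits[prob_col] >= min_probability].reset_index(drop=True)


def tm_flag(tm_residue_count: int) -> bool:
    """True if at least 18 amino acids are in predicted transmembrane helices."""
    if tm_residue_count < 0:
        raise ValueError("residue count must be >= 0")
    return tm_residue_count >= 18


# ------------------------------------------------------- contig cooccurrence

def contig_cooccurrence(
    tables: Sequence[GeneTable], family: str, per_instance: bool = False
) -> float:
    """Mean cooccurrence of ``family`` with cas genes on a shared contig.

    For each genome containing the family the default statistic is the
    indicator that any instance shares a contig with >= 1 cas gene; with
    ``per_instance`` it is the fraction of instances that do.  The observed
    value is the mean over genomes containing the family.
    """
    vals = []
    for t in tables:
        genes = t.genes
        inst = genes[genes["family_id"] == family]
        if inst.empty:
            continue
        cas_contigs = set(genes.loc[genes["is_cas"], "contig_id"])
        hit = inst["contig_id"].isin(cas_contigs)
        vals.append(float(hit.mean()) if per_instance else float(hit.any()))
    if not vals:
        raise ValueError(f"family {family!r} absent from every genome")
    return float(np.mean(vals))


def orf_reassignment_test(
    tables: Sequence[GeneTable],
    family: str,
    n_perm: int = 10_000,
    seed: int = 0,
    per_instance: bool = False,
) -> PermTestResult:
    """Permutation test of contig cooccurrence with cas genes.

    Each permutation independently relocates every instance of the family to
    the location of another uniformly chosen ORF in the same genome (cas genes
    never move) and recomputes the cooccurrence statistic.  The p-value uses
    the add-one rule on #{null >= observed}.
    """
    observed = contig_cooccurrence(tables, family, per_instance=per_instance)
    rng = np.random.default_rng(seed)
    per_genome_null: List[np.ndarray] = []
    for t in tables:
        genes = t.genes
        inst_idx = np.flatnonzero((genes["family_id"] == family).to_numpy())
        if len(inst_idx) == 0:
            continue
        if t.n_genes < 2:
            logger.warning("genome %s has a single ORF; excluded", t.genome_id)
            continue
        cas_contigs = set(genes.loc[genes["is_cas"], "contig_id"])
        on_cas_contig = genes["contig_id"].isin(cas_contigs).to_numpy()
        # draw replacement ORF indices, excluding each instance's own slot
        draws = rng.integers(0, t.n_genes - 1, size=(n_perm, len(inst_idx)))
        draws = draws + (draws >= inst_idx[None, :])
        hits = on_cas_contig[draws]
        stat = hits.mean(axis=1) if per_instance else hits.any(axis=1).astype(float)
        per_genome_null.append(stat)
    if not per_genome_null:
        raise ValueError(f"no usable genome contains family {family!r}")
    null = np.mean(np.column_stack(per_genome_null), axis=1)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermTestResult(family, observed, null, p, n_perm)


# ------------------------------------------------------------- bp distances

def gene_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Distance between two genes: larger start minus smaller end, floored at 0.

    Overlapping (and abutting) intervals get distance 0; the convention is
    symmetric in the two genes and ignores strand.
    """
    if s1 > s2:
        s1, e1, s2, e2 = s2, e2, s1, e1
    return max(0, s2 - e1)


def min_distance_to_cas(
    tables: Sequence[GeneTable], family: str
) -> Tuple[Dict[str, float], float]:
    """Minimum bp distance from ``family`` to any cas gene, per genome and overall.

    Only same-contig pairs have finite distance.  Genomes lacking the family
    are omitted; genomes where no instance shares a contig with a cas gene get
    ``inf``.
    """
    per_genome: Dict[str, float] = {}
    for t in tables:
        genes = t.genes
        inst = genes[genes["family_id"] == family]
        if inst.empty:
            continue
        cas = genes[genes["is_cas"]]
        best = math.inf
        for _, g in inst.iterrows():
            same = cas[cas["contig_id"] == g.contig_id]
            for _, c in same.iterrows():
                best = min(best, gene_gap(g.start, g.end, c.start, c.end))
        per_genome[t.genome_id] = best
    overall = min(per_genome.values()) if per_genome else math.inf
    return per_genome, overall


def random_location_null(
    tables: Sequence[GeneTable], n_reps: int = 100, seed: int = 0
) -> np.ndarray:
    """Null bp distances from uniform random genome positions to the nearest cas gene.

    For each genome and each rep one position is drawn uniformly over the
    genome's total contig span; its distance to the nearest cas gene on the
    same contig is recorded (inf if that contig carries none).  Returns an
    array of shape (n_reps, n_genomes).
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_reps, len(tables)))
    for gi, t in enumerate(tables):
        genes = t.genes
        spans = []  # (contig, length) using max gene end as the contig span
        for contig, sub in genes.groupby("contig_id", sort=False):
            spans.append((contig, int(sub["end"].max())))
        total = sum(L for _, L in spans)
        cas_by_contig = {
            contig: sub[["start", "end"]].to_numpy()
            for contig, sub in genes[genes["is_cas"]].groupby("contig_id", sort=False)
        }
        for r in range(n_reps):
            pos = rng.integers(1, total + 1)
            for contig, L in spans:
                if pos <= L:
                    break
                pos -= L
            cas = cas_by_contig.get(contig)
            if cas is None:
                out[r, gi] = math.inf
            else:
                d = np.where(
                    (cas[:, 0] <= pos) & (pos <= cas[:, 1]),
                    0,
                    np.minimum(np.abs(cas[:, 0] - pos), np.abs(pos - cas[:, 1])),
                )
                out[r, gi] = float(d.min())
    return out
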