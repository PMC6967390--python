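"""Sparse conditional-dependence network inference.

Pipeline: rank-based nonparanormal transform, sure independence screening,
Meinshausen-Buhlmann neighborhood selection (per-node lasso) along a
log-spaced regularization path, and a rotation criterion that picks the
regularization strength from permutation-null data.  The resulting graph is
undirected and unweighted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "NPNMatrix",
    "LambdaPath",
    "npn_transform",
    "screen_candidates",
    "mb_neighborhood",
    "fit_path",
    "select_ric",
    "default_screen_size",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "write_path_summary",
]

COEF_TOL = 1e-8


@dataclass(frozen=True)
class NPNMatrix:
    """Nonparanormal-transformed profiles: one standardized row per family."""

    family_ids: tuple
    sample_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "family_ids", tuple(self.family_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def correlations(self) -> np.ndarray:
        """Pearson correlation matrix; rows are mean 0 / variance 1 already."""
        return (self.values @ self.values.T) / self.n_samples


@dataclass
class LambdaPath:
    """A decreasing regularization path and the graph estimated at each value."""

    lambdas: np.ndarray
    graphs: List[nx.Graph]

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")
        if len(self.graphs) != len(self.lambdas):
            raise ValueError("one graph required per lambda")

    def edge_counts(self) -> np.ndarray:
        return np.array([g.number_of_edges() for g in self.graphs])


def npn_transform(matrix) -> NPNMatrix:
    """Shrunken-ECDF nonparanormal transform of each family's profile.

    Ranks (average ties) are mapped through the standard normal quantile at
    r/(n+1), then each row is re-standardized to mean 0, variance 1.  The
    output depends on the input only through within-row ranks, so it is
    invariant to strictly monotone transforms.
    """
    values = np.asarray(matrix.values, dtype=float)
    n = values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for the nonparanormal transform")
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        row = values[i]
        if np.all(row == row[0]):
            raise ValueError(
                f"constant profile for family {matrix.family_ids[i]!r}; filter first"
            )
        z = ndtri(rankdata(row, method="average") / (n + 1))
        z = z - z.mean()
        out[i] = z / z.std()
    return NPNMatrix(matrix.family_ids, matrix.sample_ids, out)


def default_screen_size(p: int, n: int) -> int:
    """Sure-independence-screening budget: min(p-1, ceil(n / log n))."""
    return min(p - 1, int(math.ceil(n / math.log(n))))


def screen_candidates(X: NPNMatrix, node: str, k: int,
                      corr: Optional[np.ndarray] = None) -> List[str]:
    """The k families with largest |correlation| to ``node`` (node excluded).

    Ties break deterministically by family order in the matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    i = X.family_ids.index(node)
    if corr is None:
        corr = X.correlations()
    scores = np.abs(corr[i]).copy()
    scores[i] = -np.inf
    k = min(k, X.n_families - 1)
    # stable sort on -|corr| keeps family order for exact ties
    order = np.argsort(-scores, kind="stable")[:k]
    return [X.family_ids[j] for j in sorted(order)]


def _lasso_design(X: NPNMatrix, node: str, candidates: Sequence[str]):
    idx = {f: i for i, f in enumerate(X.family_ids)}
    y = X.values[idx[node]]
    cols = [idx[c] for c in candidates]
    return X.values[cols].T, y, list(candidates)


def mb_neighborhood(
    X: NPNMatrix, node: str, lam: float, candidates: Sequence[str]
) -> Set[str]:
    """Neighborhood of ``node``: lasso support of its profile on the candidates.

    Objective is (1/2n)*RSS + lam*L1, no intercept (rows are centered).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    D, y, cand = _lasso_design(X, node, candidates)
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=100_000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            model.fit(D, y)
        except ConvergenceWarning as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"lasso did not converge for node {node!r} at lambda={lam}: {exc}"
            ) from exc
    return {c for c, b in zip(cand, model.coef_) if abs(b) > COEF_TOL}


def fit_path(
    X: NPNMatrix,
    nlambda: int = 30,
    screen: bool = True,
    lambda_min_ratio: float = 0.1,
    rule: str = "or",
    screen_size: Optional[int] = None,
) -> LambdaPath:
    """Estimate a graph at each of ``nlambda`` log-spaced regularization values.

    The path starts at the global lambda_max (largest |pairwise correlation|),
    where every neighborhood is empty, and ends at lambda_max *
    ``lambda_min_ratio``.  Per-node lasso supports are symmetrized with the OR
    rule by default (edge if either endpoint selects the other); ``rule="and"``
    keeps only mutual selections.
    """
    if nlambda < 2:
        raise ValueError("nlambda must be >= 2")
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    p, n = X.n_families, X.n_samples
    corr = X.correlations()
    off = np.abs(corr - np.diag(np.diag(corr)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1.0  # degenerate all-orthogonal input; any path is empty
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, nlambda)

    k = screen_size if screen_size is not None else default_screen_size(p, n)
    selected = [[set() for _ in range(nlambda)] for _ in range(p)]
    idx = {f: i for i, f in enumerate(X.family_ids)}
    for node in X.family_ids:
        i = idx[node]
        if screen:
            cand = screen_candidates(X, node, k, corr=corr)
        else:
            cand = [f for f in X.family_ids if f != node]
        D, y, cand = _lasso_design(X, node, cand)
        # lasso_path shares sklearn's (1/2n)*RSS + alpha*L1 objective
        _, coefs, _ = lasso_path(D, y, alphas=lambdas, max_iter=100_000, tol=1e-8)
        for li in range(nlambda):
            selected[i][li] = {
                cand[c] for c in np.nonzero(np.abs(coefs[:, li]) > COEF_TOL)[0]
            }

    graphs = []
    for li in range(nlambda):
        G = nx.Graph()
        G.add_nodes_from(X.family_ids)
        for i, node in enumerate(X.family_ids):
            for other in selected[i][li]:
                j = idx[other]
                if rule == "or" or node in selected[j][li]:
                    G.add_edge(node, other)
        graphs.append(G)
    return LambdaPath(lambdas, graphs)


def select_ric(
    X: NPNMatrix,
    path: LambdaPath,
    n_rotations: int = 20,
    seed: int = 0,
) -> Tuple[float, nx.Graph]:
    """Pick the regularization strength from rotation (permutation) nulls.

    Each rotation permutes every family's samples independently, destroying
    cross-family dependence while preserving marginals; the smallest lambda at
    which the rotated graph is empty equals the rotated data's lambda_max.
    The selection is the mean of those values over rotations, snapped to the
    nearest path lambda that is >= it.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rng = np.random.default_rng(seed)
    p, n = X.n_families, X.n_samples
    null_lams = np.empty(n_rotations)
    for r in range(n_rotations):
        rotated = np.empty_like(X.values)
        for i in range(p):
            rotated[i] = X.values[i, rng.permutation(n)]
        corr = (rotated @ rotated.T) / n
        np.fill_diagonal(corr, 0.0)
        null_lams[r] = np.abs(corr).max()
    target = float(null_lams.mean())
    at_least = np.nonzero(path.lambdas >= target)[0]
    if len(at_least) == 0:
        logger.warning(
            "rotation-selected lambda %.4f exceeds the path start; using lambda_max",
            target,
        )
        sel = 0
    else:
        sel = int(at_least[-1])  # lambdas decreasing: last index >= target is nearest
    lam = float(path.lambdas[sel])
    logger.info(
        "rotation criterion: mean null lambda_max=%.4f -> selected lambda=%.4f "
        "(index %d, %d edges)",
        target, lam, sel, path.graphs[sel].number_of_edges(),
    )
    return lam, path.graphs[sel]


def write_edgelist(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(tuple(sorted(e)) for e in G.edges()):
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path, nodes=None) -> nx.Graph:
    G = nx.Graph()
    if nodes is not None:
        G.add_nodes_from(nodes)
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "source\ttarget":
            raise ValueError("edge list must start with 'source\\ttarget' header")
        for line in fh:
            u, v = line.rstrip("\n").split("\t")
            G.add_edge(u, v)
    return G


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def write_path_summary(path_obj: LambdaPath, path) -> None:
    with open(path, "w") as fh:
        fh.write("lambda\tn_edges\n")
        for lam, g in zip(path_obj.lambdas, path_obj.graphs):
            fh.write(f"{lam:.10g}\t{g.number_of_edges()}\n")
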