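"""Imbalance-aware Hopfield label propagation (COSNet-style).

Labeled nodes are projected to (positive-neighbor input, negative-neighbor
input) points; a separating line maximizing the F-score on the labeled set
fixes the activation angle alpha and intercept q; unlabeled nodes then run
clamped asynchronous bipolar dynamics whose energy is provably non-increasing,
and the nodes ending in the positive state sin(alpha) are the predictions.
A small threshold regularization eta biases against positive states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .profiles import Label

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionPoint",
    "HopfieldParams",
    "StateVector",
    "PerfMetrics",
    "project_labeled",
    "fit_line",
    "run_dynamics",
    "predict",
    "PredictionResult",
    "cross_validate",
    "CVResult",
    "null_model",
    "NullModelResult",
]


@dataclass(frozen=True)
class ProjectionPoint:
    family_id: str
    pos_input: float  # summed adjacency to POSITIVE labeled neighbors
    neg_input: float  # summed adjacency to NEGATIVE labeled neighbors


@dataclass(frozen=True)
class HopfieldParams:
    alpha: float  # positive state sin(alpha), negative state -cos(alpha)
    q: float      # line intercept / base neuron threshold
    eta: float = 1e-4

    def __post_init__(self):
        if not 0 < self.alpha < math.pi / 2:
            raise ValueError("alpha must be in (0, pi/2)")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")

    @property
    def pos_state(self) -> float:
        return math.sin(self.alpha)

    @property
    def neg_state(self) -> float:
        return -math.cos(self.alpha)


@dataclass
class StateVector:
    node_ids: Tuple[str, ...]
    states: np.ndarray          # terminal states, in {sin a, -cos a}
    energies: List[float]       # energy after each sweep
    converged: bool
    n_sweeps: int

    def positive_nodes(self, params: HopfieldParams) -> Set[str]:
        return {n for n, s in zip(self.node_ids, self.states) if s > 0}


@dataclass(frozen=True)
class PerfMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0

    def __add__(self, other: "PerfMetrics") -> "PerfMetrics":
        return PerfMetrics(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def project_labeled(G: nx.Graph, labels: Mapping[str, Label]) -> List[ProjectionPoint]:
    """One (positive-input, negative-input) point per labeled node."""
    points = []
    for node in G.nodes:
        lab = labels.get(node, Label.UNANNOTATED)
        if lab == Label.UNANNOTATED:
            continue
        pos = neg = 0.0
        for nb in G.adj[node]:
            nb_lab = labels.get(nb, Label.UNANNOTATED)
            if nb_lab == Label.POSITIVE:
                pos += 1.0
            elif nb_lab == Label.NEGATIVE:
                neg += 1.0
        points.append(ProjectionPoint(node, pos, neg))
    return points


def _best_threshold(scores: np.ndarray, is_pos: np.ndarray) -> Tuple[float, float, float]:
    """Best F1 over thresholds 'positive iff score > q'; returns (f1, q, margin).

    The margin is the gap from q to the nearest projected score.  Among F1
    maximizers the largest q (fewest predicted positives) wins.
    """
    n = len(scores)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos_sorted = is_pos[order].astype(int)
    P = int(pos_sorted.sum())
    cum_tp = np.concatenate([[0], np.cumsum(pos_sorted)])
    i = np.arange(n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(i + P > 0, 2 * cum_tp / (i + P), 0.0)
    # a cut between equal scores is not realizable by a strict threshold
    valid = np.ones(n + 1, dtype=bool)
    valid[1:n] = s[:-1] > s[1:]
    f1[~valid] = -1.0
    best = int(np.argmax(f1))  # argmax takes the first max = largest q
    if best == 0:
        q, margin = float(s[0]) + 1.0, 1.0
    elif best == n:
        q, margin = float(s[-1]) - 1.0, 1.0
    else:
        q = float((s[best - 1] + s[best]) / 2)
        margin = float((s[best - 1] - s[best]) / 2)
    return float(f1[best]), q, margin


def fit_line(
    points: Sequence[ProjectionPoint],
    labels: Mapping[str, Label],
    angle_grid_size: int = 180,
    eta: float = 1e-4,
) -> HopfieldParams:
    """Grid-search the activation angle and intercept maximizing labeled F1.

    Scores are s_i = sin(a) * pos_input_i - cos(a) * neg_input_i; a point is
    classified positive iff s_i > q.  F1 ties are broken by the largest
    separating margin, then the smallest angle: the margin keeps the line away
    from both classes (a perfectly separable labeled set would otherwise pin
    the angle at the grid edge and collapse the positive activation), which is
    the conservative behavior the subsequent dynamics rely on.
    """
    if not points:
        raise ValueError("no labeled points")
    is_pos = np.array([labels[p.family_id] == Label.POSITIVE for p in points])
    if not is_pos.any() or is_pos.all():
        raise ValueError("need at least one POSITIVE and one NEGATIVE point")
    pos_in = np.array([p.pos_input for p in points])
    neg_in = np.array([p.neg_input for p in points])

    coords = np.column_stack([pos_in, neg_in])
    if np.all(coords == coords[0]):
        s = math.sin(math.pi / 4) * pos_in[0] - math.cos(math.pi / 4) * neg_in[0]
        logger.warning("degenerate projection (all points identical); default line")
        return HopfieldParams(math.pi / 4, s + 1e-9, eta)

    best_key, best = None, None
    for k in range(1, angle_grid_size + 1):
        alpha = (k / (angle_grid_size + 1)) * (math.pi / 2)
        scores = math.sin(alpha) * pos_in - math.cos(alpha) * neg_in
        f1, q, margin = _best_threshold(scores, is_pos)
        key = (round(f1, 12), round(margin, 12), -alpha, q)
        if best_key is None or key > best_key:
            best_key, best = key, (alpha, q)
    return HopfieldParams(best[0], best[1], eta)


def run_dynamics(
    G: nx.Graph,
    labels: Mapping[str, Label],
    params: HopfieldParams,
    max_sweeps: int = 100,
    seed: int = 0,
) -> StateVector:
    """Clamped asynchronous Hopfield dynamics on the unlabeled sub-network.

    Labeled nodes are clamped at +/- activation; unlabeled node i carries
    threshold theta_i = q + eta - (input from clamped neighbors), starts at
    the negative state and updates x_i <- sin(a) iff its unlabeled-neighbor
    input exceeds theta_i.  Energy is recorded after every sweep and is
    non-increasing; the run stops at a fixed point or after ``max_sweeps``.
    """
    a_pos, a_neg = params.pos_state, params.neg_state
    unlabeled = [n for n in G.nodes if labels.get(n, Label.UNANNOTATED) == Label.UNANNOTATED]
    m = len(unlabeled)
    idx = {n: i for i, n in enumerate(unlabeled)}

    clamped_input = np.zeros(m)
    neighbors: List[np.ndarray] = []
    for n in unlabeled:
        i = idx[n]
        nb_un = []
        for nb in G.adj[n]:
            lab = labels.get(nb, Label.UNANNOTATED)
            if lab == Label.POSITIVE:
                clamped_input[i] += a_pos
            elif lab == Label.NEGATIVE:
                clamped_input[i] += a_neg
            else:
                nb_un.append(idx[nb])
        neighbors.append(np.array(nb_un, dtype=int))

    theta = params.q + params.eta - clamped_input
    x = np.full(m, a_neg)
    h = np.zeros(m)  # unlabeled-neighbor input, maintained incrementally
    for i in range(m):
        h[neighbors[i]] += x[i]

    def energy() -> float:
        return float(-0.5 * np.dot(x, h) + np.dot(theta, x))

    rng = np.random.default_rng(seed)
    energies = []
    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        changed = False
        for i in rng.permutation(m):
            new = a_pos if h[i] - theta[i] > 0 else a_neg
            if new != x[i]:
                dx = new - x[i]
                x[i] = new
                h[neighbors[i]] += dx
                changed = True
        energies.append(energy())
        if not changed:
            converged = True
            break
    if not converged and m > 0:
        logger.warning("dynamics did not reach a fixed point in %d sweeps", max_sweeps)
    if m == 0:
        converged = True
    diffs = np.diff(energies)
    assert not len(diffs) or diffs.max() <= 1e-9, "energy increased across a sweep"
    return StateVector(tuple(unlabeled), x, energies, converged, sweeps)


@dataclass
class PredictionResult:
    predicted: Set[str]
    params: HopfieldParams
    state: StateVector


def predict(
    G: nx.Graph,
    labels: Mapping[str, Label],
    eta: float = 1e-4,
    seed: int = 0,
    max_sweeps: int = 100,
    angle_grid_size: int = 180,
) -> PredictionResult:
    """Full pipeline: project labeled nodes, fit the line, run the dynamics."""
    points = project_labeled(G, labels)
    params = fit_line(points, labels, angle_grid_size=angle_grid_size, eta=eta)
    state = run_dynamics(G, labels, params, max_sweeps=max_sweeps, seed=seed)
    return PredictionResult(state.positive_nodes(params), params, state)


@dataclass
class CVResult:
    per_fold: List[PerfMetrics]
    pooled: PerfMetrics
    fold_of: Dict[str, int]
    seed: int


def cross_validate(
    G: nx.Graph,
    labels: Mapping[str, Label],
    k: int = 5,
    eta: float = 1e-4,
    seed: int = 0,
    max_sweeps: int = 100,
) -> CVResult:
    """Stratified k-fold CV scored on annotated nodes only.

    POSITIVE nodes are spread as evenly as counts allow across folds; the
    remaining annotated nodes are assigned at random.  Held-out labels become
    UNANNOTATED during propagation, and metrics are computed against the
    held-out annotated nodes exclusively (UNANNOTATED nodes propagate but are
    never scored).
    """
    positives = [n for n in G.nodes if labels.get(n) == Label.POSITIVE]
    negatives = [n for n in G.nodes if labels.get(n) == Label.NEGATIVE]
    if len(positives) < k:
        raise ValueError(f"need at least {k} POSITIVE nodes for {k}-fold CV")
    rng = np.random.default_rng(seed)
    fold_of: Dict[str, int] = {}
    for group in (positives, negatives):
        order = rng.permutation(len(group))
        for slot, j in enumerate(order):
            fold_of[group[j]] = slot % k

    per_fold = []
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)
    for f in range(k):
        held = {n for n, fo in fold_of.items() if fo == f}
        train_labels = {
            n: (Label.UNANNOTATED if n in held else lab) for n, lab in labels.items()
        }
        res = predict(G, train_labels, eta=eta, seed=int(fold_seeds[f]),
                      max_sweeps=max_sweeps)
        tp = sum(1 for n in held if labels[n] == Label.POSITIVE and n in res.predicted)
        fn = sum(1 for n in held if labels[n] == Label.POSITIVE and n not in res.predicted)
        fp = sum(1 for n in held if labels[n] == Label.NEGATIVE and n in res.predicted)
        tn = sum(1 for n in held if labels[n] == Label.NEGATIVE and n not in res.predicted)
        per_fold.append(PerfMetrics(tp, fp, tn, fn))
    pooled = sum(per_fold[1:], per_fold[0])
    return CVResult(per_fold, pooled, fold_of, seed)


@dataclass
class NullModelResult:
    tp: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    fpr: np.ndarray


def null_model(
    n_annotated: int, n_pos: int, reps: int = 10_000, seed: int = 0
) -> NullModelResult:
    """Random predictor baseline: guess ``n_pos`` positives uniformly at random.

    Expected precision and recall are both n_pos / n_annotated.
    """
    if n_pos > n_annotated:
        raise ValueError("n_pos cannot exceed n_annotated")
    rng = np.random.default_rng(seed)
    tp = np.empty(reps, dtype=int)
    for r in range(reps):
        guess = rng.choice(n_annotated, size=n_pos, replace=False)
        tp[r] = int(np.sum(guess < n_pos))
    n_neg = n_annotated - n_pos
    precision = recall = tp / n_pos if n_pos else np.zeros(reps)
    f1 = np.where(tp > 0, 2 * precision * recall / (precision + recall + 1e-300), 0.0)
    fp = n_pos - tp
    fpr = fp / n_neg if n_neg else np.zeros(reps)
    return NullModelResult(tp, precision, recall, f1, fpr)
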