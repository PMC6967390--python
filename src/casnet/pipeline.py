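"""End-to-end orchestration: config, staged runs, manifests, benchmarks."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import analysis, colocation, hopfield, network, profiles, synth
from .profiles import Label

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_simulation_suite", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Every knob of the pipeline; round-trips through YAML unchanged."""

    # input (leave profile_path unset to simulate)
    profile_path: Optional[str] = None
    label_path: Optional[str] = None
    marker_path: Optional[str] = None
    type_map_path: Optional[str] = None

    # synthetic input
    p: int = 120
    n: int = 200
    module_sizes: List[int] = field(default_factory=lambda: [12, 10, 8])
    within_module_partial_corr: float = 0.4
    zero_inflation: float = 0.05
    n_markers: int = 10
    cas_module_index: int = 0
    labeled_fraction: float = 0.5
    annotated_fraction: float = 0.9

    # normalization / filtering
    min_frac: float = 0.10

    # network inference
    nlambda: int = 30
    lambda_min_ratio: float = 0.1
    screen: bool = True
    symmetrize_rule: str = "or"
    n_rotations: int = 20

    # clustering diagnostic
    cluster_n_draws: int = 200

    # propagation / CV
    eta: float = 1e-4
    cv_folds: int = 5
    max_sweeps: int = 100
    angle_grid_size: int = 180

    # colocation
    n_perm: int = 1000
    n_location_reps: int = 100

    # seeds (explicit so every stochastic stage is pinned)
    seed_simulate: int = 11
    seed_labels: int = 12
    seed_ric: int = 13
    seed_cluster: int = 14
    seed_cv: int = 15
    seed_predict: int = 16
    seed_colocate: int = 17

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.10g}"


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run normalize -> filter -> transform -> network -> diagnostics -> CV -> predict.

    All outputs land in ``out_dir`` together with a manifest recording the
    config hash and every seed.  Output files are written deterministically
    (sorted rows, fixed float formatting), so reruns of the same config are
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                logger.info("stage %s ...", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    # ---------------------------------------------------------------- input
    with stage("input"):
        if config.profile_path:
            for p_ in (config.profile_path, config.label_path):
                if p_ and not Path(p_).exists():
                    raise FileNotFoundError(f"input path does not exist: {p_}")
            matrix = profiles.read_profile_table(config.profile_path)
            labels = profiles.read_label_map(config.label_path)
            if config.marker_path:
                with open(config.marker_path) as fh:
                    markers = profiles.MarkerSet(
                        frozenset(line.strip() for line in fh if line.strip())
                    )
            else:
                raise FileNotFoundError("marker_path required with profile_path")
        else:
            net_cfg = synth.SyntheticNetworkConfig(
                p=config.p, n=config.n, module_sizes=tuple(config.module_sizes),
                within_module_partial_corr=config.within_module_partial_corr,
                zero_inflation=config.zero_inflation, n_markers=config.n_markers,
                cas_module_index=config.cas_module_index,
                labeled_fraction=config.labeled_fraction, seed=config.seed_simulate,
            )
            omega, truth = synth.make_precision(net_cfg)
            matrix = synth.sample_abundances(omega, net_cfg)
            labels = synth.planted_labels(
                net_cfg.family_ids, truth.true_cas, config.labeled_fraction,
                config.annotated_fraction, seed=config.seed_labels,
            )
            markers = profiles.MarkerSet(frozenset(net_cfg.marker_ids))
            profiles.write_profile_table(matrix, out / "profiles.tsv")
            profiles.write_label_map(labels, out / "labels.tsv")
            with open(out / "truth_edges.tsv", "w") as fh:
                fh.write("source\ttarget\n")
                for u, v in sorted(truth.edge_set):
                    fh.write(f"{u}\t{v}\n")

    # ------------------------------------------------------------ normalize
    with stage("normalize"):
        matrix = profiles.normalize_by_markers(matrix, markers)
        matrix = profiles.filter_prevalence(matrix, config.min_frac)
        labels = {f: labels.get(f, Label.UNANNOTATED) for f in matrix.family_ids}

    # -------------------------------------------------------------- network
    with stage("network"):
        npn = network.npn_transform(matrix)
        path = network.fit_path(
            npn, nlambda=config.nlambda, screen=config.screen,
            lambda_min_ratio=config.lambda_min_ratio, rule=config.symmetrize_rule,
        )
        lam, G = network.select_ric(
            npn, path, n_rotations=config.n_rotations, seed=config.seed_ric
        )
        network.write_edgelist(G, out / "network_edges.tsv")
        network.write_graphml(G, out / "network.graphml")
        network.write_path_summary(path, out / "lambda_path.tsv")

    # ------------------------------------------------------------ diagnostics
    with stage("cluster_check"):
        n_pos = sum(1 for v in labels.values() if v == Label.POSITIVE)
        if n_pos >= 2:
            dist = analysis.distances_to_labeled(G, labels)
            with open(out / "distance_to_cas.tsv", "w") as fh:
                fh.write("family_id\thops_to_nearest_cas\n")
                for fam in sorted(dist):
                    fh.write(f"{fam}\t{_fmt(dist[fam])}\n")
            clus = analysis.clustering_statistic(
                G, labels, n_draws=config.cluster_n_draws, seed=config.seed_cluster
            )
            with open(out / "clustering_stat.tsv", "w") as fh:
                fh.write("observed\tp_value\tn_draws\n")
                fh.write(f"{_fmt(clus.observed)}\t{_fmt(clus.p_value)}\t{config.cluster_n_draws}\n")
        else:
            logger.warning("fewer than 2 POSITIVE labels; skipping cluster check")

    # -------------------------------------------------------------------- cv
    with stage("cross_validate"):
        cv = hopfield.cross_validate(
            G, labels, k=config.cv_folds, eta=config.eta, seed=config.seed_cv,
            max_sweeps=config.max_sweeps,
        )
        with open(out / "cv_report.tsv", "w") as fh:
            fh.write("fold\ttp\tfp\ttn\tfn\tprecision\trecall\tf1\tfpr\n")
            for f, m in enumerate(cv.per_fold):
                fh.write(
                    f"{f}\t{m.tp}\t{m.fp}\t{m.tn}\t{m.fn}\t{_fmt(m.precision)}\t"
                    f"{_fmt(m.recall)}\t{_fmt(m.f1)}\t{_fmt(m.fpr)}\n"
                )
            m = cv.pooled
            fh.write(
                f"pooled\t{m.tp}\t{m.fp}\t{m.tn}\t{m.fn}\t{_fmt(m.precision)}\t"
                f"{_fmt(m.recall)}\t{_fmt(m.f1)}\t{_fmt(m.fpr)}\n"
            )

    # --------------------------------------------------------------- predict
    with stage("predict"):
        res = hopfield.predict(
            G, labels, eta=config.eta, seed=config.seed_predict,
            max_sweeps=config.max_sweeps, angle_grid_size=config.angle_grid_size,
        )
        states = dict(zip(res.state.node_ids, res.state.states))
        with open(out / "predictions.tsv", "w") as fh:
            fh.write("family_id\tscore\tpredicted\n")
            for fam in sorted(states):
                fh.write(
                    f"{fam}\t{_fmt(states[fam])}\t"
                    f"{'1' if fam in res.predicted else '0'}\n"
                )

    # ----------------------------------------------------------- type assign
    with stage("assign_types"):
        if config.type_map_path:
            tm_df = pd.read_csv(
                config.type_map_path, sep="\t", header=None,
                names=["family_id", "subtype"], dtype=str,
            )
            type_map = dict(zip(tm_df["family_id"], tm_df["subtype"]))
        else:
            # synthetic fallback: every labeled positive carries one subtype
            type_map = {
                f: "I-E" for f, v in labels.items() if v == Label.POSITIVE
            }
        with open(out / "type_assignments.tsv", "w") as fh:
            fh.write("family_id\tsubtype\tconfidence\tn_supporting\n")
            for fam in sorted(res.predicted):
                ta = analysis.assign_putative_type(G, fam, type_map)
                fh.write(
                    f"{fam}\t{ta.subtype or 'NA'}\t{ta.confidence}\t{ta.n_supporting}\n"
                )

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "selected_lambda": lam,
        "n_edges": G.number_of_edges(),
        "hopfield": {"alpha": res.params.alpha, "q": res.params.q,
                     "eta": res.params.eta, "sweeps": res.state.n_sweeps},
        "seeds": {
            k: getattr(config, k)
            for k in dataclasses.asdict(config)
            if k.startswith("seed_")
        },
        "stage_seconds": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def run_simulation_suite(seed: int = 0, quick: bool = False) -> List[dict]:
    """Planted-truth benchmarks with pass/fail against fixed thresholds."""
    rows = []

    def check(name, value, threshold, ok):
        rows.append({"check": name, "value": value, "threshold": threshold,
                     "passed": bool(ok)})

    # network recovery on planted chains
    cfg = synth.SyntheticNetworkConfig(
        p=60, n=150 if quick else 300, module_sizes=(10, 10, 10),
        within_module_partial_corr=0.4, n_markers=5, seed=seed,
    )
    omega, truth = synth.make_precision(cfg)
    mat = synth.sample_abundances(omega, cfg)
    npn = network.npn_transform(mat)
    path = network.fit_path(npn)
    _, G = network.select_ric(npn, path, seed=seed)
    est = {tuple(sorted(e)) for e in G.edges()}
    tp = len(est & truth.edge_set)
    prec = tp / len(est) if est else 0.0
    rec = tp / len(truth.edge_set)
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    check("network_edge_recovery_f1", round(f1, 4), 0.6, f1 >= 0.6)

    # propagation recovery on a planted community
    Gp, true_cas = synth.make_planted_graph(
        200 if quick else 500, 25, p_within=0.5, p_background=0.01, seed=seed
    )
    labels = synth.planted_labels(
        sorted(Gp.nodes), true_cas, labeled_fraction=1.0,
        annotated_fraction=0.8, seed=seed,
    )
    cv = hopfield.cross_validate(Gp, labels, k=5, seed=seed)
    check("propagation_pooled_fpr", round(cv.pooled.fpr, 4), 0.05,
          cv.pooled.fpr < 0.05)
    n_ann = sum(1 for v in labels.values() if v != Label.UNANNOTATED)
    n_pos = sum(1 for v in labels.values() if v == Label.POSITIVE)
    null = hopfield.null_model(n_ann, n_pos, reps=1000 if quick else 10_000,
                               seed=seed)
    thr = float(np.quantile(null.f1, 0.975))
    check("propagation_f1_beats_null", round(cv.pooled.f1, 4), round(thr, 4),
          cv.pooled.f1 > thr)

    # colocation planted signal
    gcfg = synth.SyntheticGenomeConfig(
        n_genomes=10, colocated_families=("NOVEL",), pi_coloc=1.0, seed=seed
    )
    tables = synth.simulate_genomes(gcfg)
    res = colocation.orf_reassignment_test(
        tables, "NOVEL", n_perm=200 if quick else 2000, seed=seed
    )
    min_p = 1.0 / (res.n_perm + 1)
    check("colocation_planted_p_at_floor", res.p_value, round(min_p, 6),
          res.p_value <= min_p * 1.500001)
    return rows
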