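"""Scoring, a spectral-clustering comparator, and synthetic-sweep harnesses.

ARI (adjusted Rand index) is the chance-corrected agreement between two
partitions: 1 for identical partitions (up to relabeling), ≈0 at chance.  The
spectral baseline is a comparator wrapper around scikit-learn's
normalized-Laplacian spectral clustering on the (multiplicity-weighted)
adjacency of a 2-uniform input — it is not part of the method itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score

from .annealing import AnnealingConfig, anneal, derive_seeds, multi_run
from .core import Assignment, Hypergraph
from .entropy import EntropyModel
from .generators import PlantedPartitionConfig, planted_partition

__all__ = [
    "adjusted_rand_index",
    "spectral_baseline",
    "SweepResult",
    "heatmap_sweep",
    "entropy_vs_ari",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-invariant ARI in [−1, 1]."""
    a = np.asarray(getattr(labels_a, "c", labels_a))
    b = np.asarray(getattr(labels_b, "c", labels_b))
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def spectral_baseline(graph: Hypergraph, m: int, seed: int = 0) -> Assignment:
    """m-way spectral clustering of a 2-uniform (multi)graph.

    Edge multiplicities enter as adjacency weights.  Isolated vertices are
    excluded from the eigen-decomposition and assigned to the largest
    recovered cluster afterwards.
    """
    if not graph.edges:
        raise ValueError("graph has no edges")
    if not graph.is_uniform(2):
        raise ValueError("spectral baseline requires a 2-uniform input")
    n = graph.n
    A = np.zeros((n, n))
    for u, v in graph.edges:
        if u != v:
            A[u, v] += 1.0
            A[v, u] += 1.0
    deg = A.sum(axis=1)
    keep = np.flatnonzero(deg > 0)
    if keep.size < m:
        raise ValueError("fewer connected vertices than clusters")
    sc = SpectralClustering(
        n_clusters=m, affinity="precomputed", assign_labels="kmeans",
        random_state=seed,
    )
    sub = sc.fit_predict(A[np.ix_(keep, keep)])
    labels = np.empty(n, dtype=np.int64)
    labels[keep] = sub
    if keep.size < n:
        largest = int(np.bincount(sub, minlength=m).argmax())
        labels[np.setdiff1d(np.arange(n), keep)] = largest
    return Assignment(labels, m)


@dataclass
class SweepResult:
    """Mean-ARI grid over (p2, p3) plus the settings that produced it."""

    p2_values: np.ndarray
    p3_values: np.ndarray
    ari: np.ndarray  # shape (len(p3), len(p2)), row-major in p3
    metadata: dict = field(default_factory=dict)


def _cluster_planted(h, truth, attempts, config):
    res = multi_run(h, config, attempts)
    return adjusted_rand_index(res.best_assignment, truth)


def heatmap_sweep(
    p2_values,
    p3_values,
    n: int,
    replicates: int = 2,
    attempts: int = 5,
    config: AnnealingConfig | None = None,
    seed: int = 0,
    progress: bool = False,
) -> SweepResult:
    """Mean ARI of best-of-``attempts`` clustering over a (p2, p3) grid.

    For each grid point, ``replicates`` hypergraphs are generated and each is
    clustered with the best (lowest-entropy) of ``attempts`` annealing runs;
    the pixel is the mean ARI against the planted labels.
    """
    p2_values = np.asarray(p2_values, dtype=float)
    p3_values = np.asarray(p3_values, dtype=float)
    if config is None:
        config = AnnealingConfig(m=2)
    grid = np.zeros((p3_values.size, p2_values.size))
    master = np.random.default_rng(seed)
    for j, p3 in enumerate(p3_values):
        for i, p2 in enumerate(p2_values):
            aris = []
            for _ in range(replicates):
                gseed = int(master.integers(2**31 - 1))
                h, truth = planted_partition(
                    PlantedPartitionConfig(n=n, p2=float(p2), p3=float(p3), seed=gseed)
                )
                cfg = AnnealingConfig(
                    m=config.m, steps=config.steps, beta_rate=config.beta_rate,
                    model=config.model, seed=int(master.integers(2**31 - 1)),
                )
                aris.append(_cluster_planted(h, truth, attempts, cfg))
            grid[j, i] = float(np.mean(aris))
        if progress:
            print(f"p3={p3:.2f} row done", flush=True)
    meta = dict(
        n=n, replicates=replicates, attempts=attempts, steps=config.steps,
        beta_rate=config.beta_rate, model=str(config.model.value), seed=seed,
        spectral=None,
    )
    return SweepResult(p2_values, p3_values, grid, meta)


def entropy_vs_ari(
    h: Hypergraph,
    truth: Assignment,
    runs: int,
    config: AnnealingConfig,
    models=(EntropyModel.DEGREE_CORRECTED,),
) -> list[dict]:
    """Per-run (model, best entropy, ARI) records for correlation checks.

    Each record keeps the lowest entropy seen on that run and the ARI of the
    corresponding assignment against ``truth``; over runs with real signal
    the two are inversely correlated.
    """
    records = []
    for model in models:
        model = EntropyModel(model)
        for run, s in enumerate(derive_seeds(config.seed, runs)):
            cfg = AnnealingConfig(
                m=config.m, steps=config.steps, beta_rate=config.beta_rate,
                model=model, seed=s,
            )
            res = anneal(h, cfg)
            records.append(
                dict(
                    model=model.value,
                    run=run,
                    best_log_z=res.best_log_z,
                    ari=adjusted_rand_index(res.best_assignment, truth),
                )
            )
    return records
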