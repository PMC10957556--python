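"""Modularity maximization and consensus community detection.

Single runs use the Louvain heuristic (via networkx) on the positive-weight
thresholded network; the modularity statistic Q is the Newman-Girvan weighted
form Q = sum_c [ e_c/m - (d_c/2m)^2 ].  Because a "median" of label vectors is
ill-defined, stability over restarts is obtained by consensus clustering: the
node-pair co-assignment matrix over n_iter restarts is thresholded at 0.5 and
re-clustered until every restart agrees; the median of the per-run Q values is
reported alongside the consensus partition's own Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import ThresholdedNetwork

__all__ = [
    "Partition",
    "ConsensusResult",
    "modularity_value",
    "louvain_once",
    "consensus_partition",
    "module_census",
]

#: Co-assignment threshold used during consensus clustering.
CONSENSUS_TAU = 0.5


@dataclass
class Partition:
    affiliation: np.ndarray  # labels 1..M, module 1 the largest
    q: float
    gamma_res: float = 1.0
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return int(np.unique(self.affiliation).size)


@dataclass
class ConsensusResult:
    final_partition: Partition
    n_modules: int
    module_sizes: list[int]
    q_runs: np.ndarray
    q_summary: float  # median of q_runs


def _as_weights(net: ThresholdedNetwork | np.ndarray) -> np.ndarray:
    w = net.weights if isinstance(net, ThresholdedNetwork) else np.asarray(net, float)
    if np.any(w < 0):
        raise ValueError("community detection expects nonnegative weights")
    return w


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Renumber modules 1..M by descending size (ties: smallest member index)."""
    uniq = np.unique(labels)
    stats = sorted(
        ((-(labels == u).sum(), int(np.flatnonzero(labels == u)[0]), u) for u in uniq)
    )
    mapping = {u: rank + 1 for rank, (_, _, u) in enumerate(stats)}
    return np.array([mapping[v] for v in labels], dtype=int)


def modularity_value(
    net: ThresholdedNetwork | np.ndarray, affiliation: np.ndarray, gamma_res: float = 1.0
) -> float:
    """Newman-Girvan weighted modularity of a given node partition."""
    w = _as_weights(net)
    labels = np.asarray(affiliation)
    if labels.shape[0] != w.shape[0]:
        raise ValueError("affiliation length does not match node count")
    m2 = w.sum()  # 2m
    if m2 == 0:
        raise ValueError("empty graph has no modularity")
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = w[np.ix_(mask, mask)].sum() / 2.0
        d_c = w[mask].sum()
        q += e_c / (m2 / 2.0) - gamma_res * (d_c / m2) ** 2
    return float(q)


def louvain_once(
    net: ThresholdedNetwork | np.ndarray, seed: int = 0, gamma_res: float = 1.0
) -> Partition:
    """One seeded Louvain run; deterministic given the seed."""
    w = _as_weights(net)
    g = nx.from_numpy_array(w)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma_res, seed=int(seed)
    )
    labels = np.empty(w.shape[0], dtype=int)
    for ci, nodes in enumerate(comms):
        labels[list(nodes)] = ci + 1
    labels = _canonicalize(labels)
    return Partition(
        affiliation=labels,
        q=modularity_value(w, labels, gamma_res),
        gamma_res=gamma_res,
        seed=seed,
    )


def _coassignment(label_runs: list[np.ndarray]) -> np.ndarray:
    n = label_runs[0].size
    co = np.zeros((n, n))
    for lab in label_runs:
        co += lab[:, None] == lab[None, :]
    co /= len(label_runs)
    np.fill_diagonal(co, 0.0)
    return co


def _components_partition(co_binary: np.ndarray) -> np.ndarray:
    g = nx.from_numpy_array(co_binary)
    labels = np.empty(co_binary.shape[0], dtype=int)
    for ci, comp in enumerate(nx.connected_components(g)):
        labels[list(comp)] = ci + 1
    return _canonicalize(labels)


def consensus_partition(
    net: ThresholdedNetwork | np.ndarray,
    n_iter: int = 100,
    seed: int = 0,
    gamma_res: float = 1.0,
    max_rounds: int = 20,
) -> ConsensusResult:
    """Consensus clustering over ``n_iter`` Louvain restarts.

    Restart seeds derive deterministically from ``seed``.  The co-assignment
    matrix is thresholded at 0.5 and re-clustered until all restarts agree (or
    ``max_rounds``); the final Q is recomputed on the original network.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    w = _as_weights(net)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_iter)
    runs = [louvain_once(w, seed=int(s), gamma_res=gamma_res) for s in run_seeds]
    q_runs = np.array([p.q for p in runs])
    labels = [p.affiliation for p in runs]
    co = _coassignment(labels)
    for _ in range(max_rounds):
        offdiag = co[np.triu_indices_from(co, 1)]
        if np.all((offdiag == 0) | (offdiag == 1)):
            break
        thresholded = np.where(co > CONSENSUS_TAU, co, 0.0)
        if not thresholded.any():  # no stable pair: fall back to best run
            best = labels[int(np.argmax(q_runs))]
            co = (best[:, None] == best[None, :]).astype(float)
            np.fill_diagonal(co, 0.0)
            break
        reseeds = rng.integers(0, 2**31 - 1, size=n_iter)
        labels = [
            louvain_once(thresholded, seed=int(s), gamma_res=gamma_res).affiliation
            for s in reseeds
        ]
        co = _coassignment(labels)
    final_labels = _components_partition((co > CONSENSUS_TAU).astype(float))
    final = Partition(
        affiliation=final_labels,
        q=modularity_value(w, final_labels, gamma_res),
        gamma_res=gamma_res,
        seed=seed,
    )
    sizes = [int((final_labels == c).sum()) for c in np.unique(final_labels)]
    sizes.sort(reverse=True)
    return ConsensusResult(
        final_partition=final,
        n_modules=final.n_modules,
        module_sizes=sizes,
        q_runs=q_runs,
        q_summary=float(np.median(q_runs)),
    )


def module_census(
    results: dict[str, ConsensusResult], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-subject module counts/sizes with optional group summaries attached.

    ``results`` maps subject_id -> ConsensusResult; ``groups`` maps
    subject_id -> group label.
    """
    if not results:
        raise ValueError("no consensus results supplied")
    rows = []
    for sid, res in results.items():
        rows.append(
            {
                "subject_id": sid,
                "group": (groups or {}).get(sid, "all"),
                "n_modules": res.n_modules,
                "largest_module": res.module_sizes[0],
                "median_module_size": float(np.median(res.module_sizes)),
                "q_consensus": res.final_partition.q,
                "q_median": res.q_summary,
            }
        )
    return pd.DataFrame(rows)
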