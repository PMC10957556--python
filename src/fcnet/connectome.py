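"""From ROI timeseries to Fisher-z connectivity matrices and thresholded graphs.

Pairwise Pearson correlations between node timeseries are Fisher
variance-stabilized, z = atanh(r), with |r| clipped at 1 - 1e-7 so z stays
finite.  Proportional thresholding retains the strongest fraction delta of the
N(N-1)/2 off-diagonal edges, ranked by signed z (strongest positive first)
with a deterministic lexicographic tie-break, so edge sets are nested across a
density sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectTimeseries",
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "DENSITY_GRID",
    "FISHER_CLIP",
    "correlation_matrix",
    "proportional_threshold",
    "density_sweep",
    "bootstrap_edge_threshold",
    "n_edges_at_density",
    "read_timeseries_tsv",
]

#: Default density sweep, 6% to 32% in 2% steps (14 levels).
DENSITY_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.06, 0.321, 0.02), 2))

#: |r| clip keeping atanh finite.
FISHER_CLIP = 1.0 - 1e-7


def _default_node_ids(n: int) -> list[str]:
    return [f"roi{i:02d}" for i in range(n)]


@dataclass
class SubjectTimeseries:
    """Node x time signal matrix for one subject."""

    subject_id: str
    data: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries must be a 2-D node x time matrix")
        n, t = self.data.shape
        if n < 2:
            raise ValueError("need at least 2 nodes")
        if t < 4:
            raise ValueError("need at least 4 timepoints (Fisher variance uses T-3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timeseries contains non-finite values")
        if not self.node_ids:
            self.node_ids = _default_node_ids(n)
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match data")


@dataclass
class ConnectivityMatrix:
    """Symmetric signed Fisher-z matrix, diagonal exactly zero."""

    subject_id: str
    z: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("z must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite entries")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("z must be symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("diagonal must be exactly zero")
        if not self.node_ids:
            self.node_ids = _default_node_ids(n)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class ThresholdedNetwork:
    """Weighted graph retaining the strongest fraction ``density`` of edges."""

    density: float
    weights: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.node_ids:
            self.node_ids = _default_node_ids(self.weights.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1) != 0))


def n_edges_at_density(n_nodes: int, density: float) -> int:
    """round(density * N(N-1)/2), half away from zero."""
    x = density * n_nodes * (n_nodes - 1) / 2.0
    return int(math.floor(x + 0.5))


def correlation_matrix(ts: SubjectTimeseries) -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity; zero-variance nodes are an error."""
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.node_ids[i] for i in dead)
        raise ValueError(f"zero-variance node series: {names}")
    r = np.corrcoef(ts.data)
    r = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # exact symmetry against fp noise
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, z=z, node_ids=list(ts.node_ids))


def _ranked_edges(z: np.ndarray) -> list[tuple[int, int]]:
    """Upper-triangle edges ranked by descending signed weight, ties by (i, j)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = z[iu, ju]
    order = np.lexsort((ju, iu, -w))  # primary: -w; ties: lexicographic (i, j)
    return [(int(iu[k]), int(ju[k])) for k in order]


def proportional_threshold(c: ConnectivityMatrix, density: float) -> ThresholdedNetwork:
    """Retain the top ``round(density * N(N-1)/2)`` signed-strongest edges.

    Retained edges keep their z value unchanged; all others are zeroed.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density {density} outside (0, 1]")
    n = c.n_nodes
    keep = n_edges_at_density(n, density)
    w = np.zeros_like(c.z)
    for i, j in _ranked_edges(c.z)[:keep]:
        w[i, j] = w[j, i] = c.z[i, j]
    return ThresholdedNetwork(density=density, weights=w, node_ids=list(c.node_ids))


def density_sweep(
    c: ConnectivityMatrix, grid: Sequence[float] = DENSITY_GRID
) -> list[ThresholdedNetwork]:
    """One thresholded network per grid density; edge sets are nested."""
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("density grid must be strictly increasing")
    return [proportional_threshold(c, d) for d in grid]


def bootstrap_edge_threshold(
    cohort: Sequence[ConnectivityMatrix],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap CI over subjects of each edge's mean z; edge significant when
    the CI excludes zero.

    Returns ``(r_crit, implied_density)``: the smallest |r| among significant
    edges (back-transformed from mean z) and the fraction of edges significant.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    n = cohort[0].n_nodes
    iu, ju = np.triu_indices(n, 1)
    zmat = np.stack([c.z[iu, ju] for c in cohort])  # subjects x edges
    if np.allclose(zmat.var(axis=0), 0.0):
        raise ValueError("degenerate cohort: no between-subject variability")
    rng = np.random.default_rng(seed)
    s = zmat.shape[0]
    idx = rng.integers(0, s, size=(n_boot, s))
    boot_means = zmat[idx].mean(axis=1)  # n_boot x edges
    lo = np.percentile(boot_means, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot_means, 100 * (1 - alpha / 2), axis=0)
    sig = (lo > 0) | (hi < 0)
    implied_density = float(sig.mean())
    if not sig.any():
        return float("nan"), 0.0
    mean_r = np.tanh(zmat.mean(axis=0))
    r_crit = float(np.min(np.abs(mean_r[sig])))
    return r_crit, implied_density


def read_timeseries_tsv(path: str | Path, subject_id: str | None = None) -> SubjectTimeseries:
    """Read a headerless node x time TSV timeseries file."""
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t")
    return SubjectTimeseries(subject_id=subject_id or path.stem, data=data)
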