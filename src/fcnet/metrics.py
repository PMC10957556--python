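"""Weighted graph measures on thresholded connectivity networks.

Conventions (held fixed across the package):

* Clustering uses the Onnela geometric-mean triangle formulation with weights
  normalized by the network maximum; transitivity is its global analogue,
  sum(2 t_i) / sum(k_i (k_i - 1)).
* Path lengths use the inverse-weight transform (length = 1/w); CPL averages
  finite pairwise distances, global efficiency averages 1/d with disconnected
  pairs contributing 0.
* Local efficiency of a node is the global efficiency of its neighbor-induced
  subgraph on max-normalized weights.
* Assortativity is the Pearson correlation of endpoint degree (or strength)
  over the symmetrized edge list; zero endpoint variance yields NaN, which is
  distinct from an assortativity of 0.
* The rich-club curve at level k is W_>k over the sum of the E_>k largest
  weights anywhere in the network, computed on the subgraph of nodes with
  degree > k, and normalized by the mean curve of a randomized ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectome import ThresholdedNetwork

__all__ = [
    "GlobalMetrics",
    "SmallWorldResult",
    "RichClubCurve",
    "degree_strength",
    "clustering_transitivity",
    "path_metrics",
    "local_efficiency",
    "assortativity",
    "participation_coefficient",
    "small_world",
    "rich_club",
    "node_metric_table",
    "global_metrics",
]


@dataclass
class GlobalMetrics:
    transitivity: float
    cpl: float
    global_efficiency: float
    assortativity_r: float


@dataclass
class SmallWorldResult:
    """gamma = C/C_rand, lambda = L/L_rand, SWC = gamma/lambda and the
    lattice-referenced omega-style measure SWM = L_rand/L - C/C_latt."""

    gamma: float
    lam: float
    swc: float
    swm: float


@dataclass
class RichClubCurve:
    k_grid: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray
    phi_norm: np.ndarray


def _weights(net: ThresholdedNetwork | np.ndarray) -> np.ndarray:
    w = net.weights if isinstance(net, ThresholdedNetwork) else np.asarray(net, float)
    return w


def _require_nonnegative(w: np.ndarray, what: str) -> None:
    if np.any(w < 0):
        raise ValueError(f"{what} requires nonnegative weights")


def degree_strength(net: ThresholdedNetwork | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree (count of incident edges) and strength (sum of weights)."""
    w = _weights(net)
    k = (w != 0).sum(axis=1).astype(int)
    s = w.sum(axis=1)
    return k, s


def clustering_transitivity(
    net: ThresholdedNetwork | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node and global weighted transitivity.

    Nodes with degree < 2 get CC = 0.  Transitivity of a graph with no
    connected triads is 0 by convention.
    """
    w = _weights(net)
    _require_nonnegative(w, "clustering")
    k = (w != 0).sum(axis=1)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0]), 0.0
    cube = np.cbrt(w / wmax)
    # t_i = half the diagonal of cube^3: geometric-mean triangle intensity
    t = np.diag(cube @ cube @ cube) / 2.0
    denom = k * (k - 1)
    cc = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1), 0.0)
    total_triads = float(denom.sum())
    transitivity = float(2.0 * t.sum() / total_triads) if total_triads > 0 else 0.0
    return cc, transitivity


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    lengths[~np.isfinite(lengths)] = 0.0  # csgraph: 0 = absent edge
    return shortest_path(lengths, method="D", directed=False)


def path_metrics(net: ThresholdedNetwork | np.ndarray) -> tuple[float, float]:
    """Characteristic path length and global efficiency (length = 1/weight).

    CPL averages finite pairwise distances; a graph with no connected pair has
    undefined CPL (NaN, with a warning).  Efficiency averages 1/d over all
    pairs, disconnected pairs contributing 0.
    """
    w = _weights(net)
    _require_nonnegative(w, "path metrics")
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = _distance_matrix(w)
    iu = np.triu_indices(n, 1)
    pair_d = d[iu]
    finite = np.isfinite(pair_d)
    if finite.any():
        cpl = float(pair_d[finite].mean())
    else:
        warnings.warn("fully disconnected graph: CPL undefined", stacklevel=2)
        cpl = float("nan")
    inv = np.where(finite & (pair_d > 0), 1.0 / np.where(pair_d > 0, pair_d, 1), 0.0)
    return cpl, float(inv.mean())


def local_efficiency(net: ThresholdedNetwork | np.ndarray) -> np.ndarray:
    """Per-node efficiency of the neighbor-induced subgraph.

    Weights are normalized by the network maximum so values lie in [0, 1];
    nodes with fewer than two neighbors get 0.
    """
    w = _weights(net)
    _require_nonnegative(w, "local efficiency")
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(wn[i] > 0)
        if nb.size < 2:
            continue
        sub = wn[np.ix_(nb, nb)]
        d = _distance_matrix(sub)
        iu = np.triu_indices(nb.size, 1)
        pd_ = d[iu]
        inv = np.where(np.isfinite(pd_) & (pd_ > 0), 1.0 / np.where(pd_ > 0, pd_, 1), 0.0)
        eloc[i] = float(inv.mean())
    return eloc


def assortativity(net: ThresholdedNetwork | np.ndarray, mode: str = "degree") -> float:
    """Endpoint degree/strength correlation over the symmetrized edge list.

    Returns NaN (flagged distinct from 0) when endpoint values have zero
    variance, e.g. on regular graphs.
    """
    if mode not in ("degree", "strength"):
        raise ValueError("mode must be 'degree' or 'strength'")
    w = _weights(net)
    k, s = degree_strength(w)
    x = k.astype(float) if mode == "degree" else s
    iu, ju = np.nonzero(np.triu(w, 1))
    if iu.size < 2:
        raise ValueError("need at least 2 edges")
    a = np.concatenate([x[iu], x[ju]])
    b = np.concatenate([x[ju], x[iu]])
    if np.isclose(a.var(), 0.0):
        warnings.warn("assortativity undefined: zero endpoint variance", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def participation_coefficient(
    net: ThresholdedNetwork | np.ndarray,
    partition: Sequence[int] | np.ndarray,
    mode: str = "degree",
) -> np.ndarray:
    """P_i = 1 - sum_m (d_im / d_i)^2 with d the (binary) degree.

    ``mode='strength'`` swaps degree for strength; this variant goes beyond
    the degree-based definition and is off by default.  Nodes with d_i = 0
    get P = 0.
    """
    w = _weights(net)
    labels = np.asarray(partition)
    n = w.shape[0]
    if labels.shape != (n,):
        raise ValueError("partition length does not match node count")
    contrib = (w != 0).astype(float) if mode == "degree" else w
    d = contrib.sum(axis=1)
    p = np.zeros(n)
    for m in np.unique(labels):
        dm = contrib[:, labels == m].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p += np.where(d > 0, (dm / np.where(d > 0, d, 1)) ** 2, 0.0)
    return np.where(d > 0, 1.0 - p, 0.0)


def small_world(
    net: ThresholdedNetwork | np.ndarray,
    null_ensemble: Sequence[ThresholdedNetwork | np.ndarray],
    lattice_ref: ThresholdedNetwork | np.ndarray | None = None,
) -> SmallWorldResult:
    """Small-world coefficient against a randomized ensemble, plus the
    lattice-referenced measure when a lattice reference is supplied.

    gamma and lambda are ratios of transitivity and CPL to the ensemble
    means; SWM = CPL_rand/CPL - C/C_latt (NaN without a lattice reference).
    Zero ensemble denominators yield NaN with a warning.
    """
    if len(null_ensemble) < 1:
        raise ValueError("null ensemble must contain at least one network")
    _, t_obs = clustering_transitivity(net)
    cpl_obs, _ = path_metrics(net)
    t_rand = float(np.mean([clustering_transitivity(m)[1] for m in null_ensemble]))
    cpl_rand = float(np.mean([path_metrics(m)[0] for m in null_ensemble]))
    if t_rand == 0 or cpl_rand == 0 or cpl_obs == 0:
        warnings.warn("small-world denominators degenerate", stacklevel=2)
        return SmallWorldResult(float("nan"), float("nan"), float("nan"), float("nan"))
    gamma = t_obs / t_rand
    lam = cpl_obs / cpl_rand
    swm = float("nan")
    if lattice_ref is not None:
        _, t_latt = clustering_transitivity(lattice_ref)
        if t_latt > 0:
            swm = cpl_rand / cpl_obs - t_obs / t_latt
        else:
            warnings.warn("lattice reference has zero transitivity", stacklevel=2)
    return SmallWorldResult(gamma=gamma, lam=lam, swc=gamma / lam, swm=swm)


def _phi_curve(w: np.ndarray, k_grid: np.ndarray) -> np.ndarray:
    k = (w != 0).sum(axis=1)
    iu = np.triu_indices(w.shape[0], 1)
    all_w = np.sort(w[iu][w[iu] > 0])[::-1]
    cum = np.concatenate([[0.0], np.cumsum(all_w)])
    phi = np.full(k_grid.size, np.nan)
    for idx, kk in enumerate(k_grid):
        nodes = np.flatnonzero(k > kk)
        if nodes.size < 2:
            continue
        sub = w[np.ix_(nodes, nodes)]
        su, sv = np.triu_indices(nodes.size, 1)
        vals = sub[su, sv]
        e_k = int(np.count_nonzero(vals))
        if e_k == 0:
            continue
        phi[idx] = float(vals.sum() / cum[e_k])
    return phi


def rich_club(
    net: ThresholdedNetwork | np.ndarray,
    null_ensemble: Sequence[ThresholdedNetwork | np.ndarray] = (),
) -> RichClubCurve:
    """Weighted rich-club curve Phi_w(k) for k = 1 .. max degree - 1.

    Phi_w(k) = (weight within the degree->k club) / (sum of the same number of
    globally strongest weights); Phi_norm divides by the ensemble mean curve.
    Undefined levels (club smaller than 2 nodes or edgeless, or zero/NaN
    ensemble mean) are NaN.
    """
    w = _weights(net)
    _require_nonnegative(w, "rich club")
    k = (w != 0).sum(axis=1)
    kmax = int(k.max()) if k.size else 0
    k_grid = np.arange(1, max(kmax, 1))
    phi = _phi_curve(w, k_grid)
    if null_ensemble:
        rand = np.stack([_phi_curve(_weights(m), k_grid) for m in null_ensemble])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            phi_rand_mean = np.nanmean(rand, axis=0)
    else:
        phi_rand_mean = np.full(k_grid.size, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = np.where(
            np.isnan(phi) | np.isnan(phi_rand_mean) | (phi_rand_mean == 0),
            np.nan,
            phi / phi_rand_mean,
        )
    return RichClubCurve(k_grid=k_grid, phi=phi, phi_rand_mean=phi_rand_mean, phi_norm=phi_norm)


def node_metric_table(
    net: ThresholdedNetwork, partition: Sequence[int] | np.ndarray | None = None
) -> pd.DataFrame:
    """Tidy per-node metric table at one density."""
    k, s = degree_strength(net)
    cc, _ = clustering_transitivity(net)
    eloc = local_efficiency(net)
    df = pd.DataFrame(
        {
            "node_id": net.node_ids,
            "density": net.density,
            "degree": k,
            "strength": s,
            "clustering": cc,
            "local_efficiency": eloc,
        }
    )
    if partition is not None:
        df["participation"] = participation_coefficient(net, partition)
    return df


def global_metrics(net: ThresholdedNetwork) -> GlobalMetrics:
    """Transitivity, CPL, global efficiency and degree assortativity."""
    _, trans = clustering_transitivity(net)
    cpl, eff = path_metrics(net)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = assortativity(net, mode="degree")
    return GlobalMetrics(transitivity=trans, cpl=cpl, global_efficiency=eff, assortativity_r=r)
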