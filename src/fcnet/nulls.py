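"""Degree-, strength- and weight-preserving null networks.

Signed connectivity matrices are randomized with sign-aware edge exchanges:
a swap takes two node pairs (a,b), (c,d) and exchanges their entries with
(a,d), (c,b) only when the two pairs carry one sign class and the two target
pairs carry the other (absent edges count as their own class).  Each accepted
swap therefore preserves every node's positive degree and negative degree
exactly — this also works on full matrices, where positive and negative edges
jointly occupy every node pair.  After ``n_swap_iters`` swap passes the
original weight multiset is re-assigned per sign to the randomized topology,
one edge at a time: the largest remaining weight goes to the edge whose
residual node-strength product is largest, and residuals are re-sorted at
each step.  The binary degree sequence per sign and the weight multiset are
preserved exactly; the strength sequence approximately (the quantity the
fidelity checks measure).

Sparse single-sign networks (e.g. proportionally thresholded graphs) take a
fast path of plain degree-preserving double-edge swaps on the edge list.

The lattice reference applies the same swap machinery but accepts only swaps
that move edges toward the index-ordered diagonal band, then places the
largest weights on the most band-central edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import ConnectivityMatrix, ThresholdedNetwork

__all__ = [
    "NullEnsemble",
    "randomize_signed",
    "null_ensemble",
    "lattice_reference",
]


@dataclass
class NullEnsemble:
    source_subject: str
    matrices: list[np.ndarray]
    n_swap_iters: int
    seeds: list[np.random.SeedSequence]


def _as_matrix(c) -> np.ndarray:
    if isinstance(c, ConnectivityMatrix):
        return c.z
    if isinstance(c, ThresholdedNetwork):
        return c.weights
    return np.asarray(c, dtype=float)


def _double_edge_swaps(
    edges: list[tuple[int, int]], n_attempts: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Degree-preserving rewiring of a single-sign undirected edge list."""
    edge_set = {frozenset(e) for e in edges}
    edges = [tuple(e) for e in edges]
    n_e = len(edges)
    for _ in range(n_attempts):
        p, q = rng.integers(0, n_e, size=2)
        if p == q:
            continue
        a, b = edges[p]
        c, d = edges[q]
        if rng.integers(0, 2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.update((new1, new2))
        edges[p] = (a, d)
        edges[q] = (c, b)
    return edges


def _signed_quadruple_swaps(
    r: np.ndarray,
    n_swap_iters: int,
    rng: np.random.Generator,
    max_tries_per_swap: int = 200,
) -> None:
    """In-place sign-aware swaps preserving per-node positive and negative
    degrees (absent edges form their own sign class).

    A swap exchanges the entries of pairs (a,b),(c,d) with (a,d),(c,b) when
    the first two carry one sign class and the target pairs both carry a
    different one.  Candidate pairs are drawn per sign class from the edge
    list (``n_swap_iters`` passes per class), which keeps acceptance usable
    even when one class is rare; the amount of feasible rewiring is bounded
    by how much room the opposite class leaves.
    """
    rl = r.tolist()  # python floats: fast scalar access in the hot loop
    for sign in (1.0, -1.0):
        mask = np.triu(np.array(rl), 1) * sign > 0
        ei, ej = np.nonzero(mask)
        edges = list(zip(ei.tolist(), ej.tolist()))
        n_e = len(edges)
        if n_e < 2:
            continue
        target = n_swap_iters * n_e
        done = 0
        tries = 0
        budget = target * max_tries_per_swap
        while done < target and tries < budget:
            pq = rng.integers(0, n_e, size=(min(8192, budget - tries), 2)).tolist()
            flips = rng.integers(0, 2, size=len(pq)).tolist()
            for (p, q), flip in zip(pq, flips):
                tries += 1
                if p == q:
                    continue
                a, b = edges[p]
                c, d = edges[q]
                if flip:
                    c, d = d, c
                if a == c or a == d or b == c or b == d:
                    continue
                v_ab, v_cd, v_ad, v_cb = rl[a][b], rl[c][d], rl[a][d], rl[c][b]
                s_ad = (v_ad > 0) - (v_ad < 0)
                s_cb = (v_cb > 0) - (v_cb < 0)
                if s_ad != s_cb or s_ad == sign:
                    continue
                rl[a][d] = rl[d][a] = v_ab
                rl[a][b] = rl[b][a] = v_ad
                rl[c][b] = rl[b][c] = v_cd
                rl[c][d] = rl[d][c] = v_cb
                edges[p] = (a, d)
                edges[q] = (c, b)
                done += 1
                if done >= target:
                    break
            if done >= target:
                break
    r[:, :] = rl


def _assign_weights_resorted(
    edges: list[tuple[int, int]],
    weights_desc: np.ndarray,
    target_strength: np.ndarray,
) -> dict[tuple[int, int], float]:
    """Greedy weight re-sorting: largest remaining weight to the edge with the
    largest product of residual node strengths, residuals updated each step."""
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])
    resid = target_strength.astype(float).copy()
    alive = np.ones(len(edges), dtype=bool)
    out: dict[tuple[int, int], float] = {}
    for w in weights_desc:
        idx_alive = np.flatnonzero(alive)
        scores = resid[ei[idx_alive]] * resid[ej[idx_alive]]
        e = int(idx_alive[int(np.argmax(scores))])
        out[(int(ei[e]), int(ej[e]))] = float(w)
        resid[ei[e]] -= w
        resid[ej[e]] -= w
        alive[e] = False
    return out


def randomize_signed(
    c: ConnectivityMatrix | np.ndarray,
    n_swap_iters: int = 5,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Randomize a signed symmetric matrix, preserving per-sign degree
    sequences and the weight multiset exactly, and strengths approximately.

    ``n_swap_iters`` is the number of swap passes over the edge list.
    Networks with fewer than two edges are returned unchanged (warning).
    """
    z = _as_matrix(c).copy()
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(z, 1))
    n_edges = iu.size
    if n_edges < 2:
        warnings.warn("fewer than 2 edges; returned unrandomized", stacklevel=2)
        return z
    has_pos = bool(np.any(z > 0))
    has_neg = bool(np.any(z < 0))
    if has_pos and has_neg:
        _signed_quadruple_swaps(z, n_swap_iters, rng)
        sign_topologies = {
            1.0: np.nonzero(np.triu(z, 1) > 0),
            -1.0: np.nonzero(np.triu(z, 1) < 0),
        }
    else:
        sign = 1.0 if has_pos else -1.0
        edges = list(zip(iu.tolist(), ju.tolist()))
        new_edges = _double_edge_swaps(edges, n_swap_iters * n_edges, rng)
        sign_topologies = {
            sign: (
                np.array([e[0] for e in new_edges]),
                np.array([e[1] for e in new_edges]),
            )
        }
    orig = _as_matrix(c)
    out = np.zeros_like(orig)
    for sign, (ei, ej) in sign_topologies.items():
        if ei.size == 0:
            continue
        mag = np.where(np.sign(orig) == sign, np.abs(orig), 0.0)
        strength = mag.sum(axis=1)
        oi, oj = np.nonzero(np.triu(mag, 1))
        wts_desc = np.sort(mag[oi, oj])[::-1]
        assigned = _assign_weights_resorted(
            list(zip(ei.tolist(), ej.tolist())), wts_desc, strength
        )
        for (i, j), w in assigned.items():
            out[i, j] = out[j, i] = sign * w
    return out


def null_ensemble(
    c: ConnectivityMatrix | np.ndarray,
    m: int = 100,
    n_swap_iters: int = 5,
    seed: int | None = None,
) -> NullEnsemble:
    """``m`` independent randomizations with deterministically derived seeds."""
    if m < 1:
        raise ValueError("ensemble size m must be >= 1")
    subject = c.subject_id if isinstance(c, ConnectivityMatrix) else "matrix"
    children = np.random.SeedSequence(seed).spawn(m)
    mats = [randomize_signed(c, n_swap_iters=n_swap_iters, seed=s) for s in children]
    return NullEnsemble(
        source_subject=subject,
        matrices=mats,
        n_swap_iters=n_swap_iters,
        seeds=children,
    )


def lattice_reference(
    net: ThresholdedNetwork | np.ndarray,
    seed: int | None = None,
    n_swap_iters: int = 10,
) -> ThresholdedNetwork:
    """Degree-preserving latticization: swaps are accepted only when they
    shorten total node-index distance, then the largest weights are placed on
    the most band-central edges.  Node order is the node index."""
    w = _as_matrix(net)
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(np.abs(w), 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    if len(edges) >= 2:
        edge_set = {frozenset(e) for e in edges}
        n_e = len(edges)
        for _ in range(n_swap_iters * n_e):
            p, q = rng.integers(0, n_e, size=2)
            if p == q:
                continue
            a, b = edges[p]
            c_, d = edges[q]
            if rng.integers(0, 2):
                c_, d = d, c_
            if len({a, b, c_, d}) < 4:
                continue
            if abs(a - d) + abs(c_ - b) >= abs(a - b) + abs(c_ - d):
                continue  # only accept moves toward the diagonal band
            new1, new2 = frozenset((a, d)), frozenset((c_, b))
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(frozenset((a, b)))
            edge_set.discard(frozenset((c_, d)))
            edge_set.update((new1, new2))
            edges[p] = (a, d)
            edges[q] = (c_, b)
    # strongest weights nearest the diagonal
    wts_desc = np.sort(np.abs(w[iu, ju]))[::-1]
    canon = [tuple(sorted(e)) for e in edges]
    band_order = sorted(
        range(len(canon)), key=lambda t: (abs(canon[t][0] - canon[t][1]),) + canon[t]
    )
    out = np.zeros_like(w)
    for rank, t in enumerate(band_order):
        i, j = canon[t]
        out[i, j] = out[j, i] = wts_desc[rank]
    density = net.density if isinstance(net, ThresholdedNetwork) else float("nan")
    node_ids = list(net.node_ids) if isinstance(net, ThresholdedNetwork) else []
    return ThresholdedNetwork(density=density, weights=out, node_ids=node_ids)
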