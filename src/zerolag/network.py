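"""Weighted pathlength, strength-preserving null networks, and subnetworks.

Edge weights (connectivity strengths) are inverted to lengths (1/w) so that
stronger edges are shorter; the characteristic pathlength L is the mean over
nodes of the average shortest weighted distance L_i to all other nodes.  The
normalised pathlength L' divides L_i by the mean pathlength of an ensemble
of degree- and strength-preserving random surrogates, removing the trivial
dependence of L on overall connectivity strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path


@dataclass
class PathlengthResult:
    """Shortest weighted distances and their node/network averages."""

    distances: np.ndarray        # (N, N) shortest weighted path lengths
    node_average: np.ndarray     # L_i, (N,)
    mean: float                  # L, mean over nodes
    l_rand: float | None = None  # null-ensemble mean pathlength
    normalized: float | None = None  # L' = mean_i L_i / L_rand


def _validate_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diag(w) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    if np.any(w < 0) or not np.isfinite(w).all():
        raise ValueError("weights must be finite and non-negative")
    return w


def weighted_pathlength(w: np.ndarray) -> PathlengthResult:
    """All-pairs shortest weighted paths with lengths = 1/weight.

    Raises on disconnected graphs, naming the components, since an infinite
    pathlength average is not meaningful for the dense connectivity networks
    this is designed for.
    """
    w = _validate_weights(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rows, cols = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[rows, cols], (rows, cols)), shape=w.shape)
    n_comp, labels = connected_components(lengths, directed=False)
    if n_comp > 1:
        comps = [[int(i) for i in np.flatnonzero(labels == c)]
                 for c in range(n_comp)]
        raise ValueError(f"graph is disconnected; components (node indices): {comps}")
    d = shortest_path(lengths, method="D", directed=False)
    li = d.sum(axis=1) / (n - 1)
    return PathlengthResult(distances=d, node_average=li, mean=float(li.mean()))


# ---------------------------------------------------------------------------
# null model


def _maslov_sneppen(edges: list[tuple[int, int]], n_nodes: int, quota: int,
                    rng: np.random.Generator) -> tuple[list[tuple[int, int]], int]:
    """Degree-preserving double-edge swaps; returns new edge list + accepted count."""
    edge_set = {frozenset(e) for e in edges}
    edges = [tuple(e) for e in edges]
    accepted = 0
    attempts = 0
    max_attempts = max(50 * quota, 100)
    m = len(edges)
    while accepted < quota and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.choice(m, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed rewiring: (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.update((new1, new2))
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        accepted += 1
    return edges, accepted


def _rank_matched_weights(edges: list[tuple[int, int]], weights: np.ndarray,
                          strength: np.ndarray,
                          rng: np.random.Generator,
                          jitter: float = 1.0) -> np.ndarray:
    """Assign the original weight multiset to a rewired topology.

    The sorted weights are placed on edges ranked by a jittered expected
    strength score (s_i + s_j from the original network plus Gaussian noise
    of ``jitter`` score-SDs).  This preserves the weight multiset exactly
    and the nodal strength sequence approximately (strength correlation
    ~0.96 on dense graphs) while keeping the placement random enough that
    a random weighted graph is statistically similar to its own surrogates.
    """
    expected = np.array([strength[i] + strength[j] for i, j in edges])
    score = expected + rng.normal(
        0.0, jitter * max(expected.std(), 1e-12), len(edges))
    out = np.empty(len(edges))
    out[np.argsort(score)] = np.sort(weights)
    return out


def null_network(w: np.ndarray, seed: int | np.random.Generator = 0,
                 n_rewires: int = 5, max_connect_retries: int = 10) -> np.ndarray:
    """Degree- and strength-preserving random surrogate of a weighted graph.

    The topology is randomised by Maslov-Sneppen double-edge swaps
    (``n_rewires`` accepted swaps per edge); the original weight multiset is
    then re-assigned by stochastic rank-matching against the original nodal
    strengths.  Connectivity is preserved by resampling on disconnect.  For
    complete graphs no legal swap exists, so the topology is left unchanged
    and only the weight placement is randomised.
    """
    w = _validate_weights(w)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    present = w[iu] > 0
    edges = list(zip(iu[0][present], iu[1][present]))
    weights = w[iu][present]
    m = len(edges)
    if m == 0:
        return np.zeros_like(w)
    strength = w.sum(axis=1)
    complete = m == n * (n - 1) // 2
    quota = 0 if complete else n_rewires * m
    for attempt in range(max_connect_retries):
        new_edges, accepted = _maslov_sneppen(edges, n, quota, rng)
        if not complete and accepted < quota and attempt == max_connect_retries - 1:
            warnings.warn(
                f"rewiring quota unreachable ({accepted}/{quota} swaps accepted); "
                "returning best-effort surrogate", stacklevel=2)
        new_w = np.zeros_like(w)
        vals = _rank_matched_weights(new_edges, weights, strength, rng)
        for (i, j), v in zip(new_edges, vals):
            new_w[i, j] = new_w[j, i] = v
        rows, cols = np.nonzero(new_w)
        ncomp, _ = connected_components(
            csr_matrix((np.ones(rows.size), (rows, cols)), shape=w.shape),
            directed=False)
        if ncomp == 1:
            return new_w
    warnings.warn("could not produce a connected surrogate; returning last draw",
                  stacklevel=2)
    return new_w


def normalized_pathlength(w: np.ndarray, n_null: int = 500,
                          seed: int | np.random.Generator = 0,
                          n_rewires: int = 5) -> PathlengthResult:
    """Characteristic pathlength normalised by a null-network ensemble.

    L_rand is the mean pathlength over ``n_null`` degree/strength-preserving
    surrogates; L'_i = L_i / L_rand is averaged over nodes and reported in
    ``normalized``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    res = weighted_pathlength(w)
    null_means = np.empty(n_null)
    for k in range(n_null):
        null_means[k] = weighted_pathlength(null_network(w, rng, n_rewires)).mean
    l_rand = float(null_means.mean())
    res.l_rand = l_rand
    res.normalized = float((res.node_average / l_rand).mean())
    return res


# ---------------------------------------------------------------------------
# subnetworks


def subnetwork(w: np.ndarray, region_names: list[str],
               roi_list: list[str]) -> np.ndarray:
    """Principal submatrix of ``w`` restricted to ``roi_list``, in ROI order."""
    w = np.asarray(w, dtype=float)
    index = {name: k for k, name in enumerate(region_names)}
    unknown = [r for r in roi_list if r not in index]
    if unknown:
        raise ValueError(
            f"unknown ROI names {unknown}; valid names: {list(region_names)}")
    idx = np.array([index[r] for r in roi_list])
    return w[np.ix_(idx, idx)]


def default_swm_rois() -> list[str]:
    """The 28 working-memory regions (14 per hemisphere) shipped as config.

    Prefrontal, posterior parietal, anterior cingulate, and entorhinal
    regions of the Desikan-Killiany parcellation; the list is an editable
    plain-text file (``zerolag/data/swm_rois.txt``), one region per line.
    """
    text = resources.files("zerolag").joinpath("data/swm_rois.txt").read_text()
    rois = [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
    return rois
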