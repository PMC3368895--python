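"""Binary network construction, small-world metrics and rewiring nulls.

Connectivity matrices are binarized either with an explicit threshold
(``e_ij = 1 iff z_ij > T``) or — to give every subject the same connection
density — by keeping the ``E = round(K_target * N / 2)`` strongest edges
(degree-uniform thresholding).  On the resulting undirected, unweighted
graphs we compute degree/cost, clustering coefficient, characteristic path
length, and global/local efficiency, and compare each network against an
ensemble of degree-preserving Markov-chain rewired null networks to obtain
the small-worldness

    sigma = (C_net / C_rand) / (L_net / L_rand),

averaged over the null ensemble (25 nulls by default).  The small-world
regime is the degree interval over which every network in a cohort is both
fully connected and has mean sigma > 1; a fixed-increment grid of
observation degrees (16 by default) inside that interval feeds the
statistics stage.

All heavy per-null work (BFS all-pairs distances, double-edge swaps) runs
in numba-compiled kernels; adjacency matrices are plain uint8 numpy arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

log = logging.getLogger(__name__)

MEASURES = ("C_net", "L_net", "E_local", "E_global")


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _bfs_dist_from(adj, src, dist, queue):
    n = adj.shape[0]
    for i in range(n):
        dist[i] = -1
    dist[src] = 0
    queue[0] = src
    head, tail = 0, 1
    while head < tail:
        u = queue[head]
        head += 1
        du = dist[u]
        for v in range(n):
            if adj[u, v] and dist[v] < 0:
                dist[v] = du + 1
                queue[tail] = v
                tail += 1
    return tail


@njit(cache=True)
def _apsp_bfs(adj):
    """Unweighted all-pairs shortest paths; -1 marks unreachable."""
    n = adj.shape[0]
    out = np.empty((n, n), dtype=np.int32)
    dist = np.empty(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for s in range(n):
        _bfs_dist_from(adj, s, dist, queue)
        for j in range(n):
            out[s, j] = dist[j]
    return out


@njit(cache=True)
def _is_connected(adj):
    n = adj.shape[0]
    if n == 0:
        return True
    dist = np.empty(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    reached = _bfs_dist_from(adj, 0, dist, queue)
    return reached == n


@njit(cache=True)
def _pair_efficiency_sum(adj):
    """Sum over ordered pairs of 1/d(i,j) plus the pair count (for means)."""
    n = adj.shape[0]
    dist = np.empty(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    eff = 0.0
    for s in range(n):
        _bfs_dist_from(adj, s, dist, queue)
        for j in range(n):
            if j != s and dist[j] > 0:
                eff += 1.0 / dist[j]
    return eff


@njit(cache=True)
def _clustering(adj):
    """Per-node clustering C_i = edges among neighbours / (K_i choose 2)."""
    n = adj.shape[0]
    c = np.zeros(n, dtype=np.float64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                k += 1
        if k < 2:
            continue
        e = 0
        for j in range(n):
            if not adj[i, j]:
                continue
            for l in range(j + 1, n):
                if adj[i, l] and adj[j, l]:
                    e += 1
        c[i] = 2.0 * e / (k * (k - 1))
    return c


@njit(cache=True)
def _char_path(adj):
    """(L_net, n_unreachable_pairs) over ordered pairs."""
    n = adj.shape[0]
    dist = np.empty(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    total = 0.0
    bad = 0
    for s in range(n):
        _bfs_dist_from(adj, s, dist, queue)
        for j in range(n):
            if j == s:
                continue
            if dist[j] < 0:
                bad += 1
            else:
                total += dist[j]
    if bad > 0:
        return np.inf, bad
    return total / (n * (n - 1)), 0


@njit(cache=True)
def _local_efficiency(adj):
    """Per-node efficiency of the neighbour-induced subgraph (node removed)."""
    n = adj.shape[0]
    out = np.zeros(n, dtype=np.float64)
    nbrs = np.empty(n, dtype=np.int32)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.empty((k, k), dtype=np.uint8)
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nbrs[a], nbrs[b]]
        eff = _pair_efficiency_sum(sub)
        out[i] = eff / (k * (k - 1))
    return out


@njit(cache=True)
def _rewire_kernel(adj, edges, n_accept_target, max_trials, seed):
    """Degree-preserving double-edge swaps in place.

    Picks two distinct edges (a,b), (c,d), randomises orientation, and
    rewires to (a,d), (c,b) unless that would create a self-loop or a
    multi-edge.  Returns the number of accepted swaps.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    accepted = 0
    trials = 0
    while accepted < n_accept_target and trials < max_trials:
        trials += 1
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        accepted += 1
    return accepted


# --------------------------------------------------------------------------
# binarization
# --------------------------------------------------------------------------

def _check_square_symmetric(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(z, z.T, atol=1e-8, equal_nan=True):
        raise ValueError("connectivity matrix must be symmetric")
    return z


def binarize_at_threshold(z: np.ndarray, threshold: float) -> np.ndarray:
    """Adjacency with an edge wherever z_ij > threshold (strict); zero diagonal."""
    z = _check_square_symmetric(z)
    adj = (z > threshold).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)
    return adj


def threshold_to_degree(z: np.ndarray, k_target: float) -> np.ndarray:
    """Keep the E = round(k_target*N/2) strongest edges.

    Gives every network the same connection density regardless of its
    weight distribution.  Ties in z are broken by ascending (i, j)
    lexicographic order so the edge set is deterministic.
    """
    z = _check_square_symmetric(z)
    n = z.shape[0]
    if not (0 < k_target <= n - 1):
        raise ValueError(f"k_target={k_target} outside (0, N-1]")
    n_edges = int(round(k_target * n / 2))
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"requested {n_edges} edges > {max_edges} possible")
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    # sort by descending value, then ascending (i, j) for ties
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj = np.maximum(adj, adj.T)
    return adj


def is_connected(adj: np.ndarray) -> bool:
    """True iff every node is reachable from node 0 by BFS."""
    return bool(_is_connected(np.ascontiguousarray(adj, dtype=np.uint8)))


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def degree_and_cost(adj: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(K_i, K_net, Cost_net); Cost_net = K_net / (N-1)."""
    adj = np.asarray(adj)
    k_i = adj.sum(axis=1).astype(float)
    k_net = float(k_i.mean())
    cost = k_net / (adj.shape[0] - 1)
    return k_i, k_net, cost


def clustering_coefficients(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """(C_i, C_net); C_i = 0 for nodes of degree < 2, C_net averages all nodes."""
    c_i = _clustering(np.ascontiguousarray(adj, dtype=np.uint8))
    return c_i, float(c_i.mean())


def shortest_paths(adj: np.ndarray) -> np.ndarray:
    """Unweighted pairwise distances; +inf for unreachable pairs."""
    d = _apsp_bfs(np.ascontiguousarray(adj, dtype=np.uint8)).astype(float)
    d[d < 0] = np.inf
    return d


def characteristic_path_length(dist: np.ndarray) -> tuple[np.ndarray, float]:
    """(L_i, L_net) from a distance matrix; infinity propagates."""
    n = dist.shape[0]
    off = dist[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    l_i = off.mean(axis=1)
    return l_i, float(off.mean())


def global_efficiency(dist: np.ndarray) -> float:
    """Mean of 1/d over node pairs, with 1/inf = 0."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = dist[~np.eye(n, dtype=bool)]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(off) & (off > 0), 1.0 / off, 0.0)
    return float(inv.mean())


def local_efficiency(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node neighbour-subgraph efficiency and its network mean.

    For node i the subgraph induced by its neighbours (i itself removed)
    measures how well information still flows locally if i fails; nodes
    with fewer than two neighbours contribute 0.
    """
    e_i = _local_efficiency(np.ascontiguousarray(adj, dtype=np.uint8))
    return e_i, float(e_i.mean())


@dataclass
class NetworkMetrics:
    n: int
    k_net: float
    cost: float
    c_net: float
    l_net: float
    e_global: float
    e_local: float


def network_metrics(adj: np.ndarray) -> NetworkMetrics:
    """All scalar measures of one binary network in a single pass."""
    adj = np.ascontiguousarray(adj, dtype=np.uint8)
    _, k_net, cost = degree_and_cost(adj)
    _, c_net = clustering_coefficients(adj)
    l_net, bad = _char_path(adj)
    n = adj.shape[0]
    eff = _pair_efficiency_sum(adj) / (n * (n - 1)) if n > 1 else 0.0
    _, e_loc = local_efficiency(adj)
    return NetworkMetrics(
        n=n, k_net=k_net, cost=cost, c_net=c_net,
        l_net=float(l_net), e_global=float(eff), e_local=e_loc,
    )


# --------------------------------------------------------------------------
# rewiring nulls and small-worldness
# --------------------------------------------------------------------------

def rewire_preserving_degree(
    adj: np.ndarray,
    n_swaps_factor: float = 10.0,
    seed: int | np.random.Generator | None = None,
    require_connected: bool = True,
    max_connect_retries: int = 20,
) -> np.ndarray:
    """Markov-chain randomisation with the degree sequence held fixed.

    Performs ``n_swaps_factor * E`` accepted double-edge swaps (proposals
    creating self-loops or multi-edges are rejected).  If
    ``require_connected``, keeps swapping in further rounds until the
    result is connected, up to ``max_connect_retries`` rounds.
    """
    rng = np.random.default_rng(seed)
    adj = np.ascontiguousarray(adj, dtype=np.uint8).copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    n_edges = edges.shape[0]
    if n_edges < 2:
        return adj
    target = int(round(n_swaps_factor * n_edges))
    max_trials = max(100 * target, 1000)
    for attempt in range(max_connect_retries):
        kseed = int(rng.integers(0, 2**31 - 1))
        _rewire_kernel(adj, edges, target, max_trials, kseed)
        if not require_connected or _is_connected(adj):
            return adj
    raise RuntimeError(
        "rewiring failed to reach a connected null within "
        f"{max_connect_retries} rounds; try a larger n_swaps_factor"
    )


@dataclass
class NullEnsemble:
    """Small-worldness of one network against degree-matched rewired nulls."""

    n_nulls: int
    c_net: float
    l_net: float
    c_rand: np.ndarray
    l_rand: np.ndarray
    gamma: np.ndarray        # C_net / C_rand per null
    lam: np.ndarray          # L_net / L_rand per null
    sigma_per_null: np.ndarray
    sigma: float             # mean over the ensemble
    c_rand_theory: float     # K_net / N
    l_rand_theory: float     # ln N / ln K_net
    n_excluded: int = 0


def small_worldness(
    adj: np.ndarray,
    n_nulls: int = 25,
    seed: int | np.random.Generator | None = None,
    n_swaps_factor: float = 10.0,
    require_connected_nulls: bool = True,
) -> NullEnsemble:
    """sigma = mean over nulls of (C/C_rand)/(L/L_rand).

    Each null is an independent degree-preserving rewiring of the input;
    nulls with zero clustering are excluded (with a warning) since their
    sigma is undefined.  The analytic random-graph values K_net/N and
    ln N / ln K_net are reported for diagnostics only.
    """
    rng = np.random.default_rng(seed)
    adj = np.ascontiguousarray(adj, dtype=np.uint8)
    if not _is_connected(adj):
        raise ValueError("small_worldness requires a connected network")
    n = adj.shape[0]
    _, c_net = clustering_coefficients(adj)
    l_net, _ = _char_path(adj)
    _, k_net, _ = degree_and_cost(adj)

    c_rand = np.empty(n_nulls)
    l_rand = np.empty(n_nulls)
    for b in range(n_nulls):
        null = rewire_preserving_degree(
            adj, n_swaps_factor=n_swaps_factor, seed=rng,
            require_connected=require_connected_nulls,
        )
        _, c_rand[b] = clustering_coefficients(null)
        l_rand[b], _ = _char_path(null)

    ok = c_rand > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("%d null(s) with zero clustering excluded from sigma", n_excluded)
    gamma = np.where(ok, c_net / np.where(ok, c_rand, 1.0), np.nan)
    lam = l_net / l_rand
    sigma_per_null = gamma / lam
    sigma = float(np.nanmean(sigma_per_null)) if ok.any() else float("nan")
    return NullEnsemble(
        n_nulls=n_nulls, c_net=c_net, l_net=float(l_net),
        c_rand=c_rand, l_rand=l_rand, gamma=gamma, lam=lam,
        sigma_per_null=sigma_per_null, sigma=sigma,
        c_rand_theory=k_net / n,
        l_rand_theory=float(np.log(n) / np.log(k_net)) if k_net > 1 else float("nan"),
        n_excluded=n_excluded,
    )


# --------------------------------------------------------------------------
# small-world regime and observation grid
# --------------------------------------------------------------------------

@dataclass
class DegreeGrid:
    """Validated observation degrees inside the small-world regime."""

    k_min: float
    k_max: float
    degrees: list[float]
    increment: float
    n_nulls: int = 25
    edge_counts: dict = field(default_factory=dict)

    @property
    def grid_size(self) -> int:
        return len(self.degrees)


def observation_grid(
    k_min: float, k_max: float, grid_size: int = 16, k_step: float = 0.1
) -> tuple[list[float], float]:
    """Fixed-increment observation degrees inside [k_min, k_max].

    The increment is the largest multiple of ``k_step`` such that
    ``grid_size`` degrees starting at k_min stay within k_max; e.g. a
    regime [19.9, 35.0] yields 16 degrees 19.9, 20.9, ..., 34.9 with
    increment 1.0.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    inc = np.floor((k_max - k_min) / (grid_size - 1) / k_step) * k_step
    inc = round(float(inc), 10)
    if inc < k_step:
        raise ValueError(
            f"regime [{k_min}, {k_max}] too narrow for a {grid_size}-point grid"
        )
    degrees = [round(k_min + i * inc, 10) for i in range(grid_size)]
    return degrees, inc


def _min_connecting_edges(z: np.ndarray) -> int:
    """Smallest top-E edge count whose network is connected (binary search;
    connectivity is monotone because top-E edge sets are nested)."""
    n = z.shape[0]
    lo, hi = n - 1, n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    si, sj = iu[order], ju[order]

    def connected_at(m: int) -> bool:
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[si[:m], sj[:m]] = 1
        adj = adj | adj.T
        return bool(_is_connected(adj))

    if not connected_at(hi):
        raise ValueError("network disconnected even at full density")
    while lo < hi:
        mid = (lo + hi) // 2
        if connected_at(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


def _min_sigma_at_degree(
    z_mats: list[np.ndarray],
    k: float,
    n_nulls: int,
    seed_seq: np.random.SeedSequence,
) -> float:
    worst = np.inf
    children = seed_seq.spawn(len(z_mats))
    for z, child in zip(z_mats, children):
        adj = threshold_to_degree(z, k)
        if not is_connected(adj):
            return -np.inf
        ens = small_worldness(adj, n_nulls=n_nulls, seed=np.random.default_rng(child))
        worst = min(worst, ens.sigma)
    return worst


def find_small_world_regime(
    z_mats: list[np.ndarray],
    grid_size: int = 16,
    n_nulls: int = 25,
    seed: int | None = 0,
    k_step: float = 0.1,
    k_search_max: float = 60.0,
    sigma_margin: float = 0.1,
) -> DegreeGrid:
    """Find [K_min, K_max] and an observation grid valid for every network.

    K_min is the smallest degree (on a 0.1 grid) at which every network is
    fully connected; K_max is the largest degree at which every network
    keeps mean sigma above ``1 + sigma_margin`` over the rewiring nulls
    (the margin guards the strict sigma > 1 condition against null-ensemble
    resampling noise; sigma decreases as density grows, which the binary
    search exploits).  The grid holds ``grid_size`` degrees from K_min with
    the largest 0.1-multiple increment that stays within K_max.
    """
    if not z_mats:
        raise ValueError("no connectivity matrices given")
    n = z_mats[0].shape[0]
    k_search_max = min(k_search_max, n - 1)
    seed_seq = np.random.SeedSequence(seed)

    # connectivity bound (deterministic)
    need_edges = max(_min_connecting_edges(z) for z in z_mats)
    k_min = np.ceil((2 * need_edges / n) / k_step) * k_step
    k_min = round(float(k_min), 10)

    # sigma bound (stochastic; decreasing in degree)
    lo = int(round(k_min / k_step))
    hi = int(round(k_search_max / k_step))
    sig_seq, = seed_seq.spawn(1)

    def sigma_ok(idx: int) -> bool:
        k = idx * k_step
        s = _min_sigma_at_degree(
            z_mats, k, n_nulls, np.random.SeedSequence((seed or 0) * 100003 + idx)
        )
        return s > 1.0 + sigma_margin

    if not sigma_ok(lo):
        raise ValueError(
            f"empty small-world regime: at K={lo * k_step:.1f} some network "
            "fails mean sigma > 1 over the null ensemble"
        )
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if sigma_ok(mid):
            lo = mid
        else:
            hi = mid - 1
    k_max = round(lo * k_step, 10)

    degrees, inc = observation_grid(k_min, k_max, grid_size, k_step)
    edge_counts = {k: int(round(k * n / 2)) for k in degrees}
    return DegreeGrid(
        k_min=k_min, k_max=k_max, degrees=degrees,
        increment=inc, n_nulls=n_nulls, edge_counts=edge_counts,
    )


def verify_regime(
    z_mats: dict | list,
    grid: DegreeGrid,
    seed: int | None = 0,
    n_nulls: int | None = None,
) -> pd.DataFrame:
    """Re-check both regime conditions at every grid point for every network.

    Returns one row per (network, degree) with connectedness and mean sigma;
    the regime promise holds iff all rows are connected with sigma > 1.
    """
    n_nulls = n_nulls or grid.n_nulls
    if isinstance(z_mats, dict):
        items = list(z_mats.items())
    else:
        items = list(enumerate(z_mats))
    rows = []
    root = np.random.SeedSequence(seed)
    for (key, z), child in zip(items, root.spawn(len(items))):
        for k, sub in zip(grid.degrees, child.spawn(len(grid.degrees))):
            adj = threshold_to_degree(z, k)
            conn = is_connected(adj)
            sigma = np.nan
            if conn:
                ens = small_worldness(
                    adj, n_nulls=n_nulls, seed=np.random.default_rng(sub)
                )
                sigma = ens.sigma
            rows.append({"network": key, "degree": k,
                         "connected": conn, "sigma": sigma})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# metric table
# --------------------------------------------------------------------------

def compute_metric_table(
    z_by_key: dict[tuple, np.ndarray],
    grid: DegreeGrid,
    subject_info: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Long-form measures at every observation degree plus per-subject averages.

    ``z_by_key`` maps (subject, load) to a connectivity matrix;
    ``subject_info`` maps subject to {"group": ..., "site": ...}.  Output
    columns: subject, group, site, load, observation (1..grid_size or
    "avg"), degree, measure, value.
    """
    rows = []
    for (subject, load), z in z_by_key.items():
        info = (subject_info or {}).get(subject, {})
        group = info.get("group", "NA")
        site = info.get("site", "NA")
        acc = {m: [] for m in MEASURES}
        for obs, k in enumerate(grid.degrees, start=1):
            adj = threshold_to_degree(z, k)
            if not is_connected(adj):
                raise ValueError(
                    f"network (subject={subject}, load={load}) disconnected "
                    f"at grid degree {k}: regime guarantee violated"
                )
            m = network_metrics(adj)
            vals = {"C_net": m.c_net, "L_net": m.l_net,
                    "E_local": m.e_local, "E_global": m.e_global}
            for meas, v in vals.items():
                acc[meas].append(v)
                rows.append({
                    "subject": subject, "group": group, "site": site,
                    "load": load, "observation": obs, "degree": k,
                    "measure": meas, "value": v,
                })
        for meas in MEASURES:
            rows.append({
                "subject": subject, "group": group, "site": site,
                "load": load, "observation": "avg", "degree": np.nan,
                "measure": meas, "value": float(np.mean(acc[meas])),
            })
    return pd.DataFrame(rows)
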