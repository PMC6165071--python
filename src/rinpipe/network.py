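"""Residue interaction networks with correlation-weighted edges.

The analysis chain implemented here is the package's core computation:

1. **Dynamical cross-correlation** of residue motions,
   C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>), on a per-residue
   basis atom (C-alpha by default).
2. **Contact network**: residues are nodes; the interaction strength of a
   residue pair is I_ij = 100 * n_ij / sqrt(N_i N_j), where n_ij counts
   heavy-atom pairs (one atom from each residue) within a cutoff
   (default 4.5 A, sequence neighbours |i-j| <= 1 excluded) and N_i is a
   per-residue-type normalisation (by default the maximum n_ij observed
   for that residue type in the input).  An edge is drawn iff
   I_ij >= I_min (default 2.5%).
3. **Correlation-derived edge weights**: w_ij = -ln|C_ij|; edges whose
   motion is insufficiently correlated (|C_ij| below a floor, default
   0.5) are removed from the path graph.  At the floor, w = -ln 0.5 =
   0.69.
4. **Floyd-Warshall** all-pairs shortest paths on the weighted graph,
   counting every distinct minimal-weight path (float ties compared with
   a 1e-9 tolerance).
5. **Centralities**: degree (retained-edge count; a node is a *hub* if
   degree >= 4), normalized betweenness
   C_b(n_i) = [sum_{j<k, j != i != k} g_jk(i)/g_jk] / ((N-1)(N-2)),
   and closeness within each connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import Ensemble

__all__ = [
    "CorrelationMatrix",
    "InteractionNetwork",
    "PathMatrix",
    "CentralityProfile",
    "cross_correlation",
    "contact_network",
    "weight_edges",
    "edge_weight",
    "floyd_warshall",
    "betweenness",
    "degree_and_hubs",
    "centrality_histogram",
    "to_networkx",
]

TIE_TOL = 1e-9


@dataclass
class CorrelationMatrix:
    """Symmetric per-residue cross-correlation matrix, C_ij in [-1, 1]."""

    matrix: np.ndarray
    resids: np.ndarray
    basis: str = "CA"

    def __post_init__(self) -> None:
        c = np.asarray(self.matrix, dtype=float)
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.isfinite(c).all():
            raise ValueError("correlation matrix must be finite")
        self.matrix = c


@dataclass
class InteractionNetwork:
    """Residue nodes plus contact edges with interaction strengths.

    ``edges`` columns: i, j (node indices), resid_i, resid_j, n_ij, i_ij;
    after :func:`weight_edges` also c_ij, w_ij, in_path_graph.
    """

    resids: np.ndarray
    edges: pd.DataFrame
    i_min: float
    contact_cutoff: float
    c_floor: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.resids)


@dataclass
class PathMatrix:
    """All-pairs shortest-path lengths and tie-aware path counts."""

    dist: np.ndarray  # (n, n) path lengths; +inf when disconnected
    counts: np.ndarray  # (n, n) number of distinct shortest paths
    resids: np.ndarray


@dataclass
class CentralityProfile:
    """Per-residue degree, betweenness, closeness and hub flags."""

    table: pd.DataFrame  # resid, degree, betweenness_raw, betweenness,
    #                      closeness, hub
    hub_min: int = 4


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def cross_correlation(ens: Ensemble, basis: str = "CA") -> CorrelationMatrix:
    """Dynamical cross-correlation of basis-atom displacements.

    The ensemble must already be superposed; deviations are taken from
    the time-mean position of each residue's basis atom.  A residue with
    zero variance (static) gets zero off-diagonal correlation and a
    warning.
    """
    if ens.n_frames < 2:
        raise ValueError("cross-correlation needs at least 2 frames")
    top = ens.topology
    idx, resids = [], []
    for k, (_chain, resid, _resname) in enumerate(top.residues):
        hits = [
            i for i in top.atoms_of_residue(k) if top.atoms[i].name == basis
        ]
        if hits:
            idx.append(hits[0])
            resids.append(resid)
    xyz = ens.coords[:, idx]  # (F, m, 3)
    dev = xyz - xyz.mean(axis=0)
    inner = np.einsum("fid,fjd->ij", dev, dev) / ens.n_frames
    var = np.diag(inner).copy()
    static = var <= 0
    if static.any():
        warnings.warn(
            f"{static.sum()} static residue(s); correlation set to 0",
            stacklevel=2,
        )
        var[static] = 1.0
    c = inner / np.sqrt(np.outer(var, var))
    c[static, :] = 0.0
    c[:, static] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return CorrelationMatrix(c, np.array(resids), basis)


# ---------------------------------------------------------------------------
# contact network (interaction strength I_ij)
# ---------------------------------------------------------------------------

def contact_network(
    ens: Ensemble,
    frame: int = 0,
    contact_cutoff: float = 4.5,
    i_min: float = 2.5,
    exclude_neighbors: int = 1,
    norm_table: dict[str, float] | None = None,
) -> InteractionNetwork:
    """Residue interaction network of one structure (frame of an ensemble).

    n_ij counts heavy-atom pairs within the cutoff; residue pairs within
    ``exclude_neighbors`` positions on the same chain are skipped.
    Normalisation factors N_i are per residue *type*: either supplied via
    ``norm_table`` (resname -> N) or derived from the input as the
    maximum n_ij observed for that type.  I_ij = 100 n_ij / sqrt(N_i N_j);
    an edge is retained iff I_ij >= i_min.
    """
    top = ens.topology
    if top.n_atoms == 0:
        raise ValueError("empty structure")
    heavy = np.array([a.element != "H" for a in top.atoms])
    if not heavy.any():
        raise ValueError("no heavy atoms present")
    xyz = ens.coords[frame][heavy]
    ridx = top.residue_index[heavy]
    n_res = top.n_residues
    resids = np.array([r[1] for r in top.residues])
    chains = np.array([r[0] for r in top.residues])
    resnames = [r[2] for r in top.residues]

    dists = cdist(xyz, xyz)
    close = dists <= contact_cutoff
    # accumulate heavy-atom pair counts per residue pair
    n_ij = np.zeros((n_res, n_res), dtype=int)
    ii, jj = np.nonzero(close)
    mask = ii < jj
    np.add.at(n_ij, (ridx[ii[mask]], ridx[jj[mask]]), 1)
    n_ij = n_ij + n_ij.T
    # drop self and sequence-neighbour pairs
    for a in range(n_res):
        for b in range(max(0, a - exclude_neighbors), min(n_res, a + exclude_neighbors + 1)):
            if chains[a] == chains[b]:
                n_ij[a, b] = 0

    if norm_table is None:
        norm: dict[str, float] = {}
        for a in range(n_res):
            m = n_ij[a].max() if n_res > 1 else 0
            name = resnames[a]
            norm[name] = max(norm.get(name, 0), m)
    else:
        norm = dict(norm_table)

    rows = []
    for a in range(n_res):
        na = norm.get(resnames[a], 0)
        if na <= 0:
            continue
        for b in range(a + 1, n_res):
            if n_ij[a, b] == 0:
                continue
            nb = norm.get(resnames[b], 0)
            if nb <= 0:
                continue
            strength = 100.0 * n_ij[a, b] / np.sqrt(na * nb)
            if strength >= i_min:
                rows.append(
                    {
                        "i": a,
                        "j": b,
                        "resid_i": int(resids[a]),
                        "resid_j": int(resids[b]),
                        "n_ij": int(n_ij[a, b]),
                        "i_ij": strength,
                    }
                )
    edges = pd.DataFrame(
        rows, columns=["i", "j", "resid_i", "resid_j", "n_ij", "i_ij"]
    )
    return InteractionNetwork(resids, edges, i_min, contact_cutoff)


# ---------------------------------------------------------------------------
# correlation-derived edge weights
# ---------------------------------------------------------------------------

def edge_weight(c: float) -> float:
    """Path weight of an edge with correlation c: w = -ln|c|."""
    a = abs(float(c))
    if a == 0:
        return np.inf
    return -float(np.log(a))


def weight_edges(
    net: InteractionNetwork,
    corr: CorrelationMatrix,
    c_floor: float = 0.5,
) -> InteractionNetwork:
    """Attach w_ij = -ln|C_ij| to each edge; filter the path graph.

    Edges with |C_ij| < c_floor stay in the contact network (they still
    count for degree) but are excluded from shortest-path computation.
    """
    if len(net.resids) != len(corr.resids) or np.any(
        net.resids != corr.resids
    ):
        raise ValueError("network and correlation matrix residue sets differ")
    edges = net.edges.copy()
    c_vals = np.array(
        [corr.matrix[int(r.i), int(r.j)] for r in edges.itertuples()]
    ) if len(edges) else np.empty(0)
    edges["c_ij"] = c_vals
    edges["w_ij"] = [edge_weight(c) if abs(c) >= c_floor else np.nan for c in c_vals]
    edges["in_path_graph"] = np.abs(c_vals) >= c_floor
    return InteractionNetwork(
        net.resids, edges, net.i_min, net.contact_cutoff, c_floor
    )


# ---------------------------------------------------------------------------
# shortest paths and centralities
# ---------------------------------------------------------------------------

def _adjacency(net: InteractionNetwork) -> np.ndarray:
    n = net.n_nodes
    w = np.full((n, n), np.inf)
    edges = net.edges
    if "in_path_graph" in edges.columns:
        edges = edges[edges["in_path_graph"].to_numpy(dtype=bool)]
        weights = edges["w_ij"].to_numpy(dtype=float)
    else:
        weights = np.ones(len(edges))  # unweighted contact graph
    for (i, j), wij in zip(edges[["i", "j"]].to_numpy(dtype=int), weights):
        w[i, j] = min(w[i, j], wij)
        w[j, i] = w[i, j]
    return w


def floyd_warshall(net: InteractionNetwork) -> PathMatrix:
    """All-pairs shortest paths with tie-aware path counting.

    Path length is the sum of edge weights; every distinct minimal-weight
    path is counted, with float ties compared at a 1e-9 tolerance.
    Disconnected pairs get distance +inf and count 0.
    """
    w = _adjacency(net)
    finite = w[np.isfinite(w)]
    if finite.size and finite.min() < 0:
        raise ValueError("negative edge weights are not allowed")
    n = net.n_nodes
    dist = w.copy()
    np.fill_diagonal(dist, 0.0)
    counts = np.where(np.isfinite(w), 1.0, 0.0)
    np.fill_diagonal(counts, 1.0)
    for k in range(n):
        alt = dist[:, k][:, None] + dist[k, :][None, :]
        with np.errstate(invalid="ignore"):
            closer = alt < dist - TIE_TOL
            equal = np.isfinite(alt) & (np.abs(alt - dist) <= TIE_TOL)
        # k cannot be an interior node of a path starting or ending at k,
        # and the trivial i == j path never updates
        closer[k, :] = closer[:, k] = False
        equal[k, :] = equal[:, k] = False
        np.fill_diagonal(closer, False)
        np.fill_diagonal(equal, False)
        via = counts[:, k][:, None] * counts[k, :][None, :]
        counts = np.where(closer, via, counts + np.where(equal, via, 0.0))
        dist = np.where(closer, alt, dist)
    return PathMatrix(dist, counts, net.resids.copy())


def betweenness(paths: PathMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalized betweenness per node.

    Raw: C_b(n_i) = sum_{j<k, j != i != k} g_jk(i)/g_jk, where g_jk is
    the number of shortest j-k paths and g_jk(i) those passing through i.
    Normalized: raw / ((N-1)(N-2)).  Pairs with no path contribute 0.
    """
    d, sigma = paths.dist, paths.counts
    n = d.shape[0]
    raw = np.zeros(n)
    if n < 3:
        return raw, raw.copy()
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    for i in range(n):
        with np.errstate(invalid="ignore"):
            through = (
                np.isfinite(d[:, i][:, None])
                & np.isfinite(d[i, :][None, :])
                & (np.abs(d[:, i][:, None] + d[i, :][None, :] - d) <= TIE_TOL)
            )
        g_i = sigma[:, i][:, None] * sigma[i, :][None, :]
        valid = upper & through & (sigma > 0)
        valid[i, :] = valid[:, i] = False
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(valid, g_i / np.where(sigma > 0, sigma, 1.0), 0.0)
        raw[i] = frac.sum()
    norm = raw / ((n - 1) * (n - 2))
    return raw, norm


def degree_and_hubs(
    net: InteractionNetwork,
    hub_min: int = 4,
    paths: PathMatrix | None = None,
) -> CentralityProfile:
    """Degree, hub flags and (given a path matrix) betweenness/closeness.

    Degree counts all retained contact edges (Eq.-style adjacency);
    a node is a hub iff degree >= hub_min.  Closeness is computed within
    each connected component as (m - 1) / sum of distances to the m - 1
    reachable nodes.
    """
    n = net.n_nodes
    degree = np.zeros(n, dtype=int)
    for i, j in net.edges[["i", "j"]].to_numpy(dtype=int):
        degree[i] += 1
        degree[j] += 1
    table = pd.DataFrame(
        {
            "resid": net.resids,
            "degree": degree,
            "hub": degree >= hub_min,
        }
    )
    if paths is not None:
        raw, norm = betweenness(paths)
        closeness = np.zeros(n)
        for i in range(n):
            reach = np.isfinite(paths.dist[i]) & (np.arange(n) != i)
            total = paths.dist[i, reach].sum()
            closeness[i] = reach.sum() / total if total > 0 else 0.0
        table["betweenness_raw"] = raw
        table["betweenness"] = norm
        table["closeness"] = closeness
    return CentralityProfile(table, hub_min)


def centrality_histogram(
    values: np.ndarray, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width frequency histogram over [min, max].

    Frequencies sum to the number of nodes; identical values collapse to
    a single bin.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to bin")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return np.array([lo, hi]), np.array([values.size])
    freq, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return edges, freq


def to_networkx(net: InteractionNetwork, path_graph: bool = False):
    """Export as a networkx Graph (nodes keyed by index, resid attribute)."""
    import networkx as nx

    g = nx.Graph()
    for i, resid in enumerate(net.resids):
        g.add_node(i, resid=int(resid))
    edges = net.edges
    if path_graph and "in_path_graph" in edges.columns:
        edges = edges[edges["in_path_graph"]]
    for r in edges.itertuples():
        attrs = {"n_ij": int(r.n_ij), "i_ij": float(r.i_ij)}
        if hasattr(r, "w_ij") and np.isfinite(getattr(r, "w_ij", np.nan)):
            attrs["weight"] = float(r.w_ij)
            attrs["c_ij"] = float(r.c_ij)
        g.add_edge(int(r.i), int(r.j), **attrs)
    return g
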