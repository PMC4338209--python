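"""Auto-Contractive Map (Auto-CM) semantic connectivity maps.

The Auto-CM is a three-layer contractive network (input → hidden → output of
equal width N) whose trained hidden→output weight matrix is read as a
many-to-many association strength between variables.  Training contracts the
signal twice:

    hidden   h_i = x_i · (1 − v_i / C)
    net      n_i = (1/N) · Σ_j W_ij · h_j
    output   o_i = h_i · (1 − n_i / C)

with multiplicatively gated updates, applied record by record (both deltas
computed from the pre-update state, then applied together):

    Δv_i  = α · (x_i − h_i) · (1 − v_i / C)
    ΔW_ij = α · (h_i − o_i) · (1 − W_ij / C) · h_j

C is the contraction constant (default: the number of encoded variables);
all weights live in [0, C] (clipped).  The mono-connections v saturate
towards C, the hidden signal decays to zero, and W freezes having absorbed
the co-activation structure of the data — training stops when the mean
absolute update drops below tolerance.

The 1/N factor in the net input keeps n_i ≤ max_j W_ij ≤ C, so both
contraction factors stay in [0, 1].

Weights are initialised to a small positive constant (C·1e-3, no randomness):
the update rules have v = W = 0 as a fixed point for *any* input, so an
exactly-zero start would never train, while a deterministic positive seed
value keeps the whole map reproducible bit for bit.

Downstream, symmetrized weights become link strengths s = W̄/C ∈ [0, 1],
distances d = 1 − s, and a minimum spanning tree over d gives the semantic
connectivity map.  Each input variable contributes two nodes: itself scaled
to [0, 1] ("high") and its complement ("low").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Deterministic initial weight value, as a fraction of C.
INIT_WEIGHT_FRACTION = 1e-3


@dataclass
class AutoCMModel:
    n_vars: int
    C: float
    v: np.ndarray  # (N,) input→hidden mono-connections
    W: np.ndarray  # (N, N) hidden→output connections
    epochs_run: int
    converged: bool
    mean_delta_history: list[float] = field(default_factory=list)


@dataclass
class ConnectivityMap:
    node_names: list[str]
    strengths: np.ndarray  # (N, N) in [0, 1], diagonal 1
    distances: np.ndarray  # (N, N), 1 − strengths, diagonal 0
    mst_edges: list[tuple[str, str, float]] = field(default_factory=list)


def minmax_scale(column: Sequence[float]) -> np.ndarray:
    """Scale a column to [0, 1]; missing values stay missing.

    A constant column has no range: every entry maps to 0.5 with a warning.
    """
    x = np.asarray(column, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to scale")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        warnings.warn("constant column: scaled to 0.5 everywhere", stacklevel=2)
        out = np.full_like(x, 0.5)
        out[~np.isfinite(x)] = np.nan
        return out
    return (x - lo) / (hi - lo)


def high_low_encode(scaled: pd.DataFrame) -> pd.DataFrame:
    """Complement-encode K scaled variables into 2K columns.

    Each variable X in [0, 1] yields "X high" = x and "X low" = 1 − x, so the
    map can distinguish associations of elevated values from associations of
    depressed ones.  Missing values propagate to both columns.
    """
    vals = scaled.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("high/low encoding requires values in [0, 1]")
    out = {}
    for col in scaled.columns:
        out[f"{col} high"] = scaled[col].astype(float)
        out[f"{col} low"] = 1.0 - scaled[col].astype(float)
    return pd.DataFrame(out, index=scaled.index)


def train_autocm(
    records: np.ndarray | pd.DataFrame,
    C: float | None = None,
    learning_rate: float = 0.1,
    tolerance: float = 1e-6,
    max_epochs: int = 5000,
    batch: bool = False,
) -> AutoCMModel:
    """Train an Auto-CM on an M×N table of values in [0, 1].

    Fully deterministic: constant initialisation, fixed record order, no
    randomness.  ``batch=True`` accumulates the per-record updates over an
    epoch before applying them (the online, per-record form is the default).
    """
    X = np.asarray(records, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 2:
        raise ValueError("records must be an M×N array with M ≥ 1, N ≥ 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("records contain missing values; impute or drop rows upstream")
    if X.min() < 0 or X.max() > 1:
        raise ValueError("records must be scaled to [0, 1]")
    M, N = X.shape
    if C is None:
        C = float(N)
    if C <= 0:
        raise ValueError("contraction constant C must be positive")
    alpha = learning_rate

    v = np.full(N, C * INIT_WEIGHT_FRACTION)
    W = np.full((N, N), C * INIT_WEIGHT_FRACTION)
    history: list[float] = []
    converged = False
    epochs = 0
    for epoch in range(max_epochs):
        delta_sum = 0.0
        if batch:
            dv_acc = np.zeros(N)
            dW_acc = np.zeros((N, N))
        for x in X:
            h = x * (1.0 - v / C)
            net = (W @ h) / N
            o = h * (1.0 - net / C)
            dv = alpha * (x - h) * (1.0 - v / C)
            dW = alpha * ((h - o)[:, None] * (1.0 - W / C)) * h[None, :]
            delta_sum += np.abs(dv).sum() + np.abs(dW).sum()
            if batch:
                dv_acc += dv
                dW_acc += dW
            else:
                v = np.clip(v + dv, 0.0, C)
                W = np.clip(W + dW, 0.0, C)
        if batch:
            v = np.clip(v + dv_acc, 0.0, C)
            W = np.clip(W + dW_acc, 0.0, C)
        mean_delta = delta_sum / (M * (N + N * N))
        history.append(mean_delta)
        epochs = epoch + 1
        if mean_delta < tolerance:
            converged = True
            break
    return AutoCMModel(
        n_vars=N, C=C, v=v, W=W, epochs_run=epochs, converged=converged,
        mean_delta_history=history,
    )


def weights_to_distances(model: AutoCMModel, node_names: Sequence[str] | None = None) -> ConnectivityMap:
    """Symmetrize trained weights into 0–1 link strengths and distances.

    s = W̄/C with W̄ = (W + Wᵀ)/2; d = 1 − s; the diagonal is forced to
    s = 1, d = 0 (a variable is maximally associated with itself).
    """
    if model.epochs_run < 1:
        raise ValueError("model has not been trained")
    if node_names is None:
        node_names = [f"var{i}" for i in range(model.n_vars)]
    if len(node_names) != model.n_vars:
        raise ValueError("node_names length must match the number of variables")
    w_bar = (model.W + model.W.T) / 2.0
    strengths = np.clip(w_bar / model.C, 0.0, 1.0)
    np.fill_diagonal(strengths, 1.0)
    distances = 1.0 - strengths
    np.fill_diagonal(distances, 0.0)
    return ConnectivityMap(
        node_names=list(node_names), strengths=strengths, distances=distances
    )


def mst(distances: np.ndarray, node_names: Sequence[str] | None = None) -> list[tuple[int, int, float]]:
    """Minimum spanning tree of a symmetric distance matrix (Kruskal).

    Returns N−1 edges as (i, j, distance) with i < j.  Ties are broken by
    lexicographic node-pair order: by the sorted pair of node names when
    names are given, by index pair otherwise — deterministic across runs.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    if node_names is not None and len(node_names) != n:
        raise ValueError("node_names length must match matrix size")

    def tiebreak(i: int, j: int):
        if node_names is None:
            return (i, j)
        return tuple(sorted((node_names[i], node_names[j])))

    edges = sorted(
        ((d[i, j], tiebreak(i, j), i, j) for i, j in itertools.combinations(range(n), 2)),
        key=lambda e: (e[0], e[1]),
    )
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree: list[tuple[int, int, float]] = []
    for w, _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j, float(w)))
            if len(tree) == n - 1:
                break
    return tree


def build_connectivity_map(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    C: float | None = None,
    learning_rate: float = 0.1,
    tolerance: float = 1e-6,
    max_epochs: int = 5000,
    impute_mean: bool = False,
) -> ConnectivityMap:
    """Full pipeline: scale → high/low encode → train → distances → MST.

    Rows with any missing selected variable are dropped (or mean-imputed on
    the scaled values when ``impute_mean``); needs at least 2 usable rows.
    """
    missing = [v for v in variables if v not in cohort.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled = pd.DataFrame(
            {v: minmax_scale(cohort[v].to_numpy(dtype=float)) for v in variables},
            index=cohort.index,
        )
    if impute_mean:
        scaled = scaled.fillna(scaled.mean())
    else:
        n_before = len(scaled)
        scaled = scaled.dropna()
        dropped = n_before - len(scaled)
        if dropped:
            warnings.warn(f"dropped {dropped} rows with missing variables", stacklevel=2)
    if len(scaled) < 2:
        raise ValueError("fewer than 2 usable rows after missing-data handling")
    encoded = high_low_encode(scaled)
    model = train_autocm(
        encoded.to_numpy(), C=C, learning_rate=learning_rate,
        tolerance=tolerance, max_epochs=max_epochs,
    )
    cmap = weights_to_distances(model, node_names=list(encoded.columns))
    tree = mst(cmap.distances, node_names=cmap.node_names)
    cmap.mst_edges = [
        (cmap.node_names[i], cmap.node_names[j], float(cmap.strengths[i, j]))
        for i, j, _ in tree
    ]
    return cmap


def to_networkx(cmap: ConnectivityMap) -> nx.Graph:
    """MST as a networkx graph; node attribute 'form' ∈ {high, low}, edge 'strength'."""
    g = nx.Graph()
    for name in cmap.node_names:
        form = "high" if name.endswith(" high") else "low"
        g.add_node(name, form=form)
    for a, b, s in cmap.mst_edges:
        g.add_edge(a, b, strength=round(float(s), 6))
    return g


def export_graphml(cmap: ConnectivityMap, path: str) -> None:
    nx.write_graphml(to_networkx(cmap), path)


def export_dot(cmap: ConnectivityMap, path: str) -> None:
    """Minimal DOT emitter (undirected graph, strengths as edge labels)."""
    lines = ["graph connectivity_map {"]
    for name in cmap.node_names:
        form = "high" if name.endswith(" high") else "low"
        lines.append(f'  "{name}" [form="{form}"];')
    for a, b, s in cmap.mst_edges:
        lines.append(f'  "{a}" -- "{b}" [label="{s:.2f}", strength="{s:.6f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def edges_frame(cmap: ConnectivityMap) -> pd.DataFrame:
    """MST edge list as a table (node_a, node_b, strength)."""
    return pd.DataFrame(cmap.mst_edges, columns=["node_a", "node_b", "strength"])
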