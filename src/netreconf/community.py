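"""Multilayer modularity maximization with a Louvain-like greedy optimizer.

A connectivity series is treated as an ordered stack of network layers
(one per time window).  The quality of a node-layer community assignment
``g`` is the multilayer modularity

    Q = (1/2mu) * sum_{ijs} [A_ijs - gamma * k_is k_js / (2 m_s)] d(g_is, g_js)
      + (1/2mu) * 2 * omega * sum_{is} d(g_is, g_i(s+1))

with the Newman-Girvan configuration null inside each layer (scaled by the
structural resolution gamma), ordinal interlayer coupling omega between a
node's copies in adjacent layers, and 2mu the total intra- plus interlayer
weight.  Edge weights must be nonnegative, so negative connectivity values
(the debiased estimator admits them) are clipped to zero when the network
is built; the clipped count is recorded.

The optimizer is the standard two-phase greedy scheme: sweep node-layer
tuples in seeded random order moving each to the community with maximal
strictly positive modularity gain, then aggregate communities into
super-nodes and repeat.  Because visitation order makes the algorithm
nondeterministic, partitions are estimated as seeded ensembles and reduced
to a consensus: the medoid member under mean pairwise z-scored Rand
similarity (ties broken by higher Q, then lowest seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .connectivity import ConnectivitySeries
from .exceptions import DegenerateLayerError, InvalidConfigError

__all__ = [
    "ModularityParams",
    "MultilayerNetwork",
    "MultilayerPartition",
    "PartitionEnsemble",
    "build_multilayer",
    "louvain_multilayer",
    "partition_ensemble",
    "consensus_partition",
    "static_communities",
    "canonical_labels",
    "zrand",
    "match_labels",
    "MultilayerLouvain",
]


@dataclass(frozen=True)
class ModularityParams:
    """Resolution parameters of the multilayer quality function.

    The defaults are the reference operating point (gamma = 1.025,
    omega = 9) documented for use when no scale sweep is run.
    """

    gamma: float = 1.025
    omega: float = 9.0

    def __post_init__(self):
        if not self.gamma > 0:
            raise InvalidConfigError("gamma must be > 0")
        if self.omega < 0:
            raise InvalidConfigError("omega must be >= 0")


class MultilayerNetwork:
    """Layer stack with per-layer strengths and the multilayer normalization.

    Attributes
    ----------
    layers : (L, N, N) nonnegative symmetric matrices, zero diagonal
    strengths : (L, N) per-layer node strengths k_is
    layer_weight : (L,) per-layer totals 2 m_s
    two_mu : total intra- plus interlayer weight 2 mu
    n_clipped : number of negative entries clipped to zero at build time
    """

    def __init__(self, layers: np.ndarray, gamma: float, omega: float,
                 n_clipped: int = 0):
        layers = np.asarray(layers, dtype=float)
        if layers.ndim != 3 or layers.shape[1] != layers.shape[2]:
            raise InvalidConfigError("layers must have shape (L, N, N)")
        if layers.shape[1] < 2:
            raise InvalidConfigError("need at least 2 nodes")
        self.layers = layers
        self.gamma = float(gamma)
        self.omega = float(omega)
        self.n_clipped = int(n_clipped)
        self.strengths = layers.sum(axis=2)  # (L, N)
        self.layer_weight = self.strengths.sum(axis=1)  # (L,) == 2 m_s
        if np.any(self.layer_weight <= 0):
            bad = int(np.flatnonzero(self.layer_weight <= 0)[0])
            raise DegenerateLayerError(
                f"layer {bad} has zero total weight; the configuration null "
                "is undefined"
            )
        n, L = layers.shape[1], layers.shape[0]
        self.two_mu = float(self.layer_weight.sum() + 2.0 * omega * n * (L - 1))

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]

    def modularity_matrix(self) -> np.ndarray:
        """Dense supra-modularity matrix over node-layer tuples.

        Tuple (i, s) maps to flat index s*N + i.  Block diagonal holds
        A_s - gamma k k^T / (2 m_s); off-diagonal identity blocks between
        adjacent layers hold omega.
        """
        L, n = self.n_layers, self.n_nodes
        b = np.zeros((L * n, L * n))
        for s in range(L):
            k = self.strengths[s]
            blk = self.layers[s] - self.gamma * np.outer(k, k) / self.layer_weight[s]
            b[s * n : (s + 1) * n, s * n : (s + 1) * n] = blk
        if self.omega > 0:
            idx = np.arange((L - 1) * n)
            b[idx, idx + n] += self.omega
            b[idx + n, idx] += self.omega
        return b

    def q(self, labels: np.ndarray) -> float:
        """Multilayer modularity of a (L, N) label assignment.

        Computed directly from the definition (community-wise sums), not
        via the optimizer's internal bookkeeping.
        """
        labels = np.asarray(labels)
        if labels.shape != (self.n_layers, self.n_nodes):
            raise InvalidConfigError(
                f"labels must have shape {(self.n_layers, self.n_nodes)}"
            )
        total = 0.0
        for s in range(self.n_layers):
            g = labels[s]
            k = self.strengths[s]
            for lab in np.unique(g):
                members = g == lab
                a_within = self.layers[s][np.ix_(members, members)].sum()
                k_within = k[members].sum()
                total += a_within - self.gamma * k_within**2 / self.layer_weight[s]
        if self.omega > 0 and self.n_layers > 1:
            persist = (labels[:-1] == labels[1:]).sum()
            total += 2.0 * self.omega * persist
        return total / self.two_mu


@dataclass
class MultilayerPartition:
    """An (L, N) community assignment with its quality value and seed."""

    labels: np.ndarray
    q: float
    seed: int | None = None

    @property
    def n_layers(self) -> int:
        return self.labels.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[1]

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))


def build_multilayer(conn, params: ModularityParams) -> MultilayerNetwork:
    """Build the multilayer modularity problem from a connectivity series
    (or a raw (L, N, N) stack).  Negative edge weights are clipped to zero
    — the configuration null assumes nonnegative weights — and the clipped
    count is kept on the network."""
    layers = conn.layers if isinstance(conn, ConnectivitySeries) else np.asarray(conn, float)
    layers = np.array(layers, dtype=float, copy=True)
    for s in range(layers.shape[0]):
        np.fill_diagonal(layers[s], 0.0)
    layers = 0.5 * (layers + np.swapaxes(layers, 1, 2))
    neg = layers < 0
    n_clipped = int(neg.sum()) // 2  # symmetric pairs
    layers[neg] = 0.0
    return MultilayerNetwork(layers, params.gamma, params.omega, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# generalized Louvain on a dense (supra-)modularity matrix


def _phase1(b: np.ndarray, rng: np.random.Generator, tol: float):
    """Greedy node sweeps.  Returns (labels, any_move)."""
    n = b.shape[0]
    labels = np.arange(n)
    sizes = np.ones(n, dtype=int)
    diag = np.diag(b).copy()
    any_move = False
    for _ in range(1000):
        moved = False
        for u in rng.permutation(n):
            c_old = labels[u]
            comm_w = np.bincount(labels, weights=b[u], minlength=n)
            base = comm_w[c_old] - diag[u]  # links to own community, self excluded
            comm_w[c_old] = base
            c_new = int(np.argmax(comm_w))
            best = comm_w[c_new]
            if c_new != c_old and best > base + tol:
                labels[u] = c_new
                sizes[c_old] -= 1
                sizes[c_new] += 1
                moved = any_move = True
            elif base < -tol and best <= tol:
                # every community (incl. its own) repels the node: isolate it
                free = int(np.flatnonzero(sizes == 0)[0])
                labels[u] = free
                sizes[c_old] -= 1
                sizes[free] += 1
                moved = any_move = True
        if not moved:
            break
    return labels, any_move


def _aggregate(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Collapse communities into super-nodes: B' = S^T B S."""
    k = labels.max() + 1
    rows = np.zeros((k, b.shape[0]))
    np.add.at(rows, labels, b)
    out = np.zeros((k, k))
    np.add.at(out, labels, rows.T)
    return out


def _generalized_louvain(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two-phase greedy maximization of sum_{g_u = g_v} B_uv.

    Returns flat labels (first-occurrence canonical, 0-based).
    """
    scale = np.abs(b).max()
    tol = 1e-12 * max(scale, 1.0)
    mapping = np.arange(b.shape[0])
    current = b
    while True:
        labels, any_move = _phase1(current, rng, tol)
        uniq, compact = np.unique(labels, return_inverse=True)
        mapping = compact[mapping]
        if not any_move or len(uniq) == current.shape[0]:
            break
        current = _aggregate(current, compact)
    return canonical_labels(mapping)


def canonical_labels(flat: np.ndarray) -> np.ndarray:
    """Relabel communities by first occurrence, starting at 1."""
    flat = np.asarray(flat).ravel()
    _, first = np.unique(flat, return_index=True)
    order = {flat[i]: rank + 1 for rank, i in enumerate(sorted(first))}
    return np.array([order[v] for v in flat], dtype=int)


def louvain_multilayer(net: MultilayerNetwork, seed: int = 0) -> MultilayerPartition:
    """One seeded run of the greedy optimizer.  Deterministic given seed."""
    rng = np.random.default_rng(seed)
    b = net.modularity_matrix()
    flat = _generalized_louvain(b, rng)
    labels = flat.reshape(net.n_layers, net.n_nodes)
    return MultilayerPartition(labels=labels, q=net.q(labels), seed=seed)


@dataclass
class PartitionEnsemble:
    """Seeded repeated runs plus their pairwise identity agreement."""

    partitions: list
    agreement: float

    def __len__(self):
        return len(self.partitions)


def partition_ensemble(
    net: MultilayerNetwork, n_iter: int = 100, base_seed: int = 0
) -> PartitionEnsemble:
    """``n_iter`` independent optimizer runs with seeds base_seed + k.

    ``agreement`` is the fraction of run pairs whose partitions are
    identical up to relabeling (1.0 by convention for a single run).
    """
    if n_iter < 1:
        raise InvalidConfigError("n_iter must be >= 1")
    parts = [louvain_multilayer(net, seed=base_seed + k) for k in range(n_iter)]
    if n_iter == 1:
        return PartitionEnsemble(partitions=parts, agreement=1.0)
    keys = [canonical_labels(p.labels.ravel()).tobytes() for p in parts]
    counts: dict[bytes, int] = {}
    for key in keys:
        counts[key] = counts.get(key, 0) + 1
    same = sum(c * (c - 1) // 2 for c in counts.values())
    agreement = same / (n_iter * (n_iter - 1) // 2)
    return PartitionEnsemble(partitions=parts, agreement=agreement)


# ---------------------------------------------------------------------------
# partition similarity and consensus


def _pair_counts(labels: np.ndarray) -> tuple[float, np.ndarray]:
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1) // 2).sum()), counts


def zrand(labels_a, labels_b) -> float:
    """z-scored Rand similarity of two labelings of the same elements.

    Standardizes the count of element pairs co-assigned in both labelings
    against its permutation null (fixed community sizes).  Degenerate
    labelings with zero null variance return 0.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise InvalidConfigError("labelings must cover the same elements")
    n = len(a)
    if n < 4:
        raise InvalidConfigError("z-Rand needs at least 4 elements")
    big_m = n * (n - 1) / 2.0
    m1, counts_a = _pair_counts(a)
    m2, counts_b = _pair_counts(b)
    # pairs together in both: via the contingency table
    pair_codes = a.astype(np.int64) * (b.max() + 1) + b
    _, nij = np.unique(pair_codes, return_counts=True)
    w = float((nij * (nij - 1) // 2).sum())

    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m1 + 4 * float((counts_a**3).sum())
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m2 + 4 * float((counts_b**3).sum())
    a1 = 4 * m1 - 2 * big_m
    a2 = 4 * m2 - 2 * big_m
    var = (
        big_m / 16.0
        - (a1**2) * (a2**2) / (256.0 * big_m**2)
        + c1 * c2 / (16.0 * n * (n - 1) * (n - 2))
        + ((a1**2 - 4 * c1 - 4 * big_m) * (a2**2 - 4 * c2 - 4 * big_m))
        / (64.0 * n * (n - 1) * (n - 2) * (n - 3))
    )
    if var <= 0:
        return 0.0
    return (w - m1 * m2 / big_m) / np.sqrt(var)


def consensus_partition(ens: PartitionEnsemble) -> MultilayerPartition:
    """Medoid of the ensemble under mean pairwise z-Rand similarity.

    Ties broken by higher Q, then lowest seed.  Identical partitions are
    grouped so similarity is computed once per distinct pair.
    """
    parts = ens.partitions
    if not parts:
        raise InvalidConfigError("empty ensemble")
    if len(parts) == 1:
        return parts[0]
    keys = [canonical_labels(p.labels.ravel()).tobytes() for p in parts]
    uniq_keys = list(dict.fromkeys(keys))
    if len(uniq_keys) == 1:
        return _tie_break(parts)
    rep = {key: next(p for p, k in zip(parts, keys) if k == key) for key in uniq_keys}
    mult = {key: keys.count(key) for key in uniq_keys}
    sim = {}
    for i, ka in enumerate(uniq_keys):
        for kb in uniq_keys[i + 1 :]:
            sim[(ka, kb)] = sim[(kb, ka)] = zrand(
                rep[ka].labels.ravel(), rep[kb].labels.ravel()
            )
        # similarity of a partition to an identical copy: its self z-Rand
        sim[(ka, ka)] = zrand(rep[ka].labels.ravel(), rep[ka].labels.ravel())
    n = len(parts)
    mean_sim = {}
    for key in uniq_keys:
        total = sum(
            sim[(key, other)] * (mult[other] - (other == key)) for other in uniq_keys
        )
        mean_sim[key] = total / (n - 1)
    best = max(mean_sim.values())
    contenders = [p for p, k in zip(parts, keys) if np.isclose(mean_sim[k], best)]
    return _tie_break(contenders)


def _tie_break(parts):
    return sorted(parts, key=lambda p: (-p.q, p.seed if p.seed is not None else 0))[0]


def static_communities(
    conn: ConnectivitySeries,
    params: ModularityParams,
    interval: str = "pre",
    n_iter: int = 100,
    base_seed: int = 0,
) -> np.ndarray:
    """One community label per node from the unperturbed interval.

    Runs consensus multilayer detection restricted to layers tagged
    ``interval`` and collapses to a single label per node by modal label
    across layers (smallest label wins ties).  This is the "resting"
    community definition used for community-level summaries.
    """
    sub = conn.interval(interval) if interval != "all" else conn
    if sub.layers.shape[0] == 0:
        raise InvalidConfigError(f"no layers tagged {interval!r}")
    net = build_multilayer(sub.layers, params)
    cons = consensus_partition(partition_ensemble(net, n_iter=n_iter, base_seed=base_seed))
    labels = cons.labels
    if labels.shape[0] == 1:
        return canonical_labels(labels[0])
    modal = np.empty(labels.shape[1], dtype=int)
    for i in range(labels.shape[1]):
        vals, counts = np.unique(labels[:, i], return_counts=True)
        modal[i] = vals[np.argmax(counts)]  # np.unique sorts: ties -> smallest
    return canonical_labels(modal)


def match_labels(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` to maximize overlap with ``reference`` communities
    (Hungarian assignment on the contingency table).  Unmatched communities
    keep fresh labels above the reference range."""
    from scipy.optimize import linear_sum_assignment

    labels = np.asarray(labels).ravel()
    reference = np.asarray(reference).ravel()
    lu, li = np.unique(labels, return_inverse=True)
    ru, ri = np.unique(reference, return_inverse=True)
    table = np.zeros((len(lu), len(ru)))
    np.add.at(table, (li, ri), 1.0)
    rows, cols = linear_sum_assignment(-table)
    out = np.empty_like(labels)
    assigned = dict(zip(rows, cols))
    next_fresh = int(ru.max()) + 1
    for i, lab in enumerate(lu):
        if i in assigned:
            out[labels == lab] = ru[assigned[i]]
        else:
            out[labels == lab] = next_fresh
            next_fresh += 1
    return out


class MultilayerLouvain(BaseEstimator, ClusterMixin):
    """Consensus multilayer community detection as a clustering estimator.

    Parameters
    ----------
    gamma, omega : resolution parameters of the quality function.
    n_iter : ensemble size (seeded repeated runs of the greedy optimizer).
    random_state : base seed; run k uses random_state + k.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (L, N) consensus community assignment.
    q_ : quality value of the consensus partition.
    ensemble_ : the full :class:`PartitionEnsemble`.
    agreement_ : fraction of run pairs identical up to relabeling.
    n_communities_ : distinct labels in the consensus partition.
    n_clipped_ : negative edges clipped when building the network.
    """

    def __init__(self, gamma: float = 1.025, omega: float = 9.0,
                 n_iter: int = 100, random_state: int = 0):
        self.gamma = gamma
        self.omega = omega
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        net = build_multilayer(X, ModularityParams(self.gamma, self.omega))
        ens = partition_ensemble(net, n_iter=self.n_iter, base_seed=self.random_state)
        cons = consensus_partition(ens)
        self.network_ = net
        self.ensemble_ = ens
        self.agreement_ = ens.agreement
        self.labels_ = cons.labels
        self.q_ = cons.q
        self.n_communities_ = cons.n_communities
        self.n_clipped_ = net.n_clipped
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.labels_
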