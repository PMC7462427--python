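"""Reconfiguration metrics on multilayer partitions.

Flexibility of node i is the count of community-affiliation changes between
consecutive layers, g_i, normalized by the L - 1 possible changes:
xi_i = g_i / (L - 1).  Allegiance P_ij is the fraction of layers in which
nodes i and j carry the same community label (normalized by L so that
P_ii = 1 and P is bounded by 1; a literal L - 1 normalization is available
behind a flag).  Both are invariant to community relabeling.

Pre/post comparisons compute each metric separately on the pre-pulse and
post-pulse layer blocks of one partition of the full epoch (so label
identity is consistent across the pulse), with the pulse-centered layer
excluded from both blocks.  Distance summaries relate the changes to the
Euclidean distance from the stimulation site.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError
from .simulate import Geometry

__all__ = [
    "flexibility",
    "allegiance",
    "prepost_diff",
    "stim_distance",
    "stim_allegiance",
    "top_percentile_nodes",
    "average_lr",
    "community_means",
]


def _labels_of(p) -> np.ndarray:
    labels = p.labels if hasattr(p, "labels") else np.asarray(p)
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise InvalidConfigError("labels must have shape (L, N)")
    return labels


def flexibility(p) -> np.ndarray:
    """Per-node flexibility xi = g / (L - 1) over an (L, N) partition."""
    labels = _labels_of(p)
    if labels.shape[0] < 2:
        raise InvalidConfigError("flexibility is undefined for a single layer")
    g = (labels[1:] != labels[:-1]).sum(axis=0)
    return g / (labels.shape[0] - 1)


def allegiance(p, norm: str = "layers") -> np.ndarray:
    """N x N co-assignment fraction matrix.

    ``norm='layers'`` (default) divides co-assignment counts by L, giving a
    matrix with unit diagonal and entries in [0, 1]; ``norm='transitions'``
    divides by L - 1.
    """
    labels = _labels_of(p)
    n_layers = labels.shape[0]
    counts = np.zeros((labels.shape[1], labels.shape[1]))
    for s in range(n_layers):
        counts += labels[s][:, None] == labels[s][None, :]
    if norm == "layers":
        return counts / n_layers
    if norm == "transitions":
        if n_layers < 2:
            raise InvalidConfigError("'transitions' normalization needs L >= 2")
        return counts / (n_layers - 1)
    raise InvalidConfigError(f"unknown normalization {norm!r}")


def prepost_diff(p, tags, norm: str = "layers") -> dict:
    """Metric differences between the pre- and post-pulse layer blocks.

    ``tags`` labels every layer of the partition as pre / pulse / post; the
    pulse layer is excluded from both blocks.  Returns signed (post - pre)
    and absolute differences for per-node flexibility and per-pair
    allegiance, plus the block metrics themselves.
    """
    labels = _labels_of(p)
    tags = np.asarray(tags)
    if len(tags) != labels.shape[0]:
        raise InvalidConfigError("tags must cover every layer")
    if (tags == "pulse").sum() != 1:
        raise InvalidConfigError("exactly one layer must be tagged 'pulse'")
    pre = labels[tags == "pre"]
    post = labels[tags == "post"]
    if len(pre) < 2 or len(post) < 2:
        raise InvalidConfigError("each block needs >= 2 layers for flexibility")
    flex_pre = flexibility(pre)
    flex_post = flexibility(post)
    alleg_pre = allegiance(pre, norm=norm)
    alleg_post = allegiance(post, norm=norm)
    d_flex = flex_post - flex_pre
    d_alleg = alleg_post - alleg_pre
    return {
        "flex_pre": flex_pre,
        "flex_post": flex_post,
        "d_flex": d_flex,
        "d_flex_abs": np.abs(d_flex),
        "alleg_pre": alleg_pre,
        "alleg_post": alleg_post,
        "d_alleg": d_alleg,
        "d_alleg_abs": np.abs(d_alleg),
    }


def stim_distance(geom: Geometry, communities) -> tuple[pd.DataFrame, np.ndarray]:
    """Distances (meters) from the stimulation site.

    The reference point is the coordinate of the node nearest the
    stimulation site (the stimulated node itself when it is a node of the
    geometry).  Returns a per-community table with the Euclidean distance
    from each community's member-centroid to that point, and the per-node
    distance vector for scatter summaries.  Empty communities are skipped
    with a warning.
    """
    communities = np.asarray(communities).ravel()
    if len(communities) != geom.n_nodes:
        raise InvalidConfigError("one community label per node required")
    all_dist = geom.distances_from(geom.stim_node)
    ref = geom.coordinates[int(np.argmin(all_dist))]
    node_dist = np.linalg.norm(geom.coordinates - ref, axis=1)
    rows = []
    for lab in np.unique(communities):
        members = np.flatnonzero(communities == lab)
        if len(members) == 0:  # pragma: no cover - unique() precludes this
            warnings.warn(f"community {lab!r} is empty; skipped")
            continue
        centroid = geom.coordinates[members].mean(axis=0)
        rows.append(
            {
                "community": lab,
                "n_nodes": len(members),
                "centroid_dist_m": float(np.linalg.norm(centroid - ref)),
            }
        )
    return pd.DataFrame(rows), node_dist


def stim_allegiance(d_alleg: np.ndarray, communities, stim_node: int) -> pd.DataFrame:
    """Per-community mean |change in allegiance with the stimulation node|.

    For each community: mean over member nodes (the stimulation node is
    excluded from its own pairings) of the magnitude of the allegiance
    change between that node and the stimulation node.
    """
    d_alleg = np.asarray(d_alleg)
    communities = np.asarray(communities).ravel()
    if d_alleg.shape != (len(communities), len(communities)):
        raise InvalidConfigError("d_alleg must be N x N for N labeled nodes")
    col = np.abs(d_alleg[:, stim_node])
    rows = []
    for lab in np.unique(communities):
        members = np.flatnonzero(communities == lab)
        members = members[members != stim_node]
        if len(members) == 0:
            warnings.warn(f"community {lab!r} has no members besides the "
                          "stimulation node; skipped")
            continue
        rows.append(
            {
                "community": lab,
                "n_nodes": len(members),
                "mean_abs_d_allegiance": float(col[members].mean()),
            }
        )
    return pd.DataFrame(rows)


def top_percentile_nodes(node_diffs, pct: float = 85.0):
    """Nodes at or above the ``pct``-th percentile of their differences.

    The percentile uses linear interpolation between order statistics.
    Returns ``(indices, threshold)``; the threshold is the value a summary
    plot would draw as its horizontal cutoff line.
    """
    values = np.asarray(node_diffs, dtype=float).ravel()
    if len(values) < 1:
        raise InvalidConfigError("need at least one node")
    threshold = float(np.percentile(values, pct))
    return np.flatnonzero(values >= threshold), threshold


def average_lr(left, right):
    """Elementwise mean of homologous left/right stimulation results.

    Accepts arrays or dicts of arrays (matched keys and shapes).
    """
    if isinstance(left, dict) != isinstance(right, dict):
        raise InvalidConfigError("left and right must have matching structure")
    if isinstance(left, dict):
        if set(left) != set(right):
            raise InvalidConfigError("left and right must have matching keys")
        return {k: average_lr(left[k], right[k]) for k in left}
    a = np.asarray(left, dtype=float)
    b = np.asarray(right, dtype=float)
    if a.shape != b.shape:
        raise InvalidConfigError(f"shape mismatch: {a.shape} vs {b.shape}")
    return 0.5 * (a + b)


def community_means(values: np.ndarray, communities) -> pd.DataFrame:
    """Mean of a per-node quantity within each community (the community mean
    equals the mean of its member nodes' values by construction)."""
    values = np.asarray(values, dtype=float).ravel()
    communities = np.asarray(communities).ravel()
    rows = []
    for lab in np.unique(communities):
        members = communities == lab
        rows.append(
            {
                "community": lab,
                "n_nodes": int(members.sum()),
                "mean": float(values[members].mean()),
            }
        )
    return pd.DataFrame(rows)
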