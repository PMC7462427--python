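"""(gamma, omega) scale selection against an edge-shuffled null.

For each cell of a resolution grid, the mean multilayer modularity Q of the
observed networks is compared with the mean Q of null networks obtained by
uniformly permuting each layer's pairwise connectivity values (upper
triangle, mirrored; diagonal untouched), which destroys the correlational
structure while conserving every layer's edge-weight multiset exactly.
The selected scale is the argmax of the mean difference Q_obs - Q_null
(the "difference" heuristic); ties break toward smaller omega, then
smaller gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .community import ModularityParams, build_multilayer, partition_ensemble
from .connectivity import ConnectivitySeries
from .exceptions import DegenerateLayerError, InvalidConfigError

__all__ = [
    "QSurface",
    "default_gamma_grid",
    "default_omega_grid",
    "shuffle_null",
    "q_surface",
    "select_scale",
    "ScaleSearch",
]


def default_gamma_grid() -> np.ndarray:
    """0.8 ... 1.6 in steps of 0.025 (the step implied by the reference
    optimum gamma = 1.025)."""
    return np.round(np.arange(0.8, 1.6 + 1e-9, 0.025), 3)


def default_omega_grid() -> np.ndarray:
    """Log-like ladder 0.5 ... 35."""
    return np.array([0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0, 12.0, 16.0, 22.0, 35.0])


@dataclass
class QSurface:
    """Mean modularity over a (gamma, omega) grid for observed and null
    networks, and their difference."""

    gamma_grid: np.ndarray
    omega_grid: np.ndarray
    q_obs: np.ndarray  # (G, O)
    q_null: np.ndarray  # (G, O)
    n_subjects: int = 1

    def __post_init__(self):
        g = np.asarray(self.gamma_grid, float)
        o = np.asarray(self.omega_grid, float)
        if np.any(np.diff(g) <= 0) or np.any(np.diff(o) <= 0):
            raise InvalidConfigError("grids must be strictly increasing")
        if self.q_obs.shape != (len(g), len(o)) or self.q_null.shape != self.q_obs.shape:
            raise InvalidConfigError("surface shapes must match the grids")

    @property
    def q_diff(self) -> np.ndarray:
        return self.q_obs - self.q_null


def shuffle_null(conn, rng) -> ConnectivitySeries:
    """Edge-shuffled null: within each layer independently, uniformly permute
    the N(N-1)/2 upper-triangle weights and mirror; diagonal untouched.
    Layer weight totals (indeed multisets) are conserved exactly."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    layers = conn.layers if isinstance(conn, ConnectivitySeries) else np.asarray(conn, float)
    out = np.array(layers, dtype=float, copy=True)
    n = out.shape[1]
    iu = np.triu_indices(n, k=1)
    for s in range(out.shape[0]):
        vals = out[s][iu]
        perm = rng.permutation(len(vals))
        out[s][iu] = vals[perm]
        out[s].T[iu] = out[s][iu]
    if isinstance(conn, ConnectivitySeries):
        return ConnectivitySeries(
            band=conn.band, layers=out, centers=conn.centers.copy(),
            tags=conn.tags.copy(),
        )
    return out


def _mean_q(layers, params, n_iter, base_seed) -> float:
    net = build_multilayer(layers, params)
    ens = partition_ensemble(net, n_iter=n_iter, base_seed=base_seed)
    return float(np.mean([p.q for p in ens.partitions]))


def q_surface(
    conn_by_subject,
    gamma_grid=None,
    omega_grid=None,
    n_iter_per_cell: int = 3,
    base_seed: int = 0,
) -> QSurface:
    """Per cell: mean over subjects of mean-over-runs Q for the observed
    networks and for each subject's shuffled null (one fresh shuffle per
    subject per cell).  Degenerate subjects are skipped with a warning."""
    if len(conn_by_subject) < 1:
        raise InvalidConfigError("need at least one subject")
    gamma_grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
    omega_grid = default_omega_grid() if omega_grid is None else np.asarray(omega_grid, float)
    g_n, o_n = len(gamma_grid), len(omega_grid)
    q_obs = np.zeros((g_n, o_n))
    q_null = np.zeros((g_n, o_n))
    n_used = np.zeros((g_n, o_n), dtype=int)
    # one independent shuffle stream per subject; fixed per-cell run seeds
    for subj, conn in enumerate(conn_by_subject):
        subj_rng = np.random.default_rng((base_seed, subj))
        for gi, gamma in enumerate(gamma_grid):
            for oi, omega in enumerate(omega_grid):
                params = ModularityParams(gamma=float(gamma), omega=float(omega))
                cell_seed = base_seed + 104729 * subj + 1009 * gi + oi
                try:
                    null_conn = shuffle_null(conn, subj_rng)
                    q_o = _mean_q(conn, params, n_iter_per_cell, cell_seed)
                    q_s = _mean_q(null_conn, params, n_iter_per_cell, cell_seed)
                except DegenerateLayerError as err:
                    warnings.warn(
                        f"subject {subj} skipped at (gamma={gamma}, omega={omega}): {err}"
                    )
                    continue
                q_obs[gi, oi] += q_o
                q_null[gi, oi] += q_s
                n_used[gi, oi] += 1
    if np.any(n_used == 0):
        raise DegenerateLayerError("every subject degenerate in some grid cell")
    return QSurface(
        gamma_grid=gamma_grid,
        omega_grid=omega_grid,
        q_obs=q_obs / n_used,
        q_null=q_null / n_used,
        n_subjects=len(conn_by_subject),
    )


def select_scale(surface: QSurface) -> tuple[float, float]:
    """Argmax of Q_obs - Q_null over the grid.

    Ties break toward smaller omega, then smaller gamma (so the result is
    invariant to grid ordering).  A perfectly flat surface triggers an
    ambiguous-selection warning and returns the tie-break cell.
    """
    diff = surface.q_diff
    if not np.all(np.isfinite(diff)):
        raise InvalidConfigError("surface contains non-finite values")
    cells = [
        (-diff[gi, oi], float(omega), float(gamma))
        for gi, gamma in enumerate(surface.gamma_grid)
        for oi, omega in enumerate(surface.omega_grid)
    ]
    if np.allclose(diff, diff.flat[0]):
        warnings.warn("flat Q-difference surface: scale selection is ambiguous")
    _, omega, gamma = min(cells)
    return gamma, omega


class ScaleSearch(BaseEstimator):
    """Grid search for the (gamma, omega) operating point, sklearn-style.

    ``fit`` accepts a list of connectivity series (one per subject) — or a
    single series — sweeps the grid, and exposes ``surface_`` and
    ``best_params_`` / ``best_gamma_`` / ``best_omega_``.
    """

    def __init__(self, gamma_grid=None, omega_grid=None,
                 n_iter_per_cell: int = 3, random_state: int = 0):
        self.gamma_grid = gamma_grid
        self.omega_grid = omega_grid
        self.n_iter_per_cell = n_iter_per_cell
        self.random_state = random_state

    def fit(self, X, y=None):
        subjects = X if isinstance(X, (list, tuple)) else [X]
        self.surface_ = q_surface(
            subjects,
            gamma_grid=self.gamma_grid,
            omega_grid=self.omega_grid,
            n_iter_per_cell=self.n_iter_per_cell,
            base_seed=self.random_state,
        )
        gamma, omega = select_scale(self.surface_)
        self.best_gamma_ = gamma
        self.best_omega_ = omega
        self.best_params_ = {"gamma": gamma, "omega": omega}
        return self
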