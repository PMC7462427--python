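"""End-to-end orchestration: simulate -> connectivity -> (sweep) -> detect
-> metrics -> statistics -> report tables.

The pipeline runs the full analysis chain on a synthetic study (or on
ingested trial ensembles): per-subject sliding-window dwPLI in the planted
band, optional (gamma, omega) scale selection on the pre-pulse interval
against the edge-shuffled null, consensus multilayer community detection
on the full peri-pulse epoch, static (pre-interval) community definitions,
flexibility/allegiance pre-post differences, distance-from-stimulation
summaries, top-percentile node selection, and group statistics with
Bonferroni / Benjamini-Yekutieli control.

Everything is seeded; running the same config twice produces byte-identical
tables (figures are advisory artifacts, numeric tables are the contract).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as met
from . import stats as st
from .community import (
    ModularityParams,
    MultilayerLouvain,
    match_labels,
    static_communities,
)
from .connectivity import SlidingWindowDWPLI, edge_change
from .exceptions import InvalidConfigError
from .io import config_hash
from .scale import ScaleSearch
from .simulate import (
    SimulationConfig,
    generate_geometry,
    generate_subject_ensembles,
    make_study_config,
    planted_partition,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "default_pipeline_config"]

log = logging.getLogger("netreconf")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    simulation: SimulationConfig
    # windowing
    center_spacing_samples: int = 5
    window_length: float = 0.5
    retain_span: float = 1.0
    taper: str = "hann"
    # scale selection
    sweep: bool = True
    gamma_grid: tuple = (0.8, 1.0, 1.2, 1.4, 1.6)
    omega_grid: tuple = (0.5, 2.0, 5.0, 9.0, 16.0)
    n_iter_per_cell: int = 2
    # fixed scale when sweep is off (reference operating point)
    gamma: float = 1.025
    omega: float = 9.0
    # detection
    n_iter: int = 20
    # metrics / report
    percentile: float = 85.0
    seed: int = 0
    make_figures: bool = False

    def to_yaml(self, path) -> None:
        from .io import _config_to_dict, _plain

        d = dataclasses.asdict(self)
        d["simulation"] = _config_to_dict(self.simulation)
        d["gamma_grid"] = list(self.gamma_grid)
        d["omega_grid"] = list(self.omega_grid)
        Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import tempfile

        from .io import config_from_yaml

        d = yaml.safe_load(Path(path).read_text())
        sim_d = d.pop("simulation")
        with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
            fh.write(yaml.safe_dump(sim_d))
            tmp = fh.name
        sim = config_from_yaml(tmp)
        Path(tmp).unlink()
        d["gamma_grid"] = tuple(d.get("gamma_grid", cls.gamma_grid))
        d["omega_grid"] = tuple(d.get("omega_grid", cls.omega_grid))
        return cls(simulation=sim, **d)


def default_pipeline_config(seed: int = 0, **study_kw) -> PipelineConfig:
    """Desk-scale default study: 10 synthetic subjects, 16 regions, one
    alpha-band plant with the first community restructured post-pulse."""
    sim = make_study_config(seed=seed, **study_kw)
    return PipelineConfig(simulation=sim, seed=seed)


@dataclass
class PipelineReport:
    """Tables produced by one pipeline run (plus headline recovery flags)."""

    config: PipelineConfig
    selected_gamma: float
    selected_omega: float
    edge_table: pd.DataFrame
    community_table: pd.DataFrame
    community_pairs: pd.DataFrame
    node_table: pd.DataFrame
    recovery: pd.DataFrame
    surface_table: pd.DataFrame | None
    percentile_threshold: float
    top_nodes: np.ndarray
    enrichment: float
    perturbed_community: int | None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "edges": self.edge_table,
            "communities": self.community_table,
            "community_pairs": self.community_pairs,
            "nodes": self.node_table,
            "recovery": self.recovery,
        }
        if self.surface_table is not None:
            out["qsurface"] = self.surface_table
        return out


def _sem(x: np.ndarray, axis=0):
    x = np.asarray(x, float)
    n = x.shape[axis]
    if n < 2:
        return np.full(np.delete(x.shape, axis), np.nan)
    return x.std(axis=axis, ddof=1) / np.sqrt(n)


def _perturbed_community(sim: SimulationConfig) -> int | None:
    """The planted pre-pulse community with the most members whose label
    changes after the pulse (None when the plant is unperturbed)."""
    if not sim.bands:
        return None
    plan = sim.bands[0]
    pre = np.asarray(plan.pre_partition)
    post = np.asarray(plan.post_partition)
    changed = pre != post
    if not changed.any():
        return None
    labs, counts = np.unique(pre[changed], return_counts=True)
    return int(labs[np.argmax(counts)])


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineReport:
    """Execute the full chain and return (and optionally write) the report."""
    t_start = time.time()
    sim = config.simulation
    if not sim.bands:
        raise InvalidConfigError("pipeline needs at least one planted band")
    plan = sim.bands[0]
    log.info("simulating %d subjects (seed=%d)", sim.n_subjects, sim.seed)
    ensembles = generate_subject_ensembles(sim)
    geometry = generate_geometry(sim)

    estimator = SlidingWindowDWPLI(
        band=plan.band,
        center_spacing_samples=config.center_spacing_samples,
        window_length=config.window_length,
        taper=config.taper,
        retain_span=config.retain_span,
    )
    log.info("estimating dwPLI connectivity in band %s", plan.band)
    conns = [estimator.fit(e).transform(e) for e in ensembles]

    # --- edgewise connectivity change + group test -------------------------
    n = sim.n_regions
    changes = np.stack([edge_change(c) for c in conns])  # (S, N, N)
    iu = np.triu_indices(n, k=1)
    diffs = changes[:, iu[0], iu[1]]  # (S, E)
    if sim.n_subjects >= 2:
        t_vals, p_vals, degenerate = st.one_sample_t_many(diffs, axis=0)
        finite = np.isfinite(p_vals)
        flags = np.zeros(p_vals.shape, dtype=bool)
        adjusted = np.full(p_vals.shape, np.nan)
        if finite.any():
            flags[finite], adjusted[finite] = st.fdr_by(p_vals[finite])
    else:
        t_vals = p_vals = adjusted = np.full(diffs.shape[1], np.nan)
        degenerate = np.zeros(diffs.shape[1], dtype=bool)
        flags = np.zeros(diffs.shape[1], dtype=bool)
    edge_table = pd.DataFrame(
        {
            "node_i": iu[0],
            "node_j": iu[1],
            "mean_diff": diffs.mean(axis=0),
            "sem_diff": _sem(diffs),
            "t": t_vals,
            "p": p_vals,
            "p_adj_by": adjusted,
            "sig_fdr": flags,
            "degenerate": degenerate,
        }
    )

    # --- scale selection ---------------------------------------------------
    surface_table = None
    if config.sweep:
        log.info("sweeping (gamma, omega) grid %dx%d on the pre interval",
                 len(config.gamma_grid), len(config.omega_grid))
        search = ScaleSearch(
            gamma_grid=np.asarray(config.gamma_grid),
            omega_grid=np.asarray(config.omega_grid),
            n_iter_per_cell=config.n_iter_per_cell,
            random_state=config.seed,
        ).fit([c.interval("pre") for c in conns])
        gamma, omega = search.best_gamma_, search.best_omega_
        surf = search.surface_
        rows = []
        for gi, g in enumerate(surf.gamma_grid):
            for oi, o in enumerate(surf.omega_grid):
                rows.append({"gamma": g, "omega": o, "q_obs": surf.q_obs[gi, oi],
                             "q_null": surf.q_null[gi, oi],
                             "q_diff": surf.q_diff[gi, oi]})
        surface_table = pd.DataFrame(rows)
    else:
        gamma, omega = config.gamma, config.omega
    log.info("operating point gamma=%.3f omega=%.2f", gamma, omega)
    params = ModularityParams(gamma=gamma, omega=omega)

    # --- detection + metrics per subject -----------------------------------
    reference = planted_partition(sim, plan.band, "pre")
    perturbed = _perturbed_community(sim)
    per_subject = []
    for s, conn in enumerate(conns):
        det = MultilayerLouvain(
            gamma=gamma, omega=omega, n_iter=config.n_iter,
            random_state=config.seed + 10_000 * (s + 1),
        ).fit(conn)
        static = static_communities(
            conn, params, interval="pre", n_iter=config.n_iter,
            base_seed=config.seed + 10_000 * (s + 1) + 5_000,
        )
        static = match_labels(static, reference)
        d = met.prepost_diff(det.labels_, conn.tags)
        per_subject.append(
            {"static": static, "diffs": d, "agreement": det.agreement_, "q": det.q_}
        )

    # --- community-level summaries -----------------------------------------
    comm_ids = np.unique(reference)
    # per subject x community: mean within-community pairwise |d allegiance|
    signed = np.full((sim.n_subjects, len(comm_ids)), np.nan)
    magn = np.full((sim.n_subjects, len(comm_ids)), np.nan)
    for s, rec in enumerate(per_subject):
        labels = rec["static"]
        d_alleg = rec["diffs"]["d_alleg"]
        for ci, lab in enumerate(comm_ids):
            members = np.flatnonzero(labels == lab)
            if len(members) < 2:
                continue
            pairs = np.array(list(itertools.combinations(members, 2)))
            vals = d_alleg[pairs[:, 0], pairs[:, 1]]
            signed[s, ci] = vals.mean()
            magn[s, ci] = np.abs(vals).mean()

    dist_df, node_dist = met.stim_distance(geometry, reference)
    dist_map = dict(zip(dist_df["community"], dist_df["centroid_dist_m"]))
    comm_rows = []
    for ci, lab in enumerate(comm_ids):
        col = magn[:, ci]
        ok = np.isfinite(col)
        res = st.one_sample_t(col[ok]) if ok.sum() >= 2 else None
        comm_rows.append(
            {
                "community": lab,
                "centroid_dist_m": dist_map.get(lab, np.nan),
                "mean_abs_d_alleg": np.nanmean(col) if ok.any() else np.nan,
                "sem_abs_d_alleg": _sem(col[ok]) if ok.sum() >= 2 else np.nan,
                "mean_signed_d_alleg": np.nanmean(signed[:, ci]),
                "t_vs_zero": res.statistic if res else np.nan,
                "p_vs_zero": res.pvalue if res else np.nan,
                "is_perturbed": bool(perturbed is not None and lab == perturbed),
            }
        )
    community_table = pd.DataFrame(comm_rows)

    # paired tests between communities, Bonferroni over the pair family
    pair_rows = []
    pairs = list(itertools.combinations(range(len(comm_ids)), 2))
    for ci, cj in pairs:
        a, b = magn[:, ci], magn[:, cj]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 2:
            res = st.paired_t(a[ok], b[ok])
            t_v, p_v, dg = res.statistic, res.pvalue, res.degenerate
        else:
            t_v = p_v = np.nan
            dg = True
        pair_rows.append(
            {"community_a": comm_ids[ci], "community_b": comm_ids[cj],
             "t": t_v, "p": p_v, "degenerate": dg}
        )
    community_pairs = pd.DataFrame(pair_rows)
    if len(community_pairs):
        p_arr = community_pairs["p"].to_numpy()
        finite = np.isfinite(p_arr)
        flags = np.zeros(len(p_arr), dtype=bool)
        if finite.any():
            flags[finite], alpha_corr = st.bonferroni(p_arr[finite], len(p_arr))
        else:
            alpha_corr = 0.05 / len(p_arr)
        community_pairs["sig_bonferroni"] = flags
        community_pairs["alpha_corrected"] = alpha_corr
        community_pairs["sig_uncorrected"] = p_arr < 0.05

    # --- node-level summaries ----------------------------------------------
    node_flex = np.stack([rec["diffs"]["d_flex"] for rec in per_subject])
    node_alleg_stim = np.stack(
        [np.abs(rec["diffs"]["d_alleg"][:, sim.stim_node]) for rec in per_subject]
    )
    node_alleg_mean = np.stack(
        [
            (np.abs(rec["diffs"]["d_alleg"]).sum(axis=1)
             - np.abs(np.diag(rec["diffs"]["d_alleg"]))) / (n - 1)
            for rec in per_subject
        ]
    )
    group_alleg = node_alleg_mean.mean(axis=0)
    top_nodes, threshold = met.top_percentile_nodes(group_alleg, config.percentile)
    if perturbed is not None:
        members = reference == perturbed
        frac_members_selected = np.isin(np.flatnonzero(members), top_nodes).mean()
        base_rate = len(top_nodes) / n
        enrichment = float(frac_members_selected / base_rate) if base_rate else np.nan
    else:
        enrichment = np.nan
    node_table = pd.DataFrame(
        {
            "node": np.arange(n),
            "community": reference,
            "distance_m": node_dist,
            "d_flex": node_flex.mean(axis=0),
            "sem_d_flex": _sem(node_flex),
            "abs_d_alleg_stim": node_alleg_stim.mean(axis=0),
            "abs_d_alleg_mean": group_alleg,
            "sem_abs_d_alleg_mean": _sem(node_alleg_mean),
            "top_percentile": np.isin(np.arange(n), top_nodes),
        }
    )

    # --- headline recovery flags -------------------------------------------
    rec_rows = []
    for s in range(sim.n_subjects):
        col = magn[s]
        ok = np.isfinite(col)
        best = comm_ids[np.nanargmax(col)] if ok.any() else -1
        rec_rows.append(
            {
                "subject": s,
                "largest_change_community": best,
                "perturbed_is_largest": bool(
                    perturbed is not None and best == perturbed
                ),
                "ensemble_agreement": per_subject[s]["agreement"],
                "q": per_subject[s]["q"],
            }
        )
    recovery = pd.DataFrame(rec_rows)

    report = PipelineReport(
        config=config,
        selected_gamma=float(gamma),
        selected_omega=float(omega),
        edge_table=edge_table,
        community_table=community_table,
        community_pairs=community_pairs,
        node_table=node_table,
        recovery=recovery,
        surface_table=surface_table,
        percentile_threshold=threshold,
        top_nodes=top_nodes,
        enrichment=enrichment,
        perturbed_community=perturbed,
    )
    if outdir is not None:
        _write_report(report, Path(outdir))
    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return report


def _write_report(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config_hash(report.config.simulation)}\n"
    for name, df in report.tables().items():
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    summary = {
        "selected_gamma": report.selected_gamma,
        "selected_omega": report.selected_omega,
        "percentile_threshold": float(report.percentile_threshold),
        "top_nodes": [int(i) for i in report.top_nodes],
        "enrichment": None if np.isnan(report.enrichment) else float(report.enrichment),
        "perturbed_community": report.perturbed_community,
        "n_recovered": int(report.recovery["perturbed_is_largest"].sum()),
        "n_subjects": int(len(report.recovery)),
    }
    (outdir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    report.config.to_yaml(outdir / "config.yaml")
    if report.config.make_figures:
        _write_figures(report, outdir)


def _write_figures(report: PipelineReport, outdir: Path) -> None:
    """Advisory figures; numeric tables are the contract."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = int(report.node_table["node"].max()) + 1
    mat = np.zeros((n, n))
    et = report.edge_table
    mat[et["node_i"], et["node_j"]] = et["mean_diff"]
    mat += mat.T
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mat, cmap="RdBu_r",
                   vmin=-np.abs(mat).max() or -1e-3,
                   vmax=np.abs(mat).max() or 1e-3)
    ax.set(xlabel="region", ylabel="region", title="post - pre dwPLI")
    fig.colorbar(im, ax=ax)
    fig.savefig(outdir / "edge_change.png", dpi=120)
    plt.close(fig)

    ct = report.community_table
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(ct["community"].astype(str), ct["mean_abs_d_alleg"],
           yerr=ct["sem_abs_d_alleg"], color="tab:blue")
    ax.set(xlabel="community", ylabel="mean |Δ allegiance|")
    fig.tight_layout()
    fig.savefig(outdir / "community_change.png", dpi=120)
    plt.close(fig)

    nt = report.node_table
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(nt["distance_m"], nt["abs_d_alleg_mean"],
               c=nt["community"], cmap="tab10")
    ax.axhline(report.percentile_threshold, ls=":", color="k")
    ax.set(xlabel="distance from stimulation site (m)",
           ylabel="node mean |Δ allegiance|")
    fig.tight_layout()
    fig.savefig(outdir / "node_change.png", dpi=120)
    plt.close(fig)
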