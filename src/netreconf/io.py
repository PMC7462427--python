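"""On-disk formats: HDF5 array containers, delimited tables, YAML configs."""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .community import MultilayerPartition
from .connectivity import ConnectivitySeries
from .exceptions import InvalidConfigError
from .scale import QSurface
from .simulate import BandPlan, Geometry, SimulationConfig, TrialEnsemble

__all__ = [
    "save_ensemble",
    "load_ensemble",
    "save_connectivity",
    "load_connectivity",
    "save_geometry",
    "load_geometry",
    "save_partition",
    "load_partition",
    "save_qsurface",
    "load_qsurface",
    "config_to_yaml",
    "config_from_yaml",
    "config_hash",
]


# --- simulation config <-> YAML -------------------------------------------


def _plain(v):
    """Recursively coerce numpy scalars/containers to plain Python types."""
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.ndarray):
        return [_plain(x) for x in v.tolist()]
    if isinstance(v, (list, tuple)):
        return [_plain(x) for x in v]
    if isinstance(v, dict):
        return {k: _plain(x) for k, x in v.items()}
    return v


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["epoch_span"] = list(config.epoch_span)
    d["bands"] = [
        {
            "band": list(p.band),
            "pre_partition": list(p.pre_partition),
            "post_partition": list(p.post_partition),
            "coupling": p.coupling,
            "lag_cycles": (
                list(p.lag_cycles)
                if np.ndim(p.lag_cycles) else float(p.lag_cycles)
            ),
        }
        for p in config.bands
    ]
    return _plain(d)


def config_to_yaml(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))


def config_from_yaml(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    bands = tuple(
        BandPlan(
            band=tuple(b["band"]),
            pre_partition=tuple(b["pre_partition"]),
            post_partition=tuple(b["post_partition"]),
            coupling=float(b.get("coupling", 0.8)),
            lag_cycles=(
                tuple(b["lag_cycles"])
                if isinstance(b["lag_cycles"], list) else float(b["lag_cycles"])
            ),
        )
        for b in d.get("bands", [])
    )
    return SimulationConfig(
        n_regions=int(d["n_regions"]),
        fs=float(d["fs"]),
        epoch_span=tuple(d["epoch_span"]),
        n_trials=int(d["n_trials"]),
        bands=bands,
        noise_sd=float(d["noise_sd"]),
        stim_node=int(d["stim_node"]),
        seed=int(d["seed"]),
        n_subjects=int(d.get("n_subjects", 1)),
    )


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the canonical YAML form, echoed into outputs."""
    text = yaml.safe_dump(_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# --- trial ensembles <-> HDF5 ---------------------------------------------


def save_ensemble(ens: TrialEnsemble, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ens.data, chunks=True, compression="gzip")
        f.attrs["fs"] = ens.fs
        f.attrs["pulse_index"] = ens.pulse_index
        if ens.seed is not None:
            f.attrs["seed"] = ens.seed
        if ens.config is not None:
            f.attrs["config_yaml"] = yaml.safe_dump(
                _config_to_dict(ens.config), sort_keys=True
            )


def load_ensemble(path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        pulse = int(f.attrs["pulse_index"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        config = None
        if "config_yaml" in f.attrs:
            d = yaml.safe_load(f.attrs["config_yaml"])
            bands = tuple(
                BandPlan(
                    band=tuple(b["band"]),
                    pre_partition=tuple(b["pre_partition"]),
                    post_partition=tuple(b["post_partition"]),
                    coupling=float(b["coupling"]),
                    lag_cycles=(
                        tuple(b["lag_cycles"])
                        if isinstance(b["lag_cycles"], list)
                        else float(b["lag_cycles"])
                    ),
                )
                for b in d["bands"]
            )
            config = SimulationConfig(
                n_regions=d["n_regions"], fs=d["fs"],
                epoch_span=tuple(d["epoch_span"]), n_trials=d["n_trials"],
                bands=bands, noise_sd=d["noise_sd"], stim_node=d["stim_node"],
                seed=d["seed"], n_subjects=d.get("n_subjects", 1),
            )
    return TrialEnsemble(data=data, fs=fs, pulse_index=pulse, seed=seed,
                         config=config)


# --- connectivity series <-> HDF5 + manifest ------------------------------


def save_connectivity(conn: ConnectivitySeries, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("layers", data=conn.layers, chunks=True, compression="gzip")
        f.create_dataset("centers", data=conn.centers)
        f.create_dataset("tags", data=np.array(conn.tags, dtype="S5"))
        f.attrs["band_lo"] = conn.band[0]
        f.attrs["band_hi"] = conn.band[1]
    manifest = pd.DataFrame(
        {"index": np.arange(conn.n_layers), "center_s": conn.centers,
         "tag": conn.tags}
    )
    manifest.to_csv(path.with_suffix(".manifest.tsv"), sep="\t", index=False)


def load_connectivity(path) -> ConnectivitySeries:
    with h5py.File(path, "r") as f:
        return ConnectivitySeries(
            band=(float(f.attrs["band_lo"]), float(f.attrs["band_hi"])),
            layers=f["layers"][()],
            centers=f["centers"][()],
            tags=f["tags"][()].astype("U5"),
        )


# --- geometry <-> 4-column delimited text ---------------------------------


def save_geometry(geom: Geometry, path) -> None:
    df = pd.DataFrame(geom.coordinates, columns=["x_m", "y_m", "z_m"])
    df.insert(0, "node", np.arange(len(df)))
    with open(path, "w") as fh:
        fh.write(f"# stim_node={geom.stim_node}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_geometry(path) -> Geometry:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# stim_node="):
            raise InvalidConfigError("geometry file missing stim_node header")
        stim_node = int(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    return Geometry(coordinates=df[["x_m", "y_m", "z_m"]].to_numpy(),
                    stim_node=stim_node)


# --- partitions <-> integer tables ----------------------------------------


def save_partition(p: MultilayerPartition, path, gamma=None, omega=None) -> None:
    header = [f"# q={float(p.q)!r}"]
    if gamma is not None:
        header.append(f"# gamma={float(gamma)!r}")
    if omega is not None:
        header.append(f"# omega={float(omega)!r}")
    if p.seed is not None:
        header.append(f"# seed={p.seed}")
    lines = header + [
        "\t".join(str(int(v)) for v in row) for row in p.labels
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_partition(path) -> MultilayerPartition:
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
        elif line.strip():
            rows.append([int(v) for v in line.split("\t")])
    return MultilayerPartition(
        labels=np.array(rows, dtype=int),
        q=float(meta.get("q", "nan")),
        seed=int(meta["seed"]) if "seed" in meta else None,
    )


# --- Q surface <-> long-format table --------------------------------------


def save_qsurface(surface: QSurface, path) -> None:
    rows = []
    for gi, gamma in enumerate(surface.gamma_grid):
        for oi, omega in enumerate(surface.omega_grid):
            rows.append(
                {
                    "gamma": gamma,
                    "omega": omega,
                    "q_obs": surface.q_obs[gi, oi],
                    "q_null": surface.q_null[gi, oi],
                    "q_diff": surface.q_diff[gi, oi],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_qsurface(path) -> QSurface:
    df = pd.read_csv(path, sep="\t")
    gammas = np.unique(df["gamma"])
    omegas = np.unique(df["omega"])
    q_obs = df.pivot(index="gamma", columns="omega", values="q_obs").to_numpy()
    q_null = df.pivot(index="gamma", columns="omega", values="q_null").to_numpy()
    return QSurface(gamma_grid=gammas, omega_grid=omegas, q_obs=q_obs,
                    q_null=q_null)
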