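"""Synthetic trial ensembles with planted band-specific community structure.

The generator emulates source-space recordings around a perturbation pulse:
each planted community shares one narrowband source per trial (band-pass
filtered white noise), every member receives that source with a fixed
per-node phase lag and amplitude, and independent broadband noise is added
on top.  At the pulse sample the coupling structure switches from the
pre-pulse partition to the post-pulse partition, which is the only effect
the "stimulation" has — no artifact waveform is simulated.

The delayed-shared-source model is chosen over a dynamical (e.g. Kuramoto)
system because it guarantees a nonzero imaginary cross-spectrum between
community members — exactly the quantity the dwPLI connectivity estimator
measures — with limits that can be predicted analytically (dwPLI -> 1 as
noise -> 0 for a constant nonzero lag).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import InvalidConfigError

__all__ = [
    "BandPlan",
    "Geometry",
    "SimulationConfig",
    "TrialEnsemble",
    "make_band_plan",
    "make_study_config",
    "generate_trials",
    "generate_subject_ensembles",
    "planted_partition",
    "generate_geometry",
]

#: padding (seconds) generated on each side of the epoch and trimmed after
#: band-pass filtering, so filter transients never reach the analysis window
_FILTER_PAD_S = 1.0


@dataclass(frozen=True)
class BandPlan:
    """Planted community structure for one frequency band.

    Parameters
    ----------
    band
        Closed frequency interval in Hz, e.g. ``(8.0, 12.0)`` for alpha.
    pre_partition, post_partition
        Community label per node (length ``n_regions``), before and after
        the pulse.  Labels are arbitrary hashables compared by equality.
    coupling
        Amplitude share of the shared source in each member's signal,
        in [0, 1].  0 disables the band entirely.
    lag_cycles
        Per-node phase lag of the shared source, in cycles of the band's
        center frequency.  Scalars broadcast.  Within a community, members
        must not all carry the same lag: a community with zero *relative*
        lag everywhere has a purely real cross-spectrum and is invisible
        to dwPLI by construction.
    """

    band: tuple[float, float]
    pre_partition: tuple
    post_partition: tuple
    coupling: float = 0.8
    lag_cycles: tuple | float = 0.25

    @property
    def center_frequency(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])

    def lags(self, n_regions: int) -> np.ndarray:
        lag = np.asarray(self.lag_cycles, dtype=float)
        if lag.ndim == 0:
            lag = np.full(n_regions, float(lag))
        if lag.shape != (n_regions,):
            raise InvalidConfigError(
                f"lag_cycles must be scalar or length {n_regions}, got {lag.shape}"
            )
        return lag


@dataclass(frozen=True)
class Geometry:
    """Node coordinates (meters) plus the index of the stimulated node."""

    coordinates: np.ndarray  # (n_regions, 3)
    stim_node: int

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidConfigError("coordinates must have shape (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise InvalidConfigError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_nodes(self) -> int:
        return self.coordinates.shape[0]

    def distances_from(self, node: int) -> np.ndarray:
        """Euclidean distance from ``node`` to every node, in meters."""
        d = self.coordinates - self.coordinates[node]
        return np.sqrt((d**2).sum(axis=1))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic ensemble (or replicate set)."""

    n_regions: int = 68
    fs: float = 128.0
    epoch_span: tuple[float, float] = (-2.5, 2.5)
    n_trials: int = 200
    bands: tuple[BandPlan, ...] = ()
    noise_sd: float = 0.5
    stim_node: int = 0
    seed: int = 0
    n_subjects: int = 10

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 2:
            raise InvalidConfigError("n_regions must be >= 2")
        if self.n_trials < 2:
            raise InvalidConfigError(
                "n_trials must be >= 2 (cross-trial dwPLI is undefined otherwise)"
            )
        t0, t1 = self.epoch_span
        if not (t0 < 0.0 <= t1) and not (t0 <= 0.0 < t1):
            raise InvalidConfigError("epoch_span must contain time 0 (the pulse)")
        for plan in self.bands:
            lo, hi = plan.band
            if not (0.0 < lo < hi < self.fs / 2.0):
                raise InvalidConfigError(
                    f"band {plan.band} must lie strictly inside (0, fs/2)"
                )
            for name, part in (("pre", plan.pre_partition), ("post", plan.post_partition)):
                if len(part) != self.n_regions:
                    raise InvalidConfigError(
                        f"{name}_partition has length {len(part)}, expected {self.n_regions}"
                    )
            _check_lag_visibility(plan, self.n_regions)
        if not (0 <= self.stim_node < self.n_regions):
            raise InvalidConfigError("stim_node out of range")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_span
        return int(round((t1 - t0) * self.fs)) + 1

    @property
    def pulse_index(self) -> int:
        return int(round(-self.epoch_span[0] * self.fs))

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.pulse_index) / self.fs

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _check_lag_visibility(plan: BandPlan, n_regions: int) -> None:
    """Reject communities whose members all share one lag (invisible to dwPLI)."""
    lags = plan.lags(n_regions)
    for which in (plan.pre_partition, plan.post_partition):
        labels = np.asarray(which)
        for lab in set(labels.tolist()):
            members = np.flatnonzero(labels == lab)
            if len(members) >= 2 and np.allclose(lags[members], lags[members[0]]):
                raise InvalidConfigError(
                    f"community {lab!r} in band {plan.band}: all members share "
                    "lag; zero relative lag is invisible to dwPLI"
                )


@dataclass
class TrialEnsemble:
    """Region x sample x trial array with its sampling metadata."""

    data: np.ndarray  # (n_regions, n_samples, n_trials)
    fs: float
    pulse_index: int
    seed: int | None = None
    config: SimulationConfig | None = None

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.pulse_index) / self.fs


# ---------------------------------------------------------------------------
# band-plan construction helpers


def _fixup_lags(lags: np.ndarray, partitions, margin: float = 0.03) -> np.ndarray:
    """Nudge per-node lags so that within every community (in every supplied
    partition) no pair has a relative lag within ``margin`` cycles of 0 or
    0.5 — both make the pair's imaginary cross-spectrum vanish."""
    lags = lags.copy()

    def bad_pair(a, b):
        d = abs(a - b) % 1.0
        d = min(d, 1.0 - d)
        return d < margin or abs(d - 0.5) < margin

    for _ in range(50):
        dirty = False
        for labels in partitions:
            labels = np.asarray(labels)
            for lab in set(labels.tolist()):
                members = np.flatnonzero(labels == lab)
                for ai in range(len(members)):
                    for bi in range(ai + 1, len(members)):
                        a, b = members[ai], members[bi]
                        if bad_pair(lags[a], lags[b]):
                            lags[b] += 0.07
                            dirty = True
        if not dirty:
            return lags
    raise InvalidConfigError("could not find dwPLI-visible lag assignment")


def make_band_plan(
    band: tuple[float, float],
    pre_partition,
    post_partition=None,
    coupling: float = 0.8,
    lag_step: float = 0.2,
) -> BandPlan:
    """Build a :class:`BandPlan` with automatically assigned per-node lags.

    Each node gets ``lag_step`` cycles times its rank within its pre-pulse
    community, then lags are minimally adjusted so that every within-community
    pair (pre and post) keeps a relative lag away from 0 and 0.5 cycles.
    """
    pre = tuple(pre_partition)
    post = tuple(post_partition if post_partition is not None else pre_partition)
    n = len(pre)
    labels = np.asarray(pre)
    lags = np.zeros(n)
    for lab in set(pre):
        members = np.flatnonzero(labels == lab)
        lags[members] = lag_step * np.arange(len(members))
    lags = _fixup_lags(lags, [pre, post])
    return BandPlan(
        band=tuple(float(b) for b in band),
        pre_partition=pre,
        post_partition=post,
        coupling=coupling,
        lag_cycles=tuple(lags),
    )


def make_study_config(
    n_regions: int = 16,
    n_communities: int = 4,
    perturb: bool = True,
    band: tuple[float, float] = (8.0, 12.0),
    n_trials: int = 96,
    n_subjects: int = 10,
    epoch_span: tuple[float, float] = (-1.5, 1.5),
    coupling: float = 0.8,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """Default synthetic study: equal-size planted communities in one band;
    if ``perturb``, the first community is restructured after the pulse
    (half its members defect to the second community).

    The sizes here are the package's desk-scale study conditions; see
    docs/methods.md for the rationale behind each default.
    """
    if n_regions % n_communities:
        raise InvalidConfigError("n_regions must be divisible by n_communities")
    size = n_regions // n_communities
    pre = tuple(i // size + 1 for i in range(n_regions))
    if perturb:
        post = list(pre)
        # second half of community 1 joins community 2 after the pulse
        movers = [i for i in range(n_regions) if pre[i] == 1][size // 2 :]
        for i in movers:
            post[i] = 2
        post = tuple(post)
    else:
        post = pre
    plan = make_band_plan(band, pre, post, coupling=coupling)
    return SimulationConfig(
        n_regions=n_regions,
        fs=128.0,
        epoch_span=epoch_span,
        n_trials=n_trials,
        bands=(plan,),
        noise_sd=noise_sd,
        stim_node=0,
        seed=seed,
        n_subjects=n_subjects,
    )


# ---------------------------------------------------------------------------
# generation


def _fractional_delay(x: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    """Delay ``x`` by ``tau_s`` seconds via a frequency-domain phase ramp.

    Circular wrap-around is confined to the padding that generate_trials
    trims afterwards.
    """
    n = x.shape[-1]
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.fft.irfft(spec * np.exp(-2j * np.pi * freqs * tau_s), n=n)


def generate_trials(config: SimulationConfig) -> TrialEnsemble:
    """Generate one region x sample x trial ensemble per the planted design.

    Per band and trial, one band-limited source is drawn per community
    label (a new white-noise realization each trial, 4th-order zero-phase
    Butterworth band-pass, unit variance); each member node receives it
    delayed by ``lag_cycles / center_frequency`` seconds and scaled by
    ``coupling``.  Samples strictly before the pulse follow the pre-pulse
    partition, samples at/after the pulse follow the post-pulse partition.
    Independent N(0, noise_sd^2) noise is added to every node.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_regions
    n_samp = config.n_samples
    pulse = config.pulse_index
    n_pad = int(round(_FILTER_PAD_S * config.fs))
    n_full = n_samp + 2 * n_pad

    sos_by_band = [
        signal.butter(4, plan.band, btype="bandpass", fs=config.fs, output="sos")
        for plan in config.bands
    ]

    data = np.zeros((n, n_samp, config.n_trials))
    for t in range(config.n_trials):
        x = np.zeros((n, n_samp))
        for plan, sos in zip(config.bands, sos_by_band):
            if plan.coupling == 0.0:
                continue
            f_c = plan.center_frequency
            lags = plan.lags(n)
            pre = np.asarray(plan.pre_partition)
            post = np.asarray(plan.post_partition)
            labels = sorted(set(pre.tolist()) | set(post.tolist()), key=repr)
            sources = {}
            for lab in labels:
                white = rng.standard_normal(n_full)
                src = signal.sosfiltfilt(sos, white)
                sources[lab] = src / src.std()
            for i in range(n):
                tau = lags[i] / f_c
                seg_pre = _fractional_delay(sources[pre[i]], tau, config.fs)
                if post[i] == pre[i]:
                    seg_post = seg_pre
                else:
                    seg_post = _fractional_delay(sources[post[i]], tau, config.fs)
                full = np.concatenate(
                    [
                        seg_pre[n_pad : n_pad + pulse],
                        seg_post[n_pad + pulse : n_pad + n_samp],
                    ]
                )
                x[i] += plan.coupling * full
        x += rng.standard_normal((n, n_samp)) * config.noise_sd
        data[:, :, t] = x

    return TrialEnsemble(
        data=data,
        fs=config.fs,
        pulse_index=pulse,
        seed=config.seed,
        config=config,
    )


def generate_subject_ensembles(config: SimulationConfig) -> list[TrialEnsemble]:
    """Replicate "subjects": ``n_subjects`` ensembles differing only by seed
    (seed ladder ``seed + k``)."""
    return [
        generate_trials(config.replace(seed=config.seed + k))
        for k in range(config.n_subjects)
    ]


def planted_partition(config: SimulationConfig, band, interval: str) -> np.ndarray:
    """Return the exact label vector used in generation for ``band``.

    ``interval`` is ``"pre"`` or ``"post"``.
    """
    if interval not in ("pre", "post"):
        raise KeyError(f"interval must be 'pre' or 'post', got {interval!r}")
    band = tuple(float(b) for b in band)
    for plan in config.bands:
        if plan.band == band:
            part = plan.pre_partition if interval == "pre" else plan.post_partition
            return np.asarray(part)
    raise KeyError(f"no planted band {band}; have {[p.band for p in config.bands]}")


def generate_geometry(
    config: SimulationConfig,
    coordinates: np.ndarray | None = None,
    radius_m: float = 0.15,
) -> Geometry:
    """Node geometry: user-supplied coordinates, or seeded uniform placement
    inside a sphere of ``radius_m`` (default 0.15 m, head-scale)."""
    if coordinates is not None:
        coords = np.asarray(coordinates, dtype=float)
        if coords.shape != (config.n_regions, 3):
            raise InvalidConfigError(
                f"coordinates must have shape ({config.n_regions}, 3)"
            )
        return Geometry(coordinates=coords, stim_node=config.stim_node)
    # independent stream so geometry does not perturb trial generation
    rng = np.random.default_rng((config.seed, 0x6E0))
    direction = rng.standard_normal((config.n_regions, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius_m * rng.uniform(size=(config.n_regions, 1)) ** (1.0 / 3.0)
    return Geometry(coordinates=direction * r, stim_node=config.stim_node)
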