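"""Trial-consistency dwPLI connectivity in tapered sliding windows.

The estimator is the debiased weighted phase lag index (dwPLI) of Vinck and
colleagues: for a channel pair, let ``I_j`` be the imaginary part of the
trial-``j`` cross-spectrum at one frequency.  Then

    dwPLI = sum_{j != k} I_j I_k / sum_{j != k} |I_j I_k|
          = (S^2 - Q) / (S_abs^2 - Q),   S = sum I_j, S_abs = sum |I_j|,
                                          Q = sum I_j^2.

Because only the imaginary cross-spectrum enters, zero-lag (volume-conducted)
coupling does not register; debiasing removes the positive sample-size bias
of the squared weighted PLI.  Values lie in [-1, 1]; a vanishing denominator
(all I_j = 0) is defined as 0 and flagged as degenerate.

Windows are short tapered segments (default 0.5 s Hanning) slid across the
peri-pulse epoch at a fixed sample spacing, zero-padded to the requested
frequency grid; per-frequency dwPLI is then averaged into closed frequency
bands, giving one connectivity matrix per window ("layer").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as _windows
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import EstimatorUndefinedError, InvalidConfigError
from .simulate import TrialEnsemble

__all__ = [
    "WindowSpec",
    "CrossSpectra",
    "ConnectivitySeries",
    "DwpliResult",
    "window_centers",
    "window_tags",
    "cross_spectra",
    "dwpli",
    "dwpli_from_imag",
    "band_average",
    "dwpli_series",
    "edge_change",
    "SlidingWindowDWPLI",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window / frequency-grid layout for spectral connectivity.

    Defaults reproduce the reference layout: at 128 Hz with 5-sample center
    spacing and a retained span of +/-1 s around the pulse there are 51
    windows (25 pre, the pulse window, 25 post) on a 2-25 Hz grid with
    0.5 Hz steps.
    """

    fs: float = 128.0
    epoch_span: tuple[float, float] = (-2.5, 2.5)
    center_spacing_samples: int = 5
    window_length: float = 0.5
    taper: str = "hann"  # "hann" or "dpss"
    freq_min: float = 2.0
    freq_max: float = 25.0
    freq_step: float = 0.5
    retain_span: float = 1.0
    dpss_nw: float = 2.0  # time-bandwidth product if taper == "dpss"

    def __post_init__(self):
        if self.n_window_samples < 2:
            raise InvalidConfigError("window_length x fs must be >= 2 samples")
        if not (0.0 < self.freq_min <= self.freq_max < self.fs / 2.0):
            raise InvalidConfigError("frequency grid must lie within (0, fs/2)")
        if self.taper not in ("hann", "dpss"):
            raise InvalidConfigError(f"unknown taper {self.taper!r}")
        half_win = self.window_length / 2.0
        t0, t1 = self.epoch_span
        if self.retain_span > min(-t0, t1) - half_win + 1e-12:
            raise InvalidConfigError(
                "retain_span exceeds epoch_span minus half a window; "
                "windows would extend past the epoch"
            )

    @property
    def n_window_samples(self) -> int:
        return int(round(self.window_length * self.fs))

    @property
    def nfft(self) -> int:
        # zero-pad so the DFT bin spacing equals freq_step
        return max(int(round(self.fs / self.freq_step)), self.n_window_samples)

    @property
    def freq_grid(self) -> np.ndarray:
        freqs = np.fft.rfftfreq(self.nfft, d=1.0 / self.fs)
        keep = (freqs >= self.freq_min - 1e-9) & (freqs <= self.freq_max + 1e-9)
        return freqs[keep]


def window_centers(spec: WindowSpec) -> np.ndarray:
    """Window center times (seconds, pulse at 0): all integer multiples of
    ``center_spacing_samples`` within ``retain_span``, symmetric about and
    including 0."""
    k_max = int(np.floor(spec.retain_span * spec.fs / spec.center_spacing_samples + 1e-9))
    k = np.arange(-k_max, k_max + 1)
    return k * spec.center_spacing_samples / spec.fs


def window_tags(centers: np.ndarray) -> np.ndarray:
    """Tag each window center as pre / pulse / post."""
    tags = np.where(centers < 0, "pre", "post").astype(object)
    tags[np.isclose(centers, 0.0)] = "pulse"
    return np.asarray(tags, dtype="U5")


@dataclass
class CrossSpectra:
    """Tapered per-trial spectra from which cross-spectra are formed.

    ``spectra`` has shape (n_tapers, n_trials, n_windows, n_freqs, n_regions);
    the single-taper Hanning default has n_tapers == 1.  The full Hermitian
    N x N cross-spectral matrix for one window/frequency/trial is the outer
    product of a spectrum row with its conjugate, averaged over tapers; use
    :meth:`trial_cross` to materialize it window by window (never all at
    once — that array would dwarf the spectra themselves).
    """

    spectra: np.ndarray
    freqs: np.ndarray
    centers: np.ndarray
    tags: np.ndarray
    spec: WindowSpec

    @property
    def n_trials(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_windows(self) -> int:
        return self.spectra.shape[2]

    @property
    def n_regions(self) -> int:
        return self.spectra.shape[4]

    def trial_cross(self, window: int, trials=slice(None)) -> np.ndarray:
        """Per-trial cross-spectral matrices for one window:
        shape (n_trials_selected, n_freqs, N, N), taper-averaged."""
        z = self.spectra[:, trials, window]  # (K, T, F, N)
        x = np.einsum("ktfa,ktfb->tfab", z, z.conj())
        return x / self.spectra.shape[0]


def cross_spectra(trials: TrialEnsemble, spec: WindowSpec) -> CrossSpectra:
    """Demean, taper and Fourier-transform every window of every trial.

    Segments are zero-padded (never data-padded) to ``spec.nfft`` so the DFT
    lands exactly on the requested frequency grid.  A window reaching past
    the recorded epoch raises; data are never zero-filled.
    """
    if trials.n_trials < 2:
        raise EstimatorUndefinedError("cross-trial estimation needs >= 2 trials")
    if abs(trials.fs - spec.fs) > 1e-9:
        raise InvalidConfigError(
            f"spec.fs={spec.fs} does not match ensemble fs={trials.fs}"
        )
    centers = window_centers(spec)
    tags = window_tags(centers)
    nwin = spec.n_window_samples
    half_lo = nwin // 2
    starts = (
        trials.pulse_index
        + np.round(centers * spec.fs).astype(int)
        - half_lo
    )
    if starts.min() < 0 or (starts.max() + nwin) > trials.n_samples:
        raise InvalidConfigError(
            "a window extends past the recorded epoch; extend the epoch or "
            "shrink retain_span/window_length"
        )

    if spec.taper == "hann":
        tapers = _windows.hann(nwin, sym=False)[None, :]
    else:
        n_tapers = max(int(2 * spec.dpss_nw - 1), 1)
        tapers = _windows.dpss(nwin, spec.dpss_nw, Kmax=n_tapers)

    freqs_all = np.fft.rfftfreq(spec.nfft, d=1.0 / spec.fs)
    keep = (freqs_all >= spec.freq_min - 1e-9) & (freqs_all <= spec.freq_max + 1e-9)

    # data: (N, S, T) -> segments (T, W, N, nwin)
    segs = np.empty((trials.n_trials, len(centers), trials.n_regions, nwin))
    for w, s0 in enumerate(starts):
        seg = trials.data[:, s0 : s0 + nwin, :]  # (N, nwin, T)
        segs[:, w] = np.moveaxis(seg, -1, 0)
    segs -= segs.mean(axis=-1, keepdims=True)

    k = tapers.shape[0]
    out = np.empty(
        (k, trials.n_trials, len(centers), int(keep.sum()), trials.n_regions),
        dtype=complex,
    )
    for ki in range(k):
        spec_full = np.fft.rfft(segs * tapers[ki], n=spec.nfft, axis=-1)
        out[ki] = np.moveaxis(spec_full[..., keep], -1, -2)  # (T, W, F, N)
    return CrossSpectra(
        spectra=out, freqs=freqs_all[keep], centers=centers, tags=tags, spec=spec
    )


@dataclass
class DwpliResult:
    """Per-window, per-frequency dwPLI matrices plus a degeneracy mask."""

    values: np.ndarray  # (W, F, N, N)
    degenerate: np.ndarray  # bool, same shape
    freqs: np.ndarray
    centers: np.ndarray
    tags: np.ndarray


def dwpli_from_imag(imag: np.ndarray, axis: int = 0):
    """dwPLI from per-trial imaginary cross-spectra along ``axis``.

    Returns ``(values, degenerate_mask)``.  Equivalent to the sum over all
    ordered trial pairs j != k of I_j I_k over |I_j I_k|.
    """
    s = imag.sum(axis=axis)
    q = (imag**2).sum(axis=axis)
    s_abs = np.abs(imag).sum(axis=axis)
    num = s**2 - q
    den = s_abs**2 - q
    degenerate = den <= 0.0
    values = np.divide(num, den, out=np.zeros_like(num), where=~degenerate)
    return values, degenerate


def dwpli(cs: CrossSpectra, trial_chunk: int = 32) -> DwpliResult:
    """Debiased weighted phase lag index across trials, per window/frequency.

    Trials are processed in chunks to bound the transient (T, F, N, N)
    cross-product arrays.
    """
    if cs.n_trials < 2:
        raise EstimatorUndefinedError("dwPLI needs >= 2 trials")
    w_n, f_n, n = cs.n_windows, len(cs.freqs), cs.n_regions
    values = np.empty((w_n, f_n, n, n))
    degenerate = np.empty((w_n, f_n, n, n), dtype=bool)
    for w in range(w_n):
        s = np.zeros((f_n, n, n))
        q = np.zeros((f_n, n, n))
        s_abs = np.zeros((f_n, n, n))
        for lo in range(0, cs.n_trials, trial_chunk):
            imag = cs.trial_cross(w, slice(lo, lo + trial_chunk)).imag
            s += imag.sum(axis=0)
            q += (imag**2).sum(axis=0)
            s_abs += np.abs(imag).sum(axis=0)
        num = s**2 - q
        den = s_abs**2 - q
        deg = den <= 0.0
        values[w] = np.divide(num, den, out=np.zeros_like(num), where=~deg)
        degenerate[w] = deg
    # the diagonal is self-coupling: identically degenerate (I_j == 0)
    return DwpliResult(
        values=values, degenerate=degenerate, freqs=cs.freqs,
        centers=cs.centers, tags=cs.tags,
    )


@dataclass
class ConnectivitySeries:
    """Layer-ordered band-averaged connectivity: one symmetric N x N matrix
    per retained window, tagged pre / pulse / post."""

    band: tuple[float, float]
    layers: np.ndarray  # (L, N, N)
    centers: np.ndarray
    tags: np.ndarray

    def __post_init__(self):
        n_pulse = (self.tags == "pulse").sum()
        if n_pulse > 1:
            raise InvalidConfigError("at most one layer may be tagged 'pulse'")
        has_pre = (self.tags == "pre").any()
        has_post = (self.tags == "post").any()
        if has_pre and has_post and n_pulse != 1:
            raise InvalidConfigError(
                "a full peri-pulse series must have exactly one 'pulse' layer"
            )
        if len(self.layers) != len(self.centers) or len(self.layers) != len(self.tags):
            raise InvalidConfigError("layers, centers and tags must align")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_regions(self) -> int:
        return self.layers.shape[1]

    def interval(self, tag: str) -> "ConnectivitySeries":
        """Restrict to the layers carrying one tag (e.g. the pre interval)."""
        keep = self.tags == tag
        return ConnectivitySeries(
            band=self.band,
            layers=self.layers[keep],
            centers=self.centers[keep],
            tags=self.tags[keep],
        )


def band_average(result: DwpliResult, band: tuple[float, float]) -> ConnectivitySeries:
    """Arithmetic mean of per-frequency dwPLI over bins inside the closed
    band, per window and pair."""
    lo, hi = band
    keep = (result.freqs >= lo - 1e-9) & (result.freqs <= hi + 1e-9)
    if not keep.any():
        raise InvalidConfigError(f"band {band} contains no frequency bins")
    layers = result.values[:, keep].mean(axis=1)
    layers = 0.5 * (layers + np.swapaxes(layers, 1, 2))  # enforce exact symmetry
    return ConnectivitySeries(
        band=(float(lo), float(hi)),
        layers=layers,
        centers=result.centers,
        tags=result.tags,
    )


def dwpli_series(
    trials: TrialEnsemble, spec: WindowSpec, band: tuple[float, float]
) -> ConnectivitySeries:
    """Full path: tapered cross-spectra -> dwPLI -> band average."""
    return band_average(dwpli(cross_spectra(trials, spec)), band)


def edge_change(series: ConnectivitySeries) -> np.ndarray:
    """Per-edge post-minus-pre connectivity change: mean over post-tagged
    layers minus mean over pre-tagged layers, pulse layer excluded.
    Returns an (N, N) matrix (diagonal meaningless)."""
    pre = series.tags == "pre"
    post = series.tags == "post"
    if pre.sum() == 0 or post.sum() == 0:
        raise InvalidConfigError("series needs both pre and post layers")
    if pre.sum() != post.sum():
        raise InvalidConfigError(
            f"mismatched layer counts: {pre.sum()} pre vs {post.sum()} post"
        )
    return series.layers[post].mean(axis=0) - series.layers[pre].mean(axis=0)


class SlidingWindowDWPLI(BaseEstimator, TransformerMixin):
    """Transformer from a :class:`TrialEnsemble` to a band-averaged
    :class:`ConnectivitySeries`.

    Parameters mirror :class:`WindowSpec`; ``band`` selects the closed
    frequency band averaged after per-frequency estimation.  ``fit`` only
    validates; ``transform`` performs the estimation.
    """

    def __init__(
        self,
        band=(8.0, 12.0),
        center_spacing_samples: int = 5,
        window_length: float = 0.5,
        taper: str = "hann",
        freq_min: float = 2.0,
        freq_max: float = 25.0,
        freq_step: float = 0.5,
        retain_span: float = 1.0,
    ):
        self.band = band
        self.center_spacing_samples = center_spacing_samples
        self.window_length = window_length
        self.taper = taper
        self.freq_min = freq_min
        self.freq_max = freq_max
        self.freq_step = freq_step
        self.retain_span = retain_span

    def _spec(self, X: TrialEnsemble) -> WindowSpec:
        t0 = -X.pulse_index / X.fs
        t1 = (X.n_samples - 1 - X.pulse_index) / X.fs
        return WindowSpec(
            fs=X.fs,
            epoch_span=(t0, t1),
            center_spacing_samples=self.center_spacing_samples,
            window_length=self.window_length,
            taper=self.taper,
            freq_min=self.freq_min,
            freq_max=self.freq_max,
            freq_step=self.freq_step,
            retain_span=self.retain_span,
        )

    def fit(self, X: TrialEnsemble, y=None):
        spec = self._spec(X)
        self.window_spec_ = spec
        self.centers_ = window_centers(spec)
        self.n_windows_ = len(self.centers_)
        return self

    def transform(self, X: TrialEnsemble) -> ConnectivitySeries:
        if not hasattr(self, "window_spec_"):
            self.fit(X)
        return dwpli_series(X, self._spec(X), tuple(self.band))
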