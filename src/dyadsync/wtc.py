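"""Morlet wavelet transform coherence (WTC) between paired signals.

Implements the continuous Morlet wavelet transform on a geometric scale grid
(FFT-based, Torrence & Compo normalisation), the squared wavelet coherence

    r^2(t, s) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

with the standard smoothing operator S — a scale-matched Gaussian in time
(std = s) followed by a boxcar over 0.6 octave in scale — and the
frequency-band-of-interest (FOI) average that reduces the time-scale field to
one scalar per signal pair.  Without smoothing the coherence is identically 1,
so an unsmoothed computation is refused.

The cone of influence (COI) is the e-folding boundary sqrt(2)*s of the Morlet
wavelet; points at periods longer than the local COI can be excluded from the
FOI average (default) or included, matching the convention of common WTC
toolboxes.

For permutation analyses over many signal pairs, `CwtCache` precomputes each
signal's transform and smoothed auto-spectrum so that each extra pair costs
only one cross-spectrum smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

DEFAULT_FOI = (0.02, 0.1)  # Hz; periods 10-50 s


@dataclass
class WaveletSpec:
    """Morlet CWT configuration.

    omega0 is the nondimensional centre frequency (>= 5 for the analytic
    approximation to hold); the scale grid is geometric with
    ``scales_per_octave`` voices, spanning [min_period, max_period] seconds.
    """

    omega0: float = 6.0
    scales_per_octave: int = 12
    min_period: float | None = None   # default: 2*dt
    max_period: float | None = None   # default: N*dt/2
    smooth: bool = True
    scale_smooth_octaves: float = 0.6

    def __post_init__(self):
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 (Morlet admissibility)")
        if self.scales_per_octave < 1:
            raise ValueError("scales_per_octave must be >= 1")

    @property
    def fourier_factor(self) -> float:
        """Ratio of Fourier period to scale for the Morlet wavelet."""
        return 4 * np.pi / (self.omega0 + np.sqrt(2 + self.omega0 ** 2))


@dataclass
class CoherenceField:
    """Squared coherence on the time x scale plane."""

    r_squared: np.ndarray       # (n_scales, n_times), in [0, 1]
    periods: np.ndarray         # seconds, per scale
    times: np.ndarray           # seconds
    coi: np.ndarray             # max valid period (s) per time point

    def __post_init__(self):
        if np.any(self.r_squared < -1e-9) or np.any(self.r_squared > 1 + 1e-9):
            raise ValueError("coherence must lie in [0, 1]")


@dataclass
class CoherenceSummary:
    """FOI-averaged coherence for one dyad x region x chromophore."""

    coherence: float
    foi: tuple[float, float] = DEFAULT_FOI
    coi_policy: str = "exclude"
    dyad_id: str = ""
    region: str = ""
    chromophore: str = ""

    def __post_init__(self):
        if not 0 <= self.coherence <= 1:
            raise ValueError("FOI-averaged coherence must lie in [0, 1]")


def _scale_grid(n: int, dt: float, spec: WaveletSpec):
    min_p = spec.min_period if spec.min_period is not None else 2 * dt
    max_p = spec.max_period if spec.max_period is not None else n * dt / 2
    if max_p <= min_p:
        raise ValueError("max_period must exceed min_period")
    s0 = min_p / spec.fourier_factor
    n_octaves = np.log2(max_p / min_p)
    j = np.arange(int(np.floor(n_octaves * spec.scales_per_octave)) + 1)
    scales = s0 * 2.0 ** (j / spec.scales_per_octave)
    return scales


def _prepare(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("input contains NaN/inf; handle gaps upstream")
    x = sps.detrend(x, type="linear")
    sd = x.std()
    return x / sd if sd > 0 else x


def cwt_morlet(x: np.ndarray, dt: float = 1.0, spec: WaveletSpec | None = None):
    """Continuous Morlet transform of a 1-D signal.

    The signal is linearly detrended and variance-normalised (coherence is
    scale-free; detrending stabilises edge behaviour).  Returns
    (W, scales, periods, coi) where W has shape (n_scales, n) and coi is the
    e-folding period boundary in seconds per time point.
    """
    spec = spec or WaveletSpec()
    x = _prepare(x)
    n = len(x)
    if n < 32:
        raise ValueError("need at least 32 samples")
    scales = _scale_grid(n, dt, spec)
    npad = int(2 ** np.ceil(np.log2(2 * n)))
    xhat = np.fft.fft(x, npad)
    omega = 2 * np.pi * np.fft.fftfreq(npad, d=dt)
    # Morlet daughter in frequency domain, positive frequencies only
    arg = scales[:, None] * omega[None, :] - spec.omega0
    psi_hat = (np.pi ** -0.25) * np.sqrt(2 * np.pi * scales[:, None] / dt) \
        * np.exp(-0.5 * arg ** 2) * (omega[None, :] > 0)
    W = np.fft.ifft(xhat[None, :] * psi_hat, axis=1)[:, :n]
    periods = scales * spec.fourier_factor
    dist = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi = spec.fourier_factor / np.sqrt(2) * np.maximum(dist, dt * 1e-9)
    return W, scales, periods, coi


def _smooth(field: np.ndarray, scales: np.ndarray, dt: float,
            spec: WaveletSpec) -> np.ndarray:
    """Smoothing operator S: Gaussian in time (std = scale), boxcar in scale.

    Time smoothing is done by zero-padded FFT convolution with the analytic
    Gaussian transfer function exp(-0.5 (s*omega)^2), vectorised over scales.
    """
    n_scales, n = field.shape
    npad = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2 * np.pi * np.fft.fftfreq(npad, d=dt)
    gauss = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)
    fhat = np.fft.fft(field, npad, axis=1)
    out = np.fft.ifft(fhat * gauss, axis=1)[:, :n]
    if not np.iscomplexobj(field):
        out = out.real
    width = max(1, int(round(spec.scale_smooth_octaves * spec.scales_per_octave)))
    if width > 1:
        if np.iscomplexobj(out):
            out = (uniform_filter1d(out.real, width, axis=0, mode="nearest")
                   + 1j * uniform_filter1d(out.imag, width, axis=0, mode="nearest"))
        else:
            out = uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


class CwtCache:
    """Cached transform + smoothed auto-spectrum of one signal.

    Amortises the per-signal cost when the same signal enters many coherence
    computations (the random-pairing control computes O(n^2) pairs).
    """

    def __init__(self, x: np.ndarray, dt: float = 1.0, spec: WaveletSpec | None = None):
        self.spec = spec or WaveletSpec()
        if not self.spec.smooth:
            raise ValueError("unsmoothed coherence is identically 1; refusing")
        self.dt = dt
        self.W, self.scales, self.periods, self.coi = cwt_morlet(x, dt, self.spec)
        self.auto = np.maximum(
            _smooth(np.abs(self.W) ** 2 / self.scales[:, None], self.scales, dt, self.spec),
            1e-300)
        self.times = np.arange(self.W.shape[1]) * dt


def coherence_from_caches(cx: CwtCache, cy: CwtCache) -> CoherenceField:
    if cx.W.shape != cy.W.shape:
        raise ValueError("paired signals must have equal length and spec")
    cross = _smooth(cx.W * np.conj(cy.W) / cx.scales[:, None], cx.scales, cx.dt, cx.spec)
    r2 = np.abs(cross) ** 2 / (cx.auto * cy.auto)
    r2 = np.clip(r2, 0.0, 1.0)
    return CoherenceField(r_squared=r2, periods=cx.periods, times=cx.times, coi=cx.coi)


def wavelet_coherence(x: np.ndarray, y: np.ndarray, dt: float = 1.0,
                      spec: WaveletSpec | None = None) -> CoherenceField:
    """Squared wavelet coherence between two equal-length signals.

    Coherence is symmetric by definition; arguments are canonically ordered
    internally so that coherence(x, y) and coherence(y, x) are bit-identical.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.tobytes() > y.tobytes():
        x, y = y, x
    return coherence_from_caches(CwtCache(x, dt, spec), CwtCache(y, dt, spec))


def average_foi(fieldv: CoherenceField, foi: tuple[float, float] = DEFAULT_FOI,
                coi_policy: str = "exclude", **ids) -> CoherenceSummary:
    """Mean squared coherence over the FOI band and all task time points.

    ``foi`` is in Hz; the selected periods are [1/foi_high, 1/foi_low]
    seconds.  With ``coi_policy='exclude'`` (default) points lying under the
    cone of influence are dropped before averaging; 'include' keeps them.
    """
    lo_hz, hi_hz = foi
    if not 0 < lo_hz < hi_hz:
        raise ValueError("FOI must satisfy 0 < low < high")
    if coi_policy not in ("exclude", "include"):
        raise ValueError("coi_policy must be 'exclude' or 'include'")
    p_lo, p_hi = 1.0 / hi_hz, 1.0 / lo_hz
    in_band = (fieldv.periods >= p_lo) & (fieldv.periods <= p_hi)
    if not in_band.any():
        raise ValueError("FOI selects no scales on this grid")
    sub = fieldv.r_squared[in_band, :]
    if coi_policy == "exclude":
        mask = fieldv.periods[in_band][:, None] <= fieldv.coi[None, :]
        if not mask.any():
            raise ValueError("COI excludes the entire FOI; series too short")
        value = float(sub[mask].mean())
    else:
        value = float(sub.mean())
    return CoherenceSummary(coherence=value, foi=foi, coi_policy=coi_policy, **ids)


def dyad_coherence(x: np.ndarray, y: np.ndarray, dt: float = 1.0,
                   spec: WaveletSpec | None = None,
                   foi: tuple[float, float] = DEFAULT_FOI,
                   coi_policy: str = "exclude", **ids) -> CoherenceSummary:
    """Convenience: FOI-averaged squared coherence of one signal pair."""
    return average_foi(wavelet_coherence(x, y, dt, spec), foi, coi_policy, **ids)


def coherence_matrix(xs: list[np.ndarray], ys: list[np.ndarray], dt: float = 1.0,
                     spec: WaveletSpec | None = None,
                     foi: tuple[float, float] = DEFAULT_FOI,
                     coi_policy: str = "exclude",
                     pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
    """FOI-averaged coherence for pairs (i, j) of xs[i] with ys[j].

    With ``pairs=None`` the full matrix is computed.  Transforms are cached
    per signal, so cost scales with n_signals + n_pairs rather than 2*n_pairs.
    Unrequested entries are NaN.
    """
    spec = spec or WaveletSpec()
    cx = [CwtCache(x, dt, spec) for x in xs]
    cy = [CwtCache(y, dt, spec) for y in ys]
    out = np.full((len(xs), len(ys)), np.nan)
    if pairs is None:
        pairs = [(i, j) for i in range(len(xs)) for j in range(len(ys))]
    for i, j in set(pairs):
        fieldv = coherence_from_caches(cx[i], cy[j])
        out[i, j] = average_foi(fieldv, foi, coi_policy).coherence
    return out
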