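"""Respiratory sinus arrhythmia (RSA) from interbeat intervals.

The cardiac branch of the pipeline: automated beat-artifact correction,
resampling of the irregular interbeat-interval (IBI) series to a uniform grid,
respiratory-band filtering, a continuous RSA estimate (natural log of the
IBI variance in a 15-s sliding window, emitted at 1 Hz), 29-sample epoch
means (~30-s epochs; a 300-s task yields exactly 10 epochs), and the baseline
reference value (mean of the last 29 baseline samples).

Frequency bands default to standard psychophysiology conventions:
0.12-0.40 Hz for adults (mothers) and 0.24-1.04 Hz for young children.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

ADULT_BAND = (0.12, 0.40)
CHILD_BAND = (0.24, 1.04)
DEFAULT_WINDOW_S = 15.0
DEFAULT_BLOCK = 29
VARIANCE_FLOOR = 1e-6  # ms^2; keeps ln() finite on silent input


class UnusableSeriesError(ValueError):
    """Raised when a beat series fails quality control."""


@dataclass
class IbiSeries:
    """Heartbeat series: strictly increasing beat times in seconds.

    ``ibis`` (ms) are the first differences of the beat times; segment
    boundaries (e.g. baseline vs task) are carried as half-open time windows.
    """

    beat_times: np.ndarray
    person_id: str = ""
    dyad_id: str = ""
    role: str = ""
    segments: dict = field(default_factory=dict)
    usable: bool = True
    n_corrected: int = 0

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1 or len(self.beat_times) < 2:
            raise ValueError("need at least two beat times")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def ibis(self) -> np.ndarray:
        """Interbeat intervals in milliseconds."""
        return np.diff(self.beat_times) * 1000.0

    def segment(self, name: str) -> "IbiSeries":
        t0, t1 = self.segments[name]
        keep = (self.beat_times >= t0) & (self.beat_times <= t1)
        return replace(self, beat_times=self.beat_times[keep], segments={name: (t0, t1)})


@dataclass
class RsaSeries:
    """Continuous RSA: ln(windowed IBI variance in ms^2) sampled at 1 Hz."""

    values: np.ndarray
    timestamps: np.ndarray
    window: float = DEFAULT_WINDOW_S
    variance_floor: float = VARIANCE_FLOOR

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.values) != len(self.timestamps):
            raise ValueError("values and timestamps must align")
        if len(self.timestamps) > 1 and not np.allclose(np.diff(self.timestamps), 1.0):
            raise ValueError("RSA series must be sampled at exactly 1 Hz")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RSA values must be finite (variance floor applies)")


@dataclass
class RsaEpochs:
    """Non-overlapping epoch means of a 1 Hz RSA series plus baseline reference."""

    epoch_means: np.ndarray
    block: int = DEFAULT_BLOCK
    baseline_reference: float = np.nan

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_means)


def correct_ibi_artifacts(ibi: IbiSeries, threshold_pct: float = 0.30,
                          max_flagged: float = 0.20) -> IbiSeries:
    """Automated beat editing: merge spuriously short beats, split long ones.

    An IBI deviating more than ``threshold_pct`` from the running median of its
    9 neighbours is corrected: a short beat is merged with its successor, a
    long beat split into ``round(ibi/median)`` equal beats.  Total elapsed time
    is conserved exactly (beat endpoints are never moved).  If more than
    ``max_flagged`` of beats are flagged the series is marked unusable,
    mirroring dyads dropped for unreliable physiological data.
    """
    ibis_ms = ibi.ibis
    n = len(ibis_ms)
    if n < 10:
        raise ValueError("need at least 10 beats for artifact correction")
    med = sps.medfilt(ibis_ms, kernel_size=9)
    # medfilt zero-pads the edges; fall back to the global median there
    edge = 4
    gmed = np.median(ibis_ms)
    med[:edge] = np.median(ibis_ms[:edge + 5]) if n > edge + 5 else gmed
    med[-edge:] = np.median(ibis_ms[-edge - 5:]) if n > edge + 5 else gmed

    dev = np.abs(ibis_ms - med) / med
    flagged = dev > threshold_pct
    n_flagged = int(flagged.sum())
    out = replace(ibi, n_corrected=n_flagged)
    if n_flagged / n > max_flagged:
        out.usable = False
        return out
    if n_flagged == 0:
        return out

    times = list(ibi.beat_times)
    new_times = [times[0]]
    i = 0
    while i < n:
        t_next = times[i + 1]
        if not flagged[i]:
            new_times.append(t_next)
            i += 1
            continue
        if ibis_ms[i] > med[i]:
            # long interval: split into k equal beats
            k = max(2, int(round(ibis_ms[i] / med[i])))
            t_prev = new_times[-1]
            for j in range(1, k):
                new_times.append(t_prev + (t_next - t_prev) * j / k)
            new_times.append(t_next)
            i += 1
        else:
            # short interval: merge with successor (drop the middle beat)
            if i + 2 <= n:
                new_times.append(times[min(i + 2, n)])
                i += 2
            else:
                new_times.append(t_next)
                i += 1
    out = replace(ibi, beat_times=np.asarray(new_times), n_corrected=n_flagged)
    return out


def ibi_to_uniform(ibi: IbiSeries, rate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of the IBI series onto a uniform grid.

    Each IBI is anchored at its ending beat time.  Returns (times_s, ibi_ms).
    """
    if not ibi.usable:
        raise UnusableSeriesError(f"series {ibi.person_id} marked unusable")
    anchor = ibi.beat_times[1:]
    values = ibi.ibis
    if len(anchor) < 4:
        raise ValueError("too few beats to interpolate")
    span = anchor[-1] - anchor[0]
    if span < 2.0 / rate:
        raise ValueError("series span shorter than two output samples")
    t = np.arange(np.ceil(anchor[0] * rate), np.floor(anchor[-1] * rate) + 1) / rate
    cs = CubicSpline(anchor, values)
    return t, cs(t)


def bandpass_respiratory(values: np.ndarray, rate: float,
                         band: tuple[float, float] = ADULT_BAND,
                         order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass isolating the respiratory band."""
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < low < high")
    if hi >= rate / 2:
        raise ValueError(f"band upper edge {hi} Hz at/above Nyquist ({rate / 2} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(values, dtype=float) - np.mean(values))


def continuous_rsa(filtered: np.ndarray, rate: float, times: np.ndarray | None = None,
                   window: float = DEFAULT_WINDOW_S, out_rate: float = 1.0,
                   variance_floor: float = VARIANCE_FLOOR) -> RsaSeries:
    """ln variance of the band-passed heart-period series in a sliding window.

    The window is centred on each 1 Hz output time; the first/last half-window
    use truncated windows so the output covers the full recording (a 300-s
    task keeps all 300 samples, which the 29-sample epoching relies on).
    """
    x = np.asarray(filtered, dtype=float)
    if times is None:
        times = np.arange(len(x)) / rate
    times = np.asarray(times, dtype=float)
    if times[-1] - times[0] + 1 / rate < window:
        raise ValueError("series shorter than the sliding window")
    half = window / 2.0
    t_out = np.arange(np.ceil(times[0]), np.floor(times[-1]) + 1, 1.0 / out_rate)
    # half-open centered window [t - w/2, t + w/2)
    lo = np.searchsorted(times, t_out - half, side="left")
    hi = np.searchsorted(times, t_out + half, side="left")
    vals = np.empty(len(t_out))
    for i, (a, b) in enumerate(zip(lo, hi)):
        v = np.var(x[a:b]) if b - a > 1 else 0.0
        vals[i] = np.log(max(v, variance_floor))
    return RsaSeries(values=vals, timestamps=t_out, window=window,
                     variance_floor=variance_floor)


def epoch_rsa(rsa: RsaSeries | np.ndarray, block: int = DEFAULT_BLOCK) -> RsaEpochs:
    """Average consecutive complete blocks of ``block`` samples; drop the tail."""
    values = rsa.values if isinstance(rsa, RsaSeries) else np.asarray(rsa, dtype=float)
    if block < 1:
        raise ValueError("block must be >= 1")
    n_blocks = len(values) // block
    if n_blocks < 1:
        raise ValueError(f"fewer than one block of {block} samples")
    means = values[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return RsaEpochs(epoch_means=means, block=block)


def baseline_reference(rsa_baseline: RsaSeries | np.ndarray,
                       n_last: int = DEFAULT_BLOCK) -> float:
    """Mean of the final ``n_last`` baseline RSA samples (the reference point)."""
    values = (rsa_baseline.values if isinstance(rsa_baseline, RsaSeries)
              else np.asarray(rsa_baseline, dtype=float))
    if len(values) < n_last:
        raise ValueError(f"baseline has {len(values)} samples; need >= {n_last}")
    return float(np.mean(values[-n_last:]))


def ibi_to_rsa_epochs(ibi: IbiSeries, band: tuple[float, float],
                      baseline_segment: str = "baseline", task_segment: str = "task",
                      rate: float = 4.0, window: float = DEFAULT_WINDOW_S,
                      block: int = DEFAULT_BLOCK,
                      artifact_threshold: float = 0.30) -> RsaEpochs:
    """Full cardiac branch for one person: IBI -> corrected -> RSA epochs.

    Runs artifact correction once over the whole recording, computes the 1 Hz
    continuous RSA per segment, epochs the task segment and takes the baseline
    reference from the last 29 baseline samples.
    """
    corrected = correct_ibi_artifacts(ibi, artifact_threshold)
    if not corrected.usable:
        raise UnusableSeriesError(
            f"{ibi.role} {ibi.person_id}: >20% of beats flagged, unusable")

    def _segment_rsa(name):
        seg = corrected.segment(name)
        t, u = ibi_to_uniform(seg, rate)
        filt = bandpass_respiratory(u, rate, band)
        return continuous_rsa(filt, rate, times=t, window=window)

    rsa_base = _segment_rsa(baseline_segment)
    rsa_task = _segment_rsa(task_segment)
    epochs = epoch_rsa(rsa_task, block)
    epochs.baseline_reference = baseline_reference(rsa_base)
    return epochs
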