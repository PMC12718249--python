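"""fNIRS preprocessing: raw two-wavelength intensities to region-level
hemoglobin series at 1 Hz.

Pipeline order (enforced): intensity -> optical density -> channel pruning ->
spline motion correction -> wavelet motion correction -> modified
Beer-Lambert conversion to HbO/HbR/HbT -> band-pass -> downsample to 1 Hz ->
region aggregation (left/right dlPFC, 4 channels each).

Quality control: a channel is unusable if its raw-intensity coefficient of
variation exceeds ``cv_threshold`` (default 15%) or more than
``flat_threshold`` (default 5%) of samples are flat; a region with fewer than
2 usable channels invalidates that person's region, and a dyad with any
invalid region is excluded from the neural analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.interpolate import UnivariateSpline

from . import optics

SAMPLING_RATE = 7.81  # Hz
REGIONS = ("left_dlPFC", "right_dlPFC")
CHROMOPHORES = ("HbO", "HbR", "HbT")
DEFAULT_DISTANCE_CM = 3.0
DEFAULT_CV_THRESHOLD = 15.0     # percent
DEFAULT_FLAT_THRESHOLD = 0.05   # proportion
DEFAULT_HEMO_BAND = (0.01, 0.5)  # Hz, deliberately wide; FOI does the narrowing


class PipelineOrderError(RuntimeError):
    """Raised when a preprocessing stage is re-run or run out of order."""


def _check_stage(history: list[str], stage: str, requires: str | None = None):
    if stage in history:
        raise PipelineOrderError(f"stage '{stage}' already applied: {history}")
    if requires is not None and requires not in history:
        raise PipelineOrderError(f"stage '{stage}' requires '{requires}' first")


@dataclass
class IntensityRecording:
    """Raw light intensities, shape (n_channels, n_wavelengths, n_times)."""

    samples: np.ndarray
    rate: float = SAMPLING_RATE
    wavelengths: tuple = optics.DEFAULT_WAVELENGTHS
    channel_regions: tuple = ("left_dlPFC",) * 4 + ("right_dlPFC",) * 4
    distance_cm: float = DEFAULT_DISTANCE_CM
    age_years: float = 30.0
    person_id: str = ""
    role: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[1] != len(self.wavelengths):
            raise ValueError("samples must be (channels, wavelengths, times)")
        if len(self.channel_regions) != self.samples.shape[0]:
            raise ValueError("channel_regions must name every channel")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class OdRecording:
    """Optical density relative to each channel's temporal mean intensity."""

    od: np.ndarray                       # (channels, wavelengths, times)
    reference_intensity: np.ndarray      # (channels, wavelengths)
    rate: float
    wavelengths: tuple
    channel_regions: tuple
    distance_cm: float
    age_years: float
    person_id: str = ""
    role: str = ""
    history: list = field(default_factory=lambda: ["od"])
    quality: "pd.DataFrame | None" = None


@dataclass
class HemoRecording:
    """Hemoglobin concentration changes (µM), HbT = HbO + HbR by construction."""

    hbo: np.ndarray                      # (channels, times)
    hbr: np.ndarray
    rate: float
    channel_regions: tuple
    quality_mask: np.ndarray             # (channels,) bool, True = usable
    person_id: str = ""
    role: str = ""
    history: list = field(default_factory=list)
    region_series: "pd.DataFrame | None" = None

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr


def intensity_to_od(rec: IntensityRecording) -> OdRecording:
    """OD(t) = -ln(I(t) / mean(I)), per channel and wavelength."""
    if np.any(rec.samples <= 0):
        ch = int(np.argwhere(np.any(rec.samples <= 0, axis=(1, 2)))[0][0])
        raise ValueError(f"nonpositive intensity in channel {ch}")
    ref = rec.samples.mean(axis=2)
    od = -np.log(rec.samples / ref[:, :, None])
    return OdRecording(od=od, reference_intensity=ref, rate=rec.rate,
                       wavelengths=rec.wavelengths, channel_regions=rec.channel_regions,
                       distance_cm=rec.distance_cm, age_years=rec.age_years,
                       person_id=rec.person_id, role=rec.role)


def prune_channels(od: OdRecording, cv_threshold: float = DEFAULT_CV_THRESHOLD,
                   flat_threshold: float = DEFAULT_FLAT_THRESHOLD) -> pd.DataFrame:
    """Signal-integrity QC per channel: intensity CV and flatline fraction.

    Returns a table (channel, region, cv_pct, flatline_fraction, usable,
    reason) and stores it on the recording.  A channel fails if the raw
    intensity CV at either wavelength exceeds ``cv_threshold`` percent or if
    more than ``flat_threshold`` of successive samples are unchanged.
    """
    n_times = od.od.shape[2]
    if n_times / od.rate < 30:
        raise ValueError("need at least 30 s of data for channel QC")
    intens = od.reference_intensity[:, :, None] * np.exp(-od.od)
    cv = 100.0 * intens.std(axis=2) / intens.mean(axis=2)       # (ch, wl)
    dif = np.abs(np.diff(intens, axis=2))
    scale = np.maximum(intens.std(axis=2, keepdims=True), 1e-30)
    flat = (dif < 1e-9 * scale).mean(axis=2)                    # (ch, wl)
    rows = []
    for ch in range(od.od.shape[0]):
        cv_ch = float(cv[ch].max())
        flat_ch = float(flat[ch].max())
        reason = ""
        if cv_ch > cv_threshold:
            reason = f"cv {cv_ch:.1f}% > {cv_threshold}%"
        elif flat_ch > flat_threshold:
            reason = f"flatline {flat_ch:.2f} > {flat_threshold}"
        rows.append(dict(channel=ch, region=od.channel_regions[ch], cv_pct=cv_ch,
                         flatline_fraction=flat_ch, usable=reason == "", reason=reason))
    quality = pd.DataFrame(rows)
    od.quality = quality
    if "prune" not in od.history:
        od.history.append("prune")
    return quality


def region_validity(quality: pd.DataFrame, min_channels: int = 2) -> dict:
    """Region usable iff it retains >= min_channels usable channels."""
    return {region: int(grp["usable"].sum()) >= min_channels
            for region, grp in quality.groupby("region")}


def _flag_motion(x: np.ndarray, rate: float, window_s: float, k: float) -> np.ndarray:
    """Boolean mask of samples whose moving SD exceeds k x its median."""
    w = max(3, int(round(window_s * rate)))
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    c1 = np.convolve(xp, np.ones(w) / w, mode="valid")
    c2 = np.convolve(xp ** 2, np.ones(w) / w, mode="valid")
    msd = np.sqrt(np.maximum(c2 - c1 ** 2, 0.0))[: len(x)]
    med = np.median(msd)
    if med <= 0:
        med = msd.mean() if msd.mean() > 0 else 1.0
    return msd > k * med


def spline_motion_correct(od: OdRecording, detect_window: float = 1.0,
                          detect_k: float = 5.0) -> OdRecording:
    """Spline-interpolation motion correction (MARA-style).

    Flags motion segments by a moving-SD criterion and subtracts each flagged
    segment's smooth cubic-spline trend.  Spike segments are bridged between
    their clean neighbours without touching the rest of the series; when the
    level jump across a segment is large relative to the channel's baseline
    noise (a step artifact), the segment and all subsequent data are
    re-levelled to the pre-segment baseline.  A channel flagged in its
    entirety is marked unusable.
    """
    _check_stage(od.history, "spline", requires="prune")
    out = od.od.copy()
    n_ch, n_wl, n_t = out.shape
    for ch in range(n_ch):
        for wl in range(n_wl):
            x = out[ch, wl]
            mask = _flag_motion(x, od.rate, detect_window, detect_k)
            if not mask.any():
                continue
            if mask.all():
                if od.quality is not None:
                    od.quality.loc[od.quality.channel == ch, ["usable", "reason"]] = \
                        [False, "entire channel motion-flagged"]
                continue
            corrected = x.astype(float).copy()
            clean_sd = max(float(np.std(np.diff(x[~mask]))), 1e-12)
            w = max(3, int(round(detect_window * od.rate)))
            for a, b in _contiguous(mask):
                seg = corrected[a:b].copy()
                t = np.arange(b - a, dtype=float)
                if b - a >= 4:
                    spl = UnivariateSpline(t, seg, k=3,
                                           s=len(seg) * np.var(seg) * 0.01)
                    trend = spl(t)
                else:
                    trend = np.full(b - a, seg.mean())
                resid = seg - trend
                before = corrected[max(0, a - w):a]
                after = corrected[b:b + w]
                lv_before = np.median(before) if len(before) else seg[0]
                lv_after = np.median(after) if len(after) else seg[-1]
                jump = lv_after - lv_before
                if abs(jump) > 5 * clean_sd and b < n_t:
                    # step artifact: flatten the segment at the pre-step level
                    # and pull everything after it back down
                    corrected[a:b] = lv_before + resid - np.mean(resid)
                    corrected[b:] -= jump
                else:
                    # spike: bridge between the clean neighbours, keep the
                    # detrended residual texture, leave the tail untouched
                    bridge = np.linspace(lv_before, lv_after, b - a + 2)[1:-1]
                    detr = resid - np.linspace(resid[0], resid[-1], b - a)
                    corrected[a:b] = bridge + detr
            out[ch, wl] = corrected
    new = OdRecording(od=out, reference_intensity=od.reference_intensity, rate=od.rate,
                      wavelengths=od.wavelengths, channel_regions=od.channel_regions,
                      distance_cm=od.distance_cm, age_years=od.age_years,
                      person_id=od.person_id, role=od.role,
                      history=od.history + ["spline"], quality=od.quality)
    return new


def _contiguous(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    return list(zip(starts, ends))


def wavelet_motion_correct(od: OdRecording, iqr_k: float = 1.5,
                           wavelet: str = "db4") -> OdRecording:
    """Wavelet-based artifact attenuation.

    Per channel and wavelength: discrete wavelet decomposition; detail
    coefficients lying more than ``iqr_k`` x IQR beyond the quartiles are set
    to zero; the signal is reconstructed.  Series shorter than 64 samples are
    passed through unchanged.
    """
    _check_stage(od.history, "wavelet", requires="spline")
    out = od.od.copy()
    n_ch, n_wl, n_t = out.shape
    if n_t >= 64:
        for ch in range(n_ch):
            for wl in range(n_wl):
                coeffs = pywt.wavedec(out[ch, wl], wavelet, mode="symmetric")
                for d in coeffs[1:]:
                    q1, q3 = np.percentile(d, [25, 75])
                    iqr = q3 - q1
                    bad = (d < q1 - iqr_k * iqr) | (d > q3 + iqr_k * iqr)
                    d[bad] = 0.0
                rec = pywt.waverec(coeffs, wavelet, mode="symmetric")
                out[ch, wl] = rec[:n_t]
    return OdRecording(od=out, reference_intensity=od.reference_intensity, rate=od.rate,
                       wavelengths=od.wavelengths, channel_regions=od.channel_regions,
                       distance_cm=od.distance_cm, age_years=od.age_years,
                       person_id=od.person_id, role=od.role,
                       history=od.history + ["wavelet"], quality=od.quality)


def od_to_hemoglobin(od: OdRecording, dpf: tuple[float, float] | None = None,
                     distance_cm: float | None = None) -> HemoRecording:
    """Modified Beer-Lambert inversion to HbO/HbR concentration changes (µM).

    ``dpf`` overrides the age-formula differential pathlength factors;
    HbT = HbO + HbR is available as a property.
    """
    _check_stage(od.history, "mbll", requires="od")
    d = distance_cm if distance_cm is not None else od.distance_cm
    if dpf is not None:
        e = optics.extinction_matrix(od.wavelengths)
        ell = d * np.asarray(dpf, dtype=float)
        inv = np.linalg.inv(e * ell[:, None])
        conc = np.einsum("cw,kwt->ckt", inv, od.od) * 1e6
        hbo, hbr = conc[0], conc[1]
    else:
        hbo, hbr = optics.mbll_inverse(np.moveaxis(od.od, 1, 0), d, od.age_years,
                                       od.wavelengths)
    mask = (np.ones(od.od.shape[0], dtype=bool) if od.quality is None
            else od.quality.sort_values("channel")["usable"].to_numpy())
    return HemoRecording(hbo=hbo, hbr=hbr, rate=od.rate,
                         channel_regions=od.channel_regions, quality_mask=mask,
                         person_id=od.person_id, role=od.role,
                         history=od.history + ["mbll"])


def bandpass_hemo(hemo: HemoRecording, band: tuple[float, float] = DEFAULT_HEMO_BAND,
                  order: int = 3) -> HemoRecording:
    """Zero-phase Butterworth band-pass of every channel's HbO and HbR."""
    _check_stage(hemo.history, "bandpass", requires="mbll")
    lo, hi = band
    if not 0 < lo < hi or hi >= hemo.rate / 2:
        raise ValueError(f"band {band} invalid at rate {hemo.rate} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=hemo.rate, output="sos")
    return HemoRecording(hbo=sps.sosfiltfilt(sos, hemo.hbo, axis=1),
                         hbr=sps.sosfiltfilt(sos, hemo.hbr, axis=1),
                         rate=hemo.rate, channel_regions=hemo.channel_regions,
                         quality_mask=hemo.quality_mask, person_id=hemo.person_id,
                         role=hemo.role, history=hemo.history + ["bandpass"])


def downsample_hemo(hemo: HemoRecording, target: float = 1.0) -> HemoRecording:
    """Anti-aliased resampling to ``target`` Hz (7.81 -> 1 Hz by default).

    Low-pass at 0.4 x target, then interpolate onto the exact target grid
    (the 7.81/1 ratio is non-integer, so decimation alone cannot land on it).
    """
    _check_stage(hemo.history, "downsample", requires="bandpass")
    if target >= hemo.rate:
        raise ValueError("target rate must be below the input rate")
    sos = sps.butter(4, 0.4 * target, btype="lowpass", fs=hemo.rate, output="sos")
    t_in = np.arange(hemo.hbo.shape[1]) / hemo.rate
    t_out = np.arange(0.0, t_in[-1] + 1e-9, 1.0 / target)

    def _res(x):
        xf = sps.sosfiltfilt(sos, x, axis=1)
        return np.stack([np.interp(t_out, t_in, row) for row in xf])

    return HemoRecording(hbo=_res(hemo.hbo), hbr=_res(hemo.hbr), rate=target,
                         channel_regions=hemo.channel_regions,
                         quality_mask=hemo.quality_mask, person_id=hemo.person_id,
                         role=hemo.role, history=hemo.history + ["downsample"])


def aggregate_region(hemo: HemoRecording, min_channels: int = 2) -> pd.DataFrame:
    """Mean over usable channels per region, separately per chromophore.

    Returns a long DataFrame (time_s, region, chromophore, value_uM); regions
    with fewer than ``min_channels`` usable channels are omitted (invalid).
    """
    _check_stage(hemo.history, "aggregate", requires="downsample")
    hemo.history.append("aggregate")
    regions = sorted(set(hemo.channel_regions))
    t = np.arange(hemo.hbo.shape[1]) / hemo.rate
    frames = []
    for region in regions:
        sel = np.array([r == region for r in hemo.channel_regions]) & hemo.quality_mask
        if sel.sum() < min_channels:
            continue
        for name, arr in (("HbO", hemo.hbo), ("HbR", hemo.hbr), ("HbT", hemo.hbt)):
            frames.append(pd.DataFrame({"time_s": t, "region": region,
                                        "chromophore": name,
                                        "value_uM": arr[sel].mean(axis=0)}))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time_s", "region", "chromophore", "value_uM"])
    hemo.region_series = out
    return out


def channel_accounting(usable_dyads: int, enrolled_dyads: int,
                       channels_per_person: int = 8) -> dict:
    """Channel bookkeeping: analyzed = usable x 2 x 8 vs possible = enrolled x 2 x 8."""
    analyzed = usable_dyads * 2 * channels_per_person
    total = enrolled_dyads * 2 * channels_per_person
    return dict(analyzed_channels=analyzed, total_channels=total,
                pct_usable=100.0 * analyzed / total if total else 0.0,
                pct_excluded=100.0 * (enrolled_dyads - usable_dyads) / enrolled_dyads
                if enrolled_dyads else 0.0)


def preprocess_person(rec: IntensityRecording,
                      cv_threshold: float = DEFAULT_CV_THRESHOLD,
                      flat_threshold: float = DEFAULT_FLAT_THRESHOLD,
                      band: tuple[float, float] = DEFAULT_HEMO_BAND,
                      target_rate: float = 1.0,
                      dpf: tuple[float, float] | None = None) -> HemoRecording:
    """Full preprocessing chain for one person's recording."""
    od = intensity_to_od(rec)
    prune_channels(od, cv_threshold, flat_threshold)
    od = spline_motion_correct(od)
    od = wavelet_motion_correct(od)
    hemo = od_to_hemoglobin(od, dpf=dpf)
    hemo = bandpass_hemo(hemo, band)
    hemo = downsample_hemo(hemo, target_rate)
    aggregate_region(hemo)
    return hemo
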