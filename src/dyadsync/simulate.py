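"""Synthetic mother-child dyad cohorts.

Generates cohorts whose physiological, hemodynamic, and behavioral data have
the statistical structure the downstream analysis assumes, with every effect
size controllable and fully seeded (one global seed spawns independent
per-dyad substreams, so growing a cohort never reshuffles existing dyads).

Three observable layers per dyad:

* Heartbeat series.  Each partner's interbeat interval (IBI) is a mean level
  plus a respiratory-band sinusoid (mother ~0.25 Hz, child ~0.5 Hz) whose
  slow log-amplitude envelope is a band-limited (0.01-0.05 Hz) Gaussian
  process.  Partners' log-envelopes are correlated in proportion to the
  per-dyad coupling s_i, so windowed log-variance (RSA) co-varies across
  ~30-s epochs by construction.
* fNIRS intensities.  Region-level hemodynamic sources are band-limited to
  0.02-0.1 Hz; each partner's source mixes a shared component (weight
  sqrt(f_i), f_i the per-dyad shared fraction) with an independent one, so
  the expected band coherence rises with f_i.  Channels add Mayer-wave
  (~0.1 Hz), respiratory (~0.2-0.3 Hz), cardiac (~1 Hz) and white noise, plus
  optional spike/step motion artifacts; intensities come from the forward
  modified Beer-Lambert model, so the preprocessing conversion round-trips.
* Behavior.  Maternal PANAS positive/negative affect, child gender, income
  band, and a child-dysregulation outcome generated from a linear moderation
  equation with controllable coefficients (defaults at the observed cohort
  scale: PA 36.21 (6.78), NA 19.54 (7.26), outcome mean 1.79).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import optics
from .rsa import IbiSeries
from .fnirs import IntensityRecording, SAMPLING_RATE


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


DEFAULT_BEHAVIOR_COEFS = dict(
    b0=1.79,          # outcome mean (ERC Negative Lability scale)
    b_pa=-0.01,       # per PA point
    b_na=0.02,        # per NA point
    b_sync=-3.0,      # per synchrony unit
    b_pa_x_sync=-0.47,  # interaction, per PA point x synchrony unit
    b_gender=0.02,
    b_income=0.01,
)

DEFAULT_NOISE_AMPLITUDES = dict(mayer=0.08, respiration=0.06, cardiac=0.04,
                                white=0.05)  # µM-equivalent amplitudes

INCOME_PROBS = (0.113, 0.313, 0.237, 0.337)  # 4 ordered brackets
GIRL_FRACTION = 0.54


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    n_dyads: int = 80
    seed: int = 0
    task_duration: float = 300.0       # s
    baseline_duration: float = 120.0   # s
    ibi_mean_mother: float = 800.0     # ms
    ibi_mean_child: float = 600.0      # ms
    resp_freq_mother: float = 0.25     # Hz
    resp_freq_child: float = 0.5       # Hz
    rsa_amp_mother: float = 60.0       # ms, respiratory-sinusoid amplitude
    rsa_amp_child: float = 40.0        # ms
    envelope_log_sd: float = 0.5       # SD of the slow log-amplitude envelope
    envelope_band: tuple = (0.01, 0.05)  # Hz
    envelope_partner_sd: float = 0.1   # child's independent envelope fraction
    ibi_jitter_ms: float = 2.0         # white beat-to-beat jitter
    rsa_coupling_mean: float = -0.01   # per-dyad envelope correlation s_i
    rsa_coupling_sd: float = 0.03
    hemo_rate: float = SAMPLING_RATE   # Hz
    n_channels_per_region: int = 4
    shared_fraction: float = 0.25      # mean per-dyad shared hemodynamic fraction
    shared_fraction_sd: float = 0.15
    hemo_signal_uM: float = 0.5        # SD of the neural HbO component
    noise_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_AMPLITUDES))
    motion_rate: float = 0.0           # artifacts per minute
    source_detector_cm: float = 3.0
    mother_age: float = 36.0
    child_age: float = 6.0
    pa_mean: float = 36.21
    pa_sd: float = 6.78
    na_mean: float = 19.54
    na_sd: float = 7.26
    behavior_coefs: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOR_COEFS))
    behavior_noise_sd: float = 0.30
    sync_source: str = "rsa"           # moderator truth: 'rsa' or 'coherence'

    def validate(self) -> "SimulationConfig":
        if self.n_dyads < 4:
            raise ConfigurationError("n_dyads must be >= 4")
        if not 0 <= self.shared_fraction <= 1:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        for name in ("task_duration", "baseline_duration", "hemo_rate",
                     "resp_freq_mother", "resp_freq_child", "ibi_mean_mother",
                     "ibi_mean_child"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.task_duration < 30 or self.baseline_duration < 30:
            raise ConfigurationError("durations must exceed the 15-s RSA window "
                                     "and the 29-sample baseline reference")
        if self.sync_source not in ("rsa", "coherence"):
            raise ConfigurationError("sync_source must be 'rsa' or 'coherence'")
        missing = set(DEFAULT_BEHAVIOR_COEFS) - set(self.behavior_coefs)
        if missing:
            raise ConfigurationError(f"behavior_coefs missing {sorted(missing)}")
        return self


@dataclass
class Dyad:
    dyad_id: str
    mother_ibi: IbiSeries
    child_ibi: IbiSeries
    mother_intensity: IntensityRecording
    child_intensity: IntensityRecording
    behavior: dict
    truths: dict                      # generating truths, kept apart from observables
    artifact_masks: dict = field(default_factory=dict)


@dataclass
class DyadCohort:
    config: SimulationConfig
    dyads: list

    def __len__(self):
        return len(self.dyads)

    def behavior_table(self) -> pd.DataFrame:
        return pd.DataFrame([d.behavior for d in self.dyads])

    def truths_table(self) -> pd.DataFrame:
        return pd.DataFrame([dict(dyad_id=d.dyad_id, **d.truths) for d in self.dyads])


def _slow_process(n: int, rate: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian process via random-phase spectrum."""
    nfft = int(2 ** np.ceil(np.log2(max(n, 2) * 2)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    amp = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
    if amp.sum() == 0:
        raise ConfigurationError(f"band {band} empty at rate {rate} and length {n}")
    phase = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, nfft)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_dyad_ibi(config: SimulationConfig, coupling: float,
                      rng: np.random.Generator,
                      dyad_id: str = "d000") -> tuple[IbiSeries, IbiSeries]:
    """Paired heartbeat series with envelope-coupled respiratory modulation.

    ``coupling`` in [-1, 1] is the correlation of the partners' slow
    log-amplitude envelopes; the downstream RSA coupling slope recovers it up
    to estimation noise.
    """
    if not np.isfinite(coupling):
        raise ConfigurationError("coupling must be finite")
    coupling = float(np.clip(coupling, -1.0, 1.0))
    total = config.baseline_duration + config.task_duration
    grid_rate = 8.0
    n = int(total * grid_rate) + 1
    t = np.arange(n) / grid_rate

    g_m = _slow_process(n, grid_rate, config.envelope_band, rng)
    g_own = _slow_process(n, grid_rate, config.envelope_band, rng)
    # the child's log-envelope regresses on the mother's with slope = coupling;
    # the partner-specific remainder is scaled down (envelope_partner_sd) so a
    # per-dyad epoch regression can resolve couplings at the observed scale
    g_c = (coupling * g_m
           + config.envelope_partner_sd * np.sqrt(1 - coupling ** 2) * g_own)

    series = []
    for role, mean_ibi, amp, freq, g in (
            ("mother", config.ibi_mean_mother, config.rsa_amp_mother,
             config.resp_freq_mother, g_m),
            ("child", config.ibi_mean_child, config.rsa_amp_child,
             config.resp_freq_child, g_c)):
        env = np.exp(config.envelope_log_sd * g)
        phase = rng.uniform(0, 2 * np.pi)
        ibi_t = mean_ibi + amp * env * np.sin(2 * np.pi * freq * t + phase)
        if np.any(ibi_t <= 200.0):
            raise GenerationError(
                f"{role} IBI fell to {ibi_t.min():.0f} ms; amplitudes must keep IBI > 200 ms")
        # beats: advance by the instantaneous IBI, with white jitter
        beats = [0.0]
        while beats[-1] < total:
            cur = np.interp(beats[-1], t, ibi_t)
            step = cur + rng.normal(0, config.ibi_jitter_ms)
            beats.append(beats[-1] + max(step, 200.0) / 1000.0)
        segs = {"baseline": (0.0, config.baseline_duration),
                "task": (config.baseline_duration, total)}
        series.append(IbiSeries(beat_times=np.asarray(beats), dyad_id=dyad_id,
                                person_id=f"{dyad_id}_{role}", role=role,
                                segments=segs))
    return series[0], series[1]


def _systemic_noise(n: int, rate: float, amps: dict, resp_freq: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Mayer + respiratory + cardiac sinusoids and white noise, µM scale."""
    t = np.arange(n) / rate
    out = np.zeros(n)
    for amp, freq in ((amps.get("mayer", 0.0), 0.1),
                      (amps.get("respiration", 0.0), resp_freq),
                      (amps.get("cardiac", 0.0), 1.0)):
        if amp > 0:
            f = freq * (1 + rng.normal(0, 0.02))
            out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    w = amps.get("white", 0.0)
    if w > 0:
        out += rng.normal(0, w, n)
    return out


def inject_motion_artifacts(samples: np.ndarray, rate: float, rate_per_min: float,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Insert spike and step artifacts at Poisson times into (..., time) data.

    Spikes have amplitude >= 5 x signal SD and duration 0.5-2 s; steps shift
    the baseline from the event onward.  Returns (corrupted, boolean mask of
    corrupted samples) with the mask shaped like the time axis.
    """
    if rate_per_min < 0:
        raise ConfigurationError("motion rate must be >= 0")
    x = np.array(samples, dtype=float)
    n = x.shape[-1]
    mask = np.zeros(n, dtype=bool)
    if rate_per_min == 0:
        return x, mask
    n_events = rng.poisson(rate_per_min * n / rate / 60.0)
    sd = max(float(np.std(x)), 1e-12)
    for _ in range(n_events):
        i0 = int(rng.integers(0, n))
        if rng.random() < 0.7:          # spike
            dur = int(rng.uniform(0.5, 2.0) * rate)
            i1 = min(n, i0 + max(dur, 1))
            amp = rng.uniform(5.0, 10.0) * sd * rng.choice([-1.0, 1.0])
            shape = np.hanning(2 * (i1 - i0))[i1 - i0:]
            x[..., i0:i1] += amp * shape
            mask[i0:i1] = True
        else:                            # step baseline shift
            amp = rng.uniform(3.0, 6.0) * sd * rng.choice([-1.0, 1.0])
            x[..., i0:] += amp
            mask[i0:min(n, i0 + max(int(0.5 * rate), 1))] = True
    return x, mask


def generate_dyad_hemo(config: SimulationConfig, target_coherence: float,
                       rng: np.random.Generator, dyad_id: str = "d000"
                       ) -> tuple[IntensityRecording, IntensityRecording, dict]:
    """Paired two-wavelength intensity recordings with controlled band coherence.

    Region-level HbO mixes a shared 0.02-0.1 Hz source (weight
    sqrt(target_coherence)) with an independent one; HbR is the usual
    anticorrelated fraction.  Channels add systemic noise; the forward
    modified Beer-Lambert model produces intensities.
    """
    if not 0 <= target_coherence <= 1:
        raise ConfigurationError("target_coherence must lie in [0, 1]")
    f = float(target_coherence)
    total = config.baseline_duration + config.task_duration
    rate = config.hemo_rate
    n = int(round(total * rate))
    regions = ("left_dlPFC", "right_dlPFC")
    band = (0.02, 0.1)

    shared = {r: _slow_process(n, rate, band, rng) for r in regions}
    recs, masks = [], {}
    for role, age, resp in (("mother", config.mother_age, config.resp_freq_mother),
                            ("child", config.child_age, config.resp_freq_child)):
        nch = 2 * config.n_channels_per_region
        ch_regions = tuple(r for r in regions for _ in range(config.n_channels_per_region))
        hbo = np.empty((nch, n))
        hbr = np.empty((nch, n))
        for ri, region in enumerate(regions):
            own = _slow_process(n, rate, band, rng)
            neural = (np.sqrt(f) * shared[region] + np.sqrt(1 - f) * own) \
                * config.hemo_signal_uM
            for c in range(config.n_channels_per_region):
                ch = ri * config.n_channels_per_region + c
                noise = _systemic_noise(n, rate, config.noise_amplitudes, resp, rng)
                hbo[ch] = neural + noise
                hbr[ch] = -0.3 * neural + 0.3 * noise * rng.choice([-1, 1])
        od = optics.mbll_forward(hbo, hbr, config.source_detector_cm, age)  # (wl, ch, n)
        od = np.moveaxis(od, 0, 1)                                          # (ch, wl, n)
        mask = np.zeros(n, dtype=bool)
        if config.motion_rate > 0:
            for ch in range(nch):
                od[ch], m = inject_motion_artifacts(od[ch], rate, config.motion_rate, rng)
                mask |= m
        i0 = 1.0 + 0.1 * rng.random((nch, 2))
        intensity = i0[:, :, None] * np.exp(-od)
        if np.any(intensity <= 0):
            raise GenerationError("nonphysical negative intensity generated")
        recs.append(IntensityRecording(samples=intensity, rate=rate,
                                       channel_regions=ch_regions,
                                       distance_cm=config.source_detector_cm,
                                       age_years=age, person_id=f"{dyad_id}_{role}",
                                       role=role))
        masks[role] = mask
    return recs[0], recs[1], masks


def generate_behavior(truth_sync: np.ndarray, config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Behavioral table from the generating moderation equation.

    dysregulation = b0 + b_pa*PAc + b_na*NAc + b_sync*sc + b_pa_x_sync*PAc*sc
                    + b_gender*(g - 1/2) + b_income*(inc - mean) + noise

    where PAc/NAc/sc are deviations from the generating means, so the outcome
    mean stays at b0 regardless of the coefficient settings.
    """
    b = config.behavior_coefs
    nd = len(truth_sync)
    pa = rng.normal(config.pa_mean, config.pa_sd, nd)
    na = rng.normal(config.na_mean, config.na_sd, nd)
    gender = (rng.random(nd) < GIRL_FRACTION).astype(int)
    income = rng.choice(np.arange(1, 5), size=nd, p=INCOME_PROBS)
    sync_center = (config.rsa_coupling_mean if config.sync_source == "rsa"
                   else config.shared_fraction)
    pac, nac = pa - config.pa_mean, na - config.na_mean
    sc = truth_sync - sync_center
    inc_mean = float(np.dot(np.arange(1, 5), INCOME_PROBS))
    dys = (b["b0"] + b["b_pa"] * pac + b["b_na"] * nac + b["b_sync"] * sc
           + b["b_pa_x_sync"] * pac * sc + b["b_gender"] * (gender - 0.5)
           + b["b_income"] * (income - inc_mean)
           + rng.normal(0, config.behavior_noise_sd, nd))
    return pd.DataFrame(dict(pa=pa, na=na, gender=gender, income=income,
                             dysregulation=dys))


def coupled_band_signals(shared_fraction: float, n: int, rng: np.random.Generator,
                         rate: float = 1.0, band: tuple = (0.02, 0.1),
                         noise_sd: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Region-level coupled hemodynamic pair without the optical forward stage.

    The same mixture model as :func:`generate_dyad_hemo` — shared band-limited
    source with weight sqrt(f), independent sources, white noise — useful for
    coherence calibration studies where the optics round trip is not at issue.
    """
    if not 0 <= shared_fraction <= 1:
        raise ConfigurationError("shared_fraction must lie in [0, 1]")
    z = _slow_process(n, rate, band, rng)
    f = shared_fraction
    out = []
    for _ in range(2):
        own = _slow_process(n, rate, band, rng)
        out.append(np.sqrt(f) * z + np.sqrt(1 - f) * own + rng.normal(0, noise_sd, n))
    return out[0], out[1]


def generate_cohort(config: SimulationConfig) -> DyadCohort:
    """Full synthetic cohort; deterministic under (config, seed).

    Every dyad is generated from its own substream of the global seed, so a
    cohort grown from n to n+k dyads reproduces its first n dyads exactly.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    dyad_seeds = root.spawn(config.n_dyads)

    dyads = []
    for i in range(config.n_dyads):
        rng = np.random.default_rng(dyad_seeds[i])
        dyad_id = f"d{i:03d}"
        coupling = float(np.clip(rng.normal(config.rsa_coupling_mean,
                                            config.rsa_coupling_sd), -1, 1))
        fraction = float(np.clip(rng.normal(config.shared_fraction,
                                            config.shared_fraction_sd), 0, 1))
        truth_sync = coupling if config.sync_source == "rsa" else fraction
        beh_row = generate_behavior(np.array([truth_sync]), config, rng).iloc[0]
        m_ibi, c_ibi = generate_dyad_ibi(config, coupling, rng, dyad_id)
        m_int, c_int, masks = generate_dyad_hemo(config, fraction, rng, dyad_id)
        beh = dict(dyad_id=dyad_id, **beh_row.to_dict())
        truths = dict(rsa_coupling=coupling, foi_coherence=fraction)
        dyads.append(Dyad(dyad_id=dyad_id, mother_ibi=m_ibi, child_ibi=c_ibi,
                          mother_intensity=m_int, child_intensity=c_int,
                          behavior=beh, truths=truths, artifact_masks=masks))
    return DyadCohort(config=config, dyads=dyads)
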