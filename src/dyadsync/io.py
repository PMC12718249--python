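"""CSV persistence for cohorts and stage outputs.

Cohort directory layout (all files carry unit-bearing headers):

    behavior.csv                 one row per dyad
    truths.csv                   generating truths, kept apart from observables
    beats/<dyad_id>.csv          columns: role, beat_time_s
    intensity/<dyad_id>.csv      columns: role, time_s, channel, wavelength_nm, intensity
    config.yaml                  the generating configuration, verbatim
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rsa import IbiSeries
from .fnirs import IntensityRecording
from .simulate import SimulationConfig, DyadCohort


def write_cohort(cohort: DyadCohort, outdir: str | Path) -> Path:
    out = Path(outdir)
    (out / "beats").mkdir(parents=True, exist_ok=True)
    (out / "intensity").mkdir(exist_ok=True)
    cohort.behavior_table().to_csv(out / "behavior.csv", index=False)
    cohort.truths_table().to_csv(out / "truths.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    for d in cohort.dyads:
        rows = []
        for ser in (d.mother_ibi, d.child_ibi):
            rows.append(pd.DataFrame({"role": ser.role, "beat_time_s": ser.beat_times}))
        pd.concat(rows).to_csv(out / "beats" / f"{d.dyad_id}.csv", index=False)
        frames = []
        for rec in (d.mother_intensity, d.child_intensity):
            nch, nwl, nt = rec.samples.shape
            t = np.arange(nt) / rec.rate
            for ch in range(nch):
                for wi, wl in enumerate(rec.wavelengths):
                    frames.append(pd.DataFrame({
                        "role": rec.role, "time_s": t, "channel": ch,
                        "wavelength_nm": wl, "intensity": rec.samples[ch, wi]}))
        pd.concat(frames).to_csv(out / "intensity" / f"{d.dyad_id}.csv", index=False)
    return out


def read_beats(path: str | Path, segments: dict) -> dict:
    """Read a per-dyad beat-time CSV into {role: IbiSeries}."""
    df = pd.read_csv(path)
    out = {}
    for role, grp in df.groupby("role"):
        out[role] = IbiSeries(beat_times=grp["beat_time_s"].to_numpy(),
                              role=role, segments=dict(segments))
    return out


def read_intensity(path: str | Path, distance_cm: float, ages: dict,
                   n_channels_per_region: int = 4) -> dict:
    """Read a per-dyad intensity CSV into {role: IntensityRecording}."""
    df = pd.read_csv(path)
    out = {}
    for role, grp in df.groupby("role"):
        channels = sorted(grp["channel"].unique())
        wavelengths = tuple(sorted(grp["wavelength_nm"].unique()))
        times = np.sort(grp["time_s"].unique())
        rate = 1.0 / np.median(np.diff(times))
        cube = np.empty((len(channels), len(wavelengths), len(times)))
        piv = grp.pivot_table(index=["channel", "wavelength_nm"], columns="time_s",
                              values="intensity")
        for ci, ch in enumerate(channels):
            for wi, wl in enumerate(wavelengths):
                cube[ci, wi] = piv.loc[(ch, wl)].to_numpy()
        regions = tuple(r for r in ("left_dlPFC", "right_dlPFC")
                        for _ in range(n_channels_per_region))
        out[role] = IntensityRecording(samples=cube, rate=rate,
                                       wavelengths=wavelengths,
                                       channel_regions=regions,
                                       distance_cm=distance_cm,
                                       age_years=ages[role], role=role)
    return out


def load_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for k, v in raw.items():
        if k not in fields:
            continue
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return SimulationConfig(**kwargs)
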