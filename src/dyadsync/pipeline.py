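"""End-to-end pipeline: simulate -> cardiac RSA -> fNIRS -> wavelet coherence
-> RSA synchrony -> moderation models -> random-pairing control -> report.

Stages write CSV outputs plus a content-hash manifest into a run directory;
a stage whose inputs and parameters are unchanged is skipped on re-run, so a
stats-only change never recomputes the (slow) coherence stage.  Per-dyad
exclusions (unusable beat series, pruned fNIRS regions) are logged with
reasons, mirroring attrition accounting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as dio
from . import fnirs, rsa, stats, wtc
from .coupling import CouplingModelSpec, DyadicCouplingModel
from .simulate import SimulationConfig, generate_cohort

log = logging.getLogger("dyadsync")

MODERATORS = ["rsa_sync",
              "right_dlPFC_HbR", "left_dlPFC_HbR",
              "right_dlPFC_HbO", "left_dlPFC_HbO"]


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "run"
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    estimator: str = "per_dyad_ols"
    coi_policy: str = "exclude"
    foi: tuple = wtc.DEFAULT_FOI
    n_permutations: int = 100
    alpha: float = 0.05
    stages: tuple = ("simulate", "rsa", "rsa_sync", "fnirs", "wtc",
                     "moderate", "permute", "report")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


class _Stage:
    """Content-hash keyed stage cache: skip when inputs are current."""

    def __init__(self, run: Path, name: str, key: dict, outputs: list[str]):
        self.dir = run
        self.name = name
        self.key = _hash(key)
        self.outputs = [run / o for o in outputs]
        self.manifest = run / f".{name}.manifest.json"

    def current(self) -> bool:
        if not all(o.exists() for o in self.outputs) or not self.manifest.exists():
            return False
        return json.loads(self.manifest.read_text()).get("key") == self.key

    def done(self):
        self.manifest.write_text(json.dumps({"key": self.key}))


def run_pipeline(config: PipelineConfig) -> Path:
    run = Path(config.outdir)
    run.mkdir(parents=True, exist_ok=True)
    snap = config.snapshot()
    (run / "pipeline_config.json").write_text(json.dumps(snap, indent=2))
    exclusions = []

    # --- simulate -----------------------------------------------------------
    cohort = None
    if "simulate" in config.stages:
        stage = _Stage(run, "simulate", snap["simulation"], ["cohort/behavior.csv"])
        cohort = generate_cohort(config.simulation)
        if not stage.current():
            dio.write_cohort(cohort, run / "cohort")
            stage.done()
        if set(config.stages) == {"simulate"}:
            return run
    if cohort is None:
        raise ValueError("pipeline currently requires the simulate stage")

    sim = config.simulation
    behavior = cohort.behavior_table()

    # --- cardiac RSA --------------------------------------------------------
    epochs_rows, baselines_rows = [], []
    if "rsa" in config.stages:
        stage = _Stage(run, "rsa", snap["simulation"], ["rsa_epochs.csv"])
        for d in cohort.dyads:
            try:
                m = rsa.ibi_to_rsa_epochs(d.mother_ibi, rsa.ADULT_BAND)
                c = rsa.ibi_to_rsa_epochs(d.child_ibi, rsa.CHILD_BAND)
            except (rsa.UnusableSeriesError, ValueError) as exc:
                exclusions.append(dict(dyad_id=d.dyad_id, stage="rsa", reason=str(exc)))
                continue
            k = min(m.n_epochs, c.n_epochs)
            for t in range(k):
                epochs_rows.append(dict(dyad_id=d.dyad_id, epoch=t,
                                        mother_rsa=m.epoch_means[t],
                                        child_rsa=c.epoch_means[t]))
            baselines_rows.append(dict(dyad_id=d.dyad_id,
                                       mother_baseline=m.baseline_reference,
                                       child_baseline=c.baseline_reference))
        pd.DataFrame(epochs_rows).to_csv(run / "rsa_epochs.csv", index=False)
        pd.DataFrame(baselines_rows).to_csv(run / "rsa_baselines.csv", index=False)
        stage.done()

    # --- RSA synchrony ------------------------------------------------------
    if "rsa_sync" in config.stages and epochs_rows:
        spec = CouplingModelSpec(estimator=config.estimator)
        model = DyadicCouplingModel.from_dataframe(pd.DataFrame(epochs_rows),
                                                   pd.DataFrame(baselines_rows), spec)
        cres = model.fit()
        cres.per_dyad.to_csv(run / "rsa_synchrony.csv", index=False)
        behavior = behavior.merge(
            cres.synchrony().rename("rsa_sync"), left_on="dyad_id",
            right_index=True, how="left")
        for did, why in cres.exclusions:
            exclusions.append(dict(dyad_id=did, stage="rsa_sync", reason=why))

    # --- fNIRS preprocessing ------------------------------------------------
    region_series = {}   # dyad_id -> {(region, chromo): {role: array}}
    if "fnirs" in config.stages:
        for d in cohort.dyads:
            per_dyad = {}
            valid = True
            for role, rec in (("mother", d.mother_intensity),
                              ("child", d.child_intensity)):
                hemo = fnirs.preprocess_person(rec)
                regions_present = set(hemo.region_series["region"].unique())
                if len(regions_present) < 2:
                    exclusions.append(dict(dyad_id=d.dyad_id, stage="fnirs",
                                           reason=f"{role}: region with <2 usable channels"))
                    valid = False
                    break
                task_start = sim.baseline_duration
                rs = hemo.region_series
                rs = rs[rs.time_s >= task_start]
                for (region, chromo), grp in rs.groupby(["region", "chromophore"]):
                    if chromo == "HbT":
                        continue
                    per_dyad.setdefault((region, chromo), {})[role] = \
                        grp.sort_values("time_s")["value_uM"].to_numpy()
            if valid:
                region_series[d.dyad_id] = per_dyad

    # --- wavelet coherence --------------------------------------------------
    coh_rows = []
    if "wtc" in config.stages and region_series:
        for did, per_dyad in region_series.items():
            for (region, chromo), roles in per_dyad.items():
                nmin = min(len(roles["mother"]), len(roles["child"]))
                summ = wtc.dyad_coherence(roles["mother"][:nmin], roles["child"][:nmin],
                                          dt=1.0, foi=config.foi,
                                          coi_policy=config.coi_policy,
                                          dyad_id=did, region=region, chromophore=chromo)
                coh_rows.append(dict(dyad_id=did, region=region, chromophore=chromo,
                                     coherence=summ.coherence,
                                     foi_low=config.foi[0], foi_high=config.foi[1],
                                     coi_policy=config.coi_policy))
        coh = pd.DataFrame(coh_rows)
        coh.to_csv(run / "coherence.csv", index=False)
        coh["col"] = coh["region"] + "_" + coh["chromophore"]
        wide = coh.pivot(index="dyad_id", columns="col", values="coherence")
        behavior = behavior.merge(wide, left_on="dyad_id", right_index=True, how="left")

    if "rsa_sync" in config.stages or "wtc" in config.stages:
        behavior.to_csv(run / "analysis_table.csv", index=False)

    # --- moderation models --------------------------------------------------
    if "moderate" in config.stages:
        results = {}
        for iv in ("pa", "na"):
            for moderator in MODERATORS:
                if moderator not in behavior.columns:
                    continue
                try:
                    res = stats.ModerationModel.from_dataframe(
                        behavior, iv=iv, moderator=moderator,
                        alpha=config.alpha).fit()
                except ValueError as exc:
                    log.warning("moderation %s x %s failed: %s", iv, moderator, exc)
                    continue
                results[(iv, moderator)] = res
                tab = res.params.copy()
                tab.insert(0, "term", tab.index)
                tab.to_csv(run / f"moderation_{iv}_{moderator}.csv", index=False)
        with open(run / "moderation_summary.txt", "w") as fh:
            for res in results.values():
                fh.write(res.summary() + "\n")
                if res.interaction_p < config.alpha:
                    fh.write(res.johnson_neyman().describe() + "\n")
                fh.write("\n")

    # --- random-pairing control --------------------------------------------
    if "permute" in config.stages and region_series:
        ids = sorted(region_series)
        if len(ids) >= 3:
            scheme = stats.random_pairings(ids, config.n_permutations,
                                           seed=config.simulation.seed + 1)
            pseudo_rows = []
            for region in ("left_dlPFC", "right_dlPFC"):
                for chromo in ("HbO", "HbR"):
                    mothers = {i: region_series[i][(region, chromo)]["mother"]
                               for i in ids}
                    children = {i: region_series[i][(region, chromo)]["child"]
                                for i in ids}
                    pseudo = stats.permuted_coherence(mothers, children, scheme,
                                                      foi=config.foi,
                                                      coi_policy=config.coi_policy)
                    for did, val in pseudo.items():
                        pseudo_rows.append(dict(dyad_id=did, region=region,
                                                chromophore=chromo,
                                                pseudo_coherence=val))
            pd.DataFrame(pseudo_rows).to_csv(run / "pseudo_coherence.csv", index=False)

    pd.DataFrame(exclusions, columns=["dyad_id", "stage", "reason"]) \
        .to_csv(run / "exclusions.csv", index=False)

    if "report" in config.stages:
        from .report import write_report
        write_report(run)
    return run
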