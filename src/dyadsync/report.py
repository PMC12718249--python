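"""Human-readable run report: descriptives, the ten moderation tables,
Johnson-Neyman plots for probed interactions, and the true-vs-pseudo
coherence comparison.  Sections whose stage output is missing are marked
unavailable rather than failing."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import stats


def _section(title: str) -> str:
    return f"\n## {title}\n\n"


def jn_plot(result: "stats.ModerationResults", path: Path) -> None:
    """Simple-slope vs moderator with confidence band and J-N boundaries."""
    lo, hi = result.moderator_range
    m = np.linspace(lo - 0.1 * (hi - lo), hi + 0.1 * (hi - lo), 200)
    theta, se = result.simple_slope(m)
    from scipy import stats as spstats
    t_crit = spstats.t.ppf(1 - result.spec.alpha / 2, result.f_df[1])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(m, theta, color="k", label="simple slope")
    ax.fill_between(m, theta - t_crit * se, theta + t_crit * se, alpha=0.25)
    ax.axhline(0, color="gray", lw=0.8)
    for b in result.johnson_neyman().boundaries:
        ax.axvline(b, color="crimson", ls="--", lw=0.8)
    ax.set_xlabel(f"{result.spec.moderator} (centered)")
    ax.set_ylabel(f"slope of {result.spec.iv}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_report(run: str | Path) -> Path:
    run = Path(run)
    out = [f"# dyadsync run report\n\nrun directory: `{run}`\n"]

    table_path = run / "analysis_table.csv"
    out.append(_section("Descriptives and correlations"))
    if table_path.exists():
        table = pd.read_csv(table_path)
        desc, mat = stats.correlation_table(table.drop(columns=["dyad_id"],
                                                       errors="ignore"))
        out.append(desc.round(3).to_markdown() + "\n\n")
        out.append(mat.to_markdown() + "\n")
    else:
        out.append("*unavailable*\n")

    out.append(_section("Moderation models"))
    mod_files = sorted(run.glob("moderation_*.csv"))
    if mod_files:
        for f in mod_files:
            out.append(f"### {f.stem.replace('moderation_', '')}\n\n")
            out.append(pd.read_csv(f).round(4).to_markdown(index=False) + "\n\n")
        summ = run / "moderation_summary.txt"
        if summ.exists():
            out.append("```\n" + summ.read_text() + "```\n")
    else:
        out.append("*unavailable*\n")

    out.append(_section("Johnson-Neyman probes"))
    plots = []
    if table_path.exists() and mod_files:
        table = pd.read_csv(table_path)
        for f in mod_files:
            name = f.stem.replace("moderation_", "")
            iv, moderator = name.split("_", 1)
            if moderator not in table.columns:
                continue
            try:
                res = stats.ModerationModel.from_dataframe(
                    table, iv=iv, moderator=moderator).fit()
            except (ValueError, KeyError):
                continue
            if res.interaction_p < res.spec.alpha:
                png = run / f"jn_{name}.png"
                jn_plot(res, png)
                plots.append((name, png, res))
    if plots:
        for name, png, res in plots:
            out.append(f"![J-N {name}]({png.name})\n\n"
                       f"interaction p = {res.interaction_p:.4f}\n\n"
                       + res.johnson_neyman().describe() + "\n\n")
    else:
        out.append("*no interaction crossed the significance threshold*\n")

    out.append(_section("Random-pairing control"))
    pseudo_path = run / "pseudo_coherence.csv"
    coh_path = run / "coherence.csv"
    if pseudo_path.exists() and coh_path.exists():
        pseudo = pd.read_csv(pseudo_path)
        true = pd.read_csv(coh_path)
        cmp_tab = (true.groupby(["region", "chromophore"])["coherence"].mean()
                   .rename("true_mean").to_frame()
                   .join(pseudo.groupby(["region", "chromophore"])
                         ["pseudo_coherence"].mean().rename("pseudo_mean")))
        out.append(cmp_tab.round(4).to_markdown() + "\n")
    else:
        out.append("*unavailable*\n")

    path = run / "report.md"
    path.write_text("".join(out))
    return path
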