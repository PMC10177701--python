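"""Figures and tables for a completed run.

All figures are rendered from the persisted draw-level CSVs, never from
in-memory state, so re-rendering from disk is reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .decision_analysis import EconDraws, ceac, icer_draws
from .parameters import ParameterSet, load_params
from .pipeline import RunManifest

__all__ = ["render_report", "ce_plane", "ceac_plot", "violin_plot", "shaded_fraction"]


def shaded_fraction(econ: EconDraws, lam: float) -> float:
    """Fraction of draws in the CE-plane region below the threshold ray.

    Identical by construction to the acceptability-curve value at lambda.
    """
    return float(np.mean(lam * econ.dalys_averted - econ.cost > 0))


def ce_plane(econ: EconDraws, lam: float, path: Path, epsilon: float = 1e-8) -> int:
    """Scatter of (DALYs averted, incremental cost) with the acceptable region shaded.

    Returns the number of plotted points (near-zero-effect draws are dropped,
    matching the ICER ratio summaries).
    """
    keep = np.abs(econ.dalys_averted) >= epsilon
    x, y = econ.dalys_averted[keep], econ.cost[keep]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, y, s=2, alpha=0.15, color="#30506e", rasterized=True)
    xs = np.array([0, max(float(x.max()), 1.0) * 1.05])
    ax.plot(xs, lam * xs, color="darkgreen", lw=1.2, label=f"λ = ${lam:,.0f}/DALY")
    ax.fill_between(xs, lam * xs, y2=0, color="green", alpha=0.12)
    frac = shaded_fraction(econ, lam)
    ax.set_xlabel("Incremental effectiveness (DALYs averted)")
    ax.set_ylabel("Incremental cost (2016 US$)")
    ax.set_title(f"Cost-effectiveness plane ({frac:.1%} of draws acceptable)")
    ax.legend(loc="upper left", frameon=False)
    ax.set_ylim(bottom=0)
    for ext in ("png", "svg"):
        fig.savefig(path.with_suffix(f".{ext}"), dpi=150)
    plt.close(fig)
    return int(keep.sum())


def ceac_plot(econ: EconDraws, thresholds: list[float], path: Path) -> dict[float, float]:
    curve = ceac(econ, thresholds)
    fig, ax = plt.subplots(figsize=(6, 4))
    lams = sorted(curve)
    ax.plot(lams, [curve[l] for l in lams], marker="o", color="#30506e")
    ax.set_xlabel("Willingness-to-pay threshold (US$ per DALY averted)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.set_title("Cost-effectiveness acceptability curve")
    for ext in ("png", "svg"):
        fig.savefig(path.with_suffix(f".{ext}"), dpi=150)
    plt.close(fig)
    return curve


def violin_plot(draws: pd.DataFrame, value: str, path: Path, ylabel: str) -> None:
    """One violin per SSA scenario; kernel density with Scott's bandwidth rule."""
    fig, ax = plt.subplots(figsize=(7, 4))
    sns.violinplot(
        data=draws, x="scenario", y=value, ax=ax,
        density_norm="width", bw_method="scott", inner="quartile", color="#7fa8c9",
    )
    ax.set_ylabel(ylabel)
    ax.set_xlabel("")
    for ext in ("png", "svg"):
        fig.savefig(path.with_suffix(f".{ext}"), dpi=150)
    plt.close(fig)


def render_report(manifest: RunManifest, config: str | None = None) -> dict[str, str]:
    """Render the four result artefacts plus a summary table from persisted draws."""
    outdir = Path(manifest.outdir)
    params: ParameterSet = load_params(config)
    econ_path = manifest.outputs.get("econ_draws")
    if econ_path is None or not Path(econ_path).exists():
        raise FileNotFoundError("missing econ_draws; run the 'economic' stage first")
    econ = EconDraws.from_frame(pd.read_csv(econ_path))

    c = params.constants
    outputs: dict[str, str] = {}

    n_points = ce_plane(econ, c.gdp_per_capita_usd, outdir / "ce_plane", c.icer_effect_epsilon)
    outputs["ce_plane"] = str(outdir / "ce_plane.png")
    outputs["ce_plane_points"] = str(n_points)

    lambdas = [m * c.gdp_per_capita_usd for m in params.ceac_thresholds_gdp_multiples]
    ceac_plot(econ, lambdas, outdir / "ceac")
    outputs["ceac"] = str(outdir / "ceac.png")

    if econ.benefit:
        bpath = manifest.outputs.get("benefit_draws")
        bdf = pd.read_csv(bpath)
        cost_by_id = pd.Series(econ.cost, index=np.arange(econ.S))
        bdf["cbr"] = bdf["benefit_total"] / cost_by_id.reindex(bdf["sample_id"]).to_numpy()
        bdf["npvb"] = bdf["benefit_total"] - cost_by_id.reindex(bdf["sample_id"]).to_numpy()
        violin_plot(bdf, "cbr", outdir / "cbr_violin", "Cost-benefit ratio")
        violin_plot(bdf, "npvb", outdir / "npvb_violin", "Net present value of benefit (US$)")
        outputs["cbr_violin"] = str(outdir / "cbr_violin.png")
        outputs["npvb_violin"] = str(outdir / "npvb_violin.png")
    else:
        print("no benefit scenarios present; cost-benefit plots skipped")

    # tabular summary mirroring the decision summary
    summary_json = manifest.outputs.get("decision_summary")
    if summary_json and Path(summary_json).exists():
        with open(summary_json) as fh:
            summary = json.load(fh)
        rows = [{"metric": "icer_" + k, "value": v} for k, v in summary["icer"].items()]
        rows += [{"metric": f"ceac_{k}", "value": v} for k, v in summary["ceac"].items()]
        for sid, s in summary["cba"].items():
            rows += [{"metric": f"{sid}_{k}", "value": v} for k, v in s.items()]
        table_path = outdir / "summary_table.csv"
        pd.DataFrame(rows).to_csv(table_path, index=False)
        outputs["summary_table"] = str(table_path)

    return outputs
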