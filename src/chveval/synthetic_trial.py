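"""Synthetic cluster-randomised trial panels.

Emulates a two-arm, 40-community, three-wave longitudinal panel of under-5
disease episode counts. Episodes are Poisson given a cluster-level log-normal
random intercept and a multiplicative treatment effect on incidence — the
same structure the inference model assumes — so parameter recovery can be
tested end to end without the (undeposited) field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialDesign", "simulate_trial", "summarize_panel", "read_panel", "write_panel"]

PANEL_COLUMNS = [
    "cluster_id",
    "arm",
    "wave",
    "n_children",
    "episodes_diarrhoea",
    "episodes_fever",
    "exposure_child_time",
]


@dataclass(frozen=True)
class TrialDesign:
    """Generating parameters for a synthetic two-arm cluster trial.

    Defaults emulate the study geometry (20 clusters per arm, 3 waves) at
    roughly 1/10 of the field sample size so a panel simulates in
    milliseconds; ``children_per_cluster_mean`` scales it back up.
    """

    n_clusters_per_arm: int = 20
    children_per_cluster_mean: float = 10.0
    children_per_cluster_sd: float = 2.0
    waves: int = 3
    recall_window_days: float = 14.0  # per-wave episode recall window
    cluster_sd: float = 0.3  # sd of log-scale random intercepts
    baseline_incidence: dict[str, float] = field(
        default_factory=lambda: {"diarrhoea": 2.055, "fever": 1.9}
    )
    true_rr: dict[str, float] = field(
        default_factory=lambda: {"diarrhoea": 0.862, "fever": 0.860}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters_per_arm < 2:
            raise ValueError("need at least 2 clusters per arm")
        if any(rr <= 0 for rr in self.true_rr.values()):
            raise ValueError("true rate ratios must be positive")
        if self.recall_window_days <= 0:
            raise ValueError("recall window must be positive")


def simulate_trial(design: TrialDesign) -> pd.DataFrame:
    """Simulate a trial panel; identical designs (incl. seed) give identical panels.

    For cluster j with random intercept u_j ~ Normal(0, cluster_sd) on the
    log-rate scale, the episode count in a wave is
    Poisson(exposure * incidence * exp(u_j) * RR^arm) per disease, where
    exposure is n_children x the recall window in child-years.
    """
    rng = np.random.default_rng(design.seed)
    n_arm = design.n_clusters_per_arm
    n_clusters = 2 * n_arm
    arms = np.repeat(["control", "intervention"], n_arm)
    u = rng.normal(0.0, design.cluster_sd, size=n_clusters)
    n_children = np.maximum(
        1,
        np.round(
            rng.normal(design.children_per_cluster_mean, design.children_per_cluster_sd, n_clusters)
        ).astype(int),
    )

    window_years = design.recall_window_days / 365.25
    rows = []
    for j in range(n_clusters):
        treated = arms[j] == "intervention"
        exposure = n_children[j] * window_years
        if exposure <= 0:
            raise ValueError("non-positive exposure")
        for w in range(design.waves):
            counts = {}
            for disease, inc in design.baseline_incidence.items():
                rate = inc * np.exp(u[j]) * (design.true_rr[disease] if treated else 1.0)
                counts[disease] = rng.poisson(exposure * rate)
            rows.append(
                {
                    "cluster_id": j,
                    "arm": arms[j],
                    "wave": w,
                    "n_children": n_children[j],
                    "episodes_diarrhoea": counts.get("diarrhoea", 0),
                    "episodes_fever": counts.get("fever", 0),
                    "exposure_child_time": exposure,
                }
            )
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    # binarised period-prevalence proxy: whether any episode occurred
    panel["any_diarrhoea"] = (panel["episodes_diarrhoea"] > 0).astype(int)
    panel["any_fever"] = (panel["episodes_fever"] > 0).astype(int)
    return panel


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Episode rates per child-time by arm and wave, with crude rate ratios.

    The crude rate ratio (intervention/control, pooled over waves) is attached
    as ``DataFrame.attrs['crude_rr']``; a zero control rate yields NaN rather
    than infinity.
    """
    if panel.empty:
        raise ValueError("empty panel")
    g = panel.groupby(["arm", "wave"], as_index=False).agg(
        episodes_diarrhoea=("episodes_diarrhoea", "sum"),
        episodes_fever=("episodes_fever", "sum"),
        exposure_child_time=("exposure_child_time", "sum"),
    )
    for d in ("diarrhoea", "fever"):
        g[f"rate_{d}"] = g[f"episodes_{d}"] / g["exposure_child_time"]

    crude = {}
    pooled = panel.groupby("arm")[
        ["episodes_diarrhoea", "episodes_fever", "exposure_child_time"]
    ].sum()
    for d in ("diarrhoea", "fever"):
        ctrl = pooled.loc["control", f"episodes_{d}"] / pooled.loc["control", "exposure_child_time"]
        trt = (
            pooled.loc["intervention", f"episodes_{d}"]
            / pooled.loc["intervention", "exposure_child_time"]
        )
        crude[d] = trt / ctrl if ctrl > 0 else float("nan")
    g.attrs["crude_rr"] = crude
    return g


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel file missing columns {missing}")
    return panel
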