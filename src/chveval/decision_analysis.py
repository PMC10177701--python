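"""Decision analytics: ICER, CEAC, cost-benefit ratio and net present value.

The acceptability curve uses the net-monetary-benefit rule
Pr(lambda x DALYs - cost > 0), which orders negative-effect draws correctly
where a naive "ICER < lambda" comparison would not. Intervals are
equal-tailed 95% credible intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EconDraws", "IcerSummary", "CbaSummary", "icer_draws", "ceac", "cbr_npvb"]


@dataclass
class EconDraws:
    """S-aligned economic draws: cost, DALYs averted, benefit per scenario."""

    cost: np.ndarray
    dalys_averted: np.ndarray
    benefit: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.cost = np.asarray(self.cost, dtype=float)
        self.dalys_averted = np.asarray(self.dalys_averted, dtype=float)
        if self.cost.shape != self.dalys_averted.shape:
            raise ValueError("cost and effect vectors must be aligned")
        if np.any(self.cost <= 0):
            raise ValueError("cost draws must be positive")
        for k, v in self.benefit.items():
            if np.asarray(v).shape != self.cost.shape:
                raise ValueError(f"benefit draws for {k} misaligned with cost draws")

    @property
    def S(self) -> int:
        return self.cost.size

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sample_id": np.arange(self.S),
            "cost": self.cost,
            "dalys": self.dalys_averted,
        }
        for k, v in self.benefit.items():
            data[f"benefit_{k}"] = v
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EconDraws":
        benefit = {
            c.removeprefix("benefit_"): df[c].to_numpy()
            for c in df.columns
            if c.startswith("benefit_")
        }
        return cls(df["cost"].to_numpy(), df["dalys"].to_numpy(), benefit)


@dataclass(frozen=True)
class IcerSummary:
    mean: float
    median: float
    ci_lower: float
    ci_upper: float
    n_excluded: int  # draws with |effect| below epsilon, left out of ratio summaries
    draws: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CbaSummary:
    scenario: str
    cbr_mean: float
    cbr_median: float
    npvb_median: float
    npvb_mean: float
    p_cbr_gt: dict[float, float]
    cbr_draws: np.ndarray = field(repr=False)
    npvb_draws: np.ndarray = field(repr=False)


def icer_draws(econ: EconDraws, epsilon: float = 1e-8) -> IcerSummary:
    """Per-draw cost / DALYs-averted with near-zero effects excluded from summaries.

    Negative-effect draws keep their (negative) ratio — the north-west /
    south-west quadrant semantics of the cost-effectiveness plane.
    """
    effect = econ.dalys_averted
    if np.all(effect == 0):
        raise ValueError("all effect draws are zero; ICER undefined")
    keep = np.abs(effect) >= epsilon
    ratios = econ.cost[keep] / effect[keep]
    lo, med, hi = np.percentile(ratios, [2.5, 50.0, 97.5])
    return IcerSummary(
        mean=float(np.mean(ratios)),
        median=float(med),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_excluded=int(np.sum(~keep)),
        draws=ratios,
    )


def ceac(econ: EconDraws, thresholds) -> dict[float, float]:
    """Pr(net monetary benefit > 0) at each willingness-to-pay threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be positive")
    return {
        float(lam): float(np.mean(lam * econ.dalys_averted - econ.cost > 0))
        for lam in thresholds
    }


def cbr_npvb(
    econ: EconDraws, scenario: str, p_thresholds=(1.0, 3.0)
) -> CbaSummary:
    """Cost-benefit ratio and net-present-value-of-benefit draws and summaries."""
    if scenario not in econ.benefit:
        raise KeyError(f"no benefit draws for scenario '{scenario}'")
    benefit = np.asarray(econ.benefit[scenario], dtype=float)
    cbr = benefit / econ.cost
    npvb = benefit - econ.cost
    return CbaSummary(
        scenario=scenario,
        cbr_mean=float(np.mean(cbr)),
        cbr_median=float(np.median(cbr)),
        npvb_median=float(np.median(npvb)),
        npvb_mean=float(np.mean(npvb)),
        p_cbr_gt={float(k): float(np.mean(cbr > k)) for k in p_thresholds},
        cbr_draws=cbr,
        npvb_draws=npvb,
    )
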