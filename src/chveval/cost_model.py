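"""10-year incremental programme cost: schedule, discounting, probabilistic draws.

Three cost categories drive the schedule: initial (one-time start-up outlays
at t = 0), capital (items with a lifespan, repurchased at each end of life
within the horizon, or annualised by the equivalent-annual-cost convention),
and recurrent (incurred every cycle). Probabilistic uncertainty on the total
is lognormal with the standard deviation set to a fraction (default 25%) of
the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import CostAccount, Constants, discount_factor

__all__ = [
    "CostSchedule",
    "build_schedule",
    "total_discounted_cost",
    "sample_costs",
    "lognormal_from_mean_cv",
    "accounts_from_csv",
    "accounts_to_csv",
]

CSV_COLUMNS = ["Type", "Account", "Life span", "Unit Cost USD", "Unit Cost GHS", "Total Cost USD"]
_CATEGORY_FROM_TYPE = {"Initial cost": "initial", "Capital cost": "capital", "Recurrent cost": "recurrent"}
_TYPE_FROM_CATEGORY = {v: k for k, v in _CATEGORY_FROM_TYPE.items()}


@dataclass(frozen=True)
class CostSchedule:
    """Undiscounted cost by year and account (wide table, years as rows)."""

    table: pd.DataFrame  # index: year 0..H-1; columns: account names
    categories: dict[str, str]  # account -> initial/capital/recurrent

    @property
    def horizon(self) -> int:
        return len(self.table)

    def category_totals(self) -> pd.DataFrame:
        """Undiscounted per-year totals for each category."""
        out = {}
        for cat in ("initial", "capital", "recurrent"):
            cols = [a for a, c in self.categories.items() if c == cat]
            out[cat] = self.table[cols].sum(axis=1)
        return pd.DataFrame(out)


def build_schedule(
    accounts: list[CostAccount] | tuple[CostAccount, ...],
    constants: Constants,
) -> CostSchedule:
    """Place each account's total on the 10-year grid (t = 0 is year one).

    Initial accounts appear at t = 0 only; recurrent accounts every year;
    capital accounts at t = 0, L, 2L, ... < horizon (repurchase convention)
    or as total/L every year (annualised convention).
    """
    H = constants.horizon_years
    cols = {}
    categories = {}
    for acc in accounts:
        y = np.zeros(H)
        if acc.category == "initial":
            y[0] = acc.total_cost_usd
        elif acc.category == "recurrent":
            y[:] = acc.total_cost_usd
        else:  # capital
            L = int(acc.lifespan_years)
            if L <= 0:
                raise ValueError(f"capital account '{acc.name}': lifespan must be positive")
            if constants.capital_convention == "annualised":
                y[:] = acc.total_cost_usd / L
            else:
                y[np.arange(0, H, L)] = acc.total_cost_usd
        cols[acc.name] = y
        categories[acc.name] = acc.category
    table = pd.DataFrame(cols, index=pd.RangeIndex(H, name="year"))
    return CostSchedule(table=table, categories=categories)


def total_discounted_cost(schedule: CostSchedule, r: float) -> float:
    """Present value of the whole schedule at annual rate ``r``."""
    df = discount_factor(np.arange(schedule.horizon), r)
    return float(np.sum(df * schedule.table.sum(axis=1).to_numpy()))


def lognormal_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with given arithmetic mean and cv."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def sample_costs(mean_total: float, cv: float = 0.25, S: int = 32000, seed=0) -> np.ndarray:
    """Lognormal total-cost draws with arithmetic mean ``mean_total``, sd = cv x mean."""
    if cv <= 0:
        raise ValueError("cv must be positive")
    mu, sigma = lognormal_from_mean_cv(mean_total, cv)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=sigma, size=S)


def accounts_to_csv(accounts, path) -> None:
    rows = [
        {
            "Type": _TYPE_FROM_CATEGORY[a.category],
            "Account": a.name,
            "Life span": a.lifespan_years,
            "Unit Cost USD": a.unit_cost_usd,
            "Unit Cost GHS": a.unit_cost_ghs,
            "Total Cost USD": a.total_cost_usd,
        }
        for a in accounts
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def accounts_from_csv(path) -> tuple[CostAccount, ...]:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cost table missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        life = row["Life span"]
        life = "once" if str(life).strip().lower() == "once" else int(life)
        out.append(
            CostAccount(
                name=row["Account"],
                category=_CATEGORY_FROM_TYPE[row["Type"]],
                lifespan_years=life,
                total_cost_usd=float(row["Total Cost USD"]),
                unit_cost_usd=float(row["Unit Cost USD"]),
                unit_cost_ghs=float(row["Unit Cost GHS"]),
            )
        )
    return tuple(out)
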