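"""Result containers and the published burden-panel fixture.

:class:`SimulationResult` holds per-condition 10-year outcomes per 10,000
adults (incidence, deaths, DALYs).  The totals row is always computed as the
exact sum of the condition rows, and scenario-minus-baseline deltas are exact
differences — the aggregation layer never stores totals independently of the
rows they summarize.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .risk import CONDITIONS

__all__ = [
    "QUANTITIES",
    "SimulationResult",
    "baseline_panel_result",
    "load_burden_panel",
    "panel_delta_result",
]

QUANTITIES = ["incidence_per_10k", "deaths_per_10k", "dalys_per_10k"]
_PANEL_KEYS = {"incidence_per_10k": "incidence", "deaths_per_10k": "mortality",
               "dalys_per_10k": "dalys"}


@functools.lru_cache(maxsize=1)
def load_burden_panel() -> dict:
    """The published 10-year burden panel (baseline and per-intervention
    change-from-baseline blocks, per 10,000 adults)."""
    with resources.files("ncdsim.data").joinpath("burden_panel.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class SimulationResult:
    """Per-condition outcomes per 10,000 over the horizon for one scenario.

    ``data`` is indexed by condition with columns :data:`QUANTITIES`;
    ``intervals`` optionally carries Monte-Carlo (or published) 95% bounds as
    ``<quantity>_lo`` / ``<quantity>_hi`` columns, always stored sorted
    (lower, upper).
    """

    scenario: str
    data: pd.DataFrame
    intervals: pd.DataFrame | None = None
    other_cause_deaths_per_10k: float = 0.0
    cost: object = None          # CostLedger for scenario runs
    meta: dict = field(default_factory=dict)

    def totals(self) -> pd.Series:
        """Totals row: exact sum of the condition rows."""
        return self.data.sum(axis=0)

    def deltas(self, baseline: "SimulationResult") -> pd.DataFrame:
        """Scenario minus baseline, exact, aligned by condition."""
        return self.data - baseline.data.loc[self.data.index]

    def dalys_averted(self, baseline: "SimulationResult") -> float:
        return float(-self.deltas(baseline)["dalys_per_10k"].sum())

    def to_table(self, baseline: "SimulationResult" = None) -> pd.DataFrame:
        """Publication-style layout: condition rows plus a totals row, with
        change-from-baseline columns when a baseline is attached."""
        tab = self.data.copy()
        tab.loc["total"] = self.totals()
        if baseline is not None:
            d = self.deltas(baseline)
            d.loc["total"] = d.sum(axis=0)
            for q in QUANTITIES:
                tab[f"delta_{q}"] = d[q]
        tab.insert(0, "scenario", self.scenario)
        return tab


def _panel_frame(block: dict, index_col: int) -> pd.DataFrame:
    rows = {}
    for cond in CONDITIONS:
        rows[cond] = {q: float(block[cond][_PANEL_KEYS[q]][index_col]) for q in QUANTITIES}
    return pd.DataFrame.from_dict(rows, orient="index")[QUANTITIES]


def _panel_intervals(block: dict) -> pd.DataFrame:
    rows = {}
    for cond in CONDITIONS:
        r = {}
        for q in QUANTITIES:
            lo, hi = sorted(block[cond][_PANEL_KEYS[q]][1:3])
            r[f"{q}_lo"], r[f"{q}_hi"] = float(lo), float(hi)
        rows[cond] = r
    return pd.DataFrame.from_dict(rows, orient="index")


def baseline_panel_result() -> SimulationResult:
    """The published baseline panel as a :class:`SimulationResult` (point
    estimates; published 95% intervals attached)."""
    panel = load_burden_panel()
    return SimulationResult(
        scenario="baseline",
        data=_panel_frame(panel["baseline"], 0),
        intervals=_panel_intervals(panel["baseline"]),
        meta={"source": "published burden panel fixture"},
    )


def panel_delta_result(who_id: str) -> SimulationResult:
    """A scenario result configured so its per-condition outcomes equal
    baseline plus the published change-from-baseline block for ``who_id``."""
    panel = load_burden_panel()
    if who_id not in panel["interventions"]:
        raise KeyError(f"no published change block for intervention {who_id!r}")
    base = _panel_frame(panel["baseline"], 0)
    delta = _panel_frame(panel["interventions"][who_id], 0)
    return SimulationResult(
        scenario=who_id,
        data=base + delta,
        intervals=_panel_intervals(panel["interventions"][who_id]),
        meta={"source": "published burden panel fixture", "delta_configured": True},
    )
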