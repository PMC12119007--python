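"""Pre-specified outcome scenario sets for the comparison study.

Each scenario set fixes a trial layout (stratum count I, per-stratum sample
size, uniform priors, target rate) and a list of true response-rate vectors.
Inactive strata respond at rate ``p0``, active strata at ``p1 > p0``; the
stepped scenarios are ``(p0, ..., p0, p1, ..., p1)`` with ``a`` trailing
active strata.  The target rate ``p*_i`` of every stratum is set to the set's
inactive rate ``p0``, so a stratum is active exactly when its true rate
exceeds the target — the convention of the underlying borrowing design.
Consequently all four strata of the mixed four-stratum scenario
(0.4, 0.4, 0.3, 0.5) count as active against ``p* = 0.15``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import TrialLayout

__all__ = ["Scenario", "ScenarioSet", "build_all_scenario_sets", "global_null",
           "scenario_table"]


@dataclass(frozen=True)
class Scenario:
    """One true response-rate vector with its active/inactive split."""

    true_rates: tuple[float, ...]
    active_set: frozenset[int]
    label: str = ""

    @property
    def n_strata(self) -> int:
        return len(self.true_rates)

    @property
    def inactive_set(self) -> frozenset[int]:
        return frozenset(range(self.n_strata)) - self.active_set


def _classify(rates: tuple[float, ...], targets: tuple[float, ...],
              label: str) -> Scenario:
    active = frozenset(i for i, (p, t) in enumerate(zip(rates, targets))
                       if p > t)
    return Scenario(true_rates=rates, active_set=active, label=label)


@dataclass(frozen=True)
class ScenarioSet:
    """A trial layout together with its ordered list of scenarios.

    The global null (no active stratum) comes first; stepped scenarios follow
    in ascending number of active strata; mixed-rate scenarios come last.
    """

    layout: TrialLayout
    scenarios: tuple[Scenario, ...]
    label: str
    p0: float
    p1: float

    def __post_init__(self) -> None:
        I = self.layout.n_strata
        if any(s.n_strata != I for s in self.scenarios):
            raise ValueError("all scenarios must match the layout's I")
        if self.scenarios[0].active_set:
            raise ValueError("the global null scenario must come first")

    @property
    def n_strata(self) -> int:
        return self.layout.n_strata

    @property
    def total_sample_size(self) -> int:
        return sum(self.layout.sample_sizes)


def _stepped_set(I: int, p0: float, p1: float, n: int,
                 active_counts: list[int],
                 mixed: list[tuple[float, ...]] | None = None,
                 label: str = "") -> ScenarioSet:
    layout = TrialLayout(sample_sizes=(n,) * I, target_rates=(p0,) * I)
    scens = []
    for a in active_counts:
        rates = (p0,) * (I - a) + (p1,) * a
        scens.append(_classify(rates, layout.target_rates, f"{a} of {I} active"))
    for k, rates in enumerate(mixed or []):
        scens.append(_classify(rates, layout.target_rates, f"mixed {k + 1}"))
    return ScenarioSet(layout=layout, scenarios=tuple(scens),
                       label=label or f"I={I}, n={n}, p0={p0}", p0=p0, p1=p1)


def build_all_scenario_sets() -> list[ScenarioSet]:
    """The seven pre-specified scenario sets, in their tabled order.

    Stratum counts run from 3 to 20 and total sample sizes from 72 to 480.
    The four-stratum n=20 set carries two extra mixed-rate scenarios
    ("one in the middle" and "linear"); the twenty-stratum set steps the
    number of active strata by two.
    """
    return [
        _stepped_set(3, 0.20, 0.50, 24, list(range(4))),
        _stepped_set(3, 0.15, 0.30, 53, list(range(4))),
        _stepped_set(4, 0.15, 0.40, 20, list(range(5)),
                     mixed=[(0.4, 0.4, 0.3, 0.5),
                            (0.15, 0.25, 0.35, 0.45)]),
        _stepped_set(4, 0.10, 0.35, 36, list(range(5))),
        _stepped_set(8, 0.15, 0.45, 15, list(range(9))),
        _stepped_set(9, 0.01, 0.10, 23, list(range(10))),
        _stepped_set(20, 0.10, 0.35, 24, list(range(0, 21, 2))),
    ]


def global_null(scenario_set: ScenarioSet) -> Scenario:
    """The scenario in which every stratum responds at the inactive rate."""
    s = scenario_set.scenarios[0]
    assert not s.active_set
    return s


def scenario_table(sets: list[ScenarioSet] | None = None) -> pd.DataFrame:
    """Flat audit table: one row per scenario with rates and active flags."""
    sets = build_all_scenario_sets() if sets is None else sets
    rows = []
    for ss in sets:
        for s in ss.scenarios:
            rows.append({
                "set": ss.label,
                "scenario": s.label,
                "rates": " ".join(f"{p:g}" for p in s.true_rates),
                "active": " ".join(
                    "1" if i in s.active_set else "0"
                    for i in range(s.n_strata)
                ),
            })
    return pd.DataFrame(rows)
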