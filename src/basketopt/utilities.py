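"""Utility functions balancing power against type-I error inflation.

Twelve utilities are studied: four single-scenario families, their
scenario-averaged versions, and the scenario-averaged versions with a hard
penalty on maximal per-stratum type-I error inflation.

Families (all to be maximized):

* ``ewp`` — discontinuous family-wise power-error: EWP at the scenario of
  interest if the FWER at a reference scenario (usually the global null)
  stays below ``eta1``, otherwise ``-xi1 * fwer``.
* ``ecd`` — same gate, expected number of correct decisions in the pass
  branch.
* ``2ewp`` — two-level family-wise power-error:
  ``ewp - (xi1*fwer + xi2*(fwer - eta2)*1(fwer > eta2))``.
* ``2pow`` — the stratum-wise analogue, summing power over active strata and
  subtracting the two-level penalty of each inactive stratum's TOER.

Averaged versions weight the single-scenario values over a scenario set
(weights sum to 1, uniform by default); for the ``ewp``/``ecd`` families the
reference scenario is the set's global null.  The penalized averaged versions
return the average when the maximal TOER over all scenarios and inactive
strata stays below ``eta3`` and ``-xi3 * max TOER`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .design import Divergence, TuningParams
from .oc import (
    DEFAULT_ENUMERATION_LIMIT,
    EnumerationLimitExceeded,
    ExactEngine,
    OCResult,
    mc_oc,
)
from .scenarios import ScenarioSet

__all__ = [
    "UtilityConfig",
    "UtilitySpec",
    "SetEvaluator",
    "u_ewp",
    "u_ecd",
    "u_2ewp",
    "u_2pow",
    "u_averaged",
    "u_averaged_penalized",
    "registry",
    "FAMILIES",
]

Family = Literal["ewp", "ecd", "2ewp", "2pow"]
FAMILIES: tuple[Family, ...] = ("ewp", "ecd", "2ewp", "2pow")


@dataclass(frozen=True)
class UtilityConfig:
    """Penalty parameters and scenario weights.

    ``xi1``/``xi2`` scale the first- and second-level error penalties, ``xi3``
    the hard penalty for maximal TOER inflation; ``eta1`` gates the
    discontinuous utilities, ``eta2`` triggers the second penalty level and
    ``eta3`` the hard penalty.  ``weights`` (if given) must match the
    scenario set and sum to 1.
    """

    xi1: float = 1.0
    xi2: float = 1.0
    xi3: float = 1000.0
    eta1: float = 0.05
    eta2: float = 0.1
    eta3: float = 0.2
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.xi1 <= 0 or self.xi2 <= 0 or self.xi3 <= 0:
            raise ValueError("penalty scales xi must be positive")
        for eta in (self.eta1, self.eta2, self.eta3):
            if not 0.0 <= eta <= 1.0:
                raise ValueError("eta thresholds must lie in [0,1]")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be nonnegative and sum to 1")

    def set_weights(self, n_scenarios: int) -> np.ndarray:
        if self.weights is None:
            return np.full(n_scenarios, 1.0 / n_scenarios)
        w = np.asarray(self.weights, dtype=float)
        if len(w) != n_scenarios:
            raise ValueError("weights length does not match scenario set")
        return w


def _hinge(x: float) -> float:
    """Second-level penalty indicator: active only strictly above 0."""
    return x if x > 0.0 else 0.0


def u_ewp(oc1: OCResult, oc2: OCResult, cfg: UtilityConfig) -> float:
    """Discontinuous family-wise power-error utility."""
    if oc2.fwer < cfg.eta1:
        return oc1.ewp
    return -cfg.xi1 * oc2.fwer


def u_ecd(oc1: OCResult, oc2: OCResult, cfg: UtilityConfig) -> float:
    """Expected-correct-decisions utility with the same FWER gate."""
    if oc2.fwer < cfg.eta1:
        return oc1.ecd
    return -cfg.xi1 * oc2.fwer


def u_2ewp(oc: OCResult, cfg: UtilityConfig) -> float:
    """Two-level family-wise power-error utility."""
    return oc.ewp - (
        cfg.xi1 * oc.fwer + cfg.xi2 * _hinge(oc.fwer - cfg.eta2)
    )


def u_2pow(oc: OCResult, cfg: UtilityConfig) -> float:
    """Two-level stratum-wise power-error utility."""
    pen = sum(
        cfg.xi1 * t + cfg.xi2 * _hinge(t - cfg.eta2) for t in oc.toer
    )
    return float(oc.power.sum() - pen)


def _single(family: Family, oc: OCResult, oc_null: OCResult,
            cfg: UtilityConfig) -> float:
    if family == "ewp":
        return u_ewp(oc, oc_null, cfg)
    if family == "ecd":
        return u_ecd(oc, oc_null, cfg)
    if family == "2ewp":
        return u_2ewp(oc, cfg)
    if family == "2pow":
        return u_2pow(oc, cfg)
    raise ValueError(f"unknown utility family {family!r}")


def u_averaged(
    family: Family,
    ocs: Sequence[OCResult],
    oc_null: OCResult,
    cfg: UtilityConfig,
) -> float:
    """Weighted scenario average of a single-scenario utility.

    ``ocs`` are the operating characteristics of the set's scenarios in set
    order; ``oc_null`` is the global null's (used as the reference scenario
    for the ``ewp``/``ecd`` families).
    """
    w = cfg.set_weights(len(ocs))
    return float(
        sum(wp * _single(family, oc, oc_null, cfg) for wp, oc in zip(w, ocs))
    )


def u_averaged_penalized(
    family: Family,
    ocs: Sequence[OCResult],
    oc_null: OCResult,
    cfg: UtilityConfig,
) -> float:
    """Scenario-averaged utility with hard penalty of maximal TOER inflation.

    The maximum runs over every scenario in the set and every truly inactive
    stratum; the gate is strict (< eta3).
    """
    toers = [t for oc in ocs for t in oc.toer]
    max_toer = max(toers) if toers else 0.0
    if max_toer < cfg.eta3:
        return u_averaged(family, ocs, oc_null, cfg)
    return -cfg.xi3 * max_toer


class SetEvaluator:
    """Evaluates operating characteristics of a whole scenario set per phi.

    Uses the exact enumeration engine when the layout admits it and falls
    back to Monte-Carlo simulation (n_mc trials, seeded) otherwise —
    mirroring the exact/simulation split of the study protocol.  One call
    computes a single decision sweep shared by every scenario of the set.
    """

    def __init__(
        self,
        scenario_set: ScenarioSet,
        divergence: Divergence = "jsd",
        enumeration_limit: int = DEFAULT_ENUMERATION_LIMIT,
        n_mc: int = 1000,
        seed: int = 0,
    ) -> None:
        self.scenario_set = scenario_set
        self.divergence: Divergence = divergence
        self.n_mc = n_mc
        self.seed = seed
        try:
            self._engine: ExactEngine | None = ExactEngine(
                scenario_set.layout, divergence, enumeration_limit
            )
        except EnumerationLimitExceeded:
            self._engine = None
        self.n_evaluations = 0

    @property
    def method(self) -> str:
        return "exact" if self._engine is not None else "monte_carlo"

    def oc_all(self, phi: TuningParams) -> list[OCResult]:
        """OCResult per scenario of the set, in set order."""
        self.n_evaluations += 1
        if self._engine is not None:
            return self._engine.oc_many(list(self.scenario_set.scenarios), phi)
        return [
            mc_oc(
                self.scenario_set.layout,
                sc,
                phi,
                self.divergence,
                n_mc=self.n_mc,
                seed=self.seed + k,
            )
            for k, sc in enumerate(self.scenario_set.scenarios)
        ]


@dataclass(frozen=True)
class UtilitySpec:
    """One of the twelve studied utility functions, bound to a scenario set.

    ``averaging`` is ``single`` (evaluate one scenario of interest against
    the set's global null), ``scenario_averaged`` or
    ``scenario_averaged_penalized``.  For ``single``, ``scenario_index``
    picks the scenario of interest.
    """

    family: Family
    averaging: Literal[
        "single", "scenario_averaged", "scenario_averaged_penalized"
    ]
    config: UtilityConfig = field(default_factory=UtilityConfig)
    scenario_index: int | None = None

    @property
    def name(self) -> str:
        suffix = {
            "single": "",
            "scenario_averaged": "_avg",
            "scenario_averaged_penalized": "_avg_pen",
        }[self.averaging]
        return f"u_{self.family}{suffix}"

    def evaluate_from_ocs(self, ocs: Sequence[OCResult]) -> float:
        """Value given the OCResults of the whole set (global null first)."""
        oc_null = ocs[0]
        if self.averaging == "single":
            idx = self.scenario_index
            if idx is None:
                raise ValueError("single-scenario utility needs scenario_index")
            return _single(self.family, ocs[idx], oc_null, self.config)
        if self.averaging == "scenario_averaged":
            return u_averaged(self.family, ocs, oc_null, self.config)
        return u_averaged_penalized(self.family, ocs, oc_null, self.config)

    def bind(self, evaluator: SetEvaluator) -> Callable[[TuningParams], float]:
        """Objective function phi -> utility value over the given evaluator."""

        def objective(phi: TuningParams) -> float:
            return self.evaluate_from_ocs(evaluator.oc_all(phi))

        return objective


def _default_single_index(scenario_set: ScenarioSet) -> int:
    """Scenario of interest for single-scenario utilities: about half the
    strata active (2 of 3, 2 of 4, 4 of 8, ...)."""
    I = scenario_set.n_strata
    want = -(-I // 2)  # ceil(I/2): 2 of 3, 2 of 4, 4 of 8
    best, best_diff = 0, np.inf
    for k, sc in enumerate(scenario_set.scenarios):
        # stepped scenarios only (skip mixed-rate ones)
        if len(set(sc.true_rates)) > 2:
            continue
        diff = abs(len(sc.active_set) - want)
        if diff < best_diff:
            best, best_diff = k, diff
    return best


def registry(
    scenario_set: ScenarioSet,
    cfg: UtilityConfig | None = None,
    single_scenario_index: int | None = None,
) -> list[UtilitySpec]:
    """The twelve studied utility specifications for a scenario set.

    Four single-scenario utilities (evaluated at the set's roughly
    half-active scenario against the global null), four scenario-averaged
    ones, and four penalized scenario-averaged ones.
    """
    cfg = cfg or UtilityConfig()
    idx = (
        single_scenario_index
        if single_scenario_index is not None
        else _default_single_index(scenario_set)
    )
    specs: list[UtilitySpec] = []
    for family in FAMILIES:
        specs.append(
            UtilitySpec(family=family, averaging="single", config=cfg,
                        scenario_index=idx)
        )
    for family in FAMILIES:
        specs.append(
            UtilitySpec(family=family, averaging="scenario_averaged", config=cfg)
        )
    for family in FAMILIES:
        specs.append(
            UtilitySpec(
                family=family,
                averaging="scenario_averaged_penalized",
                config=cfg,
            )
        )
    return specs
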