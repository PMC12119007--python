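"""Frequentist operating characteristics of the borrowing design.

The design's test decision is Bayesian, but its operating characteristics are
evaluated under true binomial sampling ("pragmatic Bayesianism"): responses
are drawn ``r_i ~ Bin(n_i, p_i)`` at the scenario's true rates and the
detection rule is applied to each response vector.  Two engines compute the
per-stratum rejection rates (type-I error for inactive strata, power for
active ones), the experiment-wise power EWP = P(some active stratum
detected), the family-wise error rate FWER = P(some inactive stratum
detected) and the expected number of correct decisions ECD:

* exact enumeration over all ``prod(n_i + 1)`` response vectors, each
  weighted by its product-binomial probability, and
* Monte-Carlo simulation with per-quantity standard errors.

Decisions for a given tuning vector are computed once per response vector and
reused across all scenarios of a set, so evaluating a scenario-averaged
utility costs one decision sweep plus cheap reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats

from .design import (
    BetaParams,
    Divergence,
    Outcome,
    TrialLayout,
    TuningParams,
    similarity_table,
)
from .scenarios import Scenario

__all__ = [
    "OCResult",
    "ExactEngine",
    "exact_oc",
    "mc_oc",
    "mcse_rate",
    "EnumerationLimitExceeded",
    "DEFAULT_ENUMERATION_LIMIT",
]

DEFAULT_ENUMERATION_LIMIT = 3_000_000


class EnumerationLimitExceeded(ValueError):
    """The layout has too many response vectors for exact enumeration."""


@dataclass(frozen=True)
class OCResult:
    """Operating characteristics of one (layout, scenario, phi) triple.

    ``rejection_rates[i]`` is the probability stratum ``i`` is detected:
    type-I error if the stratum is truly inactive, power if active.
    """

    rejection_rates: np.ndarray
    ewp: float
    fwer: float
    ecd: float
    active: np.ndarray  # boolean per stratum
    method: Literal["exact", "monte_carlo"]
    n_mc: int | None = None
    mcse_rates: np.ndarray | None = None
    mcse_ewp: float | None = None
    mcse_fwer: float | None = None
    mcse_ecd: float | None = None

    @property
    def toer(self) -> np.ndarray:
        """Rejection rates of the truly inactive strata."""
        return self.rejection_rates[~self.active]

    @property
    def power(self) -> np.ndarray:
        """Rejection rates of the truly active strata."""
        return self.rejection_rates[self.active]

    def to_record(self) -> dict:
        rec = {
            "method": self.method,
            "ewp": self.ewp,
            "fwer": self.fwer,
            "ecd": self.ecd,
        }
        for i, r in enumerate(self.rejection_rates):
            rec[f"rate_{i + 1}"] = float(r)
        if self.n_mc is not None:
            rec["n_mc"] = self.n_mc
            rec["mcse_ewp"] = self.mcse_ewp
            rec["mcse_fwer"] = self.mcse_fwer
            rec["mcse_ecd"] = self.mcse_ecd
            for i, s in enumerate(self.mcse_rates):
                rec[f"mcse_rate_{i + 1}"] = float(s)
        return rec


def mcse_rate(rate_hat: float, n_mc: int) -> float:
    """Monte-Carlo standard error sqrt(r(1-r)/n_mc) of a rejection-rate
    estimate; at most 0.016 for n_mc = 1000."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if not 0.0 <= rate_hat <= 1.0:
        raise ValueError("rate must lie in [0,1]")
    return float(np.sqrt(rate_hat * (1.0 - rate_hat) / n_mc))


def _pair_tables(
    layout: TrialLayout, divergence: Divergence
) -> dict[tuple[int, int], np.ndarray]:
    """Raw similarity table per stratum pair (i < j)."""
    I = layout.n_strata
    tables = {}
    for i in range(I):
        for j in range(i + 1, I):
            ni, nj = layout.sample_sizes[i], layout.sample_sizes[j]
            pi, pj = layout.priors[i], layout.priors[j]
            if (ni, pi) == (nj, pj):
                tables[(i, j)] = similarity_table(ni, pi, divergence)
            else:
                # general layouts: build the cross table entry by entry
                from .design import raw_similarity

                tab = np.empty((ni + 1, nj + 1))
                for ri in range(ni + 1):
                    Pi = BetaParams(pi.shape1 + ri, pi.shape2 + ni - ri)
                    for rj in range(nj + 1):
                        Pj = BetaParams(pj.shape1 + rj, pj.shape2 + nj - rj)
                        tab[ri, rj] = raw_similarity(Pi, Pj, divergence)
                tables[(i, j)] = tab
    return tables


def _decide_batch(
    layout: TrialLayout,
    R: np.ndarray,
    phi: TuningParams,
    divergence: Divergence,
    tables: dict[tuple[int, int], np.ndarray] | None = None,
) -> np.ndarray:
    """Detection decisions for a batch of response vectors (N, I) -> (N, I)."""
    I = layout.n_strata
    N = R.shape[0]
    if tables is None:
        tables = _pair_tables(layout, divergence)
    # apply shape exponent and strict cutoff on the small tables once
    weighted = {}
    for key, tab in tables.items():
        powered = np.power(tab, phi.epsilon)
        weighted[key] = np.where(powered > phi.tau, powered, 0.0)

    a_post = np.empty((N, I))
    b_post = np.empty((N, I))
    for j in range(I):
        a_post[:, j] = layout.priors[j].shape1 + R[:, j]
        b_post[:, j] = layout.priors[j].shape2 + layout.sample_sizes[j] - R[:, j]

    # weighted shape sums; diagonal weight is always 1
    a_bor = a_post.copy()
    b_bor = b_post.copy()
    for i in range(I):
        for j in range(I):
            if i == j:
                continue
            wtab = weighted[(min(i, j), max(i, j))]
            w = wtab[R[:, i], R[:, j]] if i < j else wtab[R[:, j], R[:, i]]
            a_bor[:, i] += w * a_post[:, j]
            b_bor[:, i] += w * b_post[:, j]

    # detect iff P(p > p*) >= lambda; tested on the lower tail, which stays
    # well-conditioned when the upper tail rounds to 1 in double precision
    targets = np.asarray(layout.target_rates)
    lower = special.betainc(a_bor, b_bor, targets[None, :])
    return lower <= 1.0 - phi.lambda_


def _summarize(
    decided: np.ndarray, weights: np.ndarray, active: np.ndarray
) -> tuple[np.ndarray, float, float, float]:
    D = decided.astype(np.float64)
    rates = weights @ D
    ewp = (
        float(weights @ decided[:, active].any(axis=1).astype(np.float64))
        if active.any()
        else 0.0
    )
    inactive = ~active
    fwer = (
        float(weights @ decided[:, inactive].any(axis=1).astype(np.float64))
        if inactive.any()
        else 0.0
    )
    ecd = float(rates[active].sum() + (1.0 - rates[inactive]).sum())
    return rates, ewp, fwer, ecd


class ExactEngine:
    """Exact enumeration engine for one layout and divergence.

    Enumerates every response vector once and exposes per-phi decision sweeps
    that can be reweighted for any scenario of the layout, which is how
    scenario-averaged utilities stay affordable inside optimization loops.
    """

    def __init__(
        self,
        layout: TrialLayout,
        divergence: Divergence = "jsd",
        enumeration_limit: int = DEFAULT_ENUMERATION_LIMIT,
    ) -> None:
        if layout.n_outcomes > enumeration_limit:
            raise EnumerationLimitExceeded(
                f"{layout.n_outcomes} response vectors exceed the limit of "
                f"{enumeration_limit}; use mc_oc instead"
            )
        self.layout = layout
        self.divergence: Divergence = divergence
        grids = [np.arange(n + 1) for n in layout.sample_sizes]
        mesh = np.meshgrid(*grids, indexing="ij")
        self.outcomes = np.stack([m.ravel() for m in mesh], axis=1)
        self._tables = _pair_tables(layout, divergence)
        self._weight_cache: dict[tuple[float, ...], np.ndarray] = {}
        # With exchangeable strata (equal sizes, priors and targets) the
        # decision for stratum i depends only on (r_i, multiset of the other
        # responses); collapsing to unique combinations cuts the number of
        # posterior tail evaluations per decision sweep by an order of
        # magnitude.
        self._exchangeable = (
            layout.n_strata > 1
            and len(set(layout.sample_sizes)) == 1
            and len(set(layout.priors)) == 1
            and len(set(layout.target_rates)) == 1
        )
        if self._exchangeable:
            R = self.outcomes
            I = layout.n_strata
            combos = np.empty((R.shape[0], I, I), dtype=R.dtype)
            for i in range(I):
                rest = np.sort(np.delete(R, i, axis=1), axis=1)
                combos[:, i, 0] = R[:, i]
                combos[:, i, 1:] = rest
            flat = combos.reshape(-1, I)
            self._unique_combos, inverse = np.unique(
                flat, axis=0, return_inverse=True
            )
            self._combo_index = inverse.reshape(R.shape[0], I)

    def _decisions_exchangeable(self, phi: TuningParams) -> np.ndarray:
        U = self._unique_combos
        prior = self.layout.priors[0]
        n = self.layout.sample_sizes[0]
        tab = similarity_table(n, prior, self.divergence)
        powered = np.power(tab, phi.epsilon)
        wtab = np.where(powered > phi.tau, powered, 0.0)
        a = prior.shape1 + U[:, 0].astype(float)
        b = prior.shape2 + n - U[:, 0].astype(float)
        for k in range(1, U.shape[1]):
            w = wtab[U[:, 0], U[:, k]]
            a += w * (prior.shape1 + U[:, k])
            b += w * (prior.shape2 + n - U[:, k])
        lower = special.betainc(a, b, self.layout.target_rates[0])
        detected = lower <= 1.0 - phi.lambda_
        return detected[self._combo_index]

    def decisions(self, phi: TuningParams) -> np.ndarray:
        if self._exchangeable:
            return self._decisions_exchangeable(phi)
        return _decide_batch(
            self.layout, self.outcomes, phi, self.divergence, self._tables
        )

    def outcome_weights(self, scenario: Scenario) -> np.ndarray:
        """Product-binomial probability of every enumerated response vector."""
        key = tuple(scenario.true_rates)
        cached = self._weight_cache.get(key)
        if cached is not None:
            return cached
        w = np.ones(len(self.outcomes))
        for i, (n, p) in enumerate(
            zip(self.layout.sample_sizes, scenario.true_rates)
        ):
            pmf = stats.binom.pmf(np.arange(n + 1), n, p)
            w *= pmf[self.outcomes[:, i]]
        self._weight_cache[key] = w
        return w

    def oc(self, scenario: Scenario, phi: TuningParams) -> OCResult:
        return self.oc_many([scenario], phi)[0]

    def oc_many(
        self, scenarios: Sequence[Scenario], phi: TuningParams
    ) -> list[OCResult]:
        """Operating characteristics for several scenarios sharing one
        decision sweep."""
        decided = self.decisions(phi)
        results = []
        for sc in scenarios:
            if len(sc.true_rates) != self.layout.n_strata:
                raise ValueError("scenario does not match layout")
            weights = self.outcome_weights(sc)
            total = weights.sum()
            if abs(total - 1.0) > 1e-12:
                raise FloatingPointError(
                    f"outcome probability mass {total} not 1"
                )
            active = np.zeros(self.layout.n_strata, dtype=bool)
            active[list(sc.active_set)] = True
            rates, ewp, fwer, ecd = _summarize(decided, weights, active)
            results.append(
                OCResult(
                    rejection_rates=rates,
                    ewp=ewp,
                    fwer=fwer,
                    ecd=ecd,
                    active=active,
                    method="exact",
                )
            )
        return results


def exact_oc(
    layout: TrialLayout,
    scenario: Scenario,
    phi: TuningParams,
    divergence: Divergence = "jsd",
    enumeration_limit: int = DEFAULT_ENUMERATION_LIMIT,
) -> OCResult:
    """Exact operating characteristics by full outcome enumeration."""
    return ExactEngine(layout, divergence, enumeration_limit).oc(scenario, phi)


def mc_oc(
    layout: TrialLayout,
    scenario: Scenario,
    phi: TuningParams,
    divergence: Divergence = "jsd",
    n_mc: int = 1000,
    seed: int = 0,
) -> OCResult:
    """Monte-Carlo operating characteristics from n_mc simulated trials."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    I = layout.n_strata
    R = np.empty((n_mc, I), dtype=np.int64)
    for i, (n, p) in enumerate(zip(layout.sample_sizes, scenario.true_rates)):
        R[:, i] = rng.binomial(n, p, size=n_mc)
    decided = _decide_batch(layout, R, phi, divergence)

    active = np.zeros(I, dtype=bool)
    active[list(scenario.active_set)] = True
    weights = np.full(n_mc, 1.0 / n_mc)
    rates, ewp, fwer, ecd = _summarize(decided, weights, active)

    correct = np.where(active[None, :], decided, ~decided).sum(axis=1)
    mcse_ecd = float(correct.std(ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else 0.0
    return OCResult(
        rejection_rates=rates,
        ewp=ewp,
        fwer=fwer,
        ecd=ecd,
        active=active,
        method="monte_carlo",
        n_mc=n_mc,
        mcse_rates=np.array([mcse_rate(r, n_mc) for r in rates]),
        mcse_ewp=mcse_rate(ewp, n_mc),
        mcse_fwer=mcse_rate(fwer, n_mc),
        mcse_ecd=mcse_ecd,
    )
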