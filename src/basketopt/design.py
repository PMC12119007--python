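"""Beta-binomial basket-trial design with divergence-based information borrowing.

A basket trial tests one therapy in ``I`` strata ("baskets") against a common
target response rate, without a control arm.  Each stratum ``i`` observes
``r_i ~ Bin(n_i, p_i)`` responders with a conjugate ``Beta(a_i, b_i)`` prior on
the response rate, so the stand-alone posterior is ``Beta(a_i + r_i,
b_i + n_i - r_i)``.  Borrowing shares information between strata whose
stand-alone posteriors look alike: the pairwise similarity

    w~_ij = 1 - D(post_i, post_j)

(for a divergence ``D``, by default the Jensen-Shannon divergence under the
natural logarithm) is sharpened and thresholded into borrowing weights

    w_ij = w~_ij ** eps   if w~_ij ** eps > tau,  else 0,

and the borrowing posterior of stratum ``i`` is the beta distribution whose
shapes are the ``w_ij``-weighted sums of all strata's posterior shapes.
Stratum ``i`` is *detected* (declared active) when the borrowing posterior
puts mass at least ``lambda`` above the target rate ``p*_i``.

The tuning vector ``phi = (lambda, eps, tau)`` is the object this package
optimizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, special

__all__ = [
    "BetaParams",
    "TrialLayout",
    "TuningParams",
    "Outcome",
    "SimilarityMatrix",
    "posterior_params",
    "kld",
    "jsd",
    "hellinger",
    "raw_similarity",
    "similarity_table",
    "similarity_matrix",
    "borrowed_posterior",
    "decide",
    "extreme_borrowing_boundary",
    "clear_similarity_cache",
]

Divergence = Literal["jsd", "hellinger"]

LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution; both must be positive."""

    shape1: float
    shape2: float

    def __post_init__(self) -> None:
        if not (self.shape1 > 0 and self.shape2 > 0):
            raise ValueError(f"beta shapes must be positive, got {self}")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        a, b = self.shape1, self.shape2
        return (
            special.xlogy(a - 1.0, x)
            + special.xlog1py(b - 1.0, -x)
            - special.betaln(a, b)
        )

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def upper_tail(self, x: float) -> float:
        """P(p > x) under this beta distribution."""
        return float(special.betaincc(self.shape1, self.shape2, x))


@dataclass(frozen=True)
class TuningParams:
    """Tuning vector phi = (lambda, eps, tau) of the borrowing design.

    ``lambda_`` is the detection threshold in [0, 1], ``epsilon`` the
    similarity-weight shape exponent in [0, inf), ``tau`` the similarity
    cutoff in [0, 1].
    """

    lambda_: float
    epsilon: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError(f"lambda must lie in [0,1], got {self.lambda_}")
        if self.epsilon < 0.0:
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0,1], got {self.tau}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda_, self.epsilon, self.tau], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TuningParams":
        return cls(float(x[0]), float(x[1]), float(x[2]))


@dataclass(frozen=True)
class TrialLayout:
    """Structural description of the basket trial.

    Parameters
    ----------
    sample_sizes
        Per-stratum patient counts ``n_i`` (length ``I >= 1``).
    target_rates
        Per-stratum target response rates ``p*_i`` in (0, 1) against which
        detection is tested.
    priors
        Per-stratum beta priors; defaults to the uninformative (1, 1).
    """

    sample_sizes: tuple[int, ...]
    target_rates: tuple[float, ...]
    priors: tuple[BetaParams, ...] = field(default=())

    def __post_init__(self) -> None:
        n = tuple(int(v) for v in self.sample_sizes)
        object.__setattr__(self, "sample_sizes", n)
        if any(v < 1 for v in n):
            raise ValueError("sample sizes must be >= 1")
        p = tuple(float(v) for v in self.target_rates)
        object.__setattr__(self, "target_rates", p)
        if len(p) != len(n):
            raise ValueError("target_rates length must match sample_sizes")
        if any(not (0.0 < v < 1.0) for v in p):
            raise ValueError("target rates must lie strictly inside (0,1)")
        priors = self.priors or tuple(BetaParams(1.0, 1.0) for _ in n)
        object.__setattr__(self, "priors", tuple(priors))
        if len(self.priors) != len(n):
            raise ValueError("priors length must match sample_sizes")

    @property
    def n_strata(self) -> int:
        return len(self.sample_sizes)

    @property
    def n_outcomes(self) -> int:
        """Number of distinct response vectors, prod(n_i + 1)."""
        out = 1
        for n in self.sample_sizes:
            out *= n + 1
        return out


@dataclass(frozen=True)
class Outcome:
    """Observed responder counts r_i, one per stratum."""

    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "responses", tuple(int(r) for r in self.responses)
        )

    def validate(self, layout: TrialLayout) -> None:
        if len(self.responses) != layout.n_strata:
            raise ValueError("outcome length does not match layout")
        for r, n in zip(self.responses, layout.sample_sizes):
            if not 0 <= r <= n:
                raise ValueError(f"response count {r} outside [0, {n}]")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Raw (w~_ij) and weighted (w_ij) pairwise similarity matrices."""

    raw: np.ndarray
    weighted: np.ndarray


def posterior_params(
    layout: TrialLayout, outcome: Outcome, stratum: int
) -> BetaParams:
    """Stand-alone (no borrowing) posterior of one stratum.

    Conjugate update: ``Beta(a_i + r_i, b_i + n_i - r_i)``.
    """
    outcome.validate(layout)
    if not 0 <= stratum < layout.n_strata:
        raise IndexError(f"stratum {stratum} out of range")
    prior = layout.priors[stratum]
    r = outcome.responses[stratum]
    n = layout.sample_sizes[stratum]
    return BetaParams(prior.shape1 + r, prior.shape2 + n - r)


# ---------------------------------------------------------------------------
# Divergences between beta posteriors
# ---------------------------------------------------------------------------


def _kld_to_mixture(P: BetaParams, Q: BetaParams) -> float:
    """KL divergence of P from the equal mixture M = (P+Q)/2, natural log."""

    def integrand(x: float) -> float:
        lp = P.logpdf(x)
        if not np.isfinite(lp):  # density 0 -> integrand 0 by convention
            return 0.0
        p = np.exp(lp)
        m = 0.5 * (p + Q.pdf(x))
        return float(p * (lp - np.log(m)))

    val, _ = integrate.quad(
        integrand, 0.0, 1.0, epsabs=1e-11, epsrel=1e-10, limit=200
    )
    if not np.isfinite(val):
        raise FloatingPointError(
            f"non-finite KLD integral for shapes {P}, {Q}"
        )
    return val


def kld(P: BetaParams, Q: BetaParams) -> float:
    """Kullback-Leibler divergence KLD(P || Q) between betas, natural log.

    Computed by adaptive quadrature on (0, 1); the integrand is taken to be 0
    wherever P's density vanishes.
    """

    def integrand(x: float) -> float:
        lp = P.logpdf(x)
        if not np.isfinite(lp):
            return 0.0
        return float(np.exp(lp) * (lp - Q.logpdf(x)))

    val, _ = integrate.quad(
        integrand, 0.0, 1.0, epsabs=1e-11, epsrel=1e-10, limit=200
    )
    if not np.isfinite(val):
        raise FloatingPointError(f"non-finite KLD integral for {P}, {Q}")
    return val


def jsd(P: BetaParams, Q: BetaParams) -> float:
    """Jensen-Shannon divergence, natural log: bounded by log 2 ~ 0.6931.

    JSD(P, Q) = (KLD(P || M) + KLD(Q || M)) / 2 with M the equal mixture.
    """
    if P == Q:
        return 0.0
    val = 0.5 * (_kld_to_mixture(P, Q) + _kld_to_mixture(Q, P))
    # clip quadrature noise at the theoretical boundaries
    return float(min(max(val, 0.0), LOG2))


def hellinger(P: BetaParams, Q: BetaParams) -> float:
    """Squared-type Hellinger distance 1 - int sqrt(P Q) between betas.

    Closed form via the beta function, evaluated in log space so extreme
    shapes do not overflow:

        HLD = 1 - B((a1+a2)/2, (b1+b2)/2) / sqrt(B(a1,b1) B(a2,b2)).
    """
    a1, b1 = P.shape1, P.shape2
    a2, b2 = Q.shape1, Q.shape2
    log_bc = special.betaln(0.5 * (a1 + a2), 0.5 * (b1 + b2)) - 0.5 * (
        special.betaln(a1, b1) + special.betaln(a2, b2)
    )
    val = 1.0 - float(np.exp(log_bc))
    return float(min(max(val, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Similarity weights
# ---------------------------------------------------------------------------

# Raw similarity depends only on the two posterior shape pairs, so exact
# enumeration over all response vectors needs only O(max_i (n_i+1)^2)
# integrals.  The cache is shared process-wide.
_SIM_CACHE: dict[tuple, float] = {}
_TABLE_CACHE: dict[tuple, np.ndarray] = {}


def clear_similarity_cache() -> None:
    _SIM_CACHE.clear()
    _TABLE_CACHE.clear()


def raw_similarity(
    P: BetaParams, Q: BetaParams, divergence: Divergence = "jsd"
) -> float:
    """w~ = 1 - D(P, Q) for the chosen divergence, memoized."""
    ka, kb = (P.shape1, P.shape2), (Q.shape1, Q.shape2)
    key = (divergence, min(ka, kb), max(ka, kb))
    try:
        return _SIM_CACHE[key]
    except KeyError:
        pass
    if divergence == "jsd":
        val = 1.0 - jsd(P, Q)
    elif divergence == "hellinger":
        val = 1.0 - hellinger(P, Q)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown divergence {divergence!r}")
    _SIM_CACHE[key] = val
    return val


def similarity_table(
    n: int, prior: BetaParams = BetaParams(1.0, 1.0),
    divergence: Divergence = "jsd",
) -> np.ndarray:
    """(n+1) x (n+1) table of raw similarities between the posteriors of all
    response-count pairs (r, r') for a single stratum size and prior."""
    key = (n, prior.shape1, prior.shape2, divergence)
    try:
        return _TABLE_CACHE[key]
    except KeyError:
        pass
    posts = [
        BetaParams(prior.shape1 + r, prior.shape2 + n - r)
        for r in range(n + 1)
    ]
    tab = np.ones((n + 1, n + 1))
    for r in range(n + 1):
        for s in range(r + 1, n + 1):
            tab[r, s] = tab[s, r] = raw_similarity(
                posts[r], posts[s], divergence
            )
    _TABLE_CACHE[key] = tab
    return tab


def _weight(raw: np.ndarray, phi: TuningParams) -> np.ndarray:
    """Apply shape exponent and strict cutoff: w = w~^eps if w~^eps > tau."""
    powered = np.power(raw, phi.epsilon)
    return np.where(powered > phi.tau, powered, 0.0)


def similarity_matrix(
    layout: TrialLayout,
    outcome: Outcome,
    phi: TuningParams,
    divergence: Divergence = "jsd",
) -> SimilarityMatrix:
    """Pairwise borrowing weights for one observed outcome.

    Raw entries are ``w~_ij = 1 - D(post_i, post_j)`` of the stand-alone
    posteriors; weighted entries are ``w~_ij^eps`` when strictly above
    ``tau``, else 0.  The diagonal of the weighted matrix is forced to 1 so a
    stratum always fully retains its own data (with ``tau = 1`` a literal
    reading would zero out self-borrowing and break the design).
    """
    outcome.validate(layout)
    I = layout.n_strata
    posts = [posterior_params(layout, outcome, i) for i in range(I)]
    raw = np.ones((I, I))
    for i in range(I):
        for j in range(i + 1, I):
            raw[i, j] = raw[j, i] = raw_similarity(posts[i], posts[j], divergence)
    weighted = _weight(raw, phi)
    np.fill_diagonal(weighted, 1.0)
    return SimilarityMatrix(raw=raw, weighted=weighted)


def borrowed_posterior(
    layout: TrialLayout,
    outcome: Outcome,
    weights: SimilarityMatrix,
    stratum: int,
) -> BetaParams:
    """Borrowing posterior: beta with weight-summed shape parameters.

    ``Beta(sum_j w_ij (a_j + r_j), sum_j w_ij (b_j + n_j - r_j))``.
    """
    outcome.validate(layout)
    if not 0 <= stratum < layout.n_strata:
        raise IndexError(f"stratum {stratum} out of range")
    w = weights.weighted[stratum]
    a = sum(
        wj * (layout.priors[j].shape1 + outcome.responses[j])
        for j, wj in enumerate(w)
    )
    b = sum(
        wj
        * (
            layout.priors[j].shape2
            + layout.sample_sizes[j]
            - outcome.responses[j]
        )
        for j, wj in enumerate(w)
    )
    if not (a > 0 and b > 0):
        raise ValueError("nonpositive borrowing posterior shape")
    return BetaParams(a, b)


def decide(
    layout: TrialLayout,
    outcome: Outcome,
    phi: TuningParams,
    divergence: Divergence = "jsd",
) -> np.ndarray:
    """Per-stratum detection decisions for one outcome.

    Stratum ``i`` is detected when ``P(p_i > p*_i | r) >= lambda`` under its
    borrowing posterior; the tail probability is one minus the regularized
    incomplete beta function.
    """
    weights = similarity_matrix(layout, outcome, phi, divergence)
    out = np.zeros(layout.n_strata, dtype=bool)
    for i in range(layout.n_strata):
        post = borrowed_posterior(layout, outcome, weights, i)
        # P(p > p*) >= lambda, tested on the lower tail where the upper tail
        # would round to 1 in double precision (so lambda = 1 never detects)
        lower = special.betainc(post.shape1, post.shape2, layout.target_rates[i])
        out[i] = lower <= 1.0 - phi.lambda_
    return out


def extreme_borrowing_boundary(
    layout: TrialLayout, tau: float, divergence: Divergence = "jsd"
) -> float:
    """Shape exponent above which borrowing collapses to the equal-responses
    indicator.

    Let ``w~* = max w~`` over all pairs of per-stratum outcomes with unequal
    response counts, enumerated over the layout's sample sizes.  For
    ``eps > log(tau)/log(w~*)`` every unequal pair's weight falls below tau
    while equal pairs keep weight 1, so raising eps (or tau) further cannot
    change any decision.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly in (0,1) for the boundary")
    if layout.n_strata < 2:
        raise ValueError("boundary requires at least two strata")
    best = -np.inf
    I = layout.n_strata
    for i in range(I):
        for j in range(i + 1, I):
            ni, nj = layout.sample_sizes[i], layout.sample_sizes[j]
            pi, pj = layout.priors[i], layout.priors[j]
            for ri in range(ni + 1):
                Pi = BetaParams(pi.shape1 + ri, pi.shape2 + ni - ri)
                for rj in range(nj + 1):
                    if ri == rj:
                        continue
                    Pj = BetaParams(pj.shape1 + rj, pj.shape2 + nj - rj)
                    best = max(best, raw_similarity(Pi, Pj, divergence))
    if not np.isfinite(best) or best <= 0.0:
        raise ValueError("layout admits no unequal response pair")
    return float(np.log(tau) / np.log(best))
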