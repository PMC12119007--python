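"""Posteriors, divergences, borrowing weights and the detection rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from basketopt import (
    Outcome,
    TrialLayout,
    TuningParams,
    borrowed_posterior,
    decide,
    extreme_borrowing_boundary,
    hellinger,
    jsd,
    kld,
    posterior_params,
    similarity_matrix,
)
from basketopt.design import LOG2, BetaParams

# Frozen oracle values from composite Gauss-Legendre quadrature at 1e5 nodes
# (panels of order-50 rules), agreeing with an independent 1e6-node run to
# well below the asserted tolerances.
KLD_UNIFORM_VS_MIX = 0.17660262192770512  # KLD(Beta(1,1) || mix with Beta(5,1))
JSD_UNIFORM_VS_51 = 0.2161926317872664
HELLINGER_11_22 = 0.03808762737860216  # equals 1 - (pi/8) * sqrt(6)
BORROWED_SHAPES_5_5_12 = [
    (15.026421739620089, 43.02642173962009),
    (15.026421739620089, 43.02642173962009),
    (15.793620067341621, 22.312066891138734),
]
EPS_EXTREME_N24_TAU07 = 17.98999786771374


@pytest.mark.parametrize(
    "prior, n, r, expected",
    [
        ((1, 1), 24, 0, (1, 25)),
        ((1, 1), 24, 10, (11, 15)),
        ((2, 3), 10, 4, (6, 9)),
    ],
)
def test_posterior_params_conjugate_update(prior, n, r, expected):
    layout = TrialLayout(
        sample_sizes=(n,),
        target_rates=(0.2,),
        priors=(BetaParams(*prior),),
    )
    post = posterior_params(layout, Outcome((r,)), 0)
    assert (post.shape1, post.shape2) == expected


def test_posterior_params_index_out_of_range(layout3):
    with pytest.raises(IndexError):
        posterior_params(layout3, Outcome((0, 0, 0)), 3)


def test_kld_of_identical_densities_is_zero():
    assert kld(BetaParams(2, 2), BetaParams(2, 2)) == pytest.approx(0.0, abs=1e-12)


def test_kld_against_quadrature_oracle():
    # KLD of the uniform from its equal mixture with Beta(5,1)
    from basketopt.design import _kld_to_mixture

    val = _kld_to_mixture(BetaParams(1, 1), BetaParams(5, 1))
    assert val == pytest.approx(KLD_UNIFORM_VS_MIX, abs=1e-8)


def test_jsd_value_symmetry_and_identity():
    assert jsd(BetaParams(1, 1), BetaParams(5, 1)) == pytest.approx(
        JSD_UNIFORM_VS_51, abs=1e-8
    )
    assert jsd(BetaParams(11, 15), BetaParams(11, 15)) == 0.0
    p, q = BetaParams(3, 21), BetaParams(9, 13)
    assert jsd(p, q) == pytest.approx(jsd(q, p), abs=1e-10)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    a1=st.floats(1.0, 40.0),
    b1=st.floats(1.0, 40.0),
    a2=st.floats(1.0, 40.0),
    b2=st.floats(1.0, 40.0),
)
def test_jsd_is_symmetric_and_bounded(a1, b1, a2, b2):
    p, q = BetaParams(a1, b1), BetaParams(a2, b2)
    v = jsd(p, q)
    assert 0.0 <= v <= LOG2
    assert v == pytest.approx(jsd(q, p), abs=1e-9)


def test_hellinger_closed_form_and_symmetry():
    assert hellinger(BetaParams(1, 1), BetaParams(2, 2)) == pytest.approx(
        HELLINGER_11_22, abs=1e-12
    )
    assert hellinger(BetaParams(3, 7), BetaParams(3, 7)) == pytest.approx(
        0.0, abs=1e-12
    )
    assert hellinger(BetaParams(3, 7), BetaParams(7, 3)) == pytest.approx(
        hellinger(BetaParams(7, 3), BetaParams(3, 7)), abs=1e-15
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a1=st.floats(1.0, 60.0),
    b1=st.floats(1.0, 60.0),
    a2=st.floats(1.0, 60.0),
    b2=st.floats(1.0, 60.0),
)
def test_hellinger_matches_direct_quadrature(a1, b1, a2, b2):
    p, q = BetaParams(a1, b1), BetaParams(a2, b2)

    def integrand(x):
        return np.sqrt(stats.beta.pdf(x, a1, b1) * stats.beta.pdf(x, a2, b2))

    bc, _ = integrate.quad(integrand, 0, 1, epsabs=1e-12, limit=300)
    assert hellinger(p, q) == pytest.approx(1.0 - bc, abs=1e-8)


def test_hellinger_extreme_shapes_stay_finite():
    v = hellinger(BetaParams(5000, 8000), BetaParams(5050, 7950))
    assert 0.0 < v < 1.0
    assert np.isfinite(hellinger(BetaParams(5000, 8000), BetaParams(4000, 9000)))


class TestSimilarityMatrix:
    def test_zero_exponent_gives_full_borrowing(self, layout3):
        sm = similarity_matrix(
            layout3, Outcome((0, 10, 24)), TuningParams(0.5, 0.0, 0.5)
        )
        assert np.allclose(sm.weighted, 1.0)

    def test_fujikawa_setting_squares_raw_similarity(self, layout3):
        phi = TuningParams(0.99, 2.0, 0.0)
        sm = similarity_matrix(layout3, Outcome((5, 5, 12)), phi)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(sm.weighted[off], sm.raw[off] ** 2)
        assert np.allclose(np.diag(sm.weighted), 1.0)

    def test_raw_similarity_range_and_symmetry(self, layout3):
        sm = similarity_matrix(
            layout3, Outcome((0, 12, 24)), TuningParams(0.9, 1.0, 0.0)
        )
        assert np.allclose(sm.raw, sm.raw.T)
        assert (sm.raw >= 1.0 - LOG2 - 1e-12).all()
        assert (sm.raw <= 1.0 + 1e-12).all()

    def test_tau_one_switches_off_borrowing(self, layout3):
        sm = similarity_matrix(
            layout3, Outcome((5, 5, 12)), TuningParams(0.99, 2.0, 1.0)
        )
        assert np.allclose(sm.weighted, np.eye(3))

    def test_above_extreme_boundary_weights_are_equality_indicator(self):
        layout = TrialLayout(sample_sizes=(4, 4, 4), target_rates=(0.2,) * 3)
        tau = 0.5
        eps = extreme_borrowing_boundary(layout, tau) + 0.5
        phi = TuningParams(0.9, eps, tau)
        # exhaustive over all 125 outcomes of the n_i = 4 layout
        for r1 in range(5):
            for r2 in range(5):
                for r3 in range(5):
                    out = Outcome((r1, r2, r3))
                    sm = similarity_matrix(layout, out, phi)
                    r = np.array([r1, r2, r3])
                    indicator = (r[:, None] == r[None, :]).astype(float)
                    assert np.array_equal(sm.weighted, indicator)


class TestBorrowedPosterior:
    def test_no_borrowing_reduces_to_plain_posterior(self, layout3):
        out = Outcome((3, 9, 20))
        phi = TuningParams(0.9, 2.0, 1.0)  # tau=1: all off-diagonal zero
        sm = similarity_matrix(layout3, out, phi)
        for i in range(3):
            plain = posterior_params(layout3, out, i)
            bor = borrowed_posterior(layout3, out, sm, i)
            assert bor == plain

    def test_full_borrowing_sums_shapes(self):
        layout = TrialLayout(sample_sizes=(24, 24), target_rates=(0.2, 0.2))
        out = Outcome((10, 10))
        sm = similarity_matrix(layout, out, TuningParams(0.9, 0.0, 0.0))
        bor = borrowed_posterior(layout, out, sm, 0)
        assert (bor.shape1, bor.shape2) == (22.0, 30.0)

    def test_fujikawa_setting_weighted_sums(self, layout3):
        out = Outcome((5, 5, 12))
        sm = similarity_matrix(layout3, out, TuningParams(0.99, 2.0, 0.0))
        for i, (a, b) in enumerate(BORROWED_SHAPES_5_5_12):
            bor = borrowed_posterior(layout3, out, sm, i)
            assert bor.shape1 == pytest.approx(a, abs=1e-6)
            assert bor.shape2 == pytest.approx(b, abs=1e-6)


class TestDecide:
    def test_lambda_zero_detects_all(self, layout3):
        assert decide(layout3, Outcome((0, 0, 0)), TuningParams(0.0, 2, 0)).all()

    def test_lambda_one_detects_none(self, layout3):
        assert not decide(
            layout3, Outcome((24, 24, 24)), TuningParams(1.0, 2, 0)
        ).any()

    def test_single_stratum_matches_incomplete_beta(self):
        layout = TrialLayout(sample_sizes=(24,), target_rates=(0.2,))
        expected = stats.beta.sf(0.2, 11, 15) >= 0.9
        got = decide(layout, Outcome((10,)), TuningParams(0.9, 2.0, 0.0))[0]
        assert got == expected

    def test_monotone_in_lambda(self, layout3, rng):
        for _ in range(10):
            out = Outcome(tuple(rng.integers(0, 25, size=3)))
            prev = np.ones(3, dtype=bool)
            for lam in np.linspace(0.0, 1.0, 9):
                d = decide(layout3, out, TuningParams(lam, 2.0, 0.3))
                assert not (d & ~prev).any()  # raising lambda never adds detections
                prev = d


class TestExtremeBorrowingBoundary:
    def test_value_for_flagship_layout(self, layout3):
        assert extreme_borrowing_boundary(layout3, 0.7) == pytest.approx(
            EPS_EXTREME_N24_TAU07, rel=1e-6
        )

    def test_at_max_similarity_boundary_is_one(self, layout3):
        # tau equal to the largest unequal-pair similarity gives exponent 1
        from basketopt.design import BetaParams, raw_similarity

        best = max(
            raw_similarity(
                BetaParams(1 + r, 25 - r), BetaParams(1 + s, 25 - s)
            )
            for r in range(25)
            for s in range(r + 1, 25)
        )
        assert extreme_borrowing_boundary(layout3, best) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_decreasing_in_tau(self, layout3):
        e1 = extreme_borrowing_boundary(layout3, 0.3)
        e2 = extreme_borrowing_boundary(layout3, 0.7)
        assert e1 > e2

    def test_degenerate_tau_rejected(self, layout3):
        with pytest.raises(ValueError):
            extreme_borrowing_boundary(layout3, 0.0)
        with pytest.raises(ValueError):
            extreme_borrowing_boundary(layout3, 1.0)


def test_tuning_params_bounds_validated():
    with pytest.raises(ValueError):
        TuningParams(-0.1, 1.0, 0.5)
    with pytest.raises(ValueError):
        TuningParams(0.5, -1.0, 0.5)
    with pytest.raises(ValueError):
        TuningParams(0.5, 1.0, 1.5)


def test_outcome_validation(layout3):
    with pytest.raises(ValueError):
        Outcome((25, 0, 0)).validate(layout3)
    with pytest.raises(ValueError):
        Outcome((1, 2)).validate(layout3)
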