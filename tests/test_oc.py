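"""Exact and Monte-Carlo operating characteristics.

The exact engine is checked against a deliberately naive brute force that
re-derives every quantity from first principles (its own quadrature-based
divergence, explicit loops over outcomes) on a 9-outcome layout.
"""

import numpy as np
import pytest
from scipy import integrate, stats

from basketopt import (
    ExactEngine,
    Scenario,
    TrialLayout,
    TuningParams,
    exact_oc,
    mc_oc,
    mcse_rate,
)
from basketopt.oc import EnumerationLimitExceeded


def _jsd_bruteforce(a1, b1, a2, b2):
    """Quadrature JSD written independently of the package implementation."""

    def kl(pa, pb, qfun):
        def ig(x):
            p = stats.beta.pdf(x, pa, pb)
            return p * np.log(p / qfun(x)) if p > 0 else 0.0

        return integrate.quad(ig, 0, 1, epsabs=1e-12, limit=200)[0]

    def m(x):
        return 0.5 * (stats.beta.pdf(x, a1, b1) + stats.beta.pdf(x, a2, b2))

    return 0.5 * (kl(a1, b1, m) + kl(a2, b2, m))


def brute_force_oc(layout, scenario, phi):
    """Loop over every outcome of a 2-stratum layout, by hand."""
    n1, n2 = layout.sample_sizes
    active = np.array(
        [i in scenario.active_set for i in range(2)], dtype=bool
    )
    rates = np.zeros(2)
    ewp = fwer = 0.0
    for r1 in range(n1 + 1):
        for r2 in range(n2 + 1):
            mass = stats.binom.pmf(r1, n1, scenario.true_rates[0]) * \
                stats.binom.pmf(r2, n2, scenario.true_rates[1])
            post = [(1 + r1, 1 + n1 - r1), (1 + r2, 1 + n2 - r2)]
            sim = 1.0 - _jsd_bruteforce(*post[0], *post[1])
            w = sim ** phi.epsilon
            w = w if w > phi.tau else 0.0
            detected = []
            for i, j in ((0, 1), (1, 0)):
                a = post[i][0] + w * post[j][0]
                b = post[i][1] + w * post[j][1]
                detected.append(
                    stats.beta.cdf(layout.target_rates[i], a, b)
                    <= 1.0 - phi.lambda_
                )
            detected = np.array(detected)
            rates += mass * detected
            if detected[active].any():
                ewp += mass
            if detected[~active].any():
                fwer += mass
    ecd = rates[active].sum() + (1.0 - rates[~active]).sum()
    return rates, ewp, fwer, ecd


class TestExactOC:
    def test_matches_bruteforce_on_nine_outcomes(self, layout2_small, scenario2):
        phi = TuningParams(0.9, 2.0, 0.0)
        res = exact_oc(layout2_small, scenario2, phi)
        rates, ewp, fwer, ecd = brute_force_oc(layout2_small, scenario2, phi)
        np.testing.assert_allclose(res.rejection_rates, rates, atol=1e-10)
        assert res.ewp == pytest.approx(ewp, abs=1e-10)
        assert res.fwer == pytest.approx(fwer, abs=1e-10)
        assert res.ecd == pytest.approx(ecd, abs=1e-10)

    def test_matches_bruteforce_with_cutoff(self, layout2_small, scenario2):
        phi = TuningParams(0.8, 1.5, 0.6)
        res = exact_oc(layout2_small, scenario2, phi)
        rates, ewp, fwer, ecd = brute_force_oc(layout2_small, scenario2, phi)
        np.testing.assert_allclose(res.rejection_rates, rates, atol=1e-10)
        assert res.fwer == pytest.approx(fwer, abs=1e-10)
        assert res.ecd == pytest.approx(ecd, abs=1e-10)

    def test_lambda_extremes(self, layout2_small, scenario2):
        all_in = exact_oc(layout2_small, scenario2, TuningParams(0.0, 2, 0))
        np.testing.assert_allclose(all_in.rejection_rates, 1.0)
        assert all_in.fwer == pytest.approx(1.0)
        assert all_in.ecd == pytest.approx(1.0)  # |R| = 1
        none_in = exact_oc(layout2_small, scenario2, TuningParams(1.0, 2, 0))
        np.testing.assert_allclose(none_in.rejection_rates, 0.0)
        assert none_in.ewp == 0.0
        assert none_in.ecd == pytest.approx(1.0)  # |Rc| = 1

    def test_ecd_identity(self, layout2_small, scenario2):
        res = exact_oc(layout2_small, scenario2, TuningParams(0.85, 1.0, 0.2))
        expected = res.power.sum() + (1.0 - res.toer).sum()
        assert res.ecd == pytest.approx(expected, abs=1e-14)
        assert res.ewp <= res.power.sum() + 1e-14
        assert res.fwer >= res.toer.max() - 1e-14

    def test_borrowing_off_reduces_to_single_stratum_formula(self):
        layout = TrialLayout(sample_sizes=(10, 10, 10),
                             target_rates=(0.2,) * 3)
        scenario = Scenario(true_rates=(0.2, 0.2, 0.5),
                            active_set=frozenset([2]))
        lam = 0.9
        res = exact_oc(layout, scenario, TuningParams(lam, 2.0, 1.0))
        for i, p in enumerate(scenario.true_rates):
            r_grid = np.arange(11)
            reject = stats.beta.cdf(0.2, 1 + r_grid, 11 - r_grid) <= 1 - lam
            closed = stats.binom.pmf(r_grid, 10, p)[reject].sum()
            assert res.rejection_rates[i] == pytest.approx(closed, abs=1e-12)

    def test_enumeration_limit_refused(self):
        layout = TrialLayout(sample_sizes=(24,) * 20,
                             target_rates=(0.1,) * 20)
        scenario = Scenario(true_rates=(0.1,) * 20, active_set=frozenset())
        with pytest.raises(EnumerationLimitExceeded):
            exact_oc(layout, scenario, TuningParams(0.99, 2, 0))

    def test_global_null_and_alternative_conventions(self, layout2_small):
        phi = TuningParams(0.9, 2.0, 0.0)
        gn = Scenario(true_rates=(0.2, 0.2), active_set=frozenset())
        res = exact_oc(layout2_small, gn, phi)
        assert res.ewp == 0.0  # no active stratum: empty union
        ga = Scenario(true_rates=(0.5, 0.5), active_set=frozenset([0, 1]))
        res = exact_oc(layout2_small, ga, phi)
        assert res.fwer == 0.0  # no inactive stratum


class TestMonteCarloOC:
    def test_deterministic_under_seed(self, layout2_small, scenario2):
        phi = TuningParams(0.9, 2.0, 0.0)
        a = mc_oc(layout2_small, scenario2, phi, n_mc=500, seed=42)
        b = mc_oc(layout2_small, scenario2, phi, n_mc=500, seed=42)
        np.testing.assert_array_equal(a.rejection_rates, b.rejection_rates)
        assert a.ewp == b.ewp and a.fwer == b.fwer and a.ecd == b.ecd

    def test_agrees_with_exact_within_four_mcse(self, layout2_small, scenario2):
        phi = TuningParams(0.9, 2.0, 0.0)
        ex = exact_oc(layout2_small, scenario2, phi)
        mc = mc_oc(layout2_small, scenario2, phi, n_mc=2000, seed=7)
        for i in range(2):
            tol = 4 * max(mcse_rate(ex.rejection_rates[i], 2000), 1e-3)
            assert abs(
                mc.rejection_rates[i] - ex.rejection_rates[i]
            ) <= tol
        assert abs(mc.ewp - ex.ewp) <= 4 * max(mcse_rate(ex.ewp, 2000), 1e-3)
        assert abs(mc.fwer - ex.fwer) <= 4 * max(mcse_rate(ex.fwer, 2000), 1e-3)

    def test_converges_with_n_mc(self, layout2_small, scenario2):
        phi = TuningParams(0.9, 2.0, 0.0)
        ex = exact_oc(layout2_small, scenario2, phi)
        errs = []
        for n_mc in (100, 1000, 10000):
            mc = mc_oc(layout2_small, scenario2, phi, n_mc=n_mc, seed=11)
            errs.append(
                np.abs(mc.rejection_rates - ex.rejection_rates).max()
            )
        assert errs[-1] < errs[0]
        assert errs[-1] <= 4 * 0.5 / np.sqrt(10000)

    def test_mcse_attached_and_bounded(self, layout2_small, scenario2):
        mc = mc_oc(layout2_small, scenario2, TuningParams(0.9, 2, 0),
                   n_mc=1000, seed=3)
        assert mc.mcse_rates is not None
        assert (mc.mcse_rates <= 0.016).all()


@pytest.mark.parametrize(
    "rate, n, expected",
    [
        (0.5, 1000, 0.015811388300841896),
        (0.0, 1000, 0.0),
        (0.3, 1000, 0.014491376746189438),
    ],
)
def test_mcse_rate_formula(rate, n, expected):
    assert mcse_rate(rate, n) == pytest.approx(expected, abs=1e-15)


def test_engine_shares_decision_sweep_across_scenarios(layout2_small):
    engine = ExactEngine(layout2_small)
    phi = TuningParams(0.9, 2.0, 0.0)
    scenarios = [
        Scenario(true_rates=(0.2, 0.2), active_set=frozenset()),
        Scenario(true_rates=(0.2, 0.5), active_set=frozenset([1])),
    ]
    many = engine.oc_many(scenarios, phi)
    for sc, got in zip(scenarios, many):
        single = exact_oc(layout2_small, sc, phi)
        np.testing.assert_allclose(
            got.rejection_rates, single.rejection_rates, atol=1e-15
        )
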