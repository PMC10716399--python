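"""TVA race model: score distributions, report probabilities, likelihoods."""

import math

import numpy as np
import pytest

from vismotor import cohort, tva
from vismotor.errors import DataIntegrityError, UndefinedRatioError


@pytest.mark.parametrize(
    "exposure, t0, masked, mu, expected",
    [(10, 15, True, 100, 0.0), (200, 15, True, 100, 185.0), (200, 15, False, 100, 285.0)],
)
def test_effective_exposure(exposure, t0, masked, mu, expected):
    assert tva.effective_exposure(exposure, t0, masked, mu) == expected


class TestWholeReportScoreDist:
    def test_zero_exposure_is_point_mass_at_zero(self):
        dist = tva.whole_report_score_dist(6, 20, 3, 0.0)
        assert dist[0] == 1.0 and dist[1:].sum() == 0.0

    def test_infinite_rate_limit(self):
        dist = tva.whole_report_score_dist(6, 1e6, 6, 200.0)
        assert dist[6] == pytest.approx(1.0)

    @pytest.mark.parametrize("C", [5.0, 20.0, 60.0])
    @pytest.mark.parametrize("K", [1.0, 2.5, 3.2, 6.0])
    @pytest.mark.parametrize("tau", [10.0, 85.0, 200.0])
    def test_normalisation(self, C, K, tau):
        dist = tva.whole_report_score_dist(6, C, K, tau)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert (dist >= 0).all()

    def test_integer_k_matches_truncated_binomial(self):
        # independent closed form: q = 1 - exp(-1/3) at n=6, C=20/s, tau=100ms
        n, C, K, tau = 6, 20.0, 3, 100.0
        q = 1 - math.exp(-1 / 3)
        pmf = [math.comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(n + 1)]
        expected = pmf[:3] + [sum(pmf[3:])] + [0, 0, 0]
        assert tva.whole_report_score_dist(n, C, K, tau) == pytest.approx(expected)

    def test_mean_monotone_in_tau_c_k(self):
        def mean(C, K, tau):
            d = tva.whole_report_score_dist(6, C, K, tau)
            return float(d @ np.arange(7))

        taus = [0, 20, 50, 100, 200]
        assert all(
            mean(20, 3.2, a) <= mean(20, 3.2, b) + 1e-12
            for a, b in zip(taus, taus[1:])
        )
        cs = [5, 10, 20, 40]
        assert all(mean(a, 3.2, 80) <= mean(b, 3.2, 80) + 1e-12 for a, b in zip(cs, cs[1:]))
        ks = [1, 2, 3, 4.5, 6]
        assert all(mean(20, a, 80) <= mean(20, b, 80) + 1e-12 for a, b in zip(ks, ks[1:]))

    def test_mean_bounded_by_capacity(self):
        for K in (1.0, 2.7, 4.0):
            d = tva.whole_report_score_dist(6, 500.0, K, 500.0)
            assert float(d @ np.arange(7)) <= min(6, K) + 1e-9


class TestWholeReportLoglik:
    def test_certain_outcome_gives_zero(self):
        trial = tva.WholeReportTrial(10.0, True, 6, 0)
        ll = tva.whole_report_loglik(dict(t0=15, C=20, K=3, mu=0), [trial])
        assert ll == pytest.approx(0.0)

    def test_additivity_under_duplication(self):
        trials = [
            tva.WholeReportTrial(80.0, True, 6, 2),
            tva.WholeReportTrial(140.0, False, 6, 3),
        ]
        p = dict(t0=15, C=20, K=3.2, mu=100)
        assert tva.whole_report_loglik(p, trials * 2) == pytest.approx(
            2 * tva.whole_report_loglik(p, trials)
        )

    def test_order_invariance(self):
        trials = [
            tva.WholeReportTrial(50.0, True, 6, 1),
            tva.WholeReportTrial(200.0, False, 6, 4),
            tva.WholeReportTrial(80.0, True, 6, 2),
        ]
        p = dict(t0=10, C=25, K=3, mu=80)
        assert tva.whole_report_loglik(p, trials) == pytest.approx(
            tva.whole_report_loglik(p, trials[::-1])
        )

    def test_matches_direct_recomputation(self):
        p = dict(t0=12, C=18, K=2.8, mu=90)
        trials = [
            tva.WholeReportTrial(50.0, True, 6, 1),
            tva.WholeReportTrial(80.0, True, 6, 3),
            tva.WholeReportTrial(140.0, False, 6, 2),
        ]
        expected = sum(
            math.log(
                tva.whole_report_score_dist(
                    6, p["C"], p["K"],
                    tva.effective_exposure(t.exposure_ms, p["t0"], t.masked, p["mu"]),
                )[t.n_correct_reported]
            )
            for t in trials
        )
        assert tva.whole_report_loglik(p, trials) == pytest.approx(expected)

    def test_rejects_overfull_report(self):
        with pytest.raises(DataIntegrityError):
            tva.WholeReportTrial(80.0, True, 6, 7)


LAYOUT_TD = (("left", "target"), ("right", "distractor"))
LAYOUT_TT = (("left", "target"), ("right", "target"))
LAYOUT_4 = (
    ("left", "target"), ("right", "target"),
    ("left", "distractor"), ("right", "distractor"),
)


class TestPartialReport:
    def test_perfect_selectivity_limit(self):
        # alpha=0: the distractor never competes, P = 1 - exp(-C tau)
        p = dict(C=20.0, K=2, alpha=0.0, w_lat=0.5)
        tau = 80.0
        (prob,) = tva.partial_report_probs(LAYOUT_TD, p, tau)
        assert prob == pytest.approx(1 - math.exp(-20.0 * tau / 1000), abs=1e-9)

    def test_symmetry_at_balanced_weights(self):
        p = dict(C=25.0, K=1.5, alpha=0.7, w_lat=0.5)
        probs = tva.partial_report_probs(LAYOUT_TT, p, 120.0)
        assert probs[0] == pytest.approx(probs[1], abs=1e-12)

    def test_two_targets_k1_closed_form(self):
        # capacity 1: P(left reported) = vL/(vL+vR) * (1 - exp(-(vL+vR) tau))
        C, w = 30.0, 0.65
        p = dict(C=C, K=1, alpha=0.5, w_lat=w)
        tau = 100.0
        vl, vr = C * w / 1000, C * (1 - w) / 1000
        expected = vl / (vl + vr) * (1 - math.exp(-(vl + vr) * tau))
        probs = tva.partial_report_probs(LAYOUT_TT, p, tau)
        assert probs[0] == pytest.approx(expected, abs=1e-6)

    def test_count_dist_consistent_with_marginals(self):
        # two independent computations: set enumeration vs per-target quadrature
        p = dict(C=22.0, K=2.4, alpha=0.6, w_lat=0.55)
        dist = tva.partial_report_count_dist(LAYOUT_4, p, 130.0)
        probs = tva.partial_report_probs(LAYOUT_4, p, 130.0)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert float(dist @ np.arange(3)) == pytest.approx(probs.sum(), abs=1e-7)

    def test_zero_exposure(self):
        p = dict(C=20.0, K=2, alpha=0.5, w_lat=0.5)
        dist = tva.partial_report_count_dist(LAYOUT_4, p, 0.0)
        assert dist[0] == 1.0

    @pytest.mark.parametrize(
        "params, tau",
        [
            (dict(C=20.0, K=2, alpha=0.7, w_lat=0.6), 150.0),
            (dict(C=25.0, K=2.4, alpha=0.5, w_lat=0.45), 120.0),
        ],
    )
    def test_race_oracle_agreement(self, params, tau, rng):
        """Analytic count distribution matches the Monte-Carlo race."""
        truth = cohort.TrueTVAParams(t0=0, mu=0, **params)
        draws = 40_000
        counts = cohort.race_target_counts(LAYOUT_4, truth, tau, rng, size=draws)
        emp = np.bincount(counts, minlength=3) / draws
        ana = tva.partial_report_count_dist(LAYOUT_4, params, tau)
        se = np.sqrt(ana * (1 - ana) / draws)
        assert (np.abs(emp - ana) <= 4 * se + 1e-4).all()


class TestChangeScores:
    def test_identity(self):
        p = tva.TVAParams(t0=15, C=20, K=3.2, mu=100)
        cs = tva.change_scores(p, p)
        assert (cs.C_change, cs.C_rc, cs.K_change, cs.K_rc) == (0.0, 1.0, 0.0, 1.0)

    def test_reported_magnitudes(self):
        pre = tva.TVAParams(t0=15, C=20.0, K=3.0, mu=100)
        post = tva.TVAParams(t0=15, C=34.89, K=3.254, mu=100)
        cs = tva.change_scores(pre, post)
        assert cs.C_change == pytest.approx(14.89)
        assert cs.K_change == pytest.approx(0.254)

    def test_nonpositive_baseline_rejected(self):
        bad = tva.TVAParams(t0=15, C=0.0, K=3.0, mu=100)
        good = tva.TVAParams(t0=15, C=20.0, K=3.0, mu=100)
        with pytest.raises(UndefinedRatioError):
            tva.change_scores(bad, good)
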