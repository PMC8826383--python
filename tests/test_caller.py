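"""Beta-Bernoulli mixture position calling: moment fits, likelihoods
(checked against direct-pdf and exhaustive latent-state oracles), decision
rules and baselines."""

import itertools
import math

import numpy as np
import pytest

from methcall.caller import (
    BetaMixtureParams,
    DegenerateFitError,
    PositionEvidence,
    beta_shapes_from_moments,
    call_position_bayes,
    call_position_mean,
    call_position_threshold,
    call_positions,
    estimate_mixture_params,
    fit_beta_moments,
    group_reads_by_position,
    log_likelihood,
)
from methcall.simulate import simulate_read_scores


def beta_pdf_direct(x: float, a: float, b: float) -> float:
    """Independent Beta density via the Gamma function."""
    const = math.gamma(a + b) / (math.gamma(a) * math.gamma(b))
    return const * x ** (a - 1) * (1 - x) ** (b - 1)


def enumeration_log_likelihood(x, params, s):
    """Exhaustively marginalize over all 2^N latent read-state vectors."""
    p_r1 = params.epsilon if s == 0 else 1 - params.gamma
    total = 0.0
    for r in itertools.product([0, 1], repeat=len(x)):
        term = 1.0
        for xi, ri in zip(x, r):
            shapes = (params.c, params.d) if ri else (params.a, params.b)
            term *= beta_pdf_direct(xi, *shapes)
            term *= p_r1 if ri else 1 - p_r1
        total += term
    return math.log(total)


def evidence(scores, position=0):
    return PositionEvidence("chr1", "+", position, np.asarray(scores, float))


class TestFitBetaMoments:
    def test_uniform_moments(self):
        a, b = beta_shapes_from_moments(0.5, 1 / 12)
        assert (a, b) == pytest.approx((1.0, 1.0))

    def test_symmetric_two_two(self):
        a, b = beta_shapes_from_moments(0.5, 0.05)
        assert (a, b) == pytest.approx((2.0, 2.0))
        # Beta(2,2) really has mean .5 and variance .05
        assert 2 / (2 + 2) == 0.5
        assert 2 * 2 / ((4) ** 2 * 5) == pytest.approx(0.05)

    def test_monte_carlo_recovery(self, rng):
        draws = rng.beta(5, 2, size=100_000)
        a, b = fit_beta_moments(draws)
        assert a == pytest.approx(5, rel=0.05)
        assert b == pytest.approx(2, rel=0.05)

    def test_infeasible_variance(self):
        with pytest.raises(DegenerateFitError):
            beta_shapes_from_moments(0.5, 0.3)  # var >= mu(1-mu)
        with pytest.raises(DegenerateFitError):
            fit_beta_moments(np.full(10, 0.4))  # zero variance


class TestEstimateMixtureParams:
    def test_two_group_recovery(self, rng):
        s0 = rng.beta(2, 8, size=100_000)
        s1 = rng.beta(8, 2, size=100_000)
        scores = np.concatenate([s0, s1])
        labels = np.concatenate([np.zeros(s0.size), np.ones(s1.size)])
        p = estimate_mixture_params(scores, labels)
        assert (p.a, p.b) == pytest.approx((2, 8), rel=0.05)
        assert (p.c, p.d) == pytest.approx((8, 2), rel=0.05)
        # gamma/epsilon are fixed operating constants, not estimated
        assert p.gamma == 0.83
        assert p.epsilon == 0.05

    def test_swapping_groups_swaps_shapes(self, rng):
        scores = np.concatenate([rng.beta(2, 8, 5000), rng.beta(8, 2, 5000)])
        labels = np.concatenate([np.zeros(5000), np.ones(5000)])
        p = estimate_mixture_params(scores, labels)
        q = estimate_mixture_params(scores, 1 - labels)
        assert (q.a, q.b) == pytest.approx((p.c, p.d))
        assert (q.c, q.d) == pytest.approx((p.a, p.b))


class TestLogLikelihood:
    def test_uniform_components_give_zero(self, rng):
        params = BetaMixtureParams(1, 1, 1, 1)
        ev = evidence(rng.random(20))
        assert log_likelihood(ev, params, 0) == pytest.approx(0, abs=1e-9)
        assert log_likelihood(ev, params, 1) == pytest.approx(0, abs=1e-9)

    def test_direct_pdf_oracle_single_read(self):
        params = BetaMixtureParams(2, 5, 5, 2)
        x = 0.9
        expected0 = math.log(
            0.95 * beta_pdf_direct(x, 2, 5) + 0.05 * beta_pdf_direct(x, 5, 2)
        )
        expected1 = math.log(
            0.83 * beta_pdf_direct(x, 2, 5) + 0.17 * beta_pdf_direct(x, 5, 2)
        )
        assert log_likelihood(evidence([x]), params, 0) == pytest.approx(expected0, abs=1e-9)
        assert log_likelihood(evidence([x]), params, 1) == pytest.approx(expected1, abs=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        """Mixture product form == sum over all 2^N latent read states."""
        for _ in range(25):
            n = int(rng.integers(1, 9))
            params = BetaMixtureParams(
                *np.round(rng.uniform(0.5, 8, size=4), 3),
                gamma=float(rng.uniform(0.5, 1)),
                epsilon=float(rng.uniform(0, 0.3)),
            )
            x = rng.uniform(0.01, 0.99, size=n)
            for s in (0, 1):
                assert log_likelihood(evidence(x), params, s) == pytest.approx(
                    enumeration_log_likelihood(x, params, s), abs=1e-9
                )

    def test_monotone_in_scores(self, rng):
        """Raising any read score never lowers the methylated-vs-unmethylated
        log-likelihood ratio when (c,d) dominates (a,b)."""
        params = BetaMixtureParams(2, 8, 8, 2)
        x = rng.uniform(0.05, 0.6, size=10)
        ev = evidence(x)
        base = log_likelihood(ev, params, 1) - log_likelihood(ev, params, 0)
        for i in range(10):
            x2 = x.copy()
            x2[i] = min(0.99, x2[i] + 0.3)
            ev2 = evidence(x2)
            lr = log_likelihood(ev2, params, 1) - log_likelihood(ev2, params, 0)
            assert lr >= base - 1e-9


class TestBayesCaller:
    def test_exchangeable_tie_goes_methylated(self, rng):
        params = BetaMixtureParams(3, 3, 3, 3, gamma=0.95, epsilon=0.05)
        call = call_position_bayes(evidence(rng.random(15)), params)
        assert call.state == "methylated"

    def test_high_scores_called_methylated(self):
        params = BetaMixtureParams(2, 5, 5, 2)
        call = call_position_bayes(evidence([0.95, 0.9, 0.85]), params)
        assert call.state == "methylated"
        assert call.log_like_meth >= call.log_like_unmeth

    def test_low_frequency_sensitivity_vs_threshold(self, rng):
        """3 of 30 reads methylated with well-separated components: the
        Bayesian caller fires while the 50% threshold stays silent."""
        params = BetaMixtureParams(1, 20, 20, 1)
        scores = np.concatenate([rng.beta(20, 1, 3), rng.beta(1, 20, 27)])
        ev = evidence(scores)
        assert call_position_bayes(ev, params).state == "methylated"
        assert call_position_threshold(ev, 0.5).state == "unmethylated"

    def test_gamma_near_one_single_read_detection(self, rng):
        """gamma -> 1, eps -> 0 with separated components: one high-scoring
        read among many flips the call to methylated."""
        params = BetaMixtureParams(1, 20, 20, 1, gamma=0.99, epsilon=0.001)
        scores = np.concatenate([[0.98], rng.beta(1, 20, 29)])
        assert call_position_bayes(evidence(scores), params).state == "methylated"


class TestBaselineCallers:
    def test_threshold_is_strict(self):
        scores = [0.9] * 2 + [0.1] * 8
        assert call_position_threshold(evidence(scores), 0.2).state == "unmethylated"
        scores = [0.9] * 3 + [0.1] * 7
        assert call_position_threshold(evidence(scores), 0.2).state == "methylated"

    def test_threshold_zero_boundary(self):
        assert call_position_threshold(evidence([0.9, 0.1]), 0.0).state == "methylated"

    def test_mean_caller(self):
        assert call_position_mean(evidence([0.9, 0.2])).state == "methylated"
        assert call_position_mean(evidence([0.4, 0.4])).state == "unmethylated"

    def test_mean_agrees_with_half_threshold_on_bimodal(self, rng):
        # odd coverage keeps the methylated fraction away from exactly 0.5
        for _ in range(20):
            scores = np.where(rng.random(21) < rng.random(),
                              rng.uniform(0.99, 1, 21), rng.uniform(0, 0.01, 21))
            ev = evidence(scores)
            t = call_position_threshold(ev, 0.5).state
            m = call_position_mean(ev).state
            assert t == m


class TestGrouping:
    def _preds(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(8)],
                "chrom": ["c"] * 8,
                "strand": ["+"] * 8,
                "position": [10] * 5 + [20] * 3,
                "score": np.linspace(0.1, 0.9, 8),
                "call": [0] * 4 + [1] * 4,
            }
        )

    def test_basic_grouping(self):
        evs, dropped = group_reads_by_position(self._preds(), min_coverage=1)
        assert {e.position: e.coverage for e in evs} == {10: 5, 20: 3}
        assert dropped == 0

    def test_min_coverage_drops(self):
        evs, dropped = group_reads_by_position(self._preds(), min_coverage=5)
        assert [e.position for e in evs] == [10]
        assert dropped == 3

    def test_conservation(self):
        preds = self._preds()
        evs, dropped = group_reads_by_position(preds, min_coverage=4)
        assert sum(e.coverage for e in evs) + dropped == len(preds)

    def test_call_positions_frame(self):
        evs, _ = group_reads_by_position(self._preds())
        df = call_positions(evs, method="threshold", t=0.2)
        assert list(df["start"]) == [10, 20]
        assert (df["end"] - df["start"] == 1).all()


def test_parameter_recovery_from_simulated_scores(rng):
    s1 = simulate_read_scores(100_000, "meth", (5.0, 2.0), rng)
    a, b = fit_beta_moments(s1)
    assert a == pytest.approx(5, rel=0.05)
    assert b == pytest.approx(2, rel=0.05)
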