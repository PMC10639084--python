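"""Dirichlet-multinomial fitting and the two-condition channel score.

The likelihood-ratio score is cross-checked against an independent numeric
maximum-likelihood oracle (a generic optimizer maximizing the same
likelihood over proportions and precision).
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from conftest import anchor_score, body_scores
from qtrna.comparative_scoring import (
    PRECISION_BOUNDS,
    PSEUDOCOUNT,
    channel_score,
    dirichlet_multinomial_loglik,
    fit_dirichlet_multinomial,
    score_positions,
)
from qtrna.pipeline import run_two_condition_pipeline


def _mle_loglik(X, alpha, eps=PSEUDOCOUNT):
    X = np.asarray(X, float) + eps
    n = X.sum(axis=1)
    A = alpha.sum()
    return float(
        np.sum(gammaln(A) - gammaln(n + A)) + np.sum(gammaln(X + alpha) - gammaln(alpha))
    )


def _mle_fit(X, eps=PSEUDOCOUNT):
    """Numerically maximize the same likelihood over (proportions, precision)."""
    X = np.asarray(X, float)
    K = X.shape[1]
    lo, hi = PRECISION_BOUNDS

    def neg(params):
        z = np.append(params[:-1], 0.0)
        p = np.exp(z - z.max())
        p /= p.sum()
        theta = np.exp(params[-1])
        return -_mle_loglik(X, theta * p, eps)

    p0 = (X + eps).sum(axis=0)
    p0 = p0 / p0.sum()
    best = None
    for log_theta0 in (np.log(10.0), np.log(1e3), np.log(hi)):
        x0 = np.append(np.log(p0[:-1] / p0[-1]), log_theta0)
        res = minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[(-20, 20)] * (K - 1) + [(np.log(lo), np.log(hi))],
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


def _mle_channel_score(A, B, eps=PSEUDOCOUNT):
    pooled = list(A) + list(B)
    return max(0.0, 2.0 * (_mle_fit(A, eps) + _mle_fit(B, eps) - _mle_fit(pooled, eps)))


class TestFit:
    def test_single_replicate_precision_at_upper_clamp(self):
        alpha = fit_dirichlet_multinomial([[8, 1, 1, 0, 0]])
        assert alpha.sum() == pytest.approx(PRECISION_BOUNDS[1])
        smoothed = np.array([8, 1, 1, 0, 0]) + PSEUDOCOUNT
        np.testing.assert_allclose(
            alpha / alpha.sum(), smoothed / smoothed.sum(), atol=1e-4
        )

    def test_identical_replicates_precision_at_clamp(self):
        alpha = fit_dirichlet_multinomial([[90, 5, 5, 0, 0]] * 3)
        assert alpha.sum() == pytest.approx(PRECISION_BOUNDS[1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_dirichlet_multinomial([[0, 0, 0]])

    def test_parameter_recovery_from_known_model(self):
        rng = np.random.default_rng(12)
        props = np.array([0.7, 0.1, 0.1, 0.05, 0.05])
        precision = 50.0
        reps = [
            rng.multinomial(1000, rng.dirichlet(precision * props)) for _ in range(6)
        ]
        alpha = fit_dirichlet_multinomial(reps)
        np.testing.assert_allclose(alpha / alpha.sum(), props, atol=0.05)


class TestChannelScore:
    def test_identical_conditions_score_zero(self):
        reps = [[95, 0, 0, 0, 5], [93, 2, 0, 0, 5], [96, 0, 1, 0, 3]]
        assert channel_score(reps, reps) <= 1e-6

    def test_agrees_with_numeric_mle_oracle(self):
        A = [[95, 0, 0, 0, 5]] * 3
        B = [[50, 40, 0, 0, 10]] * 3
        ours = channel_score(A, B)
        oracle = _mle_channel_score(A, B)
        assert ours == pytest.approx(oracle, rel=0.05)

    def test_score_scales_with_evidence(self):
        A = [[95, 0, 0, 0, 5], [90, 3, 2, 0, 5], [94, 1, 0, 0, 5]]
        B = [[70, 20, 0, 0, 10], [72, 18, 1, 0, 9], [69, 22, 0, 0, 9]]
        doubled_a = [[2 * x for x in v] for v in A]
        doubled_b = [[2 * x for x in v] for v in B]
        assert channel_score(doubled_a, doubled_b) > channel_score(A, B)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            A = rng.integers(0, 40, size=(3, 5)) + 1
            B = rng.integers(0, 40, size=(3, 5)) + 1
            assert channel_score(A, B) == channel_score(B, A)


def _tiny_pileups(counts_by_rep):
    tables = []
    for counts in counts_by_rep:
        rows = []
        for i, (a, c, g, t, d, ins) in enumerate(counts):
            rows.append(
                dict(ref_name="r", full_index=i, canonical_position=33 + i,
                     ref_base="G", coverage=a + c + g + t + d,
                     A=a, C=c, G=g, T=t, ins=ins, **{"del": d})
            )
        tables.append(pd.DataFrame(rows))
    return tables


class TestScorePositions:
    def test_additivity_and_symmetry_on_fixture_tables(self):
        A = _tiny_pileups(
            [
                [(2, 1, 95, 2, 0, 1), (0, 0, 99, 0, 1, 0)],
                [(3, 0, 96, 0, 1, 2), (1, 1, 97, 1, 0, 1)],
            ]
        )
        B = _tiny_pileups(
            [
                [(2, 40, 55, 2, 1, 1), (0, 5, 90, 0, 5, 0)],
                [(1, 38, 58, 1, 2, 0), (0, 4, 93, 1, 2, 2)],
            ]
        )
        ab = score_positions(A, B, min_cov=10)
        ba = score_positions(B, A, min_cov=10)
        np.testing.assert_array_equal(
            ab[["mis_score", "del_score", "ins_score", "total_score"]].to_numpy(),
            ba[["mis_score", "del_score", "ins_score", "total_score"]].to_numpy(),
        )
        np.testing.assert_allclose(
            ab["total_score"],
            ab["mis_score"] + ab["del_score"] + ab["ins_score"],
            rtol=0,
            atol=0,
        )

    def test_identical_conditions_zero_everywhere(self):
        A = _tiny_pileups([[(2, 1, 95, 2, 0, 1)], [(3, 0, 96, 0, 1, 2)]])
        out = score_positions(A, A, min_cov=10)
        assert (out["total_score"] <= 1e-6).all()

    def test_low_coverage_positions_missing(self):
        A = _tiny_pileups([[(2, 1, 95, 2, 0, 1)]])
        B = _tiny_pileups([[(1, 0, 4, 0, 0, 0)]])  # coverage 5
        out = score_positions(A, B, min_cov=10)
        assert out["total_score"].isna().all()

    def test_mismatched_references_rejected(self):
        A = _tiny_pileups([[(2, 1, 95, 2, 0, 1)]])
        B = _tiny_pileups([[(2, 1, 95, 2, 0, 1), (0, 0, 99, 0, 1, 0)]])
        with pytest.raises(ValueError):
            score_positions(A, B)


class TestEndToEnd:
    def test_q_signature_peaks_near_wobble(self, preset_runs):
        scores = preset_runs[("Q", 7)].scores
        body = body_scores(scores)
        top = body.loc[body["total_score"].idxmax()]
        assert 32 <= int(top["canonical_position"]) <= 36

    def test_power_monotone_in_modified_fraction(self, single_ref):
        name = single_ref[0].name
        means = []
        for frac in (0.0, 0.25, 0.5, 1.0):
            vals = [
                anchor_score(
                    run_two_condition_pipeline(
                        single_ref, {name: "Q"}, n_reads=300, replicates=3,
                        seed=200 + s, modified_fraction=frac,
                    ).scores
                )
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert all(a <= b for a, b in zip(means, means[1:]))
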