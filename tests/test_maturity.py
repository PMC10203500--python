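import math

import numpy as np
import pytest

from standthin import (
    IncrementSeries,
    RichardsParams,
    ValidationError,
    fit_richards,
    qma_analytic,
    qma_empirical,
    richards,
    richards_cai,
    stand_quantitative_maturity,
    volume_series,
)

PRINTED = RichardsParams(49.508, 0.221, 2.949)


def bisect_qma_oracle(b, c, lo=1e-6, hi=50.0, iters=200):
    """Independent bisection on f(u) = e^u - 1 - c*u, u > log(c)."""
    f = lambda u: math.exp(u) - 1.0 - c * u
    lo = math.log(c)
    while f(hi) < 0:
        hi *= 2
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) / b


class TestRichardsCurve:
    def test_zero_at_origin_and_asymptote(self):
        assert richards(0.0, PRINTED) == 0.0
        assert richards(1e4, PRINTED) == pytest.approx(PRINTED.a, rel=1e-12)

    def test_cai_matches_finite_differences(self):
        t = np.linspace(0.5, 40, 80)
        h = 1e-6
        numeric = (richards(t + h, PRINTED) - richards(t - h, PRINTED)) / (2 * h)
        assert np.allclose(richards_cai(t, PRINTED), numeric, rtol=1e-6)

    def test_curve_integrates_its_derivative(self):
        # cumulative trapezoid of dy/dt reproduces y to ~1e-6 relative
        t = np.linspace(0, 32, 20001)
        cai = richards_cai(np.maximum(t, 1e-12), PRINTED)
        integral = np.concatenate([[0.0], np.cumsum((cai[1:] + cai[:-1]) / 2 * np.diff(t))])
        assert np.allclose(integral, richards(t, PRINTED), rtol=1e-5, atol=1e-6)

    def test_cai_peaks_at_log_c_over_b(self):
        t_peak = math.log(PRINTED.c) / PRINTED.b
        t = np.linspace(0.1, 40, 4000)
        assert abs(t[np.argmax(richards_cai(t, PRINTED))] - t_peak) < 0.02

    def test_cai_vanishes_at_origin_for_c_above_one(self):
        assert richards_cai(1e-9, PRINTED) < 1e-6


class TestFitRichards:
    def test_recovers_printed_parameters_noiselessly(self):
        t = np.arange(1, 33, dtype=float)
        y = richards(t, PRINTED)
        fit = fit_richards(t, y)
        assert fit.converged
        assert fit.params.a == pytest.approx(PRINTED.a, rel=1e-3)
        assert fit.params.b == pytest.approx(PRINTED.b, rel=1e-3)
        assert fit.params.c == pytest.approx(PRINTED.c, rel=1e-3)
        assert fit.r_squared >= 1 - 1e-9
        assert fit.rmse == pytest.approx(0.0, abs=1e-5)

    def test_noisy_recovery_median_error_under_ten_percent(self):
        """2% multiplicative noise, seeded replicates: median relative error
        of each parameter stays below 10% (subset of the full study run by
        the acceptance script)."""
        t = np.arange(1, 33, dtype=float)
        y0 = richards(t, PRINTED)
        rng = np.random.default_rng(12345)
        errs = {"a": [], "b": [], "c": []}
        for _ in range(15):
            y = y0 * (1 + rng.normal(0, 0.02, size=t.size))
            fit = fit_richards(t, np.maximum(y, 0))
            errs["a"].append(abs(fit.params.a - PRINTED.a) / PRINTED.a)
            errs["b"].append(abs(fit.params.b - PRINTED.b) / PRINTED.b)
            errs["c"].append(abs(fit.params.c - PRINTED.c) / PRINTED.c)
        for k, v in errs.items():
            assert np.median(v) < 0.10, k

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_richards([1, 2, 3], [1.0, 2.0, 3.0])


class TestQmaAnalytic:
    def test_none_for_c_at_or_below_one(self):
        assert qma_analytic(RichardsParams(10, 0.2, 1.0)) is None
        assert qma_analytic(RichardsParams(10, 0.2, 0.5)) is None

    def test_printed_parameters_give_eight_and_a_half_years(self):
        assert qma_analytic(PRINTED) == pytest.approx(8.50, abs=0.01)

    def test_mai_equals_cai_at_solution(self):
        for b in (0.05, 0.15, 0.3):
            for c in (1.2, 2.0, 5.0, 12.0):
                p = RichardsParams(100.0, b, c)
                t = qma_analytic(p)
                mai = richards(t, p) / t
                cai = richards_cai(t, p)
                assert abs(mai - cai) / cai < 1e-8

    def test_agrees_with_bisection_oracle_on_grid(self):
        for b in (0.05, 0.1, 0.221, 0.4):
            for c in (1.1, 1.5, 2.949, 6.0, 20.0):
                p = RichardsParams(50.0, b, c)
                assert qma_analytic(p) == pytest.approx(bisect_qma_oracle(b, c), abs=1e-6)

    def test_independent_of_asymptote(self):
        a1 = qma_analytic(RichardsParams(10.0, 0.221, 2.949))
        a2 = qma_analytic(RichardsParams(1e4, 0.221, 2.949))
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_increasing_in_inverse_rate_and_in_shape(self):
        qmas_b = [qma_analytic(RichardsParams(10, b, 3.0)) for b in (0.4, 0.2, 0.1)]
        assert qmas_b[0] < qmas_b[1] < qmas_b[2]
        qmas_c = [qma_analytic(RichardsParams(10, 0.2, c)) for c in (1.5, 3.0, 8.0)]
        assert qmas_c[0] < qmas_c[1] < qmas_c[2]


class TestQmaEmpirical:
    def test_linear_series_has_no_crossing(self):
        t = np.arange(1, 20, dtype=float)
        assert qma_empirical(IncrementSeries(t, 3.0 * t)) is None

    def test_concave_from_start_rejected_as_spurious(self):
        # CAI below MAI at every evaluable age: no accelerating phase observed
        t = np.arange(1, 20, dtype=float)
        y = np.sqrt(t)
        assert qma_empirical(IncrementSeries(t, y)) is None

    def test_consistent_with_analytic_on_sampled_richards(self):
        for b, c in ((0.221, 2.949), (0.1, 4.0), (0.3, 2.0)):
            p = RichardsParams(100.0, b, c)
            t = np.arange(1, 61, dtype=float)
            emp = qma_empirical(IncrementSeries(t, richards(t, p)))
            assert emp is not None
            assert abs(emp - qma_analytic(p)) <= 1.0

    def test_needs_three_ages(self):
        with pytest.raises(ValidationError):
            qma_empirical(IncrementSeries([1.0, 2.0], [1.0, 2.0]))


class TestStandMaturity:
    def test_ordering_across_thinning_scenarios(self, factorial_trajectories):
        """Maturity is delayed by thinning, more by higher pre-commercial
        intensity, and most by commercial thinning; the heaviest commercial
        intensity does not culminate within the observation window."""
        qma = {}
        for traj in factorial_trajectories:
            qma.setdefault(traj.treatment, []).append(stand_quantitative_maturity(traj))

        def mean(t):
            vals = [q for q in qma[t] if q is not None]
            return float(np.mean(vals)) if vals else None

        assert all(q is not None for q in qma["CK"] + qma["TE3250"] + qma["TE2500"] + qma["TE1750"])
        assert mean("CK") < mean("TE3250") <= mean("TE2500") <= mean("TE1750")
        for commercial in ("TL400", "TL278"):
            assert all(q is not None for q in qma[commercial])
            assert mean(commercial) > mean("TE1750")
        assert all(q is None for q in qma["TL156"])

    def test_existing_basis_series_drops_at_event(self, factorial_trajectories):
        tl = next(t for t in factorial_trajectories if t.treatment == "TL400")
        existing = volume_series(tl, basis="existing")
        total = volume_series(tl)
        i23 = list(existing.ages).index(23.0)
        assert existing.values[i23] < existing.values[i23 - 1]  # removal visible
        assert total.values[i23] >= total.values[i23 - 1] - 1e-9  # conserved
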