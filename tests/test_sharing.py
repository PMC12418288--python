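"""Parasite-sharing logistic analysis: eligibility, case construction,
ML fitting against oracles, bootstrap pooling and PNS."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from parafauna import sharing
from parafauna.distances import DistanceMatrix, normalize01
from parafauna.sharing import SharingCases


def random_distance_matrix(labels, seed):
    rng = np.random.default_rng(seed)
    m = rng.random((len(labels), len(labels)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return normalize01(DistanceMatrix(list(labels), m, "TD"))


@pytest.fixture()
def toy_incidence():
    """20 hosts; p_few on 5 hosts, p_six on exactly 6, p_many on 10."""
    hosts = [f"h{i:02d}" for i in range(20)]
    inc = pd.DataFrame(0, index=["p_few", "p_six", "p_many"], columns=hosts)
    inc.iloc[0, :5] = 1
    inc.iloc[1, :6] = 1
    inc.iloc[2, 5:15] = 1
    inc.index.name = "parasite_id"
    return inc


class TestEligibility:
    def test_six_host_boundary(self, toy_incidence):
        elig = sharing.eligible_parasites(toy_incidence, min_hosts=6)
        assert elig == ["p_six", "p_many"]

    def test_all_below_threshold_warns_and_returns_empty(self, toy_incidence):
        with pytest.warns(UserWarning, match="no parasite"):
            elig = sharing.eligible_parasites(toy_incidence.iloc[[0]], min_hosts=6)
        assert elig == []


class TestCaseConstruction:
    def test_case_count_six_carriers_twenty_hosts(self, toy_incidence):
        dm = random_distance_matrix(toy_incidence.columns, 0)
        cases = sharing.build_sharing_cases("p_six", toy_incidence, dm,
                                            np.random.default_rng(1))
        # 6 sources x (5 positives + 5 negatives)
        assert len(cases) == 60
        assert cases.response.sum() == 30

    def test_carrier_carrier_cases_all_positive(self, toy_incidence):
        dm = random_distance_matrix(toy_incidence.columns, 0)
        cases = sharing.build_sharing_cases("p_six", toy_incidence, dm,
                                            np.random.default_rng(1))
        carriers = set(range(6))
        d = dm.values
        pos_d = cases.distance[cases.response == 1]
        expected = sorted(d[s, t] for s in carriers for t in carriers if s != t)
        assert sorted(pos_d) == pytest.approx(expected)

    def test_negatives_drawn_from_non_carriers(self, toy_incidence):
        dm = random_distance_matrix(toy_incidence.columns, 0)
        cases = sharing.build_sharing_cases("p_six", toy_incidence, dm,
                                            np.random.default_rng(1))
        neg_d = set(np.round(cases.distance[cases.response == 0], 12))
        carrier_pairs = {round(dm.values[s, t], 12) for s in range(6) for t in range(6) if s != t}
        # negative-case distances involve at least one non-carrier endpoint
        assert not neg_d <= carrier_pairs

    def test_same_rng_identical_case_list(self, toy_incidence):
        dm = random_distance_matrix(toy_incidence.columns, 0)
        a = sharing.build_sharing_cases("p_many", toy_incidence, dm,
                                        np.random.default_rng(7))
        b = sharing.build_sharing_cases("p_many", toy_incidence, dm,
                                        np.random.default_rng(7))
        np.testing.assert_array_equal(a.distance, b.distance)
        np.testing.assert_array_equal(a.response, b.response)

    def test_saturated_parasite_rejected(self):
        hosts = [f"h{i}" for i in range(8)]
        inc = pd.DataFrame(1, index=["p"], columns=hosts)
        dm = random_distance_matrix(hosts, 0)
        with pytest.raises(ValueError, match="every host"):
            sharing.build_sharing_cases("p", inc, dm, np.random.default_rng(0))


class TestLogisticFit:
    def test_recovery_within_3se_and_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.random(2000)
        p = special.expit(2.0 - 6.0 * d)
        y = (rng.random(2000) < p).astype(float)
        fit = sharing.fit_sharing_logistic(SharingCases("p", d, y))
        assert fit.converged

        def nll(beta):
            eta = beta[0] + beta[1] * d
            return -np.sum(y * eta - np.logaddexp(0, eta))

        oracle = optimize.minimize(nll, [0.0, 0.0], method="BFGS")
        assert fit.intercept == pytest.approx(oracle.x[0], abs=1e-4)
        assert fit.slope == pytest.approx(oracle.x[1], abs=1e-4)
        # observed-information SEs for the 3-SE truth check
        eta = fit.intercept + fit.slope * d
        w = special.expit(eta) * (1 - special.expit(eta))
        x = np.column_stack([np.ones_like(d), d])
        cov = np.linalg.inv(x.T @ (x * w[:, None]))
        se = np.sqrt(np.diag(cov))
        assert abs(fit.intercept - 2.0) < 3 * se[0]
        assert abs(fit.slope - (-6.0)) < 3 * se[1]

    def test_constant_distance_flagged_degenerate(self):
        y = np.array([0.0, 1.0] * 10)
        d = np.full(20, 0.4)
        fit = sharing.fit_sharing_logistic(SharingCases("p", d, y))
        assert not fit.converged

    def test_single_response_class_rejected(self):
        with pytest.raises(ValueError, match="both response classes"):
            sharing.fit_sharing_logistic(SharingCases("p", np.array([0.1, 0.2]),
                                                      np.array([1.0, 1.0])))

    def test_separation_flagged_not_crashed(self):
        d = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.concatenate([np.ones(10), np.zeros(10)])  # perfectly separated
        fit = sharing.fit_sharing_logistic(SharingCases("p", d, y))
        assert not fit.converged
        assert np.isnan(fit.slope)

    def test_null_slope_calibration(self):
        """With response independent of D the slope is within 3 SE of 0 in
        nearly all replicates."""
        ok = 0
        n = 2000
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = rng.random(n)
            y = (rng.random(n) < 0.5).astype(float)
            fit = sharing.fit_sharing_logistic(SharingCases("p", d, y))
            eta = fit.intercept + fit.slope * d
            w = special.expit(eta) * (1 - special.expit(eta))
            x = np.column_stack([np.ones_like(d), d])
            se = np.sqrt(np.diag(np.linalg.inv(x.T @ (x * w[:, None]))))
            ok += abs(fit.slope) < 3 * se[1]
        assert ok >= 19


class TestPNS:
    def test_mixed_signs(self):
        fits = pd.DataFrame({"b_p": [-1.0, -2.0, 3.0], "converged": [True] * 3})
        assert sharing.pns(fits) == pytest.approx(2 / 3)

    def test_all_negative(self):
        fits = pd.DataFrame({"b_p": [-1.0, -0.5], "converged": [True, True]})
        assert sharing.pns(fits) == 1.0

    def test_zero_slope_counts_as_non_negative(self):
        fits = pd.DataFrame({"b_p": [0.0, -1.0], "converged": [True, True]})
        assert sharing.pns(fits) == pytest.approx(0.5)

    def test_non_converged_excluded(self):
        fits = pd.DataFrame({"b_p": [-1.0, np.nan], "converged": [True, False]})
        assert sharing.pns(fits) == 1.0

    def test_no_converged_fits_undefined(self):
        fits = pd.DataFrame({"b_p": [np.nan], "converged": [False]})
        with pytest.raises(ValueError, match="PNS"):
            sharing.pns(fits)


class TestPooled:
    def test_single_parasite_bootstrap_centers_on_its_own_slope(self):
        rng = np.random.default_rng(0)
        hosts = [f"h{i:02d}" for i in range(40)]
        dm = random_distance_matrix(hosts, 1)
        row = np.zeros(40, int)
        row[:12] = 1
        inc = pd.DataFrame([rng.permutation(row)], index=["p0"], columns=hosts)
        inc.index.name = "parasite_id"
        fit = sharing.pooled_coefficients(inc, dm, n_iter=100, seed=4)
        own = fit.per_parasite["b_p"].iloc[0]
        boot_se = np.nanstd(fit.bootstrap_slopes) / np.sqrt(100)
        # fresh negative samples add Monte-Carlo spread around the point fit
        assert abs(fit.pooled_slope - own) < max(5 * boot_se, 0.5)

    def test_same_seed_bit_identical(self, sharing_world):
        a = sharing.pooled_coefficients(sharing_world.incidence,
                                        sharing_world.driving_distance,
                                        n_iter=20, seed=11)
        b = sharing.pooled_coefficients(sharing_world.incidence,
                                        sharing_world.driving_distance,
                                        n_iter=20, seed=11)
        assert a.pooled_slope == b.pooled_slope
        assert a.pooled_intercept == b.pooled_intercept
        np.testing.assert_array_equal(a.bootstrap_slopes, b.bootstrap_slopes)
        pd.testing.assert_frame_equal(a.per_parasite, b.per_parasite)

    def test_planted_negative_slope_recovered(self, sharing_world):
        fit = sharing.pooled_coefficients(sharing_world.incidence,
                                          sharing_world.driving_distance,
                                          n_iter=50, seed=2)
        assert fit.pooled_slope < 0
        assert fit.pns >= 0.8
        assert len(fit.bootstrap_slopes) == 50

    def test_host_permutation_invariance(self, sharing_world):
        """Permuting hosts identically in incidence and distances leaves the
        per-parasite fits unchanged (same rng draws aside)."""
        inc = sharing_world.incidence
        dm = sharing_world.driving_distance
        perm = np.random.default_rng(0).permutation(len(dm.labels))
        inc_p = inc.iloc[:, perm]
        dm_p = DistanceMatrix([dm.labels[i] for i in perm],
                              dm.values[np.ix_(perm, perm)], dm.kind, normalized=True)
        elig = sharing.eligible_parasites(inc)
        f1 = sharing.fit_parasites(elig, inc, dm, np.random.default_rng(5))
        f2 = sharing.fit_parasites(elig, inc_p, dm_p, np.random.default_rng(5))
        # case construction is canonicalized by host label, so the same rng
        # draws the same hosts and the fits agree exactly
        np.testing.assert_allclose(f1["b_p"], f2["b_p"], atol=1e-8, equal_nan=True)
        np.testing.assert_allclose(f1["a_p"], f2["a_p"], atol=1e-8, equal_nan=True)

    def test_unnormalized_distances_rejected(self, sharing_world):
        dm = sharing_world.driving_distance
        raw = DistanceMatrix(dm.labels, dm.values * 2.0, dm.kind, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            sharing.pooled_coefficients(sharing_world.incidence, raw, n_iter=5, seed=0)


class TestProbabilityCurve:
    def test_intercept_only_point(self):
        assert sharing.sharing_probability(1.3, -2.0, np.array([0.0]))[0] == \
            pytest.approx(special.expit(1.3))

    def test_flat_at_half_for_zero_coefficients(self):
        p = sharing.sharing_probability(0.0, 0.0, np.linspace(0, 1, 11))
        assert np.allclose(p, 0.5)

    def test_formula_plug_in(self):
        p = sharing.sharing_probability(2.0, -6.0, np.array([1.0]))[0]
        assert p == pytest.approx(1 / (1 + np.exp(4.0)), abs=1e-12)
        assert p == pytest.approx(0.0180, abs=5e-4)

    def test_monotone_decreasing_iff_negative_slope(self):
        grid = np.linspace(0, 1, 50)
        dec = sharing.sharing_probability(1.0, -3.0, grid)
        inc = sharing.sharing_probability(1.0, 3.0, grid)
        assert (np.diff(dec) < 0).all()
        assert (np.diff(inc) > 0).all()
        assert ((dec > 0) & (dec < 1)).all()

    def test_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError):
            sharing.sharing_probability(0.0, 1.0, np.array([1.5]))
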