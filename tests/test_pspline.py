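import numpy as np
import pytest
from helpers_surfaces import constant_surface, ramp_surface

import spotpower as spw
from spotpower import ValidationError
from spotpower.pspline import build_basis, detect_crossings, make_knots


def deboor_basis(x, knots, degree):
    """Independent B-spline basis oracle via the Cox-de Boor recursion."""
    t = np.asarray(knots, float)
    q = len(t) - degree - 1
    x = np.atleast_1d(np.asarray(x, float))
    B = np.zeros((len(x), len(t) - 1))
    hi = t[-degree - 1]
    for j in range(len(t) - 1):
        B[:, j] = ((x >= t[j]) & (x < t[j + 1])).astype(float)
        if t[j] < t[j + 1] and t[j + 1] == hi:  # right-closed last interval
            B[:, j] = np.where(x == hi, 1.0, B[:, j])
    for d in range(1, degree + 1):
        Bn = np.zeros((len(x), len(t) - 1 - d))
        for j in range(len(t) - 1 - d):
            left = np.zeros(len(x))
            if t[j + d] > t[j]:
                left = (x - t[j]) / (t[j + d] - t[j]) * B[:, j]
            right = np.zeros(len(x))
            if t[j + d + 1] > t[j + 1]:
                right = (t[j + d + 1] - x) / (t[j + d + 1] - t[j + 1]) * B[:, j + 1]
            Bn[:, j] = left + right
        B = Bn
    return B[:, :q]


class TestBasis:
    @pytest.mark.parametrize("q", [4, 7, 10])
    def test_partition_of_unity(self, q):
        knots = make_knots(0.0, 2.0, q)
        x = np.linspace(0.0, 2.0, 33)
        B = build_basis(x, knots)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_local_support_quadratic(self):
        knots = make_knots(0.0, 1.0, 8)
        B = build_basis(np.linspace(0, 1, 21), knots)
        assert np.max((B != 0).sum(axis=1)) <= 3

    def test_matches_deboor_recursion_oracle(self):
        knots = make_knots(-1.0, 2.0, 9)
        x = np.linspace(-1.0, 2.0, 50)
        np.testing.assert_allclose(
            build_basis(x, knots), deboor_basis(x, knots, 2), atol=1e-12
        )

    def test_out_of_range_rejected(self):
        knots = make_knots(0.0, 1.0, 5)
        with pytest.raises(ValidationError, match="outside"):
            build_basis(np.array([1.5]), knots)


class TestFitScam2d:
    def test_constant_power_reproduced(self):
        rng = np.random.default_rng(5)
        pi = rng.uniform(0, 1, 80)
        beta = rng.uniform(0, 2, 80)
        surf = spw.fit_scam2d((pi, beta, np.full(80, 0.42)))
        pred = surf.predict(
            np.linspace(0.02, 0.98, 25), np.linspace(0.05, 1.95, 25)
        )
        np.testing.assert_allclose(pred, 0.42, atol=1e-6)

    def test_recovers_monotone_truth(self, monotone_records):
        pi, beta, y = monotone_records
        surf = spw.fit_scam2d((pi, beta, y))
        gp = np.linspace(pi.min(), pi.max(), 40)
        gb = np.linspace(beta.min(), beta.max(), 40)
        P, B = np.meshgrid(gp, gb, indexing="ij")
        rmse = np.sqrt(
            np.mean((surf.predict(P.ravel(), B.ravel()) - P.ravel() * np.tanh(B.ravel())) ** 2)
        )
        assert rmse <= 0.05

    def test_nonmonotone_truth_still_fits_monotone(self):
        rng = np.random.default_rng(2)
        pi = rng.uniform(0.02, 0.6, 300)
        beta = rng.uniform(0.0, 3.0, 300)
        y = np.clip(0.5 + 0.5 * np.sin(6 * pi) * np.sin(2 * beta), 0, 1)
        surf = spw.fit_scam2d((pi, beta, y))
        gp = np.linspace(pi.min(), pi.max(), 101)
        gb = np.linspace(beta.min(), beta.max(), 101)
        P, B = np.meshgrid(gp, gb, indexing="ij")
        V = surf.predict(P.ravel(), B.ravel()).reshape(P.shape)
        assert np.diff(V, axis=0).min() >= -1e-8
        assert np.diff(V, axis=1).min() >= -1e-8

    def test_too_few_records_rejected(self):
        with pytest.raises(ValidationError, match=">= 20"):
            spw.fit_scam2d((np.arange(5) / 5, np.arange(5) / 5, np.zeros(5)))

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError, match="non-constant"):
            spw.fit_scam2d((np.full(30, 0.2), rng.uniform(0, 1, 30), np.zeros(30)))

    def test_gcv_selects_grid_minimum(self, monotone_records):
        pi, beta, y = monotone_records
        surf = spw.fit_scam2d((pi, beta, y), lambda_grid=(0.01, 1.0, 100.0))
        table = surf.fit_info["gcv_table"]
        best = min(table, key=lambda r: r["gcv"])
        assert (surf.lambda1, surf.lambda2) == (best["lambda1"], best["lambda2"])

    def test_heavier_penalty_trades_fit_for_smoothness(self, monotone_records):
        """Along increasing lambda the in-sample RSS rises toward the best
        penalty-null-space fit (the limit of infinite smoothing)."""
        pi, beta, y = monotone_records
        rss = []
        for lam in (1e-4, 1e-1, 1e2, 1e5):
            surf = spw.fit_scam2d((pi, beta, y), lambda_grid=(lam,))
            rss.append(surf.fit_info["rss"])
        assert np.all(np.diff(rss) >= -1e-8)

    def test_q_robustness(self, monotone_records):
        pi, beta, y = monotone_records
        gp = np.linspace(pi.min(), pi.max(), 40)
        gb = np.linspace(beta.min(), beta.max(), 40)
        P, B = np.meshgrid(gp, gb, indexing="ij")
        true = P.ravel() * np.tanh(B.ravel())
        rmses = []
        for q in (8, 12):
            surf = spw.fit_scam2d((pi, beta, y), q1=q, q2=q)
            rmses.append(np.sqrt(np.mean((surf.predict(P.ravel(), B.ravel()) - true) ** 2)))
        assert abs(rmses[0] - rmses[1]) <= 0.03


class TestPredict:
    def test_training_point_of_constant_fit(self):
        surf = constant_surface(0.3, N=4)
        assert surf.predict(0.5, 1.0) == pytest.approx(0.3)

    def test_monotone_contract_between_queries(self, monotone_records):
        pi, beta, y = monotone_records
        surf = spw.fit_scam2d((pi, beta, y))
        assert surf.predict(0.3, 2.0) >= surf.predict(0.1, 2.0)

    def test_out_of_range_clamps_and_flags(self):
        surf = ramp_surface(0.1, 0.9, N=2)
        inside, flag_in = surf.predict(0.5, 1.0, return_flag=True)
        boundary, flag_out = surf.predict(0.5, 99.0, return_flag=True)
        at_edge = surf.predict(0.5, 3.0)
        assert not flag_in and flag_out
        assert boundary == pytest.approx(at_edge)

    def test_predictions_bounded(self):
        surf = ramp_surface(-0.5, 1.7, N=2)  # coefficients outside [0,1]
        v = surf.predict(np.linspace(0, 1, 30), np.linspace(0, 3, 30))
        assert v.min() >= 0.0 and v.max() <= 1.0


class TestCrossings:
    def test_parallel_surfaces_report_empty(self):
        report = detect_crossings(
            [constant_surface(0.3, 2), constant_surface(0.5, 4)]
        )
        assert not report.has_crossings
        assert report.bounding_box is None
        assert report.cells == []

    def test_forced_crossing_matches_bruteforce_cells(self):
        lo_n = constant_surface(0.5, 2)
        hi_n = ramp_surface(0.2, 0.8, 4)  # dips below 0.5 at small pi
        grid = (np.linspace(0, 1, 21), np.linspace(0, 3, 11))
        report = detect_crossings([lo_n, hi_n], grid=grid)
        assert report.has_crossings
        # brute-force oracle: compare predictions cell by cell
        expected = set()
        for i, p in enumerate(grid[0]):
            for j, b in enumerate(grid[1]):
                if hi_n.predict(p, b) < lo_n.predict(p, b):
                    expected.add((i, j, 2, 4))
        assert set(report.cells) == expected
        (plo, phi), _ = report.bounding_box
        assert phi < 0.6  # crossings confined to the low-pi side

    def test_single_surface_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            detect_crossings([constant_surface(0.5, 2)])

    def test_unordered_N_rejected(self):
        with pytest.raises(ValidationError, match="increasing N"):
            detect_crossings([constant_surface(0.5, 4), constant_surface(0.6, 2)])


class TestCompareSurfaces:
    def test_identical_surfaces_all_zero(self):
        a = constant_surface(0.4, 2)
        diff = spw.compare_surfaces(a, a)
        np.testing.assert_allclose(diff, 0.0)

    def test_relative_difference_arithmetic(self):
        a = constant_surface(0.3, 2)
        b = constant_surface(0.04, 2)
        diff = spw.compare_surfaces(a, b)
        np.testing.assert_allclose(diff, (0.3 - 0.04) / 0.04)
        assert diff.max() == pytest.approx(6.5)

    def test_zero_reference_cells_are_nan(self):
        a = constant_surface(0.3, 2)
        b = constant_surface(0.0, 2)
        diff = spw.compare_surfaces(a, b)
        assert np.isnan(diff).all()
        assert not np.isinf(diff).any()


class TestSerialization:
    def test_json_round_trip(self, tmp_path, monotone_records):
        pi, beta, y = monotone_records
        surf = spw.fit_scam2d((pi, beta, y), N=6)
        path = tmp_path / "surface.json"
        spw.surface_to_json(surf, path)
        back = spw.surface_from_json(path)
        assert back.N == 6
        pts = (np.linspace(pi.min(), pi.max(), 15), np.linspace(beta.min(), beta.max(), 15))
        np.testing.assert_allclose(
            surf.predict(*pts), back.predict(*pts), atol=1e-12
        )
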