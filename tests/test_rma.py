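import numpy as np
import pandas as pd
import pytest

from ceda.binning import build_gapped_histogram
from ceda.rma import (
    RMAQuery,
    correlated_sse,
    locality_lattice,
    major_factor_score,
    minor_factor_entropy,
    minor_factor_profile,
    per_response_sse,
    rma_predict,
)


@pytest.fixture(scope="module")
def lattice3x3(manifold):
    table, _ = manifold
    return locality_lattice(None, table, major_names=["theta", "rho"], n_bins=3), table


class TestLocalityLattice:
    def test_three_by_three_grid_gives_nine_localities(self, lattice3x3):
        lattice, table = lattice3x3
        assert len(lattice) == 9
        assert sum(loc.size for loc in lattice.localities.values()) == len(table)

    def test_single_bin_major_gives_one_locality(self):
        df = pd.DataFrame({"x": np.full(50, 2.0), "y": np.arange(50.0)})
        lat = locality_lattice(None, df, major_names=["x"])
        assert len(lat) == 1
        assert lat.localities[(0,)].size == 50

    def test_membership_matches_brute_force_double_filter(self, lattice3x3):
        lattice, table = lattice3x3
        h_t, h_r = lattice.histograms
        for key, loc in lattice.localities.items():
            ti, ri = key
            t_ok = (
                (table["theta"] >= h_t.edges[ti])
                & (table["theta"] <= h_t.edges[ti + 1])
                if ti == h_t.n_bins - 1
                else (table["theta"] >= h_t.edges[ti]) & (table["theta"] < h_t.edges[ti + 1])
            )
            r_ok = (
                (table["rho"] >= h_r.edges[ri]) & (table["rho"] <= h_r.edges[ri + 1])
                if ri == h_r.n_bins - 1
                else (table["rho"] >= h_r.edges[ri]) & (table["rho"] < h_r.edges[ri + 1])
            )
            oracle = set(np.flatnonzero(t_ok & r_ok))
            assert set(loc.member_ids) == oracle

    def test_every_point_in_exactly_one_locality(self, lattice3x3):
        lattice, table = lattice3x3
        seen = np.concatenate([loc.member_ids for loc in lattice.localities.values()])
        assert len(seen) == len(table)
        assert len(np.unique(seen)) == len(table)


class TestMajorFactorScore:
    def test_response_copy_scores_near_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=1000)
        df = pd.DataFrame({"y1": y, "cand": y})
        assert major_factor_score(df, "cand", ["y1"]) >= 0.95

    def test_independent_candidate_scores_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "y1": rng.normal(size=2000),
                "y2": rng.normal(size=2000),
                "anchor": rng.normal(size=2000),
                "cand": rng.normal(size=2000),
            }
        )
        assert major_factor_score(df, "cand", ["y1", "y2"], anchor="anchor") <= 0.1

    def test_single_bin_candidate_scores_zero(self):
        df = pd.DataFrame({"y1": np.random.default_rng(2).normal(size=100), "cand": np.ones(100)})
        assert major_factor_score(df, "cand", ["y1"]) == 0.0

    def test_spiral_modulator_beats_nuisance(self, manifold):
        table, truth = manifold
        resp = truth["responses"]
        s_rho = major_factor_score(table, "rho", resp, anchor="theta")
        s_nui = major_factor_score(table, "nuisance1", resp, anchor="theta")
        assert s_rho > s_nui
        s_theta = major_factor_score(table, "theta", resp)
        assert s_theta > major_factor_score(table, "nuisance1", resp)


class TestMinorFactor:
    def test_constant_candidate_in_locality(self):
        h, score = minor_factor_entropy(["a"] * 30, ["a"] * 50 + ["b"] * 50)
        assert h == 0.0
        assert score == pytest.approx(1.0)

    def test_uniform_candidate_no_localization(self):
        levels = ["a", "b"] * 25
        h, score = minor_factor_entropy(levels, levels * 4)
        assert h == pytest.approx(1.0)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_planted_minor_flagged_nuisance_not(self, lattice3x3):
        lattice, table = lattice3x3
        prof = minor_factor_profile(lattice, table, ["minor", "nuisance_cat"])
        flagged = sorted(prof[prof["flagged_minor"]]["candidate"].unique())
        assert flagged == ["minor"]


class TestRMAPredict:
    def test_constant_response_locality_predicts_exactly(self):
        df = pd.DataFrame(
            {"x": np.linspace(0, 1, 40), "y1": np.full(40, 3.5), "y2": np.full(40, -1.0)}
        )
        lat = locality_lattice(None, df, major_names=["x"])
        pred = rma_predict({"x": 0.5}, lat, df, ["y1", "y2"])
        assert np.allclose(pred.response, [3.5, -1.0])

    def test_noiseless_linear_sheet_error_bounded_by_locality_spread(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.uniform(0, 1, 800), rng.uniform(0, 1, 800)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": 2.0 * x1 - 3.0 * x2})
        lat = locality_lattice(None, df, major_names=["x1", "x2"], n_bins=4)
        for _ in range(20):
            q = {"x1": rng.uniform(0, 1), "x2": rng.uniform(0, 1)}
            pred = rma_predict(q, lat, df, ["y"], k_star=20)
            members = lat.localities[pred.locality].member_ids
            spread = np.ptp(df["y"].to_numpy()[members])
            truth = 2.0 * q["x1"] - 3.0 * q["x2"]
            assert abs(pred.response[0] - truth) <= spread + 1e-12

    def test_minor_filter_reduces_rmse_at_offset_localities(self, manifold):
        table, truth = manifold
        lat = locality_lattice(None, table, major_names=["theta", "rho"], n_bins=3)
        offset_cells = {tuple(map(int, k.split(","))) for k in truth["minor_localities"]}
        rng = np.random.default_rng(4)
        for cell in offset_cells:
            members = lat.localities[cell].member_ids
            sample = rng.choice(members, size=min(40, len(members)), replace=False)
            err_f, err_u = [], []
            for i in sample:
                row = table.iloc[i]
                q = RMAQuery({"theta": row["theta"], "rho": row["rho"]}, minor=row["minor"])
                pf = rma_predict(q, lat, table, ["y1", "y2"], minor_col="minor")
                pu = rma_predict(q, lat, table, ["y1", "y2"], minor_col=None)
                target = row[["y1", "y2"]].to_numpy(dtype=float)
                err_f.append(np.sum((pf.response - target) ** 2))
                err_u.append(np.sum((pu.response - target) ** 2))
            assert np.sqrt(np.mean(err_f)) < np.sqrt(np.mean(err_u))

    def test_global_locality_equals_plain_knn_regression(self):
        from sklearn.neighbors import KNeighborsRegressor

        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "x1": rng.uniform(size=300),
                "x2": rng.uniform(size=300),
                "y1": rng.normal(size=300),
                "y2": rng.normal(size=300),
            }
        )
        lat = locality_lattice(None, df, major_names=["x1", "x2"], n_bins=1)
        assert len(lat) == 1
        knn = KNeighborsRegressor(n_neighbors=20).fit(
            df[["x1", "x2"]].to_numpy(), df[["y1", "y2"]].to_numpy()
        )
        for _ in range(25):
            q = {"x1": rng.uniform(), "x2": rng.uniform()}
            mine = rma_predict(q, lat, df, ["y1", "y2"], k_star=20).response
            ref = knn.predict(np.array([[q["x1"], q["x2"]]]))[0]
            assert np.allclose(mine, ref, atol=1e-12)

    def test_empty_minor_filter_falls_back_with_flag(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 30), "y": np.arange(30.0), "z": ["p"] * 30})
        lat = locality_lattice(None, df, major_names=["x"])
        pred = rma_predict(RMAQuery({"x": 0.5}, minor="q"), lat, df, ["y"], minor_col="z")
        assert pred.fallback and not pred.minor_filtered

    def test_query_in_unoccupied_cell_relocates(self):
        df = pd.DataFrame(
            {"x1": np.r_[np.zeros(20), np.ones(20)], "x2": np.r_[np.zeros(20), np.ones(20)],
             "y": np.r_[np.zeros(20), np.ones(20)]}
        )
        hx = build_gapped_histogram(df["x1"].to_numpy(), method="uniform", n_bins=2)
        lat = locality_lattice([hx, hx], df, major_names=["x1", "x2"])
        pred = rma_predict({"x1": 0.95, "x2": 0.05}, lat, df, ["y"])
        assert pred.relocated
        assert pred.locality in lat.localities


class TestCorrelatedSSE:
    def test_identity_covariance_equals_plain_sse(self):
        rng = np.random.default_rng(6)
        # training responses with exactly unit sample covariance
        base = rng.normal(size=(500, 2))
        base = (base - base.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(base, rowvar=False)).T)
        errors = rng.normal(size=(40, 2))
        got = correlated_sse(errors, base)
        assert got == pytest.approx(per_response_sse(errors).sum(), rel=1e-9)

    def test_zero_errors_give_zero(self):
        train = np.random.default_rng(7).normal(size=(100, 2))
        assert correlated_sse(np.zeros((10, 2)), train) == 0.0

    def test_hand_computed_quadratic_form(self):
        # Sigma = [[2,0],[0,1]]: e' Sigma^-1 e = e1^2/2 + e2^2
        rng = np.random.default_rng(8)
        train = rng.normal(size=(4000, 2)) * np.array([np.sqrt(2.0), 1.0])
        errors = np.array([[1.0, 2.0], [3.0, -1.0]])
        sigma = np.cov(train, rowvar=False, ddof=1)
        inv = np.linalg.inv(sigma)
        oracle = sum(e @ inv @ e for e in errors)
        assert correlated_sse(errors, train) == pytest.approx(oracle, abs=1e-10)

    def test_invariance_under_linear_reparameterization(self):
        rng = np.random.default_rng(9)
        train = rng.normal(size=(300, 2)) @ np.array([[1.0, 0.3], [0.0, 0.7]])
        errors = rng.normal(size=(25, 2))
        a = np.array([[2.0, -1.0], [0.5, 1.5]])
        assert correlated_sse(errors, train) == pytest.approx(
            correlated_sse(errors @ a.T, train @ a.T), rel=1e-9
        )

    def test_per_locality_scope_with_fallback(self, manifold):
        table, _ = manifold
        lat = locality_lattice(None, table, major_names=["theta", "rho"], n_bins=3)
        rng = np.random.default_rng(10)
        errors = rng.normal(0, 0.1, size=(12, 2))
        keys = [list(lat.localities)[i % 9] for i in range(12)]
        v = correlated_sse(
            errors, table[["y1", "y2"]].to_numpy(), "per_locality", lat, keys
        )
        assert v > 0
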