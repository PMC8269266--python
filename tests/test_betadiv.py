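import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.errors import InvalidArgumentError

from conftest import brute_force_bray


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        df = pd.DataFrame({"S1": [3, 4, 5], "S2": [3, 4, 5]})
        assert ea.bray_curtis(df).iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        df = pd.DataFrame({"S1": [3, 0, 5, 0], "S2": [0, 2, 0, 7]})
        assert ea.bray_curtis(df).iloc[0, 1] == pytest.approx(1.0)

    def test_raw_matches_hand_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.integers(0, 50, 10)
            y = rng.integers(0, 50, 10)
            if x.sum() == 0 or y.sum() == 0:
                continue
            df = pd.DataFrame({"S1": x, "S2": y})
            ours = ea.bray_curtis(df, hellinger=False).iloc[0, 1]
            xr, yr = x / x.sum(), y / y.sum()
            assert ours == pytest.approx(brute_force_bray(xr, yr), abs=1e-12)

    def test_hellinger_scale_invariance(self, small_counts):
        scaled = small_counts.copy()
        scaled["S1"] = scaled["S1"] * 17
        a = ea.bray_curtis(small_counts, hellinger=True)
        b = ea.bray_curtis(scaled, hellinger=True)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"S1": [1, 2], "S2": [0, 0]})
        with pytest.raises(InvalidArgumentError, match="S2"):
            ea.bray_curtis(df)


class TestPcoa:
    def test_line_embedding_recovered(self):
        pts = np.array([0.0, 1.0, 2.5, 4.0])
        d = pd.DataFrame(
            np.abs(pts[:, None] - pts[None, :]),
            index=list("abcd"), columns=list("abcd"),
        )
        res = ea.pcoa(d)
        axis1 = res.coordinates["PC1"].to_numpy()
        gaps = np.diff(np.sort(axis1))
        assert np.allclose(sorted(gaps), sorted(np.diff(pts)), atol=1e-8)

    def test_square_has_two_equal_leading_eigenvalues(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = pd.DataFrame(
            np.linalg.norm(pts[:, None] - pts[None, :], axis=2),
            index=list("abcd"), columns=list("abcd"),
        )
        res = ea.pcoa(d)
        ev = res.eigenvalues
        assert ev[0] == pytest.approx(ev[1], rel=1e-10)
        assert ev[0] > 0
        assert np.allclose(ev[2:], 0, atol=1e-10)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        d = pd.DataFrame(
            np.linalg.norm(pts[:, None] - pts[None, :], axis=2),
            index=[f"s{i}" for i in range(6)], columns=[f"s{i}" for i in range(6)],
        )
        res = ea.pcoa(d)
        coords = res.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(rec, d.to_numpy(), atol=1e-8)

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 4))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(7)]
        ours = ea.pcoa(pd.DataFrame(dm, index=ids, columns=ids))
        theirs = sk_pcoa(DistanceMatrix(dm, ids))
        assert np.allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9])[::-1],
            np.sort(theirs.eigvals[theirs.eigvals > 1e-9].to_numpy())[::-1],
            atol=1e-8,
        )

    def test_too_few_samples(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(InvalidArgumentError):
            ea.pcoa(d)


def _two_cluster_distance(n_per=8, sep=1.0):
    n = 2 * n_per
    d = np.full((n, n), sep)
    d[:n_per, :n_per] = 0.0
    d[n_per:, n_per:] = 0.0
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids), pd.Series(
        ["a"] * n_per + ["b"] * n_per, index=ids
    )


class TestPermanovaAnosim:
    def test_maximal_separation_p_is_minimum(self):
        d, g = _two_cluster_distance()
        _, p = ea.permanova(d, g, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_anosim_perfect_separation_r_is_one(self):
        d, g = _two_cluster_distance()
        r, p = ea.anosim(d, g, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_anosim_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(10)]
        g = pd.Series(["a"] * 5 + ["b"] * 5, index=ids)
        d1 = pd.DataFrame(dm, index=ids, columns=ids)
        d2 = pd.DataFrame(dm**3, index=ids, columns=ids)
        r1, _ = ea.anosim(d1, g, n_perm=99, seed=1)
        r2, _ = ea.anosim(d2, g, n_perm=99, seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_statistics_match_skbio(self):
        from skbio.stats.distance import DistanceMatrix, anosim as sk_anosim
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        pts[:6] += 1.5
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(12)]
        g = ["a"] * 6 + ["b"] * 6
        ours_f, _ = ea.permanova(pd.DataFrame(dm, index=ids, columns=ids),
                                 pd.Series(g, index=ids), n_perm=99, seed=0)
        ours_r, _ = ea.anosim(pd.DataFrame(dm, index=ids, columns=ids),
                              pd.Series(g, index=ids), n_perm=99, seed=0)
        skdm = DistanceMatrix(dm, ids)
        assert ours_f == pytest.approx(
            sk_permanova(skdm, g, permutations=9)["test statistic"], rel=1e-9
        )
        assert ours_r == pytest.approx(
            sk_anosim(skdm, g, permutations=9)["test statistic"], rel=1e-9
        )

    def test_singleton_group_rejected(self):
        d, g = _two_cluster_distance()
        g.iloc[0] = "c"
        with pytest.raises(InvalidArgumentError):
            ea.permanova(d, g, n_perm=99, seed=0)


class TestHaversine:
    def test_identical_points(self):
        assert ea.haversine_km(10, 20, 10, 20) == 0.0

    def test_quarter_great_circle(self):
        assert ea.haversine_km(0, 0, 0, 90) == pytest.approx(
            np.pi / 2 * 6371.0088, rel=1e-9
        )

    def test_matrix_metric_axioms(self):
        rng = np.random.default_rng(6)
        lat = rng.uniform(-60, 60, 8)
        lon = rng.uniform(-170, 170, 8)
        d = ea.haversine_matrix(lat, lon).to_numpy()
        assert np.allclose(d, d.T)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ea.haversine_matrix([95.0], [0.0])


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 2))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(8)]
        d = pd.DataFrame(dm, index=ids, columns=ids)
        r, p = ea.mantel(d, d, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_spearman_monotone_transform(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(8, 2))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(8)]
        d1 = pd.DataFrame(dm, index=ids, columns=ids)
        d2 = pd.DataFrame(np.sqrt(dm), index=ids, columns=ids)
        r, _ = ea.mantel(d1, d2, method="spearman", n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(9)
        p1 = rng.normal(size=(9, 2))
        p2 = rng.normal(size=(9, 2))
        ids = [f"s{i}" for i in range(9)]
        m1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=2)
        m2 = np.linalg.norm(p2[:, None] - p2[None, :], axis=2)
        ours_r, _ = ea.mantel(
            pd.DataFrame(m1, index=ids, columns=ids),
            pd.DataFrame(m2, index=ids, columns=ids),
            method="pearson", n_perm=99, seed=0,
        )
        theirs = sk_mantel(
            DistanceMatrix(m1, ids), DistanceMatrix(m2, ids),
            method="pearson", permutations=0,
        )
        assert ours_r == pytest.approx(float(theirs[0]), rel=1e-9)

    def test_mismatched_ids(self):
        d1 = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        d2 = pd.DataFrame([[0, 1], [1, 0]], index=["a", "c"], columns=["a", "c"])
        with pytest.raises(InvalidArgumentError):
            ea.mantel(d1, d2)


class TestDistanceDecay:
    def test_two_point_slope_analytic(self):
        """Two co-located groups at a known separation give the exact slope."""
        rng = np.random.default_rng(10)
        base = rng.integers(1, 50, (20, 3))
        far = rng.integers(1, 50, (20, 3))
        counts = pd.DataFrame(
            np.hstack([base, far]),
            columns=[f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)],
        )
        lats = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
        lons = [0.0] * 6
        r, p, slope = ea.distance_decay(counts, lats, lons, n_perm=99, seed=0)
        sim = 1 - ea.bray_curtis(counts).to_numpy()
        iu = np.triu_indices(6, 1)
        km = ea.haversine_km(0, 0, 1, 0)
        x = ea.haversine_matrix(lats, lons).to_numpy()[iu]
        y = sim[iu]
        s0 = (y[x > 0].mean() - y[x == 0].mean()) / km
        assert slope == pytest.approx(s0, rel=1e-9)

    def test_dispersal_limited_regime_decays(self):
        design = ea.default_design(sites_per_location=1)
        model = ea.MetacommunityModel.simulate(150, seed=20)
        counts, meta, _ = ea.simulate_dataset(
            design, model,
            ea.RegimeSpec("dispersal_limited", m=0.05, dispersal_scale=120.0),
            seed=21,
        )
        r, p, slope = ea.distance_decay(
            counts, meta["latitude"], meta["longitude"], n_perm=999, seed=22
        )
        assert slope < 0
        assert p < 0.05

    def test_colocated_samples_rejected(self):
        counts = pd.DataFrame(np.ones((4, 6), dtype=int))
        with pytest.raises(InvalidArgumentError):
            ea.distance_decay(counts, [0.0] * 6, [0.0] * 6, n_perm=99, seed=0)


class TestEnvCorrelations:
    def test_identity_and_negation(self):
        x = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]})
        cov = pd.DataFrame({"same": [1.0, 2, 3, 4, 5, 6], "neg": [-1.0, -2, -3, -4, -5, -6]})
        out = ea.env_correlations(x, cov)
        same = out[out["covariate"] == "same"]["rho"].iloc[0]
        neg = out[out["covariate"] == "neg"]["rho"].iloc[0]
        assert same == pytest.approx(1.0)
        assert neg == pytest.approx(-1.0)

    def test_hand_ranked_six_points(self):
        """Manual rank correlation on a 6-point example with a tie."""
        f = [3.0, 1.0, 4.0, 4.0, 5.0, 2.0]
        c = [30.0, 10.0, 45.0, 40.0, 50.0, 20.0]
        # ranks f: [3, 1, 4.5, 4.5, 6, 2]; ranks c: [3, 1, 5, 4, 6, 2]
        rf = np.array([3, 1, 4.5, 4.5, 6, 2])
        rc_ = np.array([3, 1, 5, 4, 6, 2])
        expected = np.corrcoef(rf, rc_)[0, 1]
        out = ea.env_correlations(pd.DataFrame({"f": f}), pd.DataFrame({"c": c}))
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_flagged(self):
        f = pd.DataFrame({"f": [1.0, 2, 3, 4, 5]})
        cov = pd.DataFrame({"const": [7.0] * 5})
        out = ea.env_correlations(f, cov)
        assert np.isnan(out["rho"].iloc[0])
        assert out["note"].iloc[0] == "constant column"
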