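"""LMM scan tests: kinship against an explicit double-loop oracle, null
heritability against a grid-search oracle, scan LODs against closed-form
OLS and a brute-force matrix-inversion GLS, permutation determinism, and
support-interval geometry."""

import numpy as np
import pandas as pd
import pytest

from strmutator import qtl
from strmutator.types import ConfigurationError, MarkerMap, ScanResult


def grid_map(chrom_sizes, spacing_cm=2.0):
    rows = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            rows.append((f"{chrom}_m{i}", chrom, i * 1_000_000 + 500, i * spacing_cm))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "pos_cm"]))


def probs_from_labels(labels):
    """labels (n, m) of 0/1 -> hard genotype probabilities."""
    pb = 1.0 - np.asarray(labels, dtype=float)
    return np.stack([pb, 1.0 - pb], axis=-1)


def random_panel(rng, n, m_per_chrom, chroms=("chr1", "chr2")):
    mm = grid_map({c: m_per_chrom for c in chroms})
    labels = rng.integers(0, 2, (n, mm.n_markers))
    return mm, probs_from_labels(labels)


class TestKinship:
    def test_identical_and_complementary_mosaics(self):
        mm = grid_map({"chr1": 4, "chr2": 4})
        labels = np.array(
            [[0, 0, 1, 1, 0, 1, 0, 1],
             [0, 0, 1, 1, 0, 1, 0, 1],
             [1, 1, 0, 0, 1, 0, 1, 0]]
        )
        K = qtl.calc_kinship_loco(probs_from_labels(labels), mm)
        for chrom in ("chr1", "chr2"):
            k = K[chrom]
            assert k[0, 1] == pytest.approx(k[0, 0])
            assert k[0, 2] == pytest.approx(0.0)
            np.testing.assert_allclose(k, k.T, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        mm = grid_map({"chr1": 2, "chr2": 2})
        # soft probabilities: 3 strains x 4 markers
        pb = rng.random((3, 4))
        probs = np.stack([pb, 1 - pb], axis=-1)
        K = qtl.calc_kinship_loco(probs, mm)
        for chrom, keep in (("chr1", [2, 3]), ("chr2", [0, 1])):
            expected = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    acc = 0.0
                    for m in keep:
                        for g in range(2):
                            acc += probs[i, m, g] * probs[j, m, g]
                    expected[i, j] = acc / len(keep)
            np.testing.assert_allclose(K[chrom], expected, atol=1e-12)

    def test_single_chromosome_falls_back_to_all_markers(self, caplog):
        mm = grid_map({"chr1": 4})
        rng = np.random.default_rng(1)
        probs = probs_from_labels(rng.integers(0, 2, (3, 4)))
        with caplog.at_level("WARNING"):
            K = qtl.calc_kinship_loco(probs, mm)
        assert "LOCO impossible" in caplog.text
        assert K["chr1"].shape == (3, 3)


class TestFitNull:
    def test_identity_kinship_pins_h2_to_zero(self):
        rng = np.random.default_rng(2)
        n = 40
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        fit = qtl.fit_null(y, X, np.eye(n) / 2)
        assert fit.h2 == 0.0
        np.testing.assert_allclose(fit.weights, np.ones(n))

    def test_degenerate_phenotype_handled(self):
        n = 20
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 + 3.0 * x  # exactly linear in covariates
        K = np.full((n, n), 0.1) + np.eye(n) * 0.4
        fit = qtl.fit_null(y, X, K)
        assert np.isfinite(fit.loglik)
        assert 0.0 <= fit.h2 <= 0.99

    def test_optimizer_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        n = 60
        mm, probs = random_panel(rng, n, 30)
        K = qtl.calc_kinship_loco(probs, mm)["chr1"]
        lam, U = np.linalg.eigh(2 * K)
        lam = np.clip(lam, 0, None)
        X = np.ones((n, 1))
        # draw y with genuine genetic covariance
        L = np.linalg.cholesky(2 * K + 1e-6 * np.eye(n))
        y = L @ rng.normal(size=n) + rng.normal(size=n)
        fit = qtl.fit_null(y, X, K)
        grid = np.arange(0.0, 0.9901, 1e-3)
        ll = [qtl._profile_loglik(h, lam, U.T @ y, U.T @ X) for h in grid]
        h2_grid = grid[int(np.argmax(ll))]
        assert abs(fit.h2 - h2_grid) <= 2e-3

    def test_h2_recovery_within_band(self):
        """Simulated phenotypes with h2 = 0.5 on mosaic kinship, n = 200:
        mean estimate within +/-0.15 over 20 replicates."""
        rng = np.random.default_rng(4)
        n = 200
        mm, probs = random_panel(rng, n, 60)
        K = qtl.calc_kinship_loco(probs, mm)["chr1"]
        lam, U = np.linalg.eigh(2 * K)
        lam = np.clip(lam, 0, None)
        X = np.ones((n, 1))
        h2_true = 0.5
        est = []
        for _ in range(20):
            g = U @ (np.sqrt(h2_true * lam) * rng.normal(size=n))
            y = g + np.sqrt(1 - h2_true) * rng.normal(size=n)
            est.append(qtl.fit_null(y, X, K, eigen=(lam, U)).h2)
        assert abs(np.mean(est) - h2_true) <= 0.15


def ols_lod(y, X, g):
    n = len(y)

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    return n / 2 * np.log10(rss(X) / rss(np.column_stack([X, g])))


def brute_force_lod(y, X, g, K, h2):
    """GLS by explicit matrix inversion, no eigen-rotation."""
    n = len(y)
    V = h2 * 2 * K + (1 - h2) * np.eye(n)
    Vi = np.linalg.inv(V)

    def rss(M):
        beta = np.linalg.solve(M.T @ Vi @ M, M.T @ Vi @ y)
        r = y - M @ beta
        return float(r @ Vi @ r)

    return n / 2 * np.log10(rss(X) / rss(np.column_stack([X, g])))


class TestScan:
    def setup_scan(self, seed=5, n=30, m=20):
        rng = np.random.default_rng(seed)
        mm, probs = random_panel(rng, n, m)
        K = qtl.calc_kinship_loco(probs, mm)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n) + probs[:, 5, 0]
        return rng, mm, probs, K, X, y

    def test_constant_phenotype_zero_lod(self):
        _, mm, probs, K, X, _ = self.setup_scan()
        res = qtl.scan1(probs, np.full(30, 3.0), K, X, mm)
        np.testing.assert_allclose(res.lod["lod"], 0.0, atol=1e-9)

    def test_zero_kinship_matches_ols_closed_form(self):
        _, mm, probs, _, X, y = self.setup_scan()
        K0 = {c: np.zeros((30, 30)) for c in mm.chromosomes}
        res = qtl.scan1(probs, y, K0, X, mm, drop_monomorphic=False)
        for i, row in res.lod.iterrows():
            j = mm.marker_index(row["marker"])
            expect = ols_lod(y, X, probs[:, j, 0])
            assert abs(row["lod"] - expect) < 1e-8

    def test_marker_equal_to_covariate_zero_lod(self):
        rng = np.random.default_rng(6)
        mm = grid_map({"chr1": 3, "chr2": 3})
        labels = rng.integers(0, 2, (20, 6))
        probs = probs_from_labels(labels)
        X = np.column_stack([np.ones(20), probs[:, 0, 0]])
        y = rng.normal(size=20)
        K = qtl.calc_kinship_loco(probs, mm)
        res = qtl.scan1(probs, y, K, X, mm, drop_monomorphic=False)
        assert res.lod.loc[res.lod["marker"] == "chr1_m0", "lod"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_inversion_small_n(self):
        """n <= 12: rotated scan equals explicit V^-1 GLS to 1e-6."""
        rng = np.random.default_rng(7)
        n = 12
        mm, probs = random_panel(rng, n, 8)
        K = qtl.calc_kinship_loco(probs, mm)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n) + 0.5 * probs[:, 3, 0]
        res = qtl.scan1(probs, y, K, X, mm, drop_monomorphic=False)
        for _, row in res.lod.iterrows():
            j = mm.marker_index(row["marker"])
            chrom = row["chrom"]
            expect = brute_force_lod(y, X, probs[:, j, 0], K[chrom], res.h2_by_chrom[chrom])
            assert abs(row["lod"] - expect) < 1e-6

    def test_affine_invariance(self):
        _, mm, probs, K, X, y = self.setup_scan(seed=8)
        r1 = qtl.scan1(probs, y, K, X, mm)
        r2 = qtl.scan1(probs, 5.0 - 3.2 * y, K, X, mm)
        np.testing.assert_allclose(r1.lod["lod"], r2.lod["lod"], atol=1e-6)

    def test_nonfinite_phenotypes_dropped_pairwise(self):
        _, mm, probs, K, X, y = self.setup_scan(seed=9)
        y2 = y.copy()
        y2[3] = np.nan
        res = qtl.scan1(probs, y2, K, X, mm)
        keep = np.arange(30) != 3
        Ks = {c: k for c, k in K.items()}
        res_manual = qtl.scan1(probs[keep], y[keep] if False else y2[keep],
                               {c: k[np.ix_(keep, keep)] for c, k in Ks.items()},
                               X[keep], mm)
        np.testing.assert_allclose(res.lod["lod"], res_manual.lod["lod"], atol=1e-9)


class TestPermutations:
    def test_monotone_and_deterministic(self):
        rng = np.random.default_rng(10)
        n = 25
        mm, probs = random_panel(rng, n, 15)
        K = qtl.calc_kinship_loco(probs, mm)
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        thr1, max1 = qtl.permutation_threshold(
            probs, y, K, X, mm, n_perm=50, alphas=(0.01, 0.05), seed=77
        )
        thr2, max2 = qtl.permutation_threshold(
            probs, y, K, X, mm, n_perm=50, alphas=(0.01, 0.05), seed=77
        )
        assert thr1[0.01] >= thr1[0.05]
        assert thr1 == thr2
        np.testing.assert_array_equal(max1, max2)

    def test_quantile_rule_type7(self):
        rng = np.random.default_rng(11)
        n = 20
        mm, probs = random_panel(rng, n, 10)
        K = qtl.calc_kinship_loco(probs, mm)
        thr, maxima = qtl.permutation_threshold(
            probs, rng.normal(size=n), K, np.ones((n, 1)), mm, n_perm=40, seed=5
        )
        assert thr[0.05] == pytest.approx(float(np.quantile(maxima, 0.95)))

    def test_invalid_n_perm(self):
        rng = np.random.default_rng(12)
        mm, probs = random_panel(rng, 10, 5)
        K = qtl.calc_kinship_loco(probs, mm)
        with pytest.raises(ConfigurationError):
            qtl.permutation_threshold(probs, np.zeros(10), K, np.ones((10, 1)), mm, n_perm=0)


def scan_result_from(lods, chrom="chr1"):
    df = pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(len(lods))],
            "chrom": chrom,
            "pos_bp": np.arange(len(lods)) * 100,
            "lod": lods,
        }
    )
    return ScanResult(df, {chrom: 0.0})


class TestSupportInterval:
    def test_single_marker_peak_extends_one_flank(self):
        scan = scan_result_from([0.1, 0.2, 5.0, 0.3, 0.1])
        lo, hi = qtl.lod_support_interval(scan, "chr1", drop=1.5)
        assert (lo, hi) == (100, 301)

    def test_infinite_drop_spans_chromosome(self):
        scan = scan_result_from([1.0, 2.0, 3.0, 2.0])
        lo, hi = qtl.lod_support_interval(scan, "chr1", drop=np.inf)
        assert (lo, hi) == (0, 301)

    def test_two_peaks_interval_confined_to_peak_run(self):
        # oracle: exhaustive scan of the toy vector; the dip below
        # peak - 1.5 separates the runs, so the far peak is excluded
        lods = [4.0, 1.0, 1.0, 5.0, 4.9]
        scan = scan_result_from(lods)
        lo, hi = qtl.lod_support_interval(scan, "chr1", drop=1.5)
        peak = max(lods)
        runs_ok = [i for i in (3, 4)]
        assert lo == 200  # one flank before marker 3
        assert hi == 401
        assert all(lods[i] >= peak - 1.5 for i in runs_ok)

    def test_flat_curve_spans_chromosome(self):
        scan = scan_result_from([2.0, 2.0, 2.0])
        assert qtl.lod_support_interval(scan, "chr1", drop=1.5) == (0, 201)

    def test_unknown_chromosome_rejected(self):
        scan = scan_result_from([1.0])
        with pytest.raises(ConfigurationError):
            qtl.lod_support_interval(scan, "chrX")
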