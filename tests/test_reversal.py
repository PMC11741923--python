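"""TLS reversal coefficient: closed form, oracles, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from reverseq.core import ValidationError
from reverseq.reversal import (classify_opposite, paired_fc, pearson_r,
                               reversal_report, tls_fit)

from conftest import contrast_frame


def tls_slope_eigen(x, y):
    """Independent TLS slope: principal eigenvector of the centered scatter."""
    X = np.column_stack([x - np.mean(x), y - np.mean(y)])
    w, v = np.linalg.eigh(X.T @ X)
    vec = v[:, np.argmax(w)]
    return vec[1] / vec[0]


def tls_slope_search(x, y, n_grid=20001):
    """Brute-force TLS slope: golden-section over the line angle.

    The best TLS line passes through the centroid; the orthogonal squared
    distance at angle t is sum((-sin t * xc + cos t * yc)^2), minimized by a
    dense grid followed by golden-section refinement.
    """
    from scipy.optimize import minimize_scalar
    xc = x - np.mean(x)
    yc = y - np.mean(y)

    def obj(t):
        return np.sum((-np.sin(t) * xc + np.cos(t) * yc) ** 2)

    ts = np.linspace(-np.pi / 2, np.pi / 2, n_grid)
    vals = [obj(t) for t in ts]
    i = int(np.argmin(vals))
    lo, hi = ts[max(i - 1, 0)], ts[min(i + 1, n_grid - 1)]
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-14})
    return np.tan(res.x)


class TestTLSFit:
    def test_collinear_points(self):
        b, a = tls_fit([0, 1, 2], [0, -1, -2])
        assert b == pytest.approx(-1.0) and a == pytest.approx(0.0)

    def test_balanced_scatter_gives_unit_slope(self):
        """S_xx = S_yy forces |b| = 1 with the sign of S_xy."""
        b, _ = tls_fit([0, 1, 0, 2], [0, 0, 1, 2])
        assert b == pytest.approx(1.0)

    def test_degenerate_cross_products(self):
        # horizontal principal axis
        b, _ = tls_fit([0, 1, 2, 3], [0.0, 0.0, 0.0, 0.0])
        assert b == 0.0
        # vertical principal axis has no finite slope
        with pytest.raises(ValidationError, match="vertical"):
            tls_fit([0, 0, 0, 1], [0, 5, -5, 0])
        with pytest.raises(ValidationError):
            tls_fit([1.0, 1.0, 1.0], [0, 1, 2])

    def test_needs_three_points(self):
        with pytest.raises(ValidationError):
            tls_fit([0, 1], [0, 1])

    @given(st.integers(0, 10_000))
    def test_matches_eigenvector_of_scatter(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(scale=0.5, size=30)
        b, _ = tls_fit(x, y)
        assert b == pytest.approx(tls_slope_eigen(x, y), abs=1e-10)

    def test_matches_orthogonal_distance_search(self, rng):
        for _ in range(10):
            x = rng.normal(size=50)
            y = rng.uniform(-1, 1) * x + rng.normal(scale=0.4, size=50)
            b, _ = tls_fit(x, y)
            assert abs(b - tls_slope_search(x, y)) < 1e-6

    def test_swap_and_negate_equivariance(self, rng):
        x = rng.normal(size=40)
        y = -0.6 * x + rng.normal(scale=0.2, size=40)
        b, _ = tls_fit(x, y)
        b_swap, _ = tls_fit(y, x)
        assert b_swap == pytest.approx(1.0 / b, rel=1e-9)
        b_neg, _ = tls_fit(x, -y)
        assert b_neg == pytest.approx(-b, rel=1e-9)


class TestPearson:
    def test_perfect_anticorrelation(self):
        r, p = pearson_r([0, 1, 2, 3], [0, -1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_independent_data_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        r, _ = pearson_r(x, y)
        assert abs(r) < 0.1

    def test_affine_invariance(self, rng):
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        r1, p1 = pearson_r(x, y)
        r2, p2 = pearson_r(3.0 * x - 2.0, 0.5 * y + 7.0)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 1, 1], [0, 1, 2])


class TestPairedFC:
    def test_all_tested_universe_keeps_every_shared_gene(self):
        genes = [f"g{i}" for i in range(10)]
        dis = contrast_frame(genes, np.linspace(-2, 2, 10), [0.5] * 10)
        trt = contrast_frame(genes, np.linspace(2, -2, 10), [0.5] * 10)
        assert len(paired_fc(dis, trt, universe="all_tested")) == 10

    def test_disjoint_gene_lists_error(self):
        dis = contrast_frame(["a", "b", "c"], [1, 2, 3], [0.01] * 3)
        trt = contrast_frame(["x", "y", "z"], [1, 2, 3], [0.01] * 3)
        with pytest.raises(ValidationError):
            paired_fc(dis, trt)

    def test_union_significant_counts_by_hand(self):
        """10 genes; 4 significant in at least one contrast -> 4 pairs."""
        genes = [f"g{i}" for i in range(10)]
        q_dis = [0.01, 0.01, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.04, 0.5]
        q_trt = [0.01, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.02]
        dis = contrast_frame(genes, np.ones(10), q_dis)
        trt = contrast_frame(genes, -np.ones(10), q_trt)
        pairs = paired_fc(dis, trt, universe="union_significant", alpha=0.05)
        assert set(pairs.index) == {"g0", "g1", "g8", "g9"}


class TestClassification:
    def test_all_five_classes_enumerated(self):
        paired = pd.DataFrame(
            {
                "x": [2.0, 2.0, 2.0, 1.0, 0.5, 0.0],
                "y": [-1.0, 1.0, 0.3, -0.4, 0.2, -1.0],
                "q_x": [0.01, 0.01, 0.01, 0.2, 0.3, 0.01],
                "q_y": [0.01, 0.01, 0.2, 0.01, 0.3, 0.01],
            },
            index=[f"g{i}" for i in range(6)],
        )
        got = classify_opposite(paired, alpha=0.05)
        assert list(got) == [
            "reversed_significant", "concordant_significant", "disease_only",
            "treatment_only", "neither",
            "concordant_significant",  # sign 0 * sign -1 = 0: never reversed
        ]

    def test_missing_qvalues_rejected(self):
        paired = pd.DataFrame({"x": [1.0] * 3, "y": [1.0] * 3,
                               "q_x": [0.1, np.nan, 0.1], "q_y": [0.1] * 3})
        with pytest.raises(ValidationError):
            classify_opposite(paired)


class TestReversalReport:
    def _tables(self, rng, n=400, rho=0.5):
        genes = [f"g{i}" for i in range(n)]
        x = rng.normal(0, 2, size=n)
        y = -rho * x + rng.normal(0, 0.1, size=n)
        dis = contrast_frame(genes, x, np.full(n, 0.01))
        trt = contrast_frame(genes, y, np.full(n, 0.01))
        return dis, trt

    def test_recovers_generating_slope(self, rng):
        dis, trt = self._tables(rng)
        rep = reversal_report(dis, trt, n_bootstrap=200, seed=1)
        assert rep.tls_slope == pytest.approx(-0.5, abs=0.05)
        assert rep.slope_ci[0] <= rep.tls_slope <= rep.slope_ci[1]
        assert rep.class_counts.sum() == rep.n_genes
        assert -1.0 <= rep.pearson_r <= 1.0

    def test_single_resample_bootstrap_contract(self, rng):
        """With B = 1 the CI collapses onto the resample/point estimates."""
        dis, trt = self._tables(rng, n=50)
        rep = reversal_report(dis, trt, n_bootstrap=1, seed=7)
        x = paired_fc(dis, trt)["x"].to_numpy()
        y = paired_fc(dis, trt)["y"].to_numpy()
        resample = np.random.default_rng(7).integers(0, len(x), size=len(x))
        b_res, _ = tls_fit(x[resample], y[resample])
        assert set(np.round(rep.slope_ci, 12)) <= {round(b_res, 12),
                                                   round(rep.tls_slope, 12)}
        assert rep.slope_ci[0] <= rep.tls_slope <= rep.slope_ci[1]

    def test_same_seed_reproducible(self, rng):
        dis, trt = self._tables(rng)
        rep1 = reversal_report(dis, trt, n_bootstrap=100, seed=5)
        rep2 = reversal_report(dis, trt, n_bootstrap=100, seed=5)
        assert rep1.slope_ci == rep2.slope_ci
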