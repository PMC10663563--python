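"""Evaluation metrics against brute-force evaluations of their formulas."""

import numpy as np
import pytest

from spacelkit import (
    accuracy_score,
    asw,
    deconv_metrics,
    domain_metrics,
    find_svgs,
    grid_similarity,
    percentage_overlap,
    register_to_truth,
)
from spacelkit.core_data import CompositionMatrix
from spacelkit.metrics import apply_affine, jsd


def _comp(arr):
    arr = np.asarray(arr, float)
    return CompositionMatrix(arr, np.array([f"t{i}" for i in range(arr.shape[1])]))


class TestDeconvMetrics:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=8)
        m = deconv_metrics(_comp(p), _comp(p))
        assert np.allclose(m["PCC"], 1.0)
        assert np.allclose(m["SSIM"], 1.0)
        assert np.allclose(m["RMSE"], 0.0)
        assert np.allclose(m["JSD"], 0.0)

    def test_two_spot_reversal_gives_negative_correlation(self):
        truth = _comp([[0.8, 0.2], [0.2, 0.8]])
        pred = _comp([[0.2, 0.8], [0.8, 0.2]])
        m = deconv_metrics(pred, truth)
        assert np.allclose(m["PCC"], -1.0)

    def test_jsd_matches_brute_force(self):
        p = np.array([0.5, 0.3, 0.2])
        q = np.array([0.2, 0.5, 0.3])
        m = (p + q) / 2
        brute = 0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m))
        assert abs(jsd(p, q) - brute) < 1e-10

    def test_ssim_matches_printed_formula(self):
        rng = np.random.default_rng(1)
        truth = rng.dirichlet(np.ones(2), size=10)
        pred = rng.dirichlet(np.ones(2), size=10)
        m = deconv_metrics(_comp(pred), _comp(truth))

        def scale(v):
            return (v - v.min()) / (v.max() - v.min())

        x, y = scale(truth[:, 0]), scale(pred[:, 0])
        c1, c2 = 0.01, 0.03
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        brute = ((2 * x.mean() * y.mean() + c1**2) * (2 * cov + c2**2)) / (
            (x.mean() ** 2 + y.mean() ** 2 + c1**2)
            * (x.std() ** 2 + y.std() ** 2 + c2**2)
        )
        assert abs(m["SSIM"][0] - brute) < 1e-10

    def test_zero_variance_truth_reported_missing(self):
        truth = _comp([[0.5, 0.5], [0.5, 0.5]])
        pred = _comp([[0.6, 0.4], [0.4, 0.6]])
        assert np.isnan(deconv_metrics(pred, truth)["PCC"][0])


class TestAccuracyScore:
    @staticmethod
    def _metrics(pcc, ssim, rmse, js):
        return {"PCC": np.array([pcc]), "SSIM": np.array([ssim]),
                "RMSE": np.array([rmse]), "JSD": np.array([js])}

    def test_two_method_dominance(self):
        res = accuracy_score({
            "A": self._metrics(0.9, 0.9, 0.05, 0.02),
            "B": self._metrics(0.5, 0.6, 0.20, 0.10),
        })
        assert res["A"] == 1.0 and res["B"] == 0.5

    def test_identical_methods_tie(self):
        m = self._metrics(0.7, 0.7, 0.1, 0.1)
        res = accuracy_score({"A": m, "B": m, "C": m})
        assert len(set(res.values())) == 1

    def test_three_method_chain(self):
        res = accuracy_score({
            "A": self._metrics(0.9, 0.9, 0.05, 0.02),
            "B": self._metrics(0.7, 0.7, 0.10, 0.05),
            "C": self._metrics(0.5, 0.5, 0.20, 0.10),
        })
        assert np.allclose([res["A"], res["B"], res["C"]], [1.0, 2 / 3, 1 / 3])

    def test_invariant_to_monotone_rescaling(self):
        methods = {
            "A": self._metrics(0.9, 0.8, 0.05, 0.02),
            "B": self._metrics(0.7, 0.9, 0.10, 0.05),
            "C": self._metrics(0.5, 0.5, 0.20, 0.01),
        }
        base = accuracy_score(methods)
        rescaled = {
            m: {"PCC": np.exp(v["PCC"]), "SSIM": v["SSIM"] ** 3,
                "RMSE": 10 * v["RMSE"], "JSD": np.sqrt(v["JSD"])}
            for m, v in methods.items()
        }
        assert accuracy_score(rescaled) == base

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            accuracy_score({"A": self._metrics(0.9, 0.9, 0.1, 0.1)})


class TestDomainMetrics:
    def test_perfect_prediction(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        coords = np.arange(12, dtype=float).reshape(6, 2)
        m = domain_metrics(labels, labels, coords)
        assert m["ARI"] == 1.0
        assert all(v == 1.0 for v in m["JI"].values())
        assert all(v == 0.0 for v in m["SD"].values())

    def test_jaccard_set_arithmetic(self):
        # domain d = spots {1,2,3}; layer l = spots {2,3,4}
        pred = np.array([9, 0, 0, 0, 9, 9])
        truth = np.array([8, 8, 0, 0, 0, 8])
        coords = np.column_stack([np.arange(6.0), np.zeros(6)])
        m = domain_metrics(pred, truth, coords)
        assert m["JI"][0] == 0.5

    def test_random_labels_ari_near_zero(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 100, (400, 2))
        aris = []
        for _ in range(20):
            a = rng.integers(0, 4, 400)
            b = rng.integers(0, 4, 400)
            aris.append(domain_metrics(a, b, coords)["ARI"])
        assert abs(np.median(aris)) < 0.05

    def test_shifting_distance_point_to_set(self):
        pred = np.array([0, 0, 1, 1])
        truth = np.array([1, 1, 0, 0])  # swapped: domain 0 corresponds to layer 1?
        coords = np.array([[0.0, 0], [1.0, 0], [10.0, 0], [11.0, 0]])
        m = domain_metrics(pred, truth, coords)
        # each domain fully matches the swapped layer label, JI = 1, SD = 0
        assert all(v == 1.0 for v in m["JI"].values())
        assert all(v == 0.0 for v in m["SD"].values())


class TestASW:
    def test_brute_force_silhouette_single_cluster(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(10, 2))
        batch = np.array([0, 1] * 5)
        clusters = np.zeros(10, dtype=int)

        d = np.linalg.norm(feats[:, None] - feats[None], axis=-1)
        sil = np.zeros(10)
        for i in range(10):
            same = (batch == batch[i]) & (np.arange(10) != i)
            a = d[i, same].mean()
            b = d[i, batch != batch[i]].mean()
            sil[i] = (b - a) / max(a, b)
        brute = np.mean(1 - np.abs(sil))
        assert abs(asw(feats, batch, clusters) - brute) < 1e-10

    def test_interleaved_batches_high(self):
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(200, 2))
        batch = rng.integers(0, 2, 200)
        clusters = np.zeros(200, dtype=int)
        assert asw(feats, batch, clusters) > 0.8

    def test_separated_batches_low(self):
        rng = np.random.default_rng(5)
        feats = np.vstack([rng.normal(0, 0.1, (50, 2)),
                           rng.normal(50, 0.1, (50, 2))])
        batch = np.repeat([0, 1], 50)
        clusters = np.zeros(100, dtype=int)
        assert asw(feats, batch, clusters) < 0.1

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            asw(np.zeros((4, 2)), np.zeros(4), np.zeros(4))


class TestPercentageOverlap:
    def test_identical(self):
        assert percentage_overlap({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint(self):
        assert percentage_overlap({1, 2}, {3, 4}) == 0.0

    def test_partial(self):
        assert percentage_overlap(set(range(3)), set(range(10))) == 0.3

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            percentage_overlap({1}, set())


class TestFindSVGs:
    @staticmethod
    def _data(seed=6, planted=True):
        rng = np.random.default_rng(seed)
        n, g = 120, 30
        labels = np.repeat([0, 1, 2], n // 3)
        expr = rng.normal(1.0, 0.3, size=(n, g)).clip(0)
        if planted:
            expr[labels == 1, 5] += 3.0  # gene 5 marks domain 1
        genes = np.array([f"g{i}" for i in range(g)], dtype=object)
        return np.log1p(expr), genes, labels

    def test_planted_gene_found(self):
        expr, genes, labels = self._data()
        out = find_svgs(expr, genes, labels)
        assert "g5" in out["lists"][1]

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        sizes = []
        for _ in range(5):
            expr, genes, labels = self._data(seed=rng.integers(1e6), planted=False)
            out = find_svgs(expr, genes, rng.permutation(labels))
            sizes.append(sum(len(v) for v in out["lists"].values()))
        assert np.median(sizes) <= 0.05 * 30 * 3

    def test_infinite_lfc_cut_empties_lists(self):
        expr, genes, labels = self._data()
        out = find_svgs(expr, genes, labels, lfc_cut=np.inf)
        assert all(len(v) == 0 for v in out["lists"].values())


class TestGridSimilarity:
    def test_self_comparison_exact(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 100, (80, 2))
        comp = rng.dirichlet(np.ones(3), size=80)
        assert grid_similarity((coords, comp), (coords, comp)) == (1.0, 1.0)

    def test_rotation_of_asymmetric_layout_scores_lower(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 100, (300, 2))
        comp = np.zeros((300, 2))
        comp[:, 0] = coords[:, 0] / 100.0  # left-right gradient
        comp[:, 1] = 1 - comp[:, 0]
        center = coords.mean(axis=0)
        rotated = 2 * center - coords  # 180 degrees about the centroid
        s_self, p_self = grid_similarity((coords, comp), (coords, comp))
        s_rot, p_rot = grid_similarity((rotated, comp), (coords, comp))
        assert s_rot < s_self and p_rot < p_self

    def test_hand_gridded_toy(self):
        # 2x2 grid, one spot per cell, known means
        coords_a = np.array([[0.1, 0.1], [0.9, 0.1], [0.1, 0.9], [0.9, 0.9]])
        comp_a = np.array([[1.0], [2.0], [3.0], [4.0]])
        comp_b = np.array([[1.0], [2.0], [3.0], [5.0]])
        ssim, pcc = grid_similarity((coords_a, comp_a), (coords_a, comp_b), grid=2)
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 3, 5])
        brute_pcc = np.corrcoef(x, y)[0, 1]
        assert abs(pcc - brute_pcc) < 1e-10


class TestRegisterToTruth:
    def test_identity_when_aligned_equals_truth(self):
        pts = np.random.default_rng(10).normal(size=(6, 2))
        M = register_to_truth(pts, pts)
        assert np.allclose(M, [[1, 0, 0], [0, 1, 0]], atol=1e-10)

    def test_recovers_rotation_plus_shift(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 10, (20, 2))
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        truth = pts @ R.T + [5.0, -2.0]
        M = register_to_truth(pts, truth)
        assert np.abs(apply_affine(pts, M) - truth).max() < 1e-6

    def test_three_points_exact_interpolation(self):
        pts = np.array([[0.0, 0], [1.0, 0], [0.0, 1]])
        truth = np.array([[1.0, 1], [3.0, 0], [0.0, 4]])
        M = register_to_truth(pts, truth)
        assert np.abs(apply_affine(pts, M) - truth).max() < 1e-10

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0], [1.0, 1], [2.0, 2]])
        with pytest.raises(ValueError):
            register_to_truth(pts, pts)
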