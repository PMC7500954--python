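"""EMD, Hellinger, silhouette and median-difference metrics."""

import numpy as np
import pandas as pd
import pytest

from cytoruv import SampleSheet
from cytoruv.cluster import ClusterAssignment
from cytoruv.metrics import (
    delta_delta_medians,
    emd_1d,
    emd_study,
    hellinger,
    hellinger_study,
    silhouette_scores,
)

from conftest import make_cells


def brute_force_silhouette(X, labels):
    """Independent O(m^2) silhouette, straight from the definition."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    m = len(X)
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    s = np.zeros(m)
    for i in range(m):
        own = (labels == labels[i])
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(
            D[i, labels == g].mean() for g in np.unique(labels) if g != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return s


class TestEMD1D:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(0).normal(size=300)
        assert emd_1d(x, x.copy()) == 0.0

    def test_point_masses_unit_apart(self):
        # masses at 0 and 1 on 0.1 bins: CDFs differ by 1 over 10 bins
        assert emd_1d(np.zeros(50), np.ones(50)) == pytest.approx(1.0)

    def test_gaussian_mean_shift(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 20000)
        y = rng.normal(0.7, 1.0, 20000)
        # EMD between equal-variance Gaussians is |mu1 - mu2|
        assert emd_1d(x, y) == pytest.approx(0.7, abs=0.1)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=200), rng.normal(1.0, 2.0, size=200)
        assert emd_1d(x, y) == pytest.approx(emd_1d(y, x), abs=1e-12)

    def test_scales_with_bin_alignment(self):
        # values inside one shared bin are indistinguishable
        assert emd_1d(np.full(10, 0.51), np.full(10, 0.59)) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError, match="nonempty"):
            emd_1d(np.array([]), np.array([1.0]))
        with pytest.raises(ValueError, match="bin_width"):
            emd_1d(np.ones(3), np.ones(3), bin_width=0.0)


class TestHellinger:
    def test_equal_is_zero(self):
        assert hellinger([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_disjoint_is_one(self):
        assert hellinger([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_value(self):
        # H^2 = (1/2)[(sqrt(.5)-1)^2 + (sqrt(.5))^2] => H = 0.541196...
        assert hellinger([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.541196, abs=1e-6)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            h = hellinger(p, q)
            assert h == pytest.approx(hellinger(q, p), abs=1e-12)
            assert 0.0 <= h <= 1.0

    def test_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            hellinger([1.1, -0.1], [0.5, 0.5])
        with pytest.raises(ValueError, match="sum to 1"):
            hellinger([0.5, 0.4], [0.5, 0.5])
        with pytest.raises(ValueError, match="length"):
            hellinger([1.0], [0.5, 0.5])


class TestSilhouette:
    def test_hand_example(self):
        # {0, 0.2} vs {10, 10.2}: a = 0.2, b in {10, 10.2} => mean ~ 0.980
        cells = make_cells(np.array([[0.0], [0.2], [10.0], [10.2]]))
        res = silhouette_scores(cells, np.array([1, 1, 2, 2]), subsample=100)
        assert res.mean == pytest.approx(0.980, abs=1e-3)
        np.testing.assert_allclose(
            sorted(res.s_values), [0.9798, 0.9798, 0.9802, 0.9802], atol=1e-3
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 4)) + rng.integers(0, 3, 300)[:, None] * 2.0
        labels = rng.integers(0, 3, 300)
        cells = make_cells(X)
        res = silhouette_scores(cells, labels, subsample=10_000)
        expected = brute_force_silhouette(X, labels)
        np.testing.assert_allclose(np.sort(res.s_values), np.sort(expected),
                                   atol=1e-10)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 3))
        cells = make_cells(X)
        res = silhouette_scores(cells, rng.integers(0, 2, 400), subsample=10_000)
        assert abs(res.mean) < 0.05

    def test_subsampling_deterministic_and_bounded(self):
        rng = np.random.default_rng(6)
        cells = make_cells(
            rng.normal(size=(600, 3)),
            sample_id=np.repeat(["a", "b", "c"], 200),
        )
        labels = np.repeat([1, 2, 1], 200)
        r1 = silhouette_scores(cells, labels, subsample=50, seed=7)
        r2 = silhouette_scores(cells, labels, subsample=50, seed=7)
        np.testing.assert_array_equal(r1.cell_indices, r2.cell_indices)
        assert len(r1.s_values) == 150

    def test_errors(self):
        cells = make_cells(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="2 groups"):
            silhouette_scores(cells, np.ones(10))
        with pytest.raises(ValueError, match="< 2 cells"):
            silhouette_scores(cells, np.array([1] * 9 + [2]))
        with pytest.raises(ValueError, match="one label per cell"):
            silhouette_scores(cells, np.ones(5))


def _two_batch_cells(rng, shift=0.0, n=400):
    v1 = rng.normal(1.0, 0.5, size=(n, 3))
    v2 = rng.normal(1.0, 0.5, size=(n, 3)) + shift
    return make_cells(
        np.vstack([v1, v2]),
        sample_id=["P_B1"] * n + ["P_B2"] * n,
        batch=[1] * n + [2] * n,
    )


class TestDeltaDelta:
    def test_identical_tables_zero(self):
        rng = np.random.default_rng(8)
        cells = _two_batch_cells(rng)
        out = delta_delta_medians(cells, cells)
        np.testing.assert_allclose(out["delta_delta"], 0.0, atol=1e-12)

    def test_detects_removed_shift(self):
        rng = np.random.default_rng(9)
        raw = _two_batch_cells(rng, shift=0.3, n=4000)
        norm = raw.with_values(
            raw.values - 0.3 * (raw.batch == 2)[:, None]
        )
        out = delta_delta_medians(raw, norm, absolute=True)
        np.testing.assert_allclose(out["delta_raw"], 0.3, atol=0.05)
        np.testing.assert_allclose(out["delta_norm"], 0.0, atol=0.05)
        np.testing.assert_allclose(out["delta_delta"], 0.3, atol=0.05)
        np.testing.assert_allclose(out["abs_delta_delta"], 0.3, atol=0.05)

    def test_requires_exactly_two_batches(self):
        rng = np.random.default_rng(10)
        cells = make_cells(
            rng.normal(size=(30, 2)), batch=np.repeat([1, 2, 3], 10),
            sample_id=np.repeat(["a", "b", "c"], 10),
        )
        with pytest.raises(ValueError, match="exactly 2 batches"):
            delta_delta_medians(cells, cells)


class TestStudyTables:
    def _sheet(self):
        return SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["P_B1", "P_B2"],
                    "patient_id": ["P", "P"],
                    "condition": ["x", "x"],
                    "batch": [1, 2],
                    "file_path": ["", ""],
                }
            )
        )

    def test_emd_study_identical_datasets(self):
        rng = np.random.default_rng(11)
        cells = _two_batch_cells(rng, shift=0.5)
        tab = emd_study(cells, cells, self._sheet())
        raw = tab[tab.dataset == "raw"].set_index("protein")["emd"]
        norm = tab[tab.dataset == "normalized"].set_index("protein")["emd"]
        np.testing.assert_allclose(raw, norm, atol=1e-12)
        assert (raw > 0.3).all()  # the 0.5 shift is visible per protein

    def test_emd_study_by_cluster_nan_for_missing(self):
        rng = np.random.default_rng(12)
        cells = _two_batch_cells(rng, n=50)
        # cluster 2 exists only in batch 1
        meta = np.where(np.arange(100) < 10, 2, 1)
        a = ClusterAssignment(np.zeros(100, int), meta, n_meta=2)
        tab = emd_study(
            cells, None, self._sheet(), by_cluster=True, assignment_raw=a
        )
        assert tab[tab.metacluster == 2]["emd"].isna().all()
        assert tab[tab.metacluster == 1]["emd"].notna().all()

    def test_emd_study_requires_replicates(self):
        rng = np.random.default_rng(13)
        cells = _two_batch_cells(rng, n=20)
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["P_B1", "P_B2"],
                    "patient_id": ["P1", "P2"],  # different patients
                    "condition": ["x", "x"],
                    "batch": [1, 2],
                    "file_path": ["", ""],
                }
            )
        )
        with pytest.raises(ValueError, match="replicated"):
            emd_study(cells, None, sheet)

    def test_hellinger_study_hand_props(self):
        props = pd.DataFrame(
            [[0.5, 0.5], [1.0, 0.0]],
            index=["P_B1", "P_B2"],
            columns=[1, 2],
        )
        tab = hellinger_study(props, self._sheet())
        assert len(tab) == 1
        assert tab["hellinger"].iloc[0] == pytest.approx(0.541196, abs=1e-6)
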