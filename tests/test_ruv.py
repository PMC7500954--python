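"""RUV-III core: replicate maps, fitting, adjustment, percentile baseline.

The independent oracle used throughout builds the replicate structure as an
explicit membership matrix M (every singleton its own group) and computes
R = (I - M (M'M)^-1 M') Y densely, then takes a full SVD — a different
construction from the implementation's grouped means and cross-product
shortcut.
"""

import numpy as np
import pandas as pd
import pytest

from cytoruv import (
    CellTable,
    NormalizationConfig,
    adjust,
    build_replicate_map,
    fit_ruv3,
    normalize_data,
    percentile_scale_baseline,
    standardize,
)
from cytoruv.cluster import ClusterAssignment
from cytoruv.ruv import ReplicateMap

from conftest import make_cells


def dense_ruv3_oracle(Y, groups, k):
    """Projection-formula reference implementation (m x m construction)."""
    m, n = Y.shape
    group_of = np.zeros(m, int)
    for gi, idx in enumerate(groups, start=1):
        group_of[np.asarray(idx)] = gi
    # membership matrix with singletons as their own columns
    cols = []
    for gi in range(1, max(group_of) + 1):
        cols.append((group_of == gi).astype(float))
    for i in np.flatnonzero(group_of == 0):
        e = np.zeros(m)
        e[i] = 1.0
        cols.append(e)
    M = np.column_stack(cols)
    R = (np.eye(m) - M @ np.linalg.inv(M.T @ M) @ M.T) @ Y
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    alpha = s[:k, None] * Vt[:k]
    W = Y @ alpha.T @ np.linalg.inv(alpha @ alpha.T)
    return W @ alpha


def random_replicate_map(rng, m, n_groups):
    group_of = np.zeros(m, int)
    groups = []
    order = rng.permutation(m)
    pos = 0
    for gi in range(1, n_groups + 1):
        size = int(rng.integers(2, 6))
        idx = np.sort(order[pos : pos + size])
        pos += size
        group_of[idx] = gi
        groups.append(((f"ref", gi), idx))
    return ReplicateMap(group_of_cell=group_of, groups=groups)


class TestFitRUV3:
    def test_k_zero_is_identity(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(30, 5))
        M = random_replicate_map(rng, 30, 3)
        fit = fit_ruv3(Y, M, k=0)
        np.testing.assert_array_equal(adjust(Y, fit), Y)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = int(rng.integers(20, 200))
            n = int(rng.integers(3, 11))
            k = int(rng.integers(1, 4))
            Y = rng.normal(size=(m, n))
            M = random_replicate_map(rng, m, int(rng.integers(2, 6)))
            fit = fit_ruv3(Y, M, k=k)
            expected = dense_ruv3_oracle(Y, [i for _, i in M.groups], k)
            assert np.abs(fit.W @ fit.alpha - expected).max() < 1e-8

    def test_exact_removal_of_aligned_rank1_effect(self):
        # grouped cells share group means across batches; a rank-1 batch
        # component added on top must be removed to numerical precision
        rng = np.random.default_rng(3)
        m, n = 120, 8
        batch = np.repeat([1, 2], m // 2)
        group_of = np.array(([1] * 20 + [2] * 20 + [0] * 20) * 2)
        M = ReplicateMap(
            group_of_cell=group_of,
            groups=[
                (("r", g), np.flatnonzero(group_of == g)) for g in (1, 2)
            ],
        )
        Z = rng.normal(size=(m, n))
        # each group is one repeated profile, so the only within-group
        # variation is the injected batch component itself
        for _, idx in M.groups:
            Z[idx] = Z[idx[0]]
        a = rng.normal(size=n)
        w = (batch == 2).astype(float)
        Y = Z + np.outer(w, a)
        fit = fit_ruv3(Y, M, k=1)
        out = adjust(Y, fit)
        for _, idx in M.groups:
            d = out[idx][batch[idx] == 1].mean(0) - out[idx][batch[idx] == 2].mean(0)
            assert np.abs(d).max() < 1e-8

    def test_reparameterization_invariance(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(60, 6))
        M = random_replicate_map(rng, 60, 4)
        fit = fit_ruv3(Y, M, k=2)
        Q = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        alpha2 = Q @ fit.alpha
        W2 = Y @ alpha2.T @ np.linalg.inv(alpha2 @ alpha2.T)
        assert np.abs(W2 @ alpha2 - fit.W @ fit.alpha).max() < 1e-10

    def test_subtracted_norm_monotone_in_k(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(80, 7))
        M = random_replicate_map(rng, 80, 5)
        norms = [
            np.linalg.norm(fit_ruv3(Y, M, k=k).unwanted) for k in range(1, 6)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_fast_path_matches_direct_svd(self):
        rng = np.random.default_rng(7)
        n = 5
        Y = rng.normal(size=(400, n))  # m > 5n triggers the cross-product path
        M = random_replicate_map(rng, 400, 6)
        fit = fit_ruv3(Y, M, k=2)
        expected = dense_ruv3_oracle(Y, [i for _, i in M.groups], 2)
        assert np.abs(fit.W @ fit.alpha - expected).max() < 1e-8

    def test_k_capped_at_rank_with_warning(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(30, 6))
        # one group of 2: residual rank is 1
        M = ReplicateMap(
            group_of_cell=np.array([1, 1] + [0] * 28),
            groups=[(("r", 1), np.array([0, 1]))],
        )
        with pytest.warns(UserWarning, match="exceeds residual rank"):
            fit = fit_ruv3(Y, M, k=4)
        assert fit.k == 1

    def test_all_singletons_error(self):
        Y = np.random.default_rng(9).normal(size=(10, 3))
        M = ReplicateMap(group_of_cell=np.zeros(10, int), groups=[])
        with pytest.raises(ValueError, match="singleton"):
            fit_ruv3(Y, M, k=1)

    def test_k_exceeding_dimensions_errors(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(20, 4))
        M = random_replicate_map(rng, 20, 2)
        with pytest.raises(ValueError, match="exceeds"):
            fit_ruv3(Y, M, k=5)


class TestReplicateMap:
    def _assignment(self, meta, n_meta):
        meta = np.asarray(meta)
        return ClusterAssignment(np.zeros(len(meta), int), meta, n_meta)

    def _cells(self, sample_id, batch, n=3):
        m = len(sample_id)
        return make_cells(
            np.random.default_rng(0).normal(size=(m, n)), sample_id, batch
        )

    def test_group_per_patient_cluster_pair(self, two_batch_sheet):
        sheet = two_batch_sheet(n_patients=2)
        # both patients in both batches, 2 clusters each, 2 cells per cell set
        sample_id, batch, meta = [], [], []
        for b in (1, 2):
            for p in ("P1", "P2"):
                for mc in (1, 2):
                    sample_id += [f"{p}_B{b}"] * 2
                    batch += [b] * 2
                    meta += [mc] * 2
        cells = self._cells(sample_id, batch)
        config = NormalizationConfig(reference_samples=["P1", "P2"], k=1, n_meta=2)
        M = build_replicate_map(self._assignment(meta, 2), cells, sheet, config)
        assert M.n_groups == 4  # 2 patients x 2 clusters
        config1 = NormalizationConfig(
            reference_samples=["P1"], k=1, clusters_to_use=[2], n_meta=2
        )
        M1 = build_replicate_map(self._assignment(meta, 2), cells, sheet, config1)
        assert M1.n_groups == 1
        assert M1.groups[0][0] == ("P1", 2)

    def test_single_batch_cluster_kept_with_warning(self, two_batch_sheet, caplog):
        sheet = two_batch_sheet(n_patients=1)
        sample_id = ["P1_B1"] * 4 + ["P1_B2"] * 2
        batch = [1] * 4 + [2] * 2
        meta = [1, 1, 2, 2, 1, 1]  # cluster 2 only in batch 1
        cells = self._cells(sample_id, batch)
        config = NormalizationConfig(reference_samples=["P1"], k=1, n_meta=2)
        import logging

        with caplog.at_level(logging.WARNING, logger="cytoruv.ruv"):
            M = build_replicate_map(self._assignment(meta, 2), cells, sheet, config)
        assert M.n_groups == 2
        assert "single" in caplog.text

    def test_no_cross_batch_group_errors(self, two_batch_sheet):
        sheet = two_batch_sheet(n_patients=1)
        sample_id = ["P1_B1"] * 2 + ["P1_B2"] * 2
        batch = [1, 1, 2, 2]
        meta = [1, 1, 2, 2]  # clusters never shared across batches
        cells = self._cells(sample_id, batch)
        config = NormalizationConfig(reference_samples=["P1"], k=1, n_meta=2)
        with pytest.raises(ValueError, match="no shared subpopulation"):
            build_replicate_map(self._assignment(meta, 2), cells, sheet, config)

    def test_unknown_reference_fails_before_clustering(
        self, small_study, small_study_arcsinh
    ):
        config = NormalizationConfig(reference_samples=["NOBODY"], k=1)
        with pytest.raises(ValueError, match="NOBODY"):
            normalize_data(
                small_study_arcsinh, small_study.sheet, small_study.panel, config
            )


class TestNormalizeData:
    def test_null_study_replicates_stay_matched(self):
        # no injected batch effect: cross-batch replicate EMD starts at the
        # sampling-noise floor and normalization must not push it above it
        from cytoruv.synthetic import default_study, simulate_study
        from cytoruv import arcsinh_transform
        from cytoruv.metrics import emd_study

        config = default_study("two_batch_paper_like", cells_per_sample=300, seed=4)
        config.cluster_shift = None
        study = simulate_study(config)
        cells = arcsinh_transform(study.cells_raw)
        nc = NormalizationConfig(
            reference_samples=config.reference_patients, k=5, seed=4
        )
        adjusted, _, _ = normalize_data(cells, study.sheet, study.panel, nc)
        emd_raw = emd_study(cells, None, study.sheet)["emd"].median()
        emd_norm = emd_study(adjusted, None, study.sheet)["emd"].median()
        assert emd_raw < 0.12  # already at the noise floor
        assert emd_norm < emd_raw + 0.02


class TestPercentileBaseline:
    def _study(self):
        rng = np.random.default_rng(11)
        # batch 2 doubled: factor must be 0.5
        v1 = rng.uniform(0, 10, size=(500, 2))
        v2 = 2.0 * rng.uniform(0, 10, size=(500, 2))
        cells = make_cells(
            np.vstack([v1, v2]),
            sample_id=["R_B1"] * 500 + ["R_B2"] * 500,
            batch=[1] * 500 + [2] * 500,
        )
        sheet = pd.DataFrame(
            {
                "sample_id": ["R_B1", "R_B2"],
                "patient_id": ["R", "R"],
                "condition": ["x", "x"],
                "batch": [1, 2],
                "file_path": ["", ""],
            }
        )
        from cytoruv import SampleSheet

        return cells, SampleSheet(sheet)

    def test_percentiles_equalized(self):
        cells, sheet = self._study()
        out = percentile_scale_baseline(cells, sheet, ["R"], percentile=95)
        p1 = np.percentile(out.values[out.batch == 1], 95, axis=0)
        p2 = np.percentile(out.values[out.batch == 2], 95, axis=0)
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        # batch 1 anchors the target: unchanged
        np.testing.assert_array_equal(out.values[:500], cells.values[:500])

    def test_identical_batches_unchanged(self):
        cells, sheet = self._study()
        same = make_cells(
            np.vstack([cells.values[:500], cells.values[:500]]),
            sample_id=cells.sample_id,
            batch=cells.batch,
        )
        out = percentile_scale_baseline(same, sheet, ["R"])
        np.testing.assert_allclose(out.values, same.values, atol=1e-12)
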