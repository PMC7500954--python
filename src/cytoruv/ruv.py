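"""Pseudo-replicate RUV-III normalization for multi-batch CyTOF data.

Model: on the standardized arcsinh scale the expression of protein ``j`` in
cell ``i`` is

    Y_ij = X_i beta_j + W_i alpha_j + eps_ij

where ``X beta`` is the (unmodelled) biology, ``W alpha`` is a rank-k
unwanted component (batch effects) and ``eps`` is noise. The method never
estimates the biology: it estimates ``W alpha`` and subtracts it.

Cells of a replicated reference sample that land in the same cluster but
were acquired in different batches are *pseudo-replicates*: any systematic
difference between them is unwanted. The fit proceeds by (1) subtracting
each pseudo-replicate group's mean from its members to form residuals,
(2) taking alpha-hat from the top-k right singular directions of the
residual matrix, and (3) regressing every cell on alpha-hat using all
proteins as negative controls to obtain W-hat. The adjusted data are
``Y - W_hat alpha_hat``, un-standardized back to the arcsinh scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterAssignment, cluster_cells
from .data import (
    CellTable,
    PanelTable,
    SampleSheet,
    StandardizationParams,
    standardize,
    unstandardize,
)

__all__ = [
    "ReplicateMap",
    "UnwantedFit",
    "NormalizationConfig",
    "build_replicate_map",
    "fit_ruv3",
    "adjust",
    "normalize_data",
    "percentile_scale_baseline",
]

log = logging.getLogger(__name__)


@dataclass
class ReplicateMap:
    """Assignment of cells to pseudo-replicate groups.

    ``group_of_cell`` holds a 1-based group index per cell, 0 for singletons.
    ``groups`` lists ``(group_key, member_indices)`` with group_key =
    (reference patient, metacluster id).
    """

    group_of_cell: np.ndarray
    groups: list[tuple[tuple[str, int], np.ndarray]]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class NormalizationConfig:
    reference_samples: list[str]  # patient ids replicated across batches
    k: int
    clusters_to_use: list[int] | str = "all"
    n_meta: int = 20
    grid_dims: tuple[int, int] = (10, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not self.reference_samples:
            raise ValueError("at least one reference patient id is required")


@dataclass
class UnwantedFit:
    """Estimated unwanted-variation factors and the standardization used."""

    alpha: np.ndarray  # k x n
    W: np.ndarray  # m x k
    k: int
    std_params: StandardizationParams | None = None
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def unwanted(self) -> np.ndarray:
        """The fitted unwanted component W-hat @ alpha-hat (m x n)."""
        if self.k == 0:
            raise ValueError("k = 0 fit has no unwanted component")
        return self.W @ self.alpha


def build_replicate_map(
    assignment: ClusterAssignment,
    cells: CellTable,
    sheet: SampleSheet,
    config: NormalizationConfig,
) -> ReplicateMap:
    """Group reference-patient cells by (patient, metacluster) across batches.

    Groups with fewer than two cells are dropped; groups whose cells all come
    from one batch are kept but logged, since they carry no cross-batch
    signal on their own. All non-reference cells are singletons.
    """
    patient_of = sheet.patient_of_sample()
    known_patients = set(sheet.table["patient_id"])
    for ref in config.reference_samples:
        if ref not in known_patients:
            raise ValueError(f"reference patient {ref!r} not in sample sheet")
        n_b = sheet.table.loc[sheet.table["patient_id"] == ref, "batch"].nunique()
        if n_b < 2:
            raise ValueError(
                f"reference patient {ref!r} present in only {n_b} batch(es)"
            )
    if config.clusters_to_use == "all":
        used = set(range(1, assignment.n_meta + 1))
    else:
        used = set(int(c) for c in config.clusters_to_use)
        bad = used - set(range(1, assignment.n_meta + 1))
        if bad:
            raise ValueError(f"clusters_to_use contains invalid ids: {sorted(bad)}")

    cell_patient = np.asarray([patient_of[s] for s in cells.sample_id])
    group_of_cell = np.zeros(cells.n_cells, dtype=int)
    groups: list[tuple[tuple[str, int], np.ndarray]] = []
    any_multibatch = False
    for ref in config.reference_samples:
        ref_mask = cell_patient == ref
        for mc in sorted(used):
            idx = np.flatnonzero(ref_mask & (assignment.metacluster_id == mc))
            if idx.size < 2:
                continue
            n_batches = len(np.unique(cells.batch[idx]))
            if n_batches < 2:
                log.warning(
                    "pseudo-replicate group (%s, cluster %d) spans a single "
                    "batch (%d cells)",
                    ref,
                    mc,
                    idx.size,
                )
            else:
                any_multibatch = True
            groups.append(((ref, mc), idx))
            group_of_cell[idx] = len(groups)
    if not any_multibatch:
        raise ValueError(
            "no shared subpopulation across batches: every pseudo-replicate "
            "group lies within a single batch"
        )
    log.info(
        "replicate map: %d groups, sizes %s",
        len(groups),
        [int(i.size) for _, i in groups],
    )
    return ReplicateMap(group_of_cell=group_of_cell, groups=groups)


def _replicate_residuals(Y: np.ndarray, M: ReplicateMap) -> np.ndarray:
    """Residuals after removing each group's mean; singleton rows are zero."""
    R = np.zeros_like(Y)
    for _, idx in M.groups:
        block = Y[idx]
        R[idx] = block - block.mean(axis=0)
    return R


def fit_ruv3(
    Y_std: np.ndarray,
    M: ReplicateMap,
    k: int,
    std_params: StandardizationParams | None = None,
) -> UnwantedFit:
    """Estimate the rank-k unwanted component from pseudo-replicate residuals.

    alpha-hat is taken as ``diag(s_1..s_k) @ V_k^T`` from the SVD of the
    residual matrix (the scaling convention is immaterial: the product
    W-hat @ alpha-hat is invariant to any invertible reparameterization).
    W-hat is the all-protein least-squares regression of each cell's profile
    on alpha-hat. When cells vastly outnumber proteins the SVD is obtained
    from the n x n residual cross-product, which is exactly equivalent.
    """
    Y_std = np.asarray(Y_std, dtype=np.float64)
    m, n = Y_std.shape
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return UnwantedFit(
            alpha=np.zeros((0, n)), W=np.zeros((m, 0)), k=0, std_params=std_params
        )
    if k > min(m, n):
        raise ValueError(f"k = {k} exceeds min(cells, proteins) = {min(m, n)}")
    if not M.groups:
        raise ValueError("all cells are singletons: no residual information")

    R = _replicate_residuals(Y_std, M)
    if m > 5 * n:
        # fastRUV-III path: eigendecompose the n x n cross-product
        G = R.T @ R
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        s = np.sqrt(evals)
        Vt = evecs[:, order].T
    else:
        _, s, Vt = np.linalg.svd(R, full_matrices=False)

    rank = int(np.sum(s > 1e-10 * s[0])) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("residual matrix is zero: nothing to estimate")
    k_eff = k
    if k > rank:
        warnings.warn(
            f"requested k = {k} exceeds residual rank {rank}; using k = {rank}",
            stacklevel=2,
        )
        k_eff = rank

    alpha = s[:k_eff, None] * Vt[:k_eff]  # k x n
    # W-hat: regression of every cell on alpha using all proteins as controls
    gram = alpha @ alpha.T
    W = np.linalg.solve(gram, alpha @ Y_std.T).T  # m x k
    return UnwantedFit(
        alpha=alpha, W=W, k=k_eff, std_params=std_params, singular_values=s
    )


def adjust(Y_std: np.ndarray, fit: UnwantedFit) -> np.ndarray:
    """Subtract the fitted unwanted component; identity when k = 0."""
    Y_std = np.asarray(Y_std, dtype=np.float64)
    if fit.k == 0:
        return Y_std.copy()
    if fit.W.shape[0] != Y_std.shape[0] or fit.alpha.shape[1] != Y_std.shape[1]:
        raise ValueError("fit shapes do not match the data matrix")
    return Y_std - fit.W @ fit.alpha


def normalize_data(
    cells: CellTable,
    sheet: SampleSheet,
    panel: PanelTable,
    config: NormalizationConfig,
    assignment: ClusterAssignment | None = None,
) -> tuple[CellTable, UnwantedFit, ClusterAssignment]:
    """Full normalization on an arcsinh-scale cell table.

    Six steps: cluster all cells (SOM + metaclustering on lineage proteins),
    define pseudo-replicates from the reference patients, form residuals,
    estimate alpha-hat by SVD, estimate W-hat with all proteins as negative
    controls, and subtract W-hat @ alpha-hat; the result is un-standardized
    back to the arcsinh scale.
    """
    # validate references before any heavy computation
    known = set(sheet.table["patient_id"])
    bad = [r for r in config.reference_samples if r not in known]
    if bad:
        raise ValueError(f"unknown reference patient id(s): {bad}")
    if assignment is None:
        assignment, _ = cluster_cells(
            cells,
            panel.lineage_names,
            n_meta=config.n_meta,
            grid_dims=config.grid_dims,
            seed=config.seed,
        )
    M = build_replicate_map(assignment, cells, sheet, config)
    Y_std_table, std_params = standardize(cells)
    fit = fit_ruv3(Y_std_table.values, M, config.k, std_params=std_params)
    if fit.singular_values.size:
        log.info(
            "RUV-III fit: k = %d, top singular values %s",
            fit.k,
            np.round(fit.singular_values[: max(fit.k, 5)], 3),
        )
    adjusted_std = adjust(Y_std_table.values, fit)
    adjusted = unstandardize(cells.with_values(adjusted_std), std_params)
    return adjusted, fit, assignment


def percentile_scale_baseline(
    raw_cells: CellTable,
    sheet: SampleSheet,
    reference_samples: list[str],
    percentile: float = 95.0,
) -> CellTable:
    """Per-batch per-protein percentile scaling of raw intensities.

    For every protein, each batch's values are multiplied by the ratio of the
    first batch's reference-sample percentile to that batch's reference
    percentile, so reference percentiles match across batches. This is the
    whole-batch scaling baseline: one factor per (protein, batch), no
    cluster awareness.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    patient_of = sheet.patient_of_sample()
    cell_patient = np.asarray([patient_of[s] for s in raw_cells.sample_id])
    ref_mask = np.isin(cell_patient, list(reference_samples))
    if not ref_mask.any():
        raise ValueError("no cells belong to the reference samples")
    batches = np.unique(raw_cells.batch)
    target = None
    out = raw_cells.values.copy()
    ref_pct = {}
    for b in batches:
        mb = ref_mask & (raw_cells.batch == b)
        if not mb.any():
            raise ValueError(f"batch {b} has no reference-sample cells")
        ref_pct[b] = np.percentile(raw_cells.values[mb], percentile, axis=0)
    target = ref_pct[batches[0]]
    for b in batches:
        factors = np.ones_like(target)
        nz = ref_pct[b] != 0
        factors[nz] = target[nz] / ref_pct[b][nz]
        skipped = np.flatnonzero(~nz)
        if skipped.size:
            warnings.warn(
                "zero reference percentile; protein(s) left unscaled in batch "
                f"{b}: {[raw_cells.protein_names[i] for i in skipped]}",
                stacklevel=2,
            )
        rows = raw_cells.batch == b
        out[rows] = out[rows] * factors
    return raw_cells.with_values(out)
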