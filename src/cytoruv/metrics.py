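"""Evaluation metrics for batch-effect correction.

Three complementary views of whether normalization worked:

* per-protein earth mover's distance (1-D Wasserstein on binned data)
  between a replicated sample's expression distributions in two batches —
  should shrink after correction;
* Hellinger distance between a replicated sample's cluster-proportion
  vectors across batches — abundances should agree;
* silhouette scores with cells grouped by batch (``s_batch``, should drop)
  versus grouped by subpopulation (``s_biology``, should not drop).

Plus the cross-batch median-difference table used when too few replicates
exist for formal differential tests: per marker, Delta = median(batch 2) -
median(batch 1), and DeltaDelta = Delta_raw - Delta_norm, the reduction in
cross-batch shift achieved by normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .cluster import ClusterAssignment, cluster_proportions
from .data import CellTable, SampleSheet

__all__ = [
    "emd_1d",
    "emd_study",
    "hellinger",
    "hellinger_study",
    "SilhouetteResult",
    "silhouette_scores",
    "delta_delta_medians",
]


def emd_1d(x: np.ndarray, y: np.ndarray, bin_width: float = 0.1) -> float:
    """Earth mover's distance between two 1-D samples on shared bins.

    Both samples are histogrammed on a common grid of ``bin_width`` bins
    spanning the pooled range (edges aligned to multiples of ``bin_width``),
    and the distance is ``sum |CDF_x - CDF_y| * bin_width``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("emd_1d requires nonempty inputs")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    start = np.floor(lo / bin_width) * bin_width
    n_bins = max(int(np.ceil((hi - start) / bin_width)) + 1, 1)
    edges = start + bin_width * np.arange(n_bins + 1)
    px, _ = np.histogram(x, bins=edges)
    py, _ = np.histogram(y, bins=edges)
    cx = np.cumsum(px / px.sum())
    cy = np.cumsum(py / py.sum())
    return float(np.sum(np.abs(cx - cy)) * bin_width)


def _replicate_pairs(sheet: SampleSheet, patients: list[str] | None):
    """(patient, batch_a, batch_b) pairs for samples replicated across batches."""
    tab = sheet.table
    out = []
    for patient, sub in tab.groupby("patient_id", sort=True):
        if patients is not None and patient not in patients:
            continue
        bs = sorted(sub["batch"].unique())
        if len(bs) < 2:
            continue
        for i in range(len(bs)):
            for j in range(i + 1, len(bs)):
                out.append((patient, bs[i], bs[j]))
    return out


def emd_study(
    study_raw: CellTable,
    study_norm: CellTable | None,
    sheet: SampleSheet,
    bin_width: float = 0.1,
    by_cluster: bool = False,
    assignment_raw: ClusterAssignment | None = None,
    assignment_norm: ClusterAssignment | None = None,
    patients: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-batch per-protein EMD for every replicated sample.

    Returns a tidy frame with one row per (dataset, patient, batch pair,
    protein [, metacluster]). With ``by_cluster`` the EMD is computed within
    each metacluster; clusters empty in either batch yield NaN entries, not
    zeros, so summaries are not biased toward agreement.
    """
    pairs = _replicate_pairs(sheet, patients)
    if not pairs:
        raise ValueError("no sample is replicated across batches")
    patient_of = sheet.patient_of_sample()
    datasets = [("raw", study_raw, assignment_raw)]
    if study_norm is not None:
        datasets.append(("normalized", study_norm, assignment_norm))

    rows = []
    for tag, cells, assignment in datasets:
        if by_cluster and assignment is None:
            raise ValueError(f"by_cluster requires a cluster assignment ({tag})")
        cell_patient = np.asarray([patient_of[s] for s in cells.sample_id])
        for patient, b1, b2 in pairs:
            m1 = (cell_patient == patient) & (cells.batch == b1)
            m2 = (cell_patient == patient) & (cells.batch == b2)
            if not (m1.any() and m2.any()):
                continue
            clusters = (
                range(1, assignment.n_meta + 1) if by_cluster else [None]
            )
            for mc in clusters:
                if mc is None:
                    s1, s2 = m1, m2
                else:
                    in_mc = assignment.metacluster_id == mc
                    s1, s2 = m1 & in_mc, m2 & in_mc
                for jp, prot in enumerate(cells.protein_names):
                    if s1.any() and s2.any():
                        d = emd_1d(
                            cells.values[s1, jp],
                            cells.values[s2, jp],
                            bin_width=bin_width,
                        )
                    else:
                        d = np.nan
                    rows.append(
                        {
                            "dataset": tag,
                            "patient_id": patient,
                            "batch_a": b1,
                            "batch_b": b2,
                            "protein": prot,
                            "metacluster": mc,
                            "emd": d,
                        }
                    )
    df = pd.DataFrame(rows)
    if not by_cluster:
        df = df.drop(columns="metacluster")
    return df


def hellinger(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger distance between two probability vectors, in [0, 1].

    H(p, q)^2 = (1/2) sum_i (sqrt(p_i) - sqrt(q_i))^2. Zero iff p = q,
    one iff the supports are disjoint.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be nonnegative")
    if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
        raise ValueError("probability vectors must sum to 1")
    h2 = 0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)
    return float(np.sqrt(min(max(h2, 0.0), 1.0)))


def hellinger_study(
    proportions: pd.DataFrame,
    sheet: SampleSheet,
    patients: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-batch Hellinger distance between per-sample cluster proportions.

    ``proportions`` is the samples x metaclusters frame from
    :func:`cytoruv.cluster.cluster_proportions`.
    """
    patient_of = sheet.patient_of_sample()
    batch_of = sheet.batch_of_sample()
    sample_of = {
        (patient_of[s], batch_of[s]): s for s in sheet.sample_ids
    }
    rows = []
    for patient, b1, b2 in _replicate_pairs(sheet, patients):
        s1, s2 = sample_of[(patient, b1)], sample_of[(patient, b2)]
        if s1 not in proportions.index or s2 not in proportions.index:
            continue
        rows.append(
            {
                "patient_id": patient,
                "batch_a": b1,
                "batch_b": b2,
                "hellinger": hellinger(
                    proportions.loc[s1].to_numpy(), proportions.loc[s2].to_numpy()
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SilhouetteResult:
    s_values: np.ndarray  # per subsampled cell
    mean: float
    cell_indices: np.ndarray  # indices into the original table


def silhouette_scores(
    cells: CellTable,
    grouping: np.ndarray,
    subsample: int = 100,
    seed: int = 0,
) -> SilhouetteResult:
    """Mean silhouette of cells under a grouping (batch or subpopulation).

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean Euclidean distance
    (over all panel proteins, arcsinh scale) to the cell's own group and b_i
    the minimum mean distance to any other group. ``subsample`` cells are
    drawn per sample with a fixed seed to keep the O(m^2) distance matrix
    tractable; pass a large value for exact computation.
    """
    grouping = np.asarray(grouping)
    if len(grouping) != cells.n_cells:
        raise ValueError("grouping must have one label per cell")
    rng = np.random.default_rng(seed)
    keep = []
    for sid in pd.unique(cells.sample_id):
        idx = np.flatnonzero(cells.sample_id == sid)
        if idx.size > subsample:
            idx = rng.choice(idx, size=subsample, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    labels = grouping[keep]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValueError(
            f"group(s) {list(small)} have < 2 cells after subsampling; "
            "increase the subsample size"
        )
    s = silhouette_samples(cells.values[keep], labels, metric="euclidean")
    return SilhouetteResult(s_values=s, mean=float(s.mean()), cell_indices=keep)


def delta_delta_medians(
    study_raw: CellTable,
    study_norm: CellTable,
    mask_raw: np.ndarray | None = None,
    mask_norm: np.ndarray | None = None,
    absolute: bool = False,
) -> pd.DataFrame:
    """Cross-batch median-difference table for a two-batch design.

    Per marker m: M_{m,b} = median over all (optionally cluster-filtered)
    cells in batch b; Delta = M_{m,2} - M_{m,1}; DeltaDelta = Delta_raw -
    Delta_norm. ``absolute`` additionally reports |Delta_raw| - |Delta_norm|,
    a variant that reads directly as shift reduction.
    """
    if study_raw.protein_names != study_norm.protein_names:
        raise ValueError("raw and normalized tables must share proteins")

    def _medians(cells: CellTable, mask):
        sub = cells if mask is None else cells.subset(np.asarray(mask))
        bs = np.unique(sub.batch)
        if len(bs) != 2:
            raise ValueError(
                f"the median-difference statistic needs exactly 2 batches, "
                f"found {len(bs)}"
            )
        m1 = np.median(sub.values[sub.batch == bs[0]], axis=0)
        m2 = np.median(sub.values[sub.batch == bs[1]], axis=0)
        return bs, m1, m2

    bs, r1, r2 = _medians(study_raw, mask_raw)
    _, n1, n2 = _medians(study_norm, mask_norm)
    d_raw = r2 - r1
    d_norm = n2 - n1
    out = pd.DataFrame(
        {
            "marker": study_raw.protein_names,
            f"median_raw_b{bs[0]}": r1,
            f"median_raw_b{bs[1]}": r2,
            "delta_raw": d_raw,
            "delta_norm": d_norm,
            "delta_delta": d_raw - d_norm,
        }
    ).set_index("marker")
    if absolute:
        out["abs_delta_delta"] = np.abs(d_raw) - np.abs(d_norm)
    return out


def batch_biology_silhouettes(
    cells: CellTable,
    assignment: ClusterAssignment,
    subsample: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Convenience: s_batch and s_biology for one dataset."""
    s_bio = silhouette_scores(
        cells, assignment.metacluster_id, subsample=subsample, seed=seed
    )
    s_bat = silhouette_scores(cells, cells.batch, subsample=subsample, seed=seed)
    return {"s_biology": s_bio.mean, "s_batch": s_bat.mean}


def proportions_for(
    cells: CellTable, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Alias re-export so metric consumers need only this module."""
    return cluster_proportions(assignment, cells)
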