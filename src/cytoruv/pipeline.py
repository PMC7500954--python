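"""End-to-end orchestration: cluster, normalize, evaluate, report.

Ties the pieces together the way an analyst runs them: load (or simulate) a
study, arcsinh-transform, cluster, normalize for one or several values of k,
then compute the evaluation metrics and diagnostic bundles for the raw and
each normalized dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, cluster_cells, cluster_proportions
from .data import CellTable, PanelTable, SampleSheet, arcsinh_transform, load_study
from .diagnostics import DiagnosticBundle, compute_bundle, render_report
from .metrics import (
    batch_biology_silhouettes,
    delta_delta_medians,
    emd_study,
    hellinger_study,
)
from .ruv import NormalizationConfig, normalize_data

__all__ = ["EvaluationResult", "evaluate_pair", "run_pipeline", "load_arcsinh_study"]

log = logging.getLogger(__name__)


def load_arcsinh_study(
    sample_sheet_path: str | Path, panel_path: str | Path, cofactor: float = 5.0
) -> tuple[CellTable, SampleSheet, PanelTable]:
    """Read a study from disk and move it onto the arcsinh scale."""
    sheet = SampleSheet.from_csv(sample_sheet_path)
    panel = PanelTable.from_csv(panel_path)
    raw = load_study(sheet, panel)
    return arcsinh_transform(raw, cofactor=cofactor), sheet, panel


@dataclass
class EvaluationResult:
    emd: pd.DataFrame
    hellinger: pd.DataFrame
    silhouettes: pd.DataFrame  # dataset x (s_batch, s_biology)
    summary: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "emd": self.emd,
            "hellinger": self.hellinger,
            "silhouettes": self.silhouettes,
        }


def evaluate_pair(
    cells_raw: CellTable,
    cells_norm: CellTable | None,
    sheet: SampleSheet,
    assignment_raw: ClusterAssignment,
    assignment_norm: ClusterAssignment | None,
    patients: list[str] | None = None,
    bin_width: float = 0.1,
    silhouette_subsample: int = 100,
    seed: int = 0,
) -> EvaluationResult:
    """Compute EMD, Hellinger and silhouette metrics for raw vs normalized.

    Each dataset is scored with its own cluster assignment, as it would be
    analysed in isolation. ``patients`` restricts the replicate pairings
    (e.g. to reference patients only); the default uses every replicated
    patient.
    """
    emd = emd_study(
        cells_raw, cells_norm, sheet, bin_width=bin_width, patients=patients
    )
    hel_frames = []
    sil_rows = []
    for tag, cells, assignment in [
        ("raw", cells_raw, assignment_raw),
        ("normalized", cells_norm, assignment_norm),
    ]:
        if cells is None:
            continue
        props = cluster_proportions(assignment, cells)
        h = hellinger_study(props, sheet, patients=patients)
        h.insert(0, "dataset", tag)
        hel_frames.append(h)
        sil = batch_biology_silhouettes(
            cells, assignment, subsample=silhouette_subsample, seed=seed
        )
        sil_rows.append({"dataset": tag, **sil})
    hel = pd.concat(hel_frames, ignore_index=True)
    sils = pd.DataFrame(sil_rows).set_index("dataset")

    summary: dict = {}
    for tag in sils.index:
        med_emd = emd.loc[emd["dataset"] == tag, "emd"].median()
        summary[f"median_emd_{tag}"] = float(med_emd)
        summary[f"mean_hellinger_{tag}"] = float(
            hel.loc[hel["dataset"] == tag, "hellinger"].mean()
        )
        summary[f"s_batch_{tag}"] = float(sils.loc[tag, "s_batch"])
        summary[f"s_biology_{tag}"] = float(sils.loc[tag, "s_biology"])
    return EvaluationResult(emd=emd, hellinger=hel, silhouettes=sils, summary=summary)


def run_pipeline(
    cells_arcsinh: CellTable,
    sheet: SampleSheet,
    panel: PanelTable,
    reference_samples: list[str],
    ks: list[int],
    out_dir: str | Path | None = None,
    clusters_to_use: list[int] | str = "all",
    n_meta: int = 20,
    grid_dims: tuple[int, int] = (10, 10),
    seed: int = 0,
    silhouette_subsample: int = 100,
    embed_per_sample: int = 0,
    delta_table: bool = True,
) -> dict:
    """Normalize for every k in ``ks`` and evaluate each result.

    Returns a dict with the raw assignment and, per k, the adjusted table,
    its assignment, the evaluation result and (if ``out_dir``) the rendered
    report path. ``embed_per_sample`` = 0 skips the t-SNE view (the costly
    display-only step).
    """
    assignment_raw, _ = cluster_cells(
        cells_arcsinh,
        panel.lineage_names,
        n_meta=n_meta,
        grid_dims=grid_dims,
        seed=seed,
    )
    with_embed = embed_per_sample > 0
    out: dict = {"assignment_raw": assignment_raw, "per_k": {}}
    bundle_raw: DiagnosticBundle | None = None
    for k in ks:
        config = NormalizationConfig(
            reference_samples=list(reference_samples),
            k=int(k),
            clusters_to_use=clusters_to_use,
            n_meta=n_meta,
            grid_dims=grid_dims,
            seed=seed,
        )
        adjusted, fit, _ = normalize_data(
            cells_arcsinh, sheet, panel, config, assignment=assignment_raw
        )
        assignment_norm, _ = cluster_cells(
            adjusted, panel.lineage_names, n_meta=n_meta, grid_dims=grid_dims,
            seed=seed,
        )
        result = evaluate_pair(
            cells_arcsinh,
            adjusted,
            sheet,
            assignment_raw,
            assignment_norm,
            silhouette_subsample=silhouette_subsample,
            seed=seed,
        )
        entry = {
            "adjusted": adjusted,
            "fit": fit,
            "assignment": assignment_norm,
            "evaluation": result,
        }
        if delta_table and len(sheet.batches) == 2:
            entry["delta_delta"] = delta_delta_medians(cells_arcsinh, adjusted)
        if out_dir is not None:
            kdir = Path(out_dir) / f"k_{k}"
            if bundle_raw is None:
                bundle_raw = compute_bundle(
                    cells_arcsinh,
                    assignment_raw,
                    panel.lineage_names,
                    tag="raw",
                    seed=seed,
                    embed_per_sample=embed_per_sample or 2000,
                    with_embedding=with_embed,
                )
            bundle_norm = compute_bundle(
                adjusted,
                assignment_norm,
                panel.lineage_names,
                tag="normalized",
                seed=seed,
                embed_per_sample=embed_per_sample or 2000,
                with_embedding=with_embed,
            )
            tables = result.tables()
            if "delta_delta" in entry:
                tables = {**tables, "delta_delta": entry["delta_delta"]}
            entry["report"] = render_report(
                bundle_raw,
                bundle_norm,
                kdir,
                metric_tables=tables,
                title=f"Batch-effect diagnostics (k = {k})",
            )
            with open(kdir / "summary.json", "w") as fh:
                json.dump(result.summary, fh, indent=2)
        out["per_k"][int(k)] = entry
        log.info("k = %d: %s", k, result.summary)
    return out
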