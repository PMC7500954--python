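"""Diagnostic computations and static report rendering.

Four diagnostic views expose batch effects before and after normalization:

1. median protein expression per sample — classical MDS map plus a
   hierarchically ordered heatmap;
2. per-sample per-protein expression distributions;
3. clustering results — a nonlinear 2-D embedding of subsampled cells and a
   linear-discriminant view of selected clusters colored by batch;
4. per-sample cluster proportions.

All quantities are computed on the arcsinh scale. The report is a static
HTML page with embedded images; every underlying table is exported as CSV
next to it.
"""

from __future__ import annotations

import base64
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .cluster import ClusterAssignment, cluster_proportions
from .data import CellTable

__all__ = [
    "median_expression",
    "mds_coordinates",
    "hierarchical_order",
    "embed_cells",
    "lda_projection",
    "DiagnosticBundle",
    "compute_bundle",
    "render_report",
]

log = logging.getLogger(__name__)


def median_expression(cells: CellTable) -> pd.DataFrame:
    """Per-sample median of every protein over all cells (samples x proteins).

    Even cell counts use the mean-of-the-two-middle-values convention.
    """
    sids = pd.unique(cells.sample_id)
    rows = []
    for sid in sids:
        mask = cells.sample_id == sid
        if not mask.any():
            raise ValueError(f"sample {sid} has no cells")
        rows.append(np.median(cells.values[mask], axis=0))
    return pd.DataFrame(rows, index=pd.Index(sids, name="sample_id"),
                        columns=cells.protein_names)


def mds_coordinates(medians: pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples from median-expression profiles.

    Double-centers the squared Euclidean distance matrix and returns the top
    two eigen-coordinates; exact (up to rigid motion) for configurations of
    intrinsic dimension <= 2.
    """
    if medians.shape[0] < 3:
        raise ValueError("MDS needs at least 3 samples")
    D2 = squareform(pdist(medians.to_numpy(), metric="sqeuclidean"))
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    lam = np.clip(evals[order[:2]], 0.0, None)
    coords = evecs[:, order[:2]] * np.sqrt(lam)
    return pd.DataFrame(coords, index=medians.index, columns=["MDS1", "MDS2"])


def hierarchical_order(medians: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage dendrogram leaf orders for samples (rows) and
    proteins (columns) of a median-expression matrix."""
    if medians.shape[0] < 2:
        raise ValueError("hierarchical ordering needs at least 2 samples")
    row_order = leaves_list(linkage(medians.to_numpy(), method="average"))
    col_order = leaves_list(linkage(medians.to_numpy().T, method="average"))
    return row_order, col_order


def embed_cells(
    cells: CellTable,
    lineage_names: list[str],
    per_sample: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """t-SNE embedding of a per-sample subsample on lineage proteins.

    Returns a frame with the original cell indices, sample/batch labels and
    the two embedding coordinates. Display only: embedding coordinates are
    never used in any metric.
    """
    from sklearn.manifold import TSNE

    if per_sample < 10:
        raise ValueError("per_sample must be at least 10")
    rng = np.random.default_rng(seed)
    keep = []
    for sid in pd.unique(cells.sample_id):
        idx = np.flatnonzero(cells.sample_id == sid)
        if idx.size > per_sample:
            idx = rng.choice(idx, size=per_sample, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    X = cells.values[np.ix_(keep, cells.column_index(list(lineage_names)))]
    perplexity = min(30.0, max(5.0, (len(keep) - 1) / 4))
    emb = TSNE(
        n_components=2, random_state=seed, init="pca", perplexity=perplexity
    ).fit_transform(X)
    return pd.DataFrame(
        {
            "cell_index": keep,
            "sample_id": cells.sample_id[keep],
            "batch": cells.batch[keep],
            "dim1": emb[:, 0],
            "dim2": emb[:, 1],
        }
    )


def lda_projection(
    cells: CellTable,
    labels: np.ndarray,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fisher linear-discriminant coordinates of cells on all panel proteins.

    With two label classes the discriminant space is one-dimensional; a
    second display axis is added from the top principal direction of the
    within-class residual. Singular within-class scatter is handled by
    shrinkage regularization (with a log note).
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask)
        X = cells.values[cell_mask]
        y = labels[cell_mask]
        idx = np.flatnonzero(cell_mask)
    else:
        X = cells.values
        y = labels
        idx = np.arange(cells.n_cells)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("LDA needs >= 2 classes with >= 2 cells each")
    n_comp = min(len(classes) - 1, X.shape[1], 2)
    try:
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_comp)
        Z = lda.fit_transform(X, y)
    except np.linalg.LinAlgError:
        log.warning("singular within-class scatter; using shrinkage LDA")
        lda = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage="auto", n_components=n_comp
        )
        Z = lda.fit_transform(X, y)
    if Z.shape[1] < 2:
        # pad with the leading residual-variance direction for 2-D display:
        # regress the LD1 scores out of every feature, then take PC1
        Xc = X - X.mean(axis=0)
        z = Z[:, 0] - Z[:, 0].mean()
        resid = Xc - np.outer(z, (z @ Xc) / (z @ z))
        pc = PCA(n_components=1, random_state=0).fit_transform(resid)
        Z = np.column_stack([Z[:, 0], pc[:, 0]])
    return pd.DataFrame(
        {
            "cell_index": idx,
            "label": y,
            "LD1": Z[:, 0],
            "LD2": Z[:, 1],
        }
    )


@dataclass
class DiagnosticBundle:
    """All computed inputs of the four diagnostic plot classes, one dataset."""

    tag: str  # "raw" or "normalized"
    medians: pd.DataFrame
    mds: pd.DataFrame
    row_order: np.ndarray
    col_order: np.ndarray
    densities: pd.DataFrame  # tidy: sample_id, protein, bin_center, density
    embedding: pd.DataFrame | None
    lda: pd.DataFrame | None
    proportions: pd.DataFrame
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _density_tables(cells: CellTable, bin_width: float = 0.1) -> pd.DataFrame:
    lo = float(cells.values.min())
    hi = float(cells.values.max())
    start = np.floor(lo / bin_width) * bin_width
    edges = start + bin_width * np.arange(
        int(np.ceil((hi - start) / bin_width)) + 2
    )
    centers = (edges[:-1] + edges[1:]) / 2
    rows = []
    for sid in pd.unique(cells.sample_id):
        mask = cells.sample_id == sid
        for j, prot in enumerate(cells.protein_names):
            dens, _ = np.histogram(cells.values[mask, j], bins=edges, density=True)
            nz = dens > 0
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "protein": prot,
                        "bin_center": centers[nz],
                        "density": dens[nz],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def compute_bundle(
    cells: CellTable,
    assignment: ClusterAssignment,
    lineage_names: list[str],
    tag: str,
    seed: int = 0,
    embed_per_sample: int = 2000,
    with_embedding: bool = True,
    lda_clusters: list[int] | None = None,
) -> DiagnosticBundle:
    """Compute all four diagnostic classes for one dataset."""
    med = median_expression(cells)
    mds = mds_coordinates(med)
    row_order, col_order = hierarchical_order(med)
    dens = _density_tables(cells)
    props = cluster_proportions(assignment, cells)
    emb = None
    if with_embedding:
        emb = embed_cells(cells, lineage_names, per_sample=embed_per_sample,
                          seed=seed)
        emb["metacluster"] = assignment.metacluster_id[emb["cell_index"]]
    lda = None
    if lda_clusters:
        mask = np.isin(assignment.metacluster_id, lda_clusters)
        if mask.sum() >= 4 and len(np.unique(cells.batch[mask])) >= 2:
            lda = lda_projection(cells, cells.batch, cell_mask=mask)
            lda["metacluster"] = assignment.metacluster_id[lda["cell_index"]]
    return DiagnosticBundle(
        tag=tag,
        medians=med,
        mds=mds,
        row_order=row_order,
        col_order=col_order,
        densities=dens,
        embedding=emb,
        lda=lda,
        proportions=props,
        seed=seed,
    )


def _fig_to_base64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _plot_bundle(bundle: DiagnosticBundle) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    images: dict[str, str] = {}

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(bundle.mds["MDS1"], bundle.mds["MDS2"], c="tab:blue")
    for sid, row in bundle.mds.iterrows():
        ax.annotate(str(sid), (row["MDS1"], row["MDS2"]), fontsize=6)
    ax.set_xlabel("MDS1")
    ax.set_ylabel("MDS2")
    ax.set_title(f"Median expression MDS ({bundle.tag})")
    images["mds"] = _fig_to_base64(fig)

    med = bundle.medians.iloc[bundle.row_order, bundle.col_order]
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(med.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(med.index)), med.index, fontsize=5)
    ax.set_xticks(range(len(med.columns)), med.columns, fontsize=5, rotation=90)
    fig.colorbar(im, ax=ax, label="median arcsinh expression")
    ax.set_title(f"Median expression heatmap ({bundle.tag})")
    images["heatmap"] = _fig_to_base64(fig)

    some = bundle.densities["protein"].unique()[:6]
    fig, axes = plt.subplots(2, 3, figsize=(9, 4), sharey=False)
    for ax, prot in zip(axes.ravel(), some):
        sub = bundle.densities[bundle.densities["protein"] == prot]
        for sid, ss in sub.groupby("sample_id"):
            ax.plot(ss["bin_center"], ss["density"], lw=0.5)
        ax.set_title(str(prot), fontsize=7)
    fig.suptitle(f"Expression distributions ({bundle.tag})")
    images["densities"] = _fig_to_base64(fig)

    if bundle.embedding is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, color_by in zip(axes, ["metacluster", "batch"]):
            sc = ax.scatter(
                bundle.embedding["dim1"],
                bundle.embedding["dim2"],
                c=bundle.embedding[color_by],
                s=2,
                cmap="tab20",
            )
            ax.set_title(f"embedding by {color_by}")
        fig.suptitle(f"Clustering embedding ({bundle.tag})")
        images["embedding"] = _fig_to_base64(fig)

    if bundle.lda is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, sub in bundle.lda.groupby("label"):
            ax.scatter(sub["LD1"], sub["LD2"], s=3, label=f"batch {lab}")
        ax.legend()
        ax.set_title(f"LDA of selected clusters by batch ({bundle.tag})")
        images["lda"] = _fig_to_base64(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    bundle.proportions.plot(kind="bar", stacked=True, ax=ax, legend=False,
                            colormap="tab20")
    ax.set_ylabel("cluster proportion")
    ax.tick_params(axis="x", labelsize=6)
    ax.set_title(f"Cluster proportions ({bundle.tag})")
    images["proportions"] = _fig_to_base64(fig)
    return images


def render_report(
    bundle_raw: DiagnosticBundle,
    bundle_norm: DiagnosticBundle | None,
    out_dir: str | Path,
    metric_tables: dict[str, pd.DataFrame] | None = None,
    title: str = "Batch-effect diagnostics",
) -> Path:
    """Write a static HTML report plus CSV exports of every table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles = [bundle_raw] + ([bundle_norm] if bundle_norm is not None else [])
    if bundle_norm is not None and list(bundle_raw.medians.columns) != list(
        bundle_norm.medians.columns
    ):
        raise ValueError("raw and normalized bundles come from different studies")

    for b in bundles:
        b.medians.to_csv(out_dir / f"medians_{b.tag}.csv")
        b.mds.to_csv(out_dir / f"mds_{b.tag}.csv")
        b.densities.to_csv(out_dir / f"densities_{b.tag}.csv", index=False)
        b.proportions.to_csv(out_dir / f"proportions_{b.tag}.csv")
        if b.embedding is not None:
            b.embedding.to_csv(out_dir / f"embedding_{b.tag}.csv", index=False)
        if b.lda is not None:
            b.lda.to_csv(out_dir / f"lda_{b.tag}.csv", index=False)
    if metric_tables:
        for name, tab in metric_tables.items():
            tab.to_csv(out_dir / f"metric_{name}.csv")

    parts = [
        "<html><head><meta charset='utf-8'>"
        f"<title>{title}</title></head><body>",
        f"<h1>{title}</h1>",
    ]
    section_names = {
        "mds": "Median protein expression — MDS",
        "heatmap": "Median protein expression — heatmap",
        "densities": "Protein expression distributions",
        "embedding": "Clustering results — embedding",
        "lda": "Clustering results — LDA",
        "proportions": "Cluster proportions",
    }
    imgs = {b.tag: _plot_bundle(b) for b in bundles}
    for key, label in section_names.items():
        blocks = [
            f"<div style='display:inline-block'><h3>{tag}</h3>"
            f"<img src='data:image/png;base64,{img[key]}'/></div>"
            for tag, img in imgs.items()
            if key in img
        ]
        if blocks:
            parts.append(f"<h2>{label}</h2>" + "".join(blocks))
    if metric_tables:
        parts.append("<h2>Metric summaries</h2>")
        for name, tab in metric_tables.items():
            parts.append(f"<h3>{name}</h3>" + tab.to_html(border=0))
    parts.append("</body></html>")
    path = out_dir / "report.html"
    path.write_text("\n".join(parts))
    return path
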