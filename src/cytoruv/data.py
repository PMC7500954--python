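"""Core study containers and transforms.

A multi-batch CyTOF study is described by three objects: a :class:`PanelTable`
(which antibody channels exist and whether each is a lineage or functional
marker), a :class:`SampleSheet` (one row per barcoded sample: patient,
condition, batch, FCS file), and a :class:`CellTable` holding the pooled
cells x proteins expression matrix with per-cell sample and batch labels.

Expression values move between three scales: raw ion counts as stored in FCS
files, the variance-stabilized arcsinh scale ``asinh(x / 5)`` on which all
modelling happens, and a standardized scale (zero mean, unit sd per protein)
used only inside the RUV-III fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import read_fcs, write_fcs

__all__ = [
    "PanelTable",
    "SampleSheet",
    "CellTable",
    "StandardizationParams",
    "load_study",
    "arcsinh_transform",
    "inverse_arcsinh_transform",
    "standardize",
    "unstandardize",
    "write_adjusted_fcs",
]

log = logging.getLogger(__name__)

PANEL_COLUMNS = ("metal", "antigen", "class")
SHEET_COLUMNS = ("sample_id", "patient_id", "condition", "batch", "file_path")
PANEL_CLASSES = {"lineage", "functional", "none"}


@dataclass(frozen=True)
class PanelTable:
    """Antibody panel: metal isotope, antigen name and marker class per channel."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PANEL_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"panel sheet missing columns: {sorted(missing)}")
        bad = set(self.table["class"]) - PANEL_CLASSES
        if bad:
            raise ValueError(f"unknown panel class values: {sorted(bad)}")
        if self.table["antigen"].duplicated().any():
            dup = self.table.loc[self.table["antigen"].duplicated(), "antigen"]
            raise ValueError(f"duplicate antigen names in panel: {list(dup)}")
        if not (self.table["class"] == "lineage").any():
            raise ValueError("panel must contain at least one lineage protein")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PanelTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def antigens(self) -> list[str]:
        return list(self.table["antigen"])

    @property
    def metals(self) -> list[str]:
        return list(self.table["metal"])

    @property
    def lineage_names(self) -> list[str]:
        return list(self.table.loc[self.table["class"] == "lineage", "antigen"])

    @property
    def functional_names(self) -> list[str]:
        return list(self.table.loc[self.table["class"] == "functional", "antigen"])


@dataclass(frozen=True)
class SampleSheet:
    """Study design: one row per acquired (barcoded) sample."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SHEET_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {list(dup)}")
        object.__setattr__(
            self,
            "table",
            self.table.assign(batch=self.table["batch"].astype(int)),
        )
        if (self.table["batch"] < 1).any():
            raise ValueError("batch numbers must be >= 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, dtype={"sample_id": str, "patient_id": str}))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def batches(self) -> list[int]:
        return sorted(self.table["batch"].unique())

    def patient_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["patient_id"]))

    def batch_of_sample(self) -> dict[str, int]:
        return dict(zip(self.table["sample_id"], self.table["batch"]))

    def replicated_patients(self) -> list[str]:
        """Patients acquired in more than one batch (candidate references)."""
        g = self.table.groupby("patient_id")["batch"].nunique()
        return sorted(g.index[g >= 2])


@dataclass
class CellTable:
    """Pooled cells x proteins matrix with per-cell sample and batch labels."""

    values: np.ndarray
    sample_id: np.ndarray  # per-cell sample label (object/str)
    batch: np.ndarray  # per-cell batch (int)
    protein_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_id = np.asarray(self.sample_id)
        self.batch = np.asarray(self.batch, dtype=int)
        m, n = self.values.shape
        if len(self.sample_id) != m or len(self.batch) != m:
            raise ValueError("per-cell labels must match number of rows")
        if len(self.protein_names) != n:
            raise ValueError("protein_names must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cell table contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: list[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.protein_names)}
        missing = [x for x in names if x not in pos]
        if missing:
            raise KeyError(f"unknown protein name(s): {missing}")
        return np.asarray([pos[x] for x in names], dtype=int)

    def with_values(self, values: np.ndarray) -> "CellTable":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    def subset(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        return CellTable(
            self.values[mask],
            self.sample_id[mask],
            self.batch[mask],
            list(self.protein_names),
        )

    def sample_mask(self, sample_ids: list[str] | set[str]) -> np.ndarray:
        wanted = set(sample_ids)
        return np.asarray([s in wanted for s in self.sample_id])


@dataclass(frozen=True)
class StandardizationParams:
    """Per-protein mean and sample standard deviation (ddof=1) across all cells."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("standard deviations must be positive")


def _match_channels(fcs, panel: PanelTable, path: str) -> np.ndarray:
    """Column index of each panel antigen in an FCS file.

    Antigens are matched first against $PnS (stain labels), then $PnN.
    """
    by_label = {}
    for i, lab in enumerate(fcs.channel_labels):
        by_label.setdefault(lab, i)
    by_name = {}
    for i, nm in enumerate(fcs.channel_names):
        by_name.setdefault(nm, i)
    cols = []
    for antigen in panel.antigens:
        if antigen in by_label:
            cols.append(by_label[antigen])
        elif antigen in by_name:
            cols.append(by_name[antigen])
        else:
            raise ValueError(
                f"channel for antigen {antigen!r} not found in file {path}"
            )
    return np.asarray(cols, dtype=int)


def load_study(sheet: SampleSheet, panel: PanelTable) -> CellTable:
    """Read every FCS file in the sample sheet into one raw-intensity table.

    Cells are ordered by sample-sheet row, then by within-file event order.
    Channels are restricted to, and ordered as, the panel antigens.
    """
    blocks, samples, batches = [], [], []
    for row in sheet.table.itertuples(index=False):
        path = str(row.file_path)
        fcs = read_fcs(path)
        if fcs.n_events == 0:
            raise ValueError(f"FCS file {path} contains no events")
        cols = _match_channels(fcs, panel, path)
        blocks.append(fcs.data[:, cols])
        samples.append(np.full(fcs.n_events, row.sample_id, dtype=object))
        batches.append(np.full(fcs.n_events, int(row.batch), dtype=int))
        log.info("loaded %s: %d events", row.sample_id, fcs.n_events)
    return CellTable(
        np.vstack(blocks),
        np.concatenate(samples),
        np.concatenate(batches),
        panel.antigens,
    )


def arcsinh_transform(cells: CellTable, cofactor: float = 5.0) -> CellTable:
    """Apply the cytometry variance-stabilizing transform asinh(x / cofactor)."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return cells.with_values(np.arcsinh(cells.values / cofactor))


def inverse_arcsinh_transform(cells: CellTable, cofactor: float = 5.0) -> CellTable:
    """Map arcsinh-scale values back to the raw intensity scale."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return cells.with_values(np.sinh(cells.values) * cofactor)


def standardize(cells: CellTable) -> tuple[CellTable, StandardizationParams]:
    """Center and scale each protein to zero mean and unit sd across all cells."""
    if cells.n_cells < 2:
        raise ValueError("standardization needs at least 2 cells")
    mean = cells.values.mean(axis=0)
    sd = cells.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [cells.protein_names[i] for i in zero]
        raise ValueError(f"constant protein column(s), sd = 0: {names}")
    params = StandardizationParams(mean=mean, sd=sd)
    return cells.with_values((cells.values - mean) / sd), params


def unstandardize(cells: CellTable, params: StandardizationParams) -> CellTable:
    """Exact inverse of :func:`standardize`."""
    return cells.with_values(cells.values * params.sd + params.mean)


def write_adjusted_fcs(
    cells: CellTable,
    out_dir: str | Path,
    back_transform: bool = True,
    cofactor: float = 5.0,
    panel: PanelTable | None = None,
) -> list[Path]:
    """Write one FCS 3.1 file per sample.

    With ``back_transform`` the arcsinh-scale values are mapped back to the
    raw scale (``cofactor * sinh(v)``) so downstream cytometry tools see
    intensities; otherwise arcsinh-scale values are stored as-is.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = cells.protein_names
    metals = None
    if panel is not None:
        metal_of = dict(zip(panel.antigens, panel.metals))
        metals = [metal_of.get(a, a) for a in names]
    paths = []
    for sid in pd.unique(cells.sample_id):
        mask = cells.sample_id == sid
        vals = cells.values[mask]
        if back_transform:
            vals = np.sinh(vals) * cofactor
        path = out_dir / f"{sid}.fcs"
        write_fcs(
            path,
            vals,
            channel_names=metals if metals is not None else names,
            channel_labels=names,
            extra_text={"$SRC": str(sid)},
        )
        paths.append(path)
    return paths
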