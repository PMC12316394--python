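"""Reading, validating and subsetting two-condition Visium-style datasets.

A dataset is a genes x spots integer count matrix plus per-spot metadata:
planar coordinates (Space Ranger pixel convention), the tissue slice each
spot came from, a region-of-interest (ROI) label assigned by a pathologist
or analyst, and the experimental condition of the slice.  Power estimation
downstream always operates on the spots of a single ROI, split by condition.

On-disk layout follows Space Ranger: a MatrixMarket ``.mtx`` count matrix
(genes as rows), ``features.tsv`` / ``barcodes.tsv`` sidecars, and a
``tissue_positions`` CSV with columns
``barcode, in_tissue, array_row, array_col, pxl_row, pxl_col``.
Condition and ROI annotations arrive as two small CSVs: a sample sheet
mapping ``slice_id -> condition`` and a per-barcode ROI table.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ValidationError",
    "SpotDataset",
    "ROISelection",
    "read_visium_slice",
    "attach_annotations",
    "select_roi",
    "combine_slices",
    "write_visium_slice",
    "write_dataset",
]

NO_ROI = "none"

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row",
    "pxl_col",
]


class ValidationError(ValueError):
    """Raised when an input dataset violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpotDataset:
    """Genes x spots counts with per-spot slice, ROI and condition labels.

    ``counts`` is a non-negative integer CSR matrix with genes as rows.
    ``spot_xy`` holds (pxl_col, pxl_row) full-resolution pixel coordinates;
    ``array_rowcol`` keeps the hex-grid array indices as metadata.
    ``conditions`` is empty-string until :func:`attach_annotations` joins the
    sample sheet; each slice carries exactly one condition.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    spot_barcodes: np.ndarray
    spot_xy: np.ndarray
    slice_ids: np.ndarray
    roi_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    conditions: np.ndarray = field(default=None)  # type: ignore[assignment]
    array_rowcol: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_barcodes = np.asarray(self.spot_barcodes, dtype=object)
        self.spot_xy = np.asarray(self.spot_xy, dtype=float)
        self.slice_ids = np.asarray(self.slice_ids, dtype=object)
        if self.roi_labels is None:
            self.roi_labels = np.full(self.n_spots, NO_ROI, dtype=object)
        else:
            self.roi_labels = np.asarray(self.roi_labels, dtype=object)
        if self.conditions is None:
            self.conditions = np.full(self.n_spots, "", dtype=object)
        else:
            self.conditions = np.asarray(self.conditions, dtype=object)
        self._validate()

    # -- invariants --------------------------------------------------------
    def _validate(self) -> None:
        g, s = self.counts.shape
        if len(self.gene_ids) != g or len(self.spot_barcodes) != s:
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.spot_barcodes)} barcodes"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError(
                "counts must be non-negative integers; got fractional or "
                "negative entries (normalized input is refused, normalization "
                "happens downstream)"
            )
        if len(set(self.spot_barcodes)) != s:
            raise ValidationError("spot barcodes are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene ids are not unique")
        for name, arr, n in [
            ("spot_xy", self.spot_xy, s),
            ("slice_ids", self.slice_ids, s),
            ("roi_labels", self.roi_labels, s),
            ("conditions", self.conditions, s),
        ]:
            if len(arr) != n:
                raise ValidationError(f"{name} has length {len(arr)}, expected {n}")
        # a slice must not straddle conditions
        cond_by_slice: dict[str, str] = {}
        for sl, cond in zip(self.slice_ids, self.conditions):
            if sl in cond_by_slice and cond_by_slice[sl] != cond:
                raise ValidationError(f"slice {sl!r} carries two condition labels")
            cond_by_slice[sl] = cond

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def condition_labels(self) -> list[str]:
        """Distinct non-empty condition labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            if c:
                seen.setdefault(c, None)
        return list(seen)

    def subset_spots(self, idx: np.ndarray) -> "SpotDataset":
        idx = np.asarray(idx)
        return SpotDataset(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            spot_barcodes=self.spot_barcodes[idx],
            spot_xy=self.spot_xy[idx],
            slice_ids=self.slice_ids[idx],
            roi_labels=self.roi_labels[idx],
            conditions=self.conditions[idx],
            array_rowcol=None if self.array_rowcol is None else self.array_rowcol[idx],
        )


@dataclass(frozen=True)
class ROISelection:
    """Spot indices of one ROI, split by condition.

    Construction fails unless both conditions contribute at least one spot,
    so a selection is always usable for two-group resampling.
    """

    roi_label: str
    spots_per_condition: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.spots_per_condition) != 2:
            raise ValidationError(
                f"ROI selection needs exactly two conditions, got "
                f"{list(self.spots_per_condition)}"
            )
        for cond, idx in self.spots_per_condition.items():
            if len(idx) == 0:
                raise ValidationError(
                    f"condition {cond!r} has no spots in ROI {self.roi_label!r}"
                )

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.spots_per_condition.items()}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_nohdr(path: str | Path) -> pd.DataFrame:
    with _open_maybe_gzip(path) as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def _read_positions(path: str | Path) -> pd.DataFrame:
    """Read a tissue_positions CSV, tolerating both header dialects."""
    with open(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.split(",")[0].lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise ValidationError(
            f"positions file {path} has {df.shape[1]} columns, expected 6 "
            f"({', '.join(POSITION_COLUMNS)})"
        )
    df = df.iloc[:, :6]
    df.columns = POSITION_COLUMNS
    df["barcode"] = df["barcode"].astype(str)
    return df


def _dedup_gene_ids(ids: Sequence[str]) -> np.ndarray:
    """Disambiguate duplicate gene ids by suffixing ``_1``, ``_2``, ..."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}_{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return np.asarray(out, dtype=object)


def read_visium_slice(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    positions_path: str | Path,
    slice_id: str,
) -> SpotDataset:
    """Read one Visium slice, keeping only in-tissue spots.

    Parameters mirror the Space Ranger per-sample output: the MatrixMarket
    count matrix (genes x barcodes), the features/barcodes TSV sidecars and
    the tissue-positions CSV.  Spots with ``in_tissue == 0`` are dropped;
    barcodes present in the matrix but missing from the positions file are a
    hard error (the files belong to different captures).
    """
    for p in (matrix_path, features_path, barcodes_path, positions_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    with _open_maybe_gzip(matrix_path) as fh:
        mat = scipy.io.mmread(io.StringIO(fh.read()))
    mat = sp.csr_matrix(mat)
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise ValidationError(f"{matrix_path}: matrix contains non-integer counts")
    features = _read_tsv_nohdr(features_path)
    barcodes = _read_tsv_nohdr(barcodes_path)[0].astype(str).to_numpy()
    if mat.shape != (len(features), len(barcodes)):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    positions = _read_positions(positions_path)
    pos_by_bc = positions.set_index("barcode")
    missing = sorted(set(barcodes) - set(pos_by_bc.index))
    if missing:
        raise ValidationError(
            f"{len(missing)} barcode(s) in matrix absent from positions file: "
            + ", ".join(missing[:10])
        )
    pos = pos_by_bc.loc[barcodes]
    keep = (pos["in_tissue"].astype(int) == 1).to_numpy()
    if not keep.any():
        raise ValidationError(f"slice {slice_id!r}: no in-tissue spots")
    idx = np.flatnonzero(keep)
    pos = pos.iloc[idx]
    return SpotDataset(
        counts=mat[:, idx],
        gene_ids=_dedup_gene_ids(features[0].astype(str)),
        spot_barcodes=barcodes[idx],
        spot_xy=pos[["pxl_col", "pxl_row"]].to_numpy(dtype=float),
        slice_ids=np.full(idx.size, slice_id, dtype=object),
        array_rowcol=pos[["array_row", "array_col"]].to_numpy(dtype=int),
    )


def combine_slices(slices: Sequence[SpotDataset]) -> SpotDataset:
    """Concatenate per-slice datasets sharing the same gene index.

    Visium barcodes repeat across captures, so barcodes are prefixed with
    their slice id whenever the naive concatenation would collide.
    """
    if not slices:
        raise ValidationError("no slices to combine")
    ref = slices[0].gene_ids
    for ds in slices[1:]:
        if not np.array_equal(ds.gene_ids, ref):
            raise ValidationError("slices have different gene indices")
    barcodes = np.concatenate([ds.spot_barcodes for ds in slices])
    if len(set(barcodes)) != len(barcodes):
        barcodes = np.concatenate(
            [
                np.array(
                    [f"{sl}:{bc}" for sl, bc in zip(ds.slice_ids, ds.spot_barcodes)],
                    dtype=object,
                )
                for ds in slices
            ]
        )
    rowcol = None
    if all(ds.array_rowcol is not None for ds in slices):
        rowcol = np.concatenate([ds.array_rowcol for ds in slices])
    return SpotDataset(
        counts=sp.hstack([ds.counts for ds in slices], format="csr"),
        gene_ids=ref,
        spot_barcodes=barcodes,
        spot_xy=np.concatenate([ds.spot_xy for ds in slices]),
        slice_ids=np.concatenate([ds.slice_ids for ds in slices]),
        roi_labels=np.concatenate([ds.roi_labels for ds in slices]),
        conditions=np.concatenate([ds.conditions for ds in slices]),
        array_rowcol=rowcol,
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def attach_annotations(
    ds: SpotDataset,
    samplesheet: pd.DataFrame | str | Path,
    roi_csv: pd.DataFrame | str | Path | None = None,
) -> SpotDataset:
    """Join the slice->condition sample sheet and per-barcode ROI labels.

    The sample sheet must cover every slice in ``ds`` and define exactly two
    conditions.  Barcodes absent from the ROI table get the label ``"none"``.
    Returns a new dataset; ``ds`` is not modified.
    """
    if not isinstance(samplesheet, pd.DataFrame):
        samplesheet = pd.read_csv(samplesheet, dtype=str)
    if not {"slice_id", "condition"} <= set(samplesheet.columns):
        raise ValidationError("samplesheet needs columns slice_id, condition")
    cond_map = dict(
        zip(samplesheet["slice_id"].astype(str), samplesheet["condition"].astype(str))
    )
    n_cond = len(set(cond_map.values()))
    if n_cond != 2:
        raise ValidationError(
            f"samplesheet defines {n_cond} conditions; exactly 2 required"
        )
    missing = sorted({str(s) for s in ds.slice_ids} - set(cond_map))
    if missing:
        raise ValidationError(f"slices missing from samplesheet: {', '.join(missing)}")
    conditions = np.array([cond_map[str(s)] for s in ds.slice_ids], dtype=object)

    roi_labels = np.full(ds.n_spots, NO_ROI, dtype=object)
    if roi_csv is not None:
        if not isinstance(roi_csv, pd.DataFrame):
            roi_csv = pd.read_csv(roi_csv, dtype=str)
        if not {"barcode", "roi_label"} <= set(roi_csv.columns):
            raise ValidationError("ROI table needs columns barcode, roi_label")
        roi_map = dict(
            zip(roi_csv["barcode"].astype(str), roi_csv["roi_label"].astype(str))
        )
        for i, bc in enumerate(ds.spot_barcodes):
            lab = roi_map.get(str(bc))
            if lab is not None:
                roi_labels[i] = lab
    return replace(ds, conditions=conditions, roi_labels=roi_labels)


def select_roi(ds: SpotDataset, roi_label: str) -> ROISelection:
    """Collect the per-condition spot indices of one ROI.

    Index order is input (column) order, so the selection is deterministic.
    Fails if the label is unknown, conditions are not attached, or one
    condition contributes no spots.
    """
    conds = ds.condition_labels()
    if len(conds) != 2:
        raise ValidationError(
            f"dataset has {len(conds)} condition labels; attach_annotations "
            "must define exactly 2"
        )
    mask = ds.roi_labels == roi_label
    if not mask.any():
        raise ValidationError(f"ROI label {roi_label!r} not present in dataset")
    per_cond = {}
    for cond in conds:
        idx = np.flatnonzero(mask & (ds.conditions == cond))
        if idx.size == 0:
            raise ValidationError(
                f"condition {cond!r} has no spots in ROI {roi_label!r}"
            )
        per_cond[cond] = idx
    return ROISelection(roi_label=roi_label, spots_per_condition=per_cond)


# ---------------------------------------------------------------------------
# writers (fixture / round-trip support)
# ---------------------------------------------------------------------------


def write_visium_slice(ds: SpotDataset, outdir: str | Path) -> None:
    """Write a one-slice dataset in the Space Ranger text layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(ds.counts, dtype=int))
    pd.DataFrame(
        {"gene_id": ds.gene_ids, "gene_name": ds.gene_ids}
    ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(ds.spot_barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    rowcol = (
        ds.array_rowcol
        if ds.array_rowcol is not None
        else np.zeros((ds.n_spots, 2), dtype=int)
    )
    pd.DataFrame(
        {
            "barcode": ds.spot_barcodes,
            "in_tissue": 1,
            "array_row": rowcol[:, 0],
            "array_col": rowcol[:, 1],
            "pxl_row": ds.spot_xy[:, 1],
            "pxl_col": ds.spot_xy[:, 0],
        }
    ).to_csv(outdir / "tissue_positions.csv", index=False)


def write_dataset(ds: SpotDataset, outdir: str | Path) -> None:
    """Write a multi-slice dataset: one Space Ranger directory per slice plus
    samplesheet.csv and roi.csv at the top level."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sl in dict.fromkeys(ds.slice_ids):
        idx = np.flatnonzero(ds.slice_ids == sl)
        write_visium_slice(ds.subset_spots(idx), outdir / str(sl))
        cond = ds.conditions[idx[0]]
        rows.append({"slice_id": sl, "condition": cond})
    pd.DataFrame(rows).to_csv(outdir / "samplesheet.csv", index=False)
    annotated = ds.roi_labels != NO_ROI
    pd.DataFrame(
        {
            "barcode": ds.spot_barcodes[annotated],
            "roi_label": ds.roi_labels[annotated],
        }
    ).to_csv(outdir / "roi.csv", index=False)


def read_dataset(outdir: str | Path) -> SpotDataset:
    """Read back a directory written by :func:`write_dataset`."""
    outdir = Path(outdir)
    sheet = pd.read_csv(outdir / "samplesheet.csv", dtype=str)
    slices = []
    for sl in sheet["slice_id"]:
        d = outdir / str(sl)
        slices.append(
            read_visium_slice(
                d / "matrix.mtx",
                d / "features.tsv",
                d / "barcodes.tsv",
                d / "tissue_positions.csv",
                slice_id=str(sl),
            )
        )
    ds = combine_slices(slices)
    roi_path = outdir / "roi.csv"
    roi = pd.read_csv(roi_path, dtype=str) if roi_path.exists() else None
    if roi is not None and roi.empty:
        roi = None
    return attach_annotations(ds, sheet, roi)
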