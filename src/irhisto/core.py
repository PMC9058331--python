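"""Domain types for FTIR hyperspectral tissue data and on-disk containers.

The package works with two in-memory containers and two file formats:

* :class:`HyperCube` — one sample's absorbance image cube (row, column,
  wavenumber band) plus metadata, stored as an HDF5 file with datasets
  ``axis`` and ``data`` and attributes ``sample_id``, ``pathology`` and
  ``pixel_size_um``.
* :class:`SpectraTable` — a flat, labelled collection of spectra sharing a
  single wavenumber axis, stored either as HDF5 (full precision) or as CSV
  (9 significant digits; one metadata block followed by one column per
  wavenumber).

Coordinates are (row, column), 0-based, row 0 at the image top; bands are
ordered by ascending wavenumber; the stored quantity is absorbance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not follow the documented container layout."""


class InvariantError(ValueError):
    """A domain-type invariant is violated."""


class Pathology(str, enum.Enum):
    """The four diagnostic groups of the colonic-polyp study design."""

    NORMAL = "normal"
    ADENOMA = "adenoma"
    EPITHELIAL_MISPLACEMENT = "epithelial_misplacement"
    CANCER = "cancer"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for confusion matrices and class lists.
PATHOLOGY_ORDER: tuple[Pathology, ...] = (
    Pathology.NORMAL,
    Pathology.ADENOMA,
    Pathology.EPITHELIAL_MISPLACEMENT,
    Pathology.CANCER,
)


class TissueClass(str, enum.Enum):
    """Histology classes a cluster may be labelled with."""

    NUCLEAR = "nuclear"
    CYTOPLASMIC = "cytoplasmic"
    MUCIN = "mucin"
    LAMINA_PROPRIA = "lamina_propria"
    SUBMUCOSA = "submucosa"
    STROMA = "stroma"
    BACKGROUND = "background"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Epithelium is defined as the union of nuclear and cytoplasmic classes.
EPITHELIUM: frozenset[TissueClass] = frozenset(
    {TissueClass.NUCLEAR, TissueClass.CYTOPLASMIC}
)


def _as_pathology(value) -> Pathology:
    if isinstance(value, Pathology):
        return value
    try:
        return Pathology(str(value))
    except ValueError:
        raise InvariantError(
            f"unknown pathology {value!r}; expected one of "
            f"{[p.value for p in Pathology]}"
        ) from None


def _as_tissue_class(value) -> TissueClass:
    if isinstance(value, TissueClass):
        return value
    try:
        return TissueClass(str(value))
    except ValueError:
        raise InvariantError(f"unknown tissue class {value!r}") from None


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing, uniformly spaced wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InvariantError("axis must be 1-D with at least 2 points")
        if not np.all(values > 0):
            raise InvariantError("wavenumbers must be positive")
        diffs = np.diff(values)
        if not np.all(diffs > 0):
            raise InvariantError("axis must be strictly increasing")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=1e-9, atol=0.0):
            raise InvariantError("axis spacing must be uniform (rtol 1e-9)")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the axis point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):  # frozen dataclass with array field
        return hash((self.values.shape, self.values.tobytes()))


@dataclass
class HyperCube:
    """One sample's absorbance cube, indexed (row, column, band)."""

    sample_id: str
    pathology: Pathology
    axis: WavenumberAxis
    data: np.ndarray
    pixel_size: float = 1.1  # µm per pixel edge

    def __post_init__(self):
        self.pathology = _as_pathology(self.pathology)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvariantError("cube data must be 3-D (row, column, band)")
        if self.data.shape[2] != len(self.axis):
            raise InvariantError(
                f"band dimension {self.data.shape[2]} does not match axis "
                f"length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvariantError("cube data must be finite")
        if not self.pixel_size > 0:
            raise InvariantError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


#: Metadata columns of a SpectraTable, in storage order.
META_COLUMNS = ("sample_id", "pathology", "tissue_class", "row", "column")


@dataclass
class SpectraTable:
    """Flat collection of labelled spectra sharing one wavenumber axis.

    ``meta`` holds one row per spectrum with columns ``sample_id``,
    ``pathology``, ``tissue_class``, ``row``, ``column``; ``spectra`` is the
    matching (n_records, n_bands) absorbance matrix.
    """

    axis: WavenumberAxis
    meta: pd.DataFrame
    spectra: np.ndarray

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise InvariantError("spectra must be a 2-D matrix")
        if self.spectra.shape[1] != len(self.axis):
            raise InvariantError(
                f"spectrum length {self.spectra.shape[1]} does not match "
                f"axis length {len(self.axis)}"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise InvariantError(f"meta lacks columns {missing}")
        if len(self.meta) != self.spectra.shape[0]:
            raise InvariantError("meta and spectra row counts differ")
        self.meta = self.meta.reset_index(drop=True)
        key = self.meta[["sample_id", "row", "column"]]
        if key.duplicated().any():
            raise InvariantError("(sample_id, row, column) must be unique")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.meta["sample_id"]))

    def select(self, mask: np.ndarray) -> "SpectraTable":
        mask = np.asarray(mask, dtype=bool)
        return SpectraTable(
            self.axis, self.meta.loc[mask].copy(), self.spectra[mask]
        )

    def for_sample(self, sample_id: str) -> "SpectraTable":
        return self.select(self.meta["sample_id"].to_numpy() == sample_id)

    def with_spectra(self, spectra: np.ndarray,
                     axis: WavenumberAxis | None = None) -> "SpectraTable":
        """Same records, new spectral values (and optionally new axis)."""
        return SpectraTable(axis or self.axis, self.meta.copy(), spectra)


def concat_tables(tables: Sequence[SpectraTable]) -> SpectraTable:
    """Concatenate tables that share one axis."""
    if not tables:
        raise InvariantError("cannot concatenate zero tables")
    axis = tables[0].axis
    for t in tables[1:]:
        if t.axis != axis:
            raise InvariantError("tables have differing axes")
    meta = pd.concat([t.meta for t in tables], ignore_index=True)
    spectra = np.vstack([t.spectra for t in tables])
    return SpectraTable(axis, meta, spectra)


# ---------------------------------------------------------------------------
# HyperCube container I/O (HDF5)
# ---------------------------------------------------------------------------

def write_cube(cube: HyperCube, path) -> None:
    """Write a cube to the HDF5 container layout."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("axis", data=cube.axis.values)
        fh.create_dataset("data", data=cube.data)
        fh.attrs["sample_id"] = cube.sample_id
        fh.attrs["pathology"] = cube.pathology.value
        fh.attrs["pixel_size_um"] = cube.pixel_size


def read_cube(path) -> HyperCube:
    """Read a cube written by :func:`write_cube`."""
    with h5py.File(path, "r") as fh:
        for key in ("axis", "data"):
            if key not in fh:
                raise FormatError(f"cube file lacks dataset '{key}'")
        for key in ("sample_id", "pathology", "pixel_size_um"):
            if key not in fh.attrs:
                raise FormatError(f"cube file lacks attribute '{key}'")
        axis = WavenumberAxis(fh["axis"][()])
        data = fh["data"][()]
        return HyperCube(
            sample_id=str(fh.attrs["sample_id"]),
            pathology=_as_pathology(fh.attrs["pathology"]),
            axis=axis,
            data=data,
            pixel_size=float(fh.attrs["pixel_size_um"]),
        )


def flatten_cube(cube: HyperCube, mask: np.ndarray | None = None) -> SpectraTable:
    """One record per (unmasked) pixel; tissue_class starts as background."""
    rows, cols, _ = cube.data.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise InvariantError(
                f"mask shape {mask.shape} does not match cube spatial shape "
                f"{(rows, cols)}"
            )
    rr, cc = np.nonzero(mask)
    meta = pd.DataFrame(
        {
            "sample_id": cube.sample_id,
            "pathology": cube.pathology.value,
            "tissue_class": TissueClass.BACKGROUND.value,
            "row": rr.astype(int),
            "column": cc.astype(int),
        }
    )
    return SpectraTable(cube.axis, meta, cube.data[rr, cc, :])


# ---------------------------------------------------------------------------
# SpectraTable container I/O (HDF5 binary variant; CSV text variant)
# ---------------------------------------------------------------------------

def write_spectra(table: SpectraTable, path) -> None:
    """Write a spectra table; format chosen by suffix (.csv else HDF5)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_spectra_csv(table, path)
    else:
        _write_spectra_hdf5(table, path)


def read_spectra(path) -> SpectraTable:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_spectra_csv(path)
    return _read_spectra_hdf5(path)


def _write_spectra_hdf5(table: SpectraTable, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("axis", data=table.axis.values)
        fh.create_dataset("spectra", data=table.spectra)
        str_dt = h5py.string_dtype(encoding="utf-8")
        for col in ("sample_id", "pathology", "tissue_class"):
            fh.create_dataset(
                f"meta/{col}",
                data=table.meta[col].astype(str).to_numpy(),
                dtype=str_dt,
            )
        for col in ("row", "column"):
            fh.create_dataset(f"meta/{col}", data=table.meta[col].to_numpy(int))


def _read_spectra_hdf5(path) -> SpectraTable:
    with h5py.File(path, "r") as fh:
        for key in ("axis", "spectra"):
            if key not in fh:
                raise FormatError(f"spectra file lacks dataset '{key}'")
        axis = WavenumberAxis(fh["axis"][()])
        spectra = fh["spectra"][()]
        meta = {}
        for col in META_COLUMNS:
            key = f"meta/{col}"
            if key not in fh:
                raise FormatError(f"spectra file lacks dataset '{key}'")
            values = fh[key][()]
            if col in ("row", "column"):
                meta[col] = values.astype(int)
            else:
                meta[col] = [v.decode() if isinstance(v, bytes) else str(v)
                             for v in values]
        return SpectraTable(axis, pd.DataFrame(meta), spectra)


def _write_spectra_csv(table: SpectraTable, path) -> None:
    # header carries the wavenumbers; values stored to 9 significant digits
    wn_cols = [f"{w:.9g}" for w in table.axis.values]
    df = table.meta[list(META_COLUMNS)].copy()
    spec = pd.DataFrame(table.spectra, columns=wn_cols, index=df.index)
    pd.concat([df, spec], axis=1).to_csv(path, index=False, float_format="%.9g")


def _read_spectra_csv(path) -> SpectraTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed spectra CSV: {exc}") from exc
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spectra CSV lacks metadata columns {missing}")
    wn_cols = [c for c in df.columns if c not in META_COLUMNS]
    if len(wn_cols) < 2:
        raise FormatError("spectra CSV has fewer than 2 wavenumber columns")
    try:
        axis = WavenumberAxis(np.array([float(c) for c in wn_cols]))
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber column header: {exc}") from exc
    meta = df[list(META_COLUMNS)].copy()
    if len(df):
        spectra = df[wn_cols].to_numpy(float)
        if not np.all(np.isfinite(spectra)):
            raise FormatError("spectra CSV contains missing or ragged values")
    else:
        spectra = np.empty((0, len(axis)))
    meta["row"] = meta["row"].astype(int)
    meta["column"] = meta["column"].astype(int)
    return SpectraTable(axis, meta, spectra)
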