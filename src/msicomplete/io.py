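"""Readers and writers: imzML import, the internal chunked sparse store,
factor-model persistence, and ion-image export.

The internal store is an HDF5 file holding the dataset in compressed sparse
column layout (``values``/``row_index``/``col_ptr``) together with
``pixel_coords`` and ``mz_axis``; columns are ion images, the dominant access
pattern.  Free-form metadata lives in a JSON sidecar next to the file.
Intensities are stored as 4-byte floats, the width all storage accounting
assumes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import scipy.sparse as sp

from .core import LowRankFactors, ObservationMask, SpectraMatrix

__all__ = [
    "read_imzml",
    "write_imzml",
    "write_store",
    "read_store",
    "save_factors",
    "load_factors",
    "save_mask",
    "load_mask",
    "save_ion_image",
    "IntegrityError",
]


class IntegrityError(RuntimeError):
    """A persisted artifact failed its checksum."""


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------


def read_imzml(
    path,
    min_intensity: float = 0.0,
    common_axis: Optional[np.ndarray] = None,
) -> SpectraMatrix:
    """Read a continuous-mode imzML file into a sparse :class:`SpectraMatrix`.

    Intensities below ``min_intensity`` are dropped to implicit sparse zeros
    at import time (equivalent to clipping the densely-read matrix).
    Processed-mode files, whose spectra carry individual m/z axes, are
    accepted only with a user-supplied ``common_axis``; each centroid is then
    assigned to the nearest axis bin.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    n_spectra = len(parser.coordinates)
    if n_spectra == 0:
        raise ValueError(f"{path}: no spectra")

    axis0, _ = parser.getspectrum(0)
    axis = np.asarray(common_axis, dtype=np.float64) if common_axis is not None else axis0
    n = axis.size

    rows, cols, data = [], [], []
    for i in range(n_spectra):
        mzs, ints = parser.getspectrum(i)
        if common_axis is None and (
            mzs.size != axis.size or not np.allclose(mzs, axis)
        ):
            raise ValueError(
                f"{path}: spectrum {i} has its own m/z axis (processed-mode "
                "imzML); supply common_axis= to resample onto a shared axis"
            )
        if common_axis is not None:
            j = np.clip(np.searchsorted(axis, mzs), 0, n - 1)
            left_closer = (j > 0) & (
                np.abs(mzs - axis[np.maximum(j - 1, 0)]) < np.abs(mzs - axis[j])
            )
            j = np.where(left_closer, j - 1, j)
        else:
            j = np.arange(n)
        # same boundary convention as core.clip: values >= threshold survive
        keep = ints >= min_intensity if min_intensity > 0 else ints != 0
        rows.append(np.full(int(keep.sum()), i, dtype=np.int64))
        cols.append(np.asarray(j)[keep].astype(np.int64))
        data.append(np.asarray(ints)[keep].astype(np.float64))

    values = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_spectra, n),
    )
    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=np.int64)
    return SpectraMatrix(values, coords, axis, {"source": str(path)})


def write_imzml(M: SpectraMatrix, path) -> None:
    """Write a continuous-mode imzML file (full spectra on the shared axis)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous") as writer:
        dense = M.values.toarray()
        for i in range(M.n_pixels):
            x, y = M.pixel_coords[i]
            writer.addSpectrum(M.mz_axis, dense[i], (int(x) + 1, int(y) + 1, 1))


# ---------------------------------------------------------------------------
# internal chunked sparse store
# ---------------------------------------------------------------------------


def write_store(M: SpectraMatrix, path) -> None:
    """Persist a :class:`SpectraMatrix` as a chunked CSC HDF5 store."""
    path = Path(path)
    csc = M.values.tocsc()
    with h5py.File(path, "w") as f:
        f.attrs["shape"] = M.shape
        f.attrs["format"] = "csc"
        f.create_dataset("values", data=csc.data.astype(np.float32), chunks=True)
        f.create_dataset("row_index", data=csc.indices.astype(np.int64), chunks=True)
        f.create_dataset("col_ptr", data=csc.indptr.astype(np.int64))
        f.create_dataset("pixel_coords", data=M.pixel_coords)
        f.create_dataset("mz_axis", data=M.mz_axis)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(M.metadata, indent=2, default=str)
    )


def read_store(path) -> SpectraMatrix:
    path = Path(path)
    with h5py.File(path, "r") as f:
        shape = tuple(int(v) for v in f.attrs["shape"])
        csc = sp.csc_matrix(
            (f["values"][:].astype(np.float64), f["row_index"][:], f["col_ptr"][:]),
            shape=shape,
        )
        coords = f["pixel_coords"][:]
        mz_axis = f["mz_axis"][:]
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SpectraMatrix(csc.tocsr(), coords, mz_axis, metadata)


# ---------------------------------------------------------------------------
# factor models
# ---------------------------------------------------------------------------


def _factor_checksum(U: np.ndarray, s: np.ndarray, V: np.ndarray) -> str:
    h = hashlib.sha256()
    for arr in (U, s, V):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def save_factors(F: LowRankFactors, path) -> None:
    """Persist factors at 4-byte precision with an integrity checksum."""
    U = F.left.astype(np.float32)
    s = F.singvals.astype(np.float32)
    V = F.right.astype(np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("U", data=U)
        f.create_dataset("s", data=s)
        f.create_dataset("V", data=V)
        f.attrs["sha256"] = _factor_checksum(U, s, V)
        f.attrs["rank"] = F.rank


def load_factors(path) -> LowRankFactors:
    with h5py.File(path, "r") as f:
        U, s, V = f["U"][:], f["s"][:], f["V"][:]
        stored = f.attrs["sha256"]
    actual = _factor_checksum(U, s, V)
    if actual != stored:
        raise IntegrityError(
            f"{path}: factor checksum mismatch (stored {stored[:12]}…, "
            f"recomputed {actual[:12]}…)"
        )
    return LowRankFactors(U.astype(np.float64), s.astype(np.float64), V.astype(np.float64))


# ---------------------------------------------------------------------------
# observation masks
# ---------------------------------------------------------------------------


def save_mask(mask: ObservationMask, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["shape"] = mask.shape
        f.create_dataset("rows", data=mask.rows)
        f.create_dataset("cols", data=mask.cols)


def load_mask(path) -> ObservationMask:
    with h5py.File(path, "r") as f:
        shape = tuple(int(v) for v in f.attrs["shape"])
        return ObservationMask(f["rows"][:], f["cols"][:], shape)


# ---------------------------------------------------------------------------
# ion-image export
# ---------------------------------------------------------------------------


def save_ion_image(img: np.ndarray, path, cmap: str = "viridis") -> None:
    """Export an ion image as PNG (colormapped) or TIFF (raw float32)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.astype(np.float32))
    else:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        plt.imsave(path, np.ma.masked_invalid(img), cmap=cmap)
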