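"""Readers and writers for hyperspectral cubes and phantom ground truth.

Native storage is HDF5 (datasets ``cube`` and ``axis``, attribute
``pixel_size_um``; optional masks and a planted-EV truth table). Two
plain-text interchange formats are supported for fixtures and generic
instrument exports: a whitespace-delimited matrix with a wavenumber header
row (one spectrum per line, spatial shape in a leading ``# shape:`` comment)
and a long-form per-pixel CSV (row, col[, z], wavenumber_cm1, intensity).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectral import HyperCube, SpectralAxis
from .synth import EvPixel, PhantomTruth

__all__ = [
    "read_cube",
    "write_cube_h5",
    "read_cube_h5",
    "write_cube_text",
    "read_cube_text",
    "write_cube_csv",
    "read_cube_csv",
    "write_truth_csv",
    "read_truth_csv",
]


def write_cube_h5(path, cube: HyperCube, truth: PhantomTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data)
        f.create_dataset("axis", data=cube.axis.values)
        f.attrs["pixel_size_um"] = cube.pixel_size_um
        if cube.empty_mask is not None:
            f.create_dataset("empty_mask", data=cube.empty_mask)
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("cell_mask", data=truth.cell_mask)
            masks = g.create_group("component_masks")
            for name, mask in truth.component_masks.items():
                masks.create_dataset(name, data=mask)
            if truth.ev_pixels:
                g.create_dataset(
                    "ev_pixels",
                    data=np.array(
                        [
                            (p.row, p.col, p.amplitude, p.placement.encode())
                            for p in truth.ev_pixels
                        ],
                        dtype=[("row", "i8"), ("col", "i8"), ("amplitude", "f8"), ("placement", "S16")],
                    ),
                )
            g.attrs["noise_sd"] = truth.noise_sd
            g.attrs["seed"] = truth.seed


def read_cube_h5(path) -> HyperCube:
    with h5py.File(path, "r") as f:
        axis = SpectralAxis(f["axis"][:])
        data = f["cube"][:]
        pixel_size = float(f.attrs.get("pixel_size_um", 0.5))
        empty = f["empty_mask"][:].astype(bool) if "empty_mask" in f else None
    return HyperCube(axis, data, pixel_size, empty)


def write_cube_text(path, cube: HyperCube) -> None:
    """Wavenumber-header matrix: one spectrum per line, row-major pixels."""
    shape = " ".join(str(s) for s in cube.spatial_shape)
    with open(path, "w") as f:
        f.write(f"# shape: {shape}\n")
        f.write(f"# pixel_size_um: {cube.pixel_size_um}\n")
        f.write(" ".join(f"{v:.10g}" for v in cube.axis.values) + "\n")
        flat = cube.data.reshape(-1, cube.axis.n_bins)
        for row in flat:
            f.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_cube_text(path) -> HyperCube:
    shape: tuple[int, ...] | None = None
    pixel_size = 0.5
    axis: SpectralAxis | None = None
    rows: list[np.ndarray] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text[1:].strip()
                if body.startswith("shape:"):
                    shape = tuple(int(v) for v in body.split(":", 1)[1].split())
                elif body.startswith("pixel_size_um:"):
                    pixel_size = float(body.split(":", 1)[1])
                continue
            try:
                values = np.array([float(v) for v in text.replace(",", " ").split()])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: unparseable value ({exc})") from None
            if axis is None:
                axis = SpectralAxis(values)  # header row of wavenumbers
            else:
                if values.size != axis.n_bins:
                    raise ValueError(
                        f"line {lineno}: ragged row with {values.size} values, "
                        f"expected {axis.n_bins}"
                    )
                rows.append(values)
    if axis is None:
        raise ValueError("missing wavenumber header row")
    if not rows:
        raise ValueError("no spectra after the header row")
    data = np.stack(rows)
    if shape is None:
        shape = (len(rows), 1)
    if int(np.prod(shape)) != len(rows):
        raise ValueError(
            f"declared shape {shape} needs {int(np.prod(shape))} spectra, got {len(rows)}"
        )
    return HyperCube(axis, data.reshape(*shape, axis.n_bins), pixel_size)


def write_cube_csv(path, cube: HyperCube) -> None:
    """Long-form per-pixel CSV (tiny fixtures only)."""
    if cube.is_3d:
        h, w, z, b = cube.data.shape
        rr, cc, zz, bb = np.meshgrid(range(h), range(w), range(z), range(b), indexing="ij")
        frame = pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "z": zz.ravel(),
                "wavenumber_cm1": cube.axis.values[bb.ravel()],
                "intensity": cube.data.ravel(),
            }
        )
    else:
        h, w, b = cube.data.shape
        rr, cc, bb = np.meshgrid(range(h), range(w), range(b), indexing="ij")
        frame = pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "wavenumber_cm1": cube.axis.values[bb.ravel()],
                "intensity": cube.data.ravel(),
            }
        )
    frame.to_csv(path, index=False, float_format="%.10g")


def read_cube_csv(path, pixel_size_um: float = 0.5) -> HyperCube:
    frame = pd.read_csv(path)
    required = {"row", "col", "wavenumber_cm1", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"per-pixel CSV missing columns: {sorted(missing)}")
    has_z = "z" in frame.columns
    wavenumbers = np.sort(frame["wavenumber_cm1"].unique())
    axis = SpectralAxis(wavenumbers)
    h = int(frame["row"].max()) + 1
    w = int(frame["col"].max()) + 1
    index_cols = ["row", "col", "z"] if has_z else ["row", "col"]
    shape = (h, w, int(frame["z"].max()) + 1, axis.n_bins) if has_z else (h, w, axis.n_bins)
    if len(frame) != int(np.prod(shape)):
        raise ValueError(
            f"per-pixel CSV is incomplete: {len(frame)} rows, expected {int(np.prod(shape))}"
        )
    frame = frame.sort_values(index_cols + ["wavenumber_cm1"])
    data = frame["intensity"].to_numpy().reshape(shape)
    return HyperCube(axis, data, pixel_size_um)


def write_truth_csv(path, truth: PhantomTruth) -> None:
    truth.ev_table().to_csv(path, index=False, float_format="%.10g")


def read_truth_csv(path) -> list[EvPixel]:
    frame = pd.read_csv(path)
    return [
        EvPixel(int(r.row), int(r.col), float(r.amplitude), str(r.placement))
        for r in frame.itertuples()
    ]


_READERS = {
    ".h5": read_cube_h5,
    ".hdf5": read_cube_h5,
    ".txt": read_cube_text,
    ".dat": read_cube_text,
    ".csv": read_cube_csv,
}


def read_cube(path, format: str | None = None) -> HyperCube:
    """Load a cube, inferring the format from the extension unless given
    explicitly as one of h5/text/csv."""
    path = Path(path)
    if format is not None:
        reader = {"h5": read_cube_h5, "hdf5": read_cube_h5, "text": read_cube_text, "csv": read_cube_csv}.get(format)
        if reader is None:
            raise ValueError(f"unknown cube format {format!r}")
        return reader(path)
    reader = _READERS.get(path.suffix.lower())
    if reader is None:
        raise ValueError(f"cannot infer cube format from extension {path.suffix!r}")
    return reader(path)
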