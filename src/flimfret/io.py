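"""Readers and writers.

The project's native container is a single-file HDF5 layout holding the
per-pixel TCSPC counts (unsigned integers), the shared time-bin edges, and
a metadata block; round trips are bit-exact for counts and edges.  ICS
(Image Cytometry Standard) is supported for interchange with FLIM
acquisition software: ICS 1.0 (separate .ics header + .ids data) is read
and written, ICS 2.0 (inline data) is read.  Tabular results go to CSV
with a stable column order and fixed float format; heatmaps to PNG with
the conventional red-long/blue-short lifetime colormap; ring labels to
TIFF.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile
from matplotlib import colormaps
from matplotlib.figure import Figure

from .contours import RingLabels, RingProfile
from .histogram import TCSPCImage
from .mapping import LifetimeMap

__all__ = [
    "FormatError",
    "DimensionError",
    "write_container",
    "read_container",
    "write_ics",
    "read_ics",
    "write_lifetime_map_csv",
    "write_ring_profile_csv",
    "read_ring_profile_csv",
    "write_heatmap_png",
    "write_ring_labels_tiff",
]

CONTAINER_VERSION = "1.0"
FLOAT_FORMAT = "%.6f"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class DimensionError(FormatError):
    """A file lacks a required dimension (e.g. no time axis)."""


def _atomic_write(path: Path, write_fn) -> None:
    """Write via a temp file in the destination directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# native HDF5 container
# ---------------------------------------------------------------------------

def write_container(path, image: TCSPCImage) -> None:
    """Write a TCSPCImage to the native HDF5 container."""

    def _write(tmp: Path) -> None:
        with h5py.File(tmp, "w") as f:
            f.attrs["format_version"] = CONTAINER_VERSION
            f.attrs["metadata_json"] = json.dumps(image.metadata, default=str)
            f.create_dataset("counts", data=image.counts.astype(np.uint32), compression="gzip")
            f.create_dataset("bin_edges_ns", data=image.bin_edges)

    _atomic_write(Path(path), _write)


def read_container(path) -> TCSPCImage:
    """Read a TCSPCImage from the native HDF5 container."""
    with h5py.File(path, "r") as f:
        if "counts" not in f or "bin_edges_ns" not in f:
            raise FormatError(f"{path}: missing counts/bin_edges_ns datasets")
        counts = f["counts"][()]
        edges = f["bin_edges_ns"][()]
        metadata = json.loads(f.attrs.get("metadata_json", "{}"))
    return TCSPCImage(counts.astype(np.int64), edges, metadata)


# ---------------------------------------------------------------------------
# ICS (Image Cytometry Standard)
# ---------------------------------------------------------------------------

_ICS_SEP = "\t"
_DTYPES = {
    ("integer", "unsigned", 8): "<u1",
    ("integer", "unsigned", 16): "<u2",
    ("integer", "unsigned", 32): "<u4",
    ("integer", "signed", 16): "<i2",
    ("integer", "signed", 32): "<i4",
    ("real", "signed", 32): "<f4",
    ("real", "signed", 64): "<f8",
}


def write_ics(path, image: TCSPCImage) -> None:
    """Write ICS 1.0: a text ``.ics`` header plus a raw ``.ids`` data file.

    Layout order is ``bits x y t`` with x varying fastest; counts are stored
    as 32-bit little-endian unsigned integers.
    """
    path = Path(path)
    if path.suffix != ".ics":
        raise ValueError("ICS path must end in .ics")
    dt = float(image.bin_edges[1] - image.bin_edges[0])
    header_lines = [
        f"ics_version{_ICS_SEP}1.0",
        f"filename{_ICS_SEP}{path.stem}",
        f"layout{_ICS_SEP}parameters{_ICS_SEP}4",
        f"layout{_ICS_SEP}order{_ICS_SEP}bits{_ICS_SEP}x{_ICS_SEP}y{_ICS_SEP}t",
        f"layout{_ICS_SEP}sizes{_ICS_SEP}32{_ICS_SEP}{image.width}{_ICS_SEP}"
        f"{image.height}{_ICS_SEP}{image.n_bins}",
        f"representation{_ICS_SEP}format{_ICS_SEP}integer",
        f"representation{_ICS_SEP}sign{_ICS_SEP}unsigned",
        f"representation{_ICS_SEP}byte_order{_ICS_SEP}1{_ICS_SEP}2{_ICS_SEP}3{_ICS_SEP}4",
        f"parameter{_ICS_SEP}scale{_ICS_SEP}1.0{_ICS_SEP}1.0{_ICS_SEP}1.0{_ICS_SEP}{dt!r}",
        f"parameter{_ICS_SEP}units{_ICS_SEP}relative{_ICS_SEP}pixels{_ICS_SEP}pixels{_ICS_SEP}ns",
    ]
    for key, value in image.metadata.items():
        header_lines.append(f"history{_ICS_SEP}{key}{_ICS_SEP}{value}")
    header_lines.append("end")
    header = "\n".join(header_lines) + "\n"
    # order bits x y t: t is the slowest axis on disk -> (t, y, x) C-order
    data = np.ascontiguousarray(image.counts.transpose(2, 0, 1)).astype("<u4")
    _atomic_write(path, lambda tmp: tmp.write_text(header))
    _atomic_write(path.with_suffix(".ids"), lambda tmp: data.tofile(tmp))


def _parse_ics_header(text: str) -> tuple[dict[str, list[str]], int]:
    """Parse header lines into ``{"category subkey": values}``; return the
    character offset just past the ``end`` line (for ICS 2.0 inline data)."""
    fields: dict[str, list[str]] = {}
    offset = 0
    for line in text.splitlines(keepends=True):
        stripped = line.strip("\r\n\x00 ")
        offset += len(line)
        if stripped == "end":
            break
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(_ICS_SEP)
        if parts[0] == "ics_version":
            fields["ics_version"] = parts[1:]
        elif len(parts) >= 3:
            fields.setdefault(f"{parts[0]} {parts[1]}", parts[2:])
        elif len(parts) == 2:
            fields.setdefault(parts[0], parts[1:])
    else:
        raise FormatError("ICS header has no 'end' line")
    return fields, offset


def read_ics(path) -> TCSPCImage:
    """Read an ICS 1.0/2.0 file with a time dimension into a TCSPCImage.

    Raises
    ------
    FormatError
        Missing or garbled header fields, or truncated data.
    DimensionError
        The file has no time ('t') axis.
    """
    path = Path(path)
    raw = path.read_bytes()
    # the header is ASCII text; ICS 2.0 appends binary data after 'end'
    try:
        text = raw.decode("latin-1")
    except UnicodeDecodeError as exc:  # pragma: no cover - latin-1 never fails
        raise FormatError(f"{path}: undecodable header") from exc
    fields, offset = _parse_ics_header(text)
    version = fields.get("ics_version", ["?"])[0]

    for required in ("layout order", "layout sizes"):
        if required not in fields:
            raise FormatError(f"{path}: missing header field '{required}'")
    order = fields["layout order"]
    try:
        sizes = [int(s) for s in fields["layout sizes"]]
    except ValueError:
        raise FormatError(f"{path}: garbled field 'layout sizes'") from None
    if len(order) != len(sizes) or not order or order[0] != "bits":
        raise FormatError(f"{path}: inconsistent 'layout order'/'layout sizes'")
    axes = order[1:]
    dims = dict(zip(axes, sizes[1:]))
    if "t" not in axes:
        raise DimensionError(f"{path}: no time ('t') dimension")
    for ax in ("x", "y"):
        if ax not in axes:
            raise DimensionError(f"{path}: no spatial ('{ax}') dimension")

    fmt = fields.get("representation format", ["integer"])[0]
    sign = fields.get("representation sign", ["unsigned"])[0]
    bits = sizes[0]
    dtype = _DTYPES.get((fmt, sign, bits))
    if dtype is None:
        raise FormatError(f"{path}: unsupported representation {fmt}/{sign}/{bits}")

    n_items = int(np.prod(sizes[1:]))
    n_bytes = n_items * bits // 8
    if version.startswith("2"):
        payload = raw[offset : offset + n_bytes]
    else:
        ids_path = path.with_suffix(".ids")
        if not ids_path.exists():
            raise FormatError(f"{path}: missing data file {ids_path.name}")
        payload = ids_path.read_bytes()
    if len(payload) < n_bytes:
        raise FormatError(
            f"{path}: truncated data ({len(payload)} bytes, expected {n_bytes})"
        )
    flat = np.frombuffer(payload[:n_bytes], dtype=dtype)
    # first listed axis varies fastest -> on-disk C-order shape is reversed
    arr = flat.reshape(tuple(dims[ax] for ax in reversed(axes)))
    arr = np.moveaxis(
        arr, [len(axes) - 1 - axes.index(ax) for ax in ("y", "x", "t")], [0, 1, 2]
    )

    dt = 1.0
    if "parameter scale" in fields:
        scales = fields["parameter scale"]
        # the scale vector may or may not include the leading 'bits' entry
        if len(scales) == len(order):
            scales = scales[1:]
        if len(scales) == len(axes):
            try:
                dt = float(scales[axes.index("t")])
            except ValueError:
                raise FormatError(f"{path}: garbled field 'parameter scale'") from None
    edges = np.arange(dims["t"] + 1) * dt
    metadata: dict[str, Any] = {
        k.split(" ", 1)[1]: v[0] for k, v in fields.items() if k.startswith("history ")
    }
    return TCSPCImage(np.ascontiguousarray(arr).astype(np.int64), edges, metadata)


# ---------------------------------------------------------------------------
# tabular and image outputs
# ---------------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path) -> None:
    _atomic_write(
        Path(path), lambda tmp: frame.to_csv(tmp, index=False, float_format=FLOAT_FORMAT)
    )


def write_lifetime_map_csv(lifetimes: LifetimeMap, path) -> None:
    """Lifetime map as CSV: bin_row, bin_col, tau_ns, n_photons, valid."""
    _write_csv(lifetimes.to_frame(), path)


def write_ring_profile_csv(profile: RingProfile, path, cell_id: str | None = None) -> None:
    """Ring profile as CSV: [cell_id,] ring_bin, tau_ns, n_photons, n_pixels, valid."""
    frame = profile.to_frame()
    if cell_id is not None:
        frame.insert(0, "cell_id", cell_id)
    _write_csv(frame, path)


def read_ring_profile_csv(path) -> pd.DataFrame:
    """Reload a ring-profile CSV (tau values and flags, not pooled decays)."""
    frame = pd.read_csv(path)
    required = {"ring_bin", "tau_ns", "n_photons", "n_pixels", "valid"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_heatmap_png(
    values: np.ndarray,
    path,
    label: str = "lifetime (ns)",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Render a value grid as a PNG heatmap.

    Uses the FLIM convention of red for long lifetimes and blue for short;
    NaN (invalid) cells render in a distinct missing-data grey.
    """
    values = np.asarray(values, dtype=float)
    cmap = colormaps["jet"].copy()
    cmap.set_bad("0.35")
    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot(111)
    masked = np.ma.masked_invalid(values)
    im = ax.imshow(masked, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xticks([])
    ax.set_yticks([])
    _atomic_write(Path(path), lambda tmp: fig.savefig(tmp, format="png", dpi=150))


def write_ring_labels_tiff(rings: RingLabels, path) -> None:
    """Ring-label image as int32 TIFF (0 = mask, -1 = beyond rings)."""
    _atomic_write(
        Path(path), lambda tmp: tifffile.imwrite(tmp, rings.labels.astype(np.int32))
    )
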