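"""File formats: hyperspectral cubes (ENVI, NPZ, CSV), RGB images, masks,
and index images with JSON sidecars.

The ENVI reader/writer covers the subset of the format this tool needs:
a plain-text ``.hdr`` next to a flat binary file, BSQ/BIL/BIP interleaves,
the common numeric data types, optional ``wavelength`` and ``pixel size``
fields.  The CSV dialect is a self-describing text table (pixels x bands
with a wavenumber header row) for toolchains without binary support.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .preprocess import ForegroundMask, HyperspectralCube, RGBImage
from .segmentation import IndexImage

__all__ = [
    "read_cube",
    "write_envi",
    "read_envi",
    "write_npz_cube",
    "read_npz_cube",
    "write_csv_cube",
    "read_csv_cube",
    "read_rgb",
    "write_rgb",
    "read_mask",
    "write_mask",
    "read_index_image",
    "write_index_image",
]

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(
    hdr_path: str | Path, cube: HyperspectralCube, interleave: str = "bsq"
) -> Path:
    """Write a cube as ENVI header + raw binary (float32) next to it."""
    hdr_path = Path(hdr_path)
    data_path = hdr_path.with_suffix(".raw")
    rows, cols = cube.shape
    values = cube.values.astype(np.float32)
    interleave = interleave.lower()
    if interleave == "bsq":
        arr = values.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = values.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = values
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    arr.tofile(data_path)
    wl = ", ".join(f"{w:.6g}" for w in cube.wavenumbers)
    hdr_path.write_text(
        "ENVI\n"
        "description = {specreg hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size = {{{cube.pixel_size:.6g}, {cube.pixel_size:.6g}}}\n"
        "wavelength units = cm-1\n"
        f"wavelength = {{{wl}}}\n"
    )
    return hdr_path


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    key = None
    buffer = ""
    for line in text.splitlines():
        if key is None:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().lower()
            buffer = value.strip()
        else:
            buffer += " " + line.strip()
        if buffer.startswith("{") and not buffer.endswith("}"):
            continue  # multi-line braces
        fields[key] = buffer.strip("{} ")
        key = None
    return fields


def read_envi(hdr_path: str | Path) -> HyperspectralCube:
    """Read an ENVI cube (header + flat binary)."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", "0"))
    data_path = None
    for cand in (hdr_path.with_suffix(""), hdr_path.with_suffix(".raw"),
                 hdr_path.with_suffix(".img"), hdr_path.with_suffix(".dat")):
        if cand.exists() and cand != hdr_path:
            data_path = cand
            break
    if data_path is None:
        raise FileNotFoundError(f"no binary data file found next to {hdr_path}")
    raw = np.fromfile(data_path, dtype=dtype, offset=offset, count=rows * cols * bands)
    if interleave == "bsq":
        values = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    if "wavelength" in fields:
        wavenumbers = np.array([float(w) for w in fields["wavelength"].split(",")])
    else:
        wavenumbers = np.arange(bands, dtype=np.float64)
    pixel_size = 1.0
    if "pixel size" in fields:
        pixel_size = float(fields["pixel size"].split(",")[0])
    return HyperspectralCube(values.astype(np.float64), wavenumbers, pixel_size)


def write_npz_cube(path: str | Path, cube: HyperspectralCube) -> Path:
    path = Path(path)
    np.savez_compressed(
        path, values=cube.values, wavenumbers=cube.wavenumbers, pixel_size=cube.pixel_size
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_npz_cube(path: str | Path) -> HyperspectralCube:
    with np.load(path) as data:
        return HyperspectralCube(
            data["values"], data["wavenumbers"], float(data["pixel_size"])
        )


def write_csv_cube(path: str | Path, cube: HyperspectralCube) -> Path:
    """Self-describing text cube: metadata comments, wavenumber row, then
    one line of band values per pixel in row-major order."""
    path = Path(path)
    rows, cols = cube.shape
    with path.open("w") as fh:
        fh.write("# specreg hyperspectral cube\n")
        fh.write(f"# rows={rows} cols={cols} pixel_size={cube.pixel_size:.6g}\n")
        fh.write(",".join(f"{w:.6g}" for w in cube.wavenumbers) + "\n")
        np.savetxt(fh, cube.values.reshape(rows * cols, cube.n_bands), fmt="%.6g", delimiter=",")
    return path


def read_csv_cube(path: str | Path) -> HyperspectralCube:
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, value = token.partition("=")
                        meta[key] = float(value)
            else:
                header_lines.append(line)
                break
        wavenumbers = np.array([float(w) for w in header_lines[0].split(",")])
        table = np.loadtxt(fh, delimiter=",", ndmin=2)
    rows, cols = int(meta["rows"]), int(meta["cols"])
    return HyperspectralCube(
        table.reshape(rows, cols, wavenumbers.size), wavenumbers, meta.get("pixel_size", 1.0)
    )


def read_cube(path: str | Path, pixel_size: float | None = None) -> HyperspectralCube:
    """Dispatch on extension: .hdr (ENVI), .npz, or .csv."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".hdr":
        cube = read_envi(path)
    elif suffix == ".npz":
        cube = read_npz_cube(path)
    elif suffix == ".csv":
        cube = read_csv_cube(path)
    else:
        raise ValueError(f"unrecognized cube format {suffix!r} (expected .hdr/.npz/.csv)")
    if pixel_size is not None:
        cube.pixel_size = pixel_size
    return cube


def read_rgb(path: str | Path, pixel_size: float) -> RGBImage:
    """Read an 8-bit RGB PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    else:
        values = np.asarray(Image.open(path).convert("RGB"))
    if values.ndim == 2:
        values = np.stack([values] * 3, axis=-1)
    return RGBImage(values[..., :3].astype(np.uint8), pixel_size)


def write_rgb(path: str | Path, image: RGBImage) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values)
    else:
        Image.fromarray(image.values, mode="RGB").save(path)
    return path


def write_mask(path: str | Path, mask: ForegroundMask) -> Path:
    path = Path(path)
    Image.fromarray(np.where(mask.mask, 255, 0).astype(np.uint8), mode="L").save(path)
    return path


def read_mask(path: str | Path) -> ForegroundMask:
    values = np.asarray(Image.open(path).convert("L"))
    return ForegroundMask(values > 0)


def write_index_image(path: str | Path, index: IndexImage) -> Path:
    """Index image as single-channel PNG (gray = label) + JSON sidecar."""
    path = Path(path)
    if index.k > 255:
        raise ValueError("cannot serialize more than 255 labels to 8-bit PNG")
    Image.fromarray(index.labels.astype(np.uint8), mode="L").save(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"k": index.k, "modality": index.modality, "pixel_size": index.pixel_size}
        )
    )
    return path


def read_index_image(path: str | Path) -> IndexImage:
    path = Path(path)
    labels = np.asarray(Image.open(path).convert("L")).astype(np.int32)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return IndexImage(
        labels,
        k=int(meta.get("k", labels.max())),
        modality=meta.get("modality", "spectral"),
        pixel_size=meta.get("pixel_size"),
    )
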