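"""File I/O: MRC2014 image stacks/volumes, .tlt angle lists, flat run configs.

The MRC reader/writer implements the MRC2014 dialect directly on numpy: a
1024-byte little-endian header followed by the raster, nx fastest.  Output is
always mode 2 (32-bit float) with correct dmin/dmax/dmean/rms statistics;
input modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16) are accepted and
converted to float32.  Data arrays use the (nz, ny, nx) axis order, i.e. for a
tilt series (view, row-along-tilt-axis, detector column) and for a volume the
package-wide (slice-along-tilt-axis, thickness, width) convention, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TiltGeometry, make_geometry

_HEADER_BYTES = 1024

_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}

_HEADER_DTYPE = np.dtype([
    ("nx", "<i4"), ("ny", "<i4"), ("nz", "<i4"),
    ("mode", "<i4"),
    ("nxstart", "<i4"), ("nystart", "<i4"), ("nzstart", "<i4"),
    ("mx", "<i4"), ("my", "<i4"), ("mz", "<i4"),
    ("cella", "<f4", 3), ("cellb", "<f4", 3),
    ("mapc", "<i4"), ("mapr", "<i4"), ("maps", "<i4"),
    ("dmin", "<f4"), ("dmax", "<f4"), ("dmean", "<f4"),
    ("ispg", "<i4"), ("nsymbt", "<i4"),
    ("extra1", "V8"), ("exttyp", "S4"), ("nversion", "<i4"), ("extra2", "V84"),
    ("origin", "<f4", 3),
    ("map", "S4"), ("machst", "V4"),
    ("rms", "<f4"),
    ("nlabl", "<i4"), ("label", "S80", 10),
])
assert _HEADER_DTYPE.itemsize == _HEADER_BYTES


class MrcFormatError(ValueError):
    """Raised when a file does not parse as the supported MRC2014 subset."""


@dataclass(frozen=True)
class MrcHeader:
    """The header fields callers care about."""

    nx: int
    ny: int
    nz: int
    mode: int
    voxel_size: tuple[float, float, float]
    dmin: float
    dmax: float
    dmean: float
    rms: float


def read_mrc(path) -> tuple[np.ndarray, MrcHeader]:
    """Read an MRC2014 file; returns (float32 data of shape (nz, ny, nx), header)."""
    with open(path, "rb") as f:
        raw = f.read()
    if len(raw) < _HEADER_BYTES:
        raise MrcFormatError(f"{path}: file shorter than the 1024-byte MRC header")
    hdr = np.frombuffer(raw[:_HEADER_BYTES], dtype=_HEADER_DTYPE)[0]
    if bytes(hdr["map"]) not in (b"MAP ", b"MAP\x00"):
        raise MrcFormatError(f"{path}: MAP identifier missing (field 'map'); not an MRC2014 file")
    nx, ny, nz, mode = (int(hdr["nx"]), int(hdr["ny"]), int(hdr["nz"]), int(hdr["mode"]))
    if mode not in _MODE_DTYPES:
        raise MrcFormatError(f"{path}: unsupported MRC mode {mode} (field 'mode'); "
                             f"supported: {sorted(_MODE_DTYPES)}")
    if min(nx, ny, nz) <= 0:
        raise MrcFormatError(f"{path}: non-positive dimensions nx/ny/nz = {nx}/{ny}/{nz}")
    dtype = _MODE_DTYPES[mode]
    nsymbt = int(hdr["nsymbt"])
    need = _HEADER_BYTES + nsymbt + nx * ny * nz * dtype.itemsize
    if len(raw) < need:
        raise MrcFormatError(f"{path}: truncated data block (need {need} bytes for "
                             f"nx*ny*nz={nx}*{ny}*{nz}, have {len(raw)})")
    data = np.frombuffer(raw[_HEADER_BYTES + nsymbt : need], dtype=dtype)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    mx, my, mz = max(int(hdr["mx"]), 1), max(int(hdr["my"]), 1), max(int(hdr["mz"]), 1)
    cella = hdr["cella"]
    voxel = (float(cella[0]) / mx, float(cella[1]) / my, float(cella[2]) / mz)
    return data, MrcHeader(nx, ny, nz, mode, voxel,
                           float(hdr["dmin"]), float(hdr["dmax"]),
                           float(hdr["dmean"]), float(hdr["rms"]))


def write_mrc(path, data: np.ndarray, voxel_size: float | tuple = 1.0) -> None:
    """Write ``data`` (shape (nz, ny, nx) or (ny, nx)) as MRC2014 mode 2."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.size == 0:
        raise ValueError(f"expected a nonempty 2-D or 3-D array, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("MRC output requires finite data")
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    hdr = np.zeros(1, dtype=_HEADER_DTYPE)[0]
    hdr["nx"], hdr["ny"], hdr["nz"] = nx, ny, nz
    hdr["mode"] = 2
    hdr["mx"], hdr["my"], hdr["mz"] = nx, ny, nz
    hdr["cella"] = (voxel_size[0] * nx, voxel_size[1] * ny, voxel_size[2] * nz)
    hdr["cellb"] = (90.0, 90.0, 90.0)
    hdr["mapc"], hdr["mapr"], hdr["maps"] = 1, 2, 3
    hdr["dmin"] = float(data.min())
    hdr["dmax"] = float(data.max())
    hdr["dmean"] = float(data.mean(dtype=np.float64))
    hdr["ispg"] = 1 if nz > 1 else 0
    hdr["nversion"] = 20140
    hdr["map"] = b"MAP "
    hdr["machst"] = np.void(bytes((0x44, 0x44, 0x00, 0x00)))
    hdr["rms"] = float(data.std(dtype=np.float64))
    hdr["nlabl"] = 1
    hdr["label"][0] = b"blobtomo"
    with open(path, "wb") as f:
        f.write(hdr.tobytes())
        f.write(data.tobytes())


def read_tlt(path) -> np.ndarray:
    """Read a .tlt tilt-angle file (one angle in degrees per line, ascending).

    Blank lines are tolerated; a non-numeric line raises with its line number.
    """
    angles = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                angles.append(float(text))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: {text!r} is not a number") from None
    if not angles:
        raise ValueError(f"{path}: no tilt angles found")
    return np.asarray(angles, dtype=np.float64)


def write_tlt(path, angles_deg) -> None:
    with open(path, "w") as f:
        for a in np.asarray(angles_deg, dtype=np.float64):
            f.write(f"{a:.6f}\n")


def read_geometry(tlt_path, n_rays: int) -> TiltGeometry:
    """Read and validate a .tlt file into a :class:`TiltGeometry`."""
    return make_geometry(read_tlt(tlt_path), n_rays)


# documented run-configuration keys and their parsers
_CONFIG_SCHEMA = {
    "angles": str,          # path to a .tlt file
    "tilt_series": str,     # path to the tilt-series MRC
    "output": str,          # output path
    "iterations": int,
    "relaxation": float,
    "blob_a": float,
    "blob_m": int,
    "blob_alpha": float,
    "symmetry": int,        # blob-ELLR symmetry level 0..3
    "workers": int,
    "exchange": str,        # sync | async
    "seed": int,
    "footprint": str,       # blob | linear
    "thickness": int,       # reconstructed slice-plane depth n_z
}


def read_config(path) -> dict:
    """Parse a flat ``key = value`` run-configuration text file."""
    cfg = {}
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            if "=" not in text:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value', got {text!r}")
            key, value = (part.strip() for part in text.split("=", 1))
            if key not in _CONFIG_SCHEMA:
                raise ValueError(f"{path}: line {lineno}: unknown config key {key!r}")
            try:
                cfg[key] = _CONFIG_SCHEMA[key](value)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: cannot parse {value!r} "
                                 f"as {_CONFIG_SCHEMA[key].__name__}") from None
    return cfg


def write_config(path, cfg: dict) -> None:
    unknown = set(cfg) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    with open(path, "w") as f:
        for key, value in cfg.items():
            f.write(f"{key} = {value}\n")
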