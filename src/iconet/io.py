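"""File I/O: MRC2014 image stacks, .tlt tilt-angle files, traces and configs.

The MRC2014 container is the standard interchange format for electron
tomography stacks and volumes.  Reading supports modes 0 (int8), 1 (int16),
2 (float32) and 6 (uint16); writing always emits mode 2 (32-bit float),
little-endian, with the machine stamp set and the pixel size stored in the
cell dimensions.  Extended headers are skipped on read and never written.
The .tlt sidecar is plain text, one tilt angle in degrees per line, in
stack order.
"""

from __future__ import annotations

import struct

import numpy as np

from .tilt_geometry import TiltScheme

__all__ = [
    "read_mrc",
    "write_mrc",
    "read_tlt",
    "write_tlt",
    "write_trace_csv",
    "load_config_yaml",
    "save_config_yaml",
]

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MAP_OFFSET = 208  # bytes: 'MAP ' magic
_MACHST_OFFSET = 212


def write_mrc(stack: np.ndarray, path, voxel_size: float = 1.0) -> None:
    """Write a 2D image or 3D stack as a mode-2 (float32) MRC2014 file.

    ``stack`` is interpreted as (nz, ny, nx); a 2D array is written with
    nz = 1.  Float32 input round-trips bit-identically.
    """
    data = np.asarray(stack)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("stack must be 2D or 3D")
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)        # nx ny nz
    struct.pack_into("<i", header, 12, 2)                 # mode 2
    struct.pack_into("<3i", header, 28, nx, ny, nz)       # mx my mz
    struct.pack_into(                                     # cella (Å-agnostic: nm*px)
        "<3f", header, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)           # mapc mapr maps
    struct.pack_into(
        "<3f", header, 76,
        float(data.min()), float(data.max()), float(data.mean()),
    )
    struct.pack_into("<i", header, 92, 0)                  # ispg (image stack)
    struct.pack_into("<i", header, 96, 0)                  # nsymbt
    header[_MAP_OFFSET:_MAP_OFFSET + 4] = b"MAP "
    header[_MACHST_OFFSET:_MACHST_OFFSET + 4] = bytes([0x44, 0x44, 0x00, 0x00])
    struct.pack_into("<f", header, 216, float(data.std()))  # rms
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def read_mrc(path):
    """Read an MRC2014 file; returns ``(stack, voxel_size)``.

    The stack has shape (nz, ny, nx) in the file's dtype (float32 for
    mode 2).  Big-endian files (machine stamp 0x11) are byte-swapped;
    truncated files raise without returning a partial array.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header ({len(header)} bytes)")
        magic = header[_MAP_OFFSET:_MAP_OFFSET + 4]
        if magic != b"MAP ":
            raise ValueError(
                f"{path}: bad MAP magic in header word 53: {magic!r}"
            )
        stamp = header[_MACHST_OFFSET]
        if stamp == 0x44:
            bo = "<"
        elif stamp == 0x11:
            bo = ">"
        else:
            raise ValueError(
                f"{path}: unrecognized machine stamp byte 0x{stamp:02x}"
            )
        nx, ny, nz = struct.unpack_from(f"{bo}3i", header, 0)
        (mode,) = struct.unpack_from(f"{bo}i", header, 12)
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        (mx,) = struct.unpack_from(f"{bo}i", header, 28)
        (xlen,) = struct.unpack_from(f"{bo}f", header, 40)
        (nsymbt,) = struct.unpack_from(f"{bo}i", header, 96)
        if nsymbt:
            fh.seek(nsymbt, 1)  # skip extended header
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder(bo)
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) != count * dtype.itemsize:
            raise ValueError(
                f"{path}: truncated data block "
                f"({len(raw)} of {count * dtype.itemsize} bytes)"
            )
    data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    voxel_size = xlen / mx if mx else 1.0
    return data.astype(data.dtype.newbyteorder("=")), float(voxel_size)


def read_tlt(path, pixel_size: float = 1.0) -> TiltScheme:
    """Read a .tlt file (one decimal tilt angle in degrees per line)."""
    angles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                angles.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric tilt angle on line {lineno}: {text!r}"
                ) from None
    if not angles:
        raise ValueError(f"{path}: empty tilt-angle file")
    return TiltScheme(np.array(angles), pixel_size)


def write_tlt(scheme: TiltScheme, path) -> None:
    with open(path, "w") as fh:
        for angle in scheme.angles:
            fh.write(f"{angle:.4f}\n")


def check_pairing(stack: np.ndarray, scheme: TiltScheme) -> None:
    """Assert an MRC stack and a tilt scheme describe the same tilt series."""
    if stack.shape[0] != scheme.n_tilts:
        raise ValueError(
            f"stack depth {stack.shape[0]} does not match "
            f"tilt-angle count {scheme.n_tilts}"
        )


def load_config_yaml(path) -> dict:
    """Read a YAML mapping of reconstruction settings (CLI flag names)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return data


def save_config_yaml(config: dict, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_trace_csv(trace, path) -> None:
    """Write an IterationTrace as CSV (iteration, residual_norm, alpha, q)."""
    with open(path, "w") as fh:
        fh.write("iteration,residual_norm,alpha,q\n")
        for i, (rn, a, q) in enumerate(
            zip(trace.residual_norm, trace.alpha, trace.q_before)
        ):
            fh.write(f"{i},{rn},{a},{q}\n")
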