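"""Minimal Interfile-dialect serialisation for sinograms and voxel volumes.

A text header (``.hs`` for projection data, ``.hv`` for volumes) paired with a
raw little-endian float32 binary payload (``.s``/``.v``).  Only the key subset
needed for interchange is implemented: magic line, data file name, number
format, byte order, matrix sizes, scaling factor, plus toolkit-specific keys
(scanner parameters, geometry class).  Write-then-read round trips are exact
on values and metadata.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import numpy as np

from .geometry import ScannerSpec
from .projdata import ProjData
from .volume import VoxelVolume

_MAGIC = "!INTERFILE  :="
_SPEC_KEYS = ("n_sectors", "blocks_per_sector_trans", "blocks_per_sector_axial",
              "crystals_per_block_trans", "crystals_per_block_axial",
              "crystal_pitch_trans", "crystal_pitch_axial", "crystal_depth",
              "inter_block_gap", "apothem")


def _header_lines(pairs):
    lines = [_MAGIC]
    for k, v in pairs:
        lines.append(f"{k} := {'' if v is None else v}")
    lines.append("!END OF INTERFILE :=")
    return "\n".join(lines) + "\n"


def _parse_header(text: str) -> dict:
    out = {}
    first = True
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if first:
            if not line.startswith("!INTERFILE"):
                raise ValueError("not an Interfile header (missing magic line)")
            first = False
            continue
        if ":=" not in line:
            raise ValueError(f"malformed header line: {raw!r}")
        key, _, val = line.partition(":=")
        out[key.strip().lstrip("!").lower()] = val.strip()
    if first:
        raise ValueError("empty header")
    return out


def _spec_pairs(spec: ScannerSpec):
    d = asdict(spec)
    return [(f"scanner {k}", d[k]) for k in _SPEC_KEYS]


def _spec_from_header(h: dict) -> ScannerSpec:
    kw = {}
    for k in _SPEC_KEYS:
        val = h.get(f"scanner {k}", "")
        if val in ("", "None"):
            kw[k] = None if k == "apothem" else 0
        elif k.startswith(("crystal_pitch", "crystal_depth", "inter_block_gap", "apothem")):
            kw[k] = float(val)
        else:
            kw[k] = int(val)
    return ScannerSpec(**kw)


def write_interfile(obj, path: str) -> None:
    """Write a :class:`ProjData` (``.hs``/``.s``) or :class:`VoxelVolume`
    (``.hv``/``.v``) as header + raw float32 little-endian payload."""
    base, ext = os.path.splitext(path)
    if isinstance(obj, ProjData):
        hdr_path = base + ".hs"
        data_path = base + ".s"
    elif isinstance(obj, VoxelVolume):
        hdr_path = base + ".hv"
        data_path = base + ".v"
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")

    values = np.ascontiguousarray(obj.values, dtype="<f4")
    pairs = [("name of data file", os.path.basename(data_path)),
             ("number format", "float"),
             ("number of bytes per pixel", 4),
             ("imagedata byte order", "LITTLEENDIAN"),
             ("number of dimensions", values.ndim)]
    # matrix sizes: [1] is the fastest-varying dimension
    for i, n in enumerate(reversed(values.shape), start=1):
        pairs.append((f"matrix size [{i}]", n))
    pairs.append(("data scaling factor", 1.0))

    if isinstance(obj, ProjData):
        pairs += [("polypet data type", "projdata"),
                  ("geometry class", obj.geometry_class or ""),
                  ("tangential size", obj.tangential_size),
                  ("maximum ring difference", obj.max_ring_diff),
                  ("rebinned", int(obj.rebinned))]
    else:
        pairs += [("polypet data type", "volume")]
        for i, ax in enumerate("xyz"):
            pairs.append((f"scaling factor (mm/pixel) [{i + 1}]", obj.voxel_size[i]))
            pairs.append((f"first pixel offset (mm) [{i + 1}]", obj.origin[i]))
    pairs += _spec_pairs(obj.spec) if getattr(obj, "spec", None) is not None else []
    with open(hdr_path, "w") as fh:
        fh.write(_header_lines(pairs))
    values.tofile(data_path)


def read_interfile(path: str):
    """Read a header written by :func:`write_interfile`; returns the object."""
    with open(path) as fh:
        h = _parse_header(fh.read())
    data_path = os.path.join(os.path.dirname(path), h["name of data file"])
    ndim = int(h["number of dimensions"])
    shape = tuple(int(h[f"matrix size [{i}]"]) for i in range(ndim, 0, -1))
    if h.get("number format", "float") != "float" or int(h.get("number of bytes per pixel", 4)) != 4:
        raise ValueError("only float32 payloads are supported")
    raw = np.fromfile(data_path, dtype="<f4")
    expected = int(np.prod(shape))
    if raw.size != expected:
        raise ValueError(f"binary payload has {raw.size} values, header declares {expected}")
    values = raw.reshape(shape).astype(np.float64)

    kind = h.get("polypet data type", "")
    if kind == "projdata":
        spec = _spec_from_header(h)
        gc = h.get("geometry class") or None
        return ProjData(spec=spec, values=values, geometry_class=gc,
                        tangential_size=int(h["tangential size"]),
                        max_ring_diff=int(h["maximum ring difference"]),
                        rebinned=bool(int(h.get("rebinned", 0))))
    if kind == "volume":
        voxel_size = tuple(float(h[f"scaling factor (mm/pixel) [{i + 1}]"]) for i in range(3))
        origin = tuple(float(h[f"first pixel offset (mm) [{i + 1}]"]) for i in range(3))
        return VoxelVolume(values=values, voxel_size=voxel_size, origin=origin)
    raise ValueError(f"unrecognised data type {kind!r}")
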