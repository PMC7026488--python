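"""Decode ParaVision 2dseq reconstructions and write NIfTI-1 files.

The 2dseq file is a flat stream of frames of raw integers (or floats),
x-fastest, scaled per frame by slope/offset arrays from ``visu_pars``.
With ``VisuCoreDim`` 3 each frame is a volume and the frame count is the
number of timepoints; with ``VisuCoreDim`` 2 each frame is a slice of a
single volume.  More exotic frame groupings (multi-echo, multi-channel)
are rejected rather than guessed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .jcampdx import ParameterDict

__all__ = [
    "VolumetricImage",
    "CorruptDataError",
    "UnsupportedFormatError",
    "WORD_TYPES",
    "BYTE_ORDERS",
    "decode_2dseq",
    "build_affine",
    "write_nifti",
]

logger = logging.getLogger(__name__)

WORD_TYPES = {
    "_8BIT_UNSGN_INT": np.dtype(np.uint8),
    "_16BIT_SGN_INT": np.dtype(np.int16),
    "_32BIT_SGN_INT": np.dtype(np.int32),
    "_32BIT_FLOAT": np.dtype(np.float32),
}

BYTE_ORDERS = {"littleEndian": "<", "bigEndian": ">"}


class CorruptDataError(ValueError):
    """The 2dseq byte count disagrees with the visu_pars geometry."""


class UnsupportedFormatError(ValueError):
    """visu_pars describes a layout this decoder does not handle."""


@dataclass
class VolumetricImage:
    """Decoded voxel data plus spatial transform and timing.

    ``voxels`` holds scaled values (``raw * slope + offset``); ``raw``
    keeps the unscaled integers for lossless re-encoding.  ``value_slope``
    and ``value_offset`` are the scalar scaling when it is uniform across
    frames, else ``None`` (scaling already baked into ``voxels``).
    """

    voxels: np.ndarray  # (x, y, z[, t])
    affine: np.ndarray  # 4x4, millimetres
    repetition_time: float | None  # seconds, 4D only
    value_slope: float | None
    value_offset: float | None
    raw: np.ndarray | None = None


def _as_list(value, length: int | None = None) -> list:
    if isinstance(value, (list, tuple)):
        out = list(value)
    elif value is None:
        out = []
    else:
        out = [value]
    if length is not None and len(out) == 1 and length > 1:
        out = out * length
    return out


def decode_2dseq(data: bytes, visu: ParameterDict) -> VolumetricImage:
    """Decode raw 2dseq bytes using visu_pars metadata.

    Raises :class:`CorruptDataError` when the byte count does not equal
    ``wordsize * prod(matrix) * frames`` and :class:`UnsupportedFormatError`
    for unknown word types / byte orders / core dimensions.
    """
    word_type = visu.get("VisuCoreWordType")
    if word_type not in WORD_TYPES:
        raise UnsupportedFormatError(f"unknown word type {word_type!r}")
    byte_order = visu.get("VisuCoreByteOrder", "littleEndian")
    if byte_order not in BYTE_ORDERS:
        raise UnsupportedFormatError(f"unknown byte order {byte_order!r}")
    dtype = WORD_TYPES[word_type].newbyteorder(BYTE_ORDERS[byte_order])

    size = [int(v) for v in _as_list(visu.get("VisuCoreSize"))]
    if not size:
        raise UnsupportedFormatError("missing VisuCoreSize")
    dim = int(visu.get("VisuCoreDim", len(size)))
    if dim != len(size):
        raise UnsupportedFormatError(
            f"VisuCoreDim {dim} inconsistent with VisuCoreSize {size}"
        )
    if dim not in (2, 3):
        raise UnsupportedFormatError(f"unsupported VisuCoreDim {dim}")
    frames = int(visu.get("VisuCoreFrameCount", 1))

    expected = dtype.itemsize * int(np.prod(size)) * frames
    if len(data) != expected:
        raise CorruptDataError(
            f"2dseq size mismatch: expected {expected} bytes "
            f"({'x'.join(map(str, size))} x {frames} frames of "
            f"{dtype.itemsize}-byte words), got {len(data)}"
        )

    raw = np.frombuffer(data, dtype=dtype)
    # frames are stored consecutively, each frame x-fastest
    raw = raw.reshape((frames, *size[::-1]))

    slopes = [float(s) for s in _as_list(visu.get("VisuCoreDataSlope", 1.0), frames)]
    offsets = [float(o) for o in _as_list(visu.get("VisuCoreDataOffs", 0.0), frames)]
    if len(slopes) != frames or len(offsets) != frames:
        raise CorruptDataError(
            f"slope/offset arrays ({len(slopes)}/{len(offsets)}) "
            f"do not match frame count {frames}"
        )
    scaled = raw.astype(np.float64)
    for f in range(frames):
        scaled[f] = scaled[f] * slopes[f] + offsets[f]

    uniform = len(set(slopes)) == 1 and len(set(offsets)) == 1
    if dim == 3:
        # (frames, z, y, x) -> (x, y, z, t); frames are volumes
        voxels = scaled.transpose(3, 2, 1, 0)
        raw_xyzt = raw.transpose(3, 2, 1, 0)
        if frames == 1:
            voxels = voxels[..., 0]
            raw_xyzt = raw_xyzt[..., 0]
    else:
        # (frames, y, x) -> (x, y, z); frames are slices of one volume
        voxels = scaled.transpose(2, 1, 0)
        raw_xyzt = raw.transpose(2, 1, 0)

    tr = None
    if voxels.ndim == 4:
        tr_ms = visu.get("VisuAcqRepetitionTime")
        if isinstance(tr_ms, list):
            tr_ms = tr_ms[0] if tr_ms else None
        if isinstance(tr_ms, (int, float)) and tr_ms > 0:
            tr = float(tr_ms) / 1000.0

    return VolumetricImage(
        voxels=np.ascontiguousarray(voxels),
        affine=build_affine(visu),
        repetition_time=tr,
        value_slope=slopes[0] if uniform else None,
        value_offset=offsets[0] if uniform else None,
        raw=np.ascontiguousarray(raw_xyzt),
    )


def build_affine(visu: ParameterDict) -> np.ndarray:
    """Build the voxel-to-world (mm) transform from visu_pars geometry.

    Voxel sizes are ``VisuCoreExtent / VisuCoreSize``; the 3x3 block is
    the transposed ``VisuCoreOrientation`` matrix times the voxel-size
    diagonal, and the translation is ``VisuCorePosition``.  Missing
    geometry degrades to a diagonal affine with a logged warning.
    """
    size = [int(v) for v in _as_list(visu.get("VisuCoreSize"))]
    extent = [float(v) for v in _as_list(visu.get("VisuCoreExtent"))]
    while len(size) < 3:
        size.append(1)
    if len(extent) < len(size):
        logger.warning(
            "%s: missing/short VisuCoreExtent, assuming unit voxels",
            visu.source_path,
        )
        extent = extent + [float(s) for s in size[len(extent):]]
    vox = np.array([e / s for e, s in zip(extent[:3], size[:3])], dtype=float)

    affine = np.eye(4)
    orientation = _as_list(visu.get("VisuCoreOrientation"))
    if len(orientation) >= 9:
        rot = np.array(orientation[:9], dtype=float).reshape(3, 3)
        affine[:3, :3] = rot.T @ np.diag(vox)
    else:
        if orientation:
            logger.warning(
                "%s: short VisuCoreOrientation, using diagonal affine",
                visu.source_path,
            )
        affine[:3, :3] = np.diag(vox)
    position = _as_list(visu.get("VisuCorePosition"))
    if len(position) >= 3:
        affine[:3, 3] = [float(v) for v in position[:3]]
    if np.linalg.det(affine[:3, :3]) == 0:
        raise UnsupportedFormatError("degenerate orientation matrix in visu_pars")
    return affine


def write_nifti(
    image: VolumetricImage,
    path: str | Path,
    keep_int: bool = False,
    canonical: bool = False,
) -> Path:
    """Write a gzip-compressed NIfTI-1 file deterministically.

    By default scaling is baked into float32 data.  ``keep_int`` preserves
    the raw integer data and records uniform slope/offset in the scl
    header fields instead (falls back to baking when scaling varies per
    frame).  ``canonical`` reorients to the closest RAS orientation.
    The gzip stream is written with a zeroed mtime so identical inputs
    produce byte-identical files.
    """
    path = Path(path)
    as_int = keep_int and image.raw is not None and image.value_slope is not None
    if as_int:
        data = image.raw
        if data.dtype.byteorder == ">":
            data = data.astype(data.dtype.newbyteorder("="))
        img = nib.Nifti1Image(data, image.affine)
    else:
        if keep_int:
            logger.warning(
                "%s: per-frame scaling varies, baking values into float32", path
            )
        img = nib.Nifti1Image(image.voxels.astype(np.float32), image.affine)
    if canonical:
        img = nib.as_closest_canonical(img)
    header = img.header
    header.set_xyzt_units("mm", "sec")
    if img.ndim == 4 and image.repetition_time:
        zooms = header.get_zooms()
        header.set_zooms((*zooms[:3], image.repetition_time))
    payload = img.to_bytes()
    if as_int:
        # nibabel recomputes scl_* during serialization, so the slope and
        # intercept are patched at their fixed NIfTI-1 header offsets.
        scl = np.array(
            [image.value_slope, image.value_offset], dtype="<f4"
        ).tobytes()
        payload = payload[:112] + scl + payload[120:]
    # fileobj + zeroed mtime keeps the gzip stream free of the file name
    # and timestamp, so identical inputs give byte-identical outputs
    with open(path, "wb") as raw_handle:
        with gzip.GzipFile(
            filename="", fileobj=raw_handle, mode="wb", compresslevel=6, mtime=0
        ) as handle:
            handle.write(payload)
    return path
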