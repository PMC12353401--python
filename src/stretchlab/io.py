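"""Readers and writers for stacks, displacement fields, strain fields.

On-disk conventions:

* Image stacks: multi-page TIFF, any of 8/16-bit integer or 32-bit float.
* Displacement fields: 3-page float32 TIFF in page order u, v, valid,
  plus a JSON sidecar (`<file>.json`) with source/target indices.
* Strain fields: 3-page float32 TIFF in page order eps_xx, eps_yy, eps_xy,
  plus a JSON sidecar with kind, interval and pixel size.
* Raw pixel-by-pixel displacement text files: one header line
  ``width height``, then H rows of W whitespace-separated x-displacements,
  then H rows of W y-displacements.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from .strain import DisplacementField, FrameStack, StrainField

logger = logging.getLogger(__name__)


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def read_stack(path, pixel_size: float | None = None) -> FrameStack:
    """Read a multi-page TIFF time series into a FrameStack.

    Pixel size resolution order: explicit argument > JSON sidecar written by
    :func:`write_stack` > TIFF XResolution tag > 1.0 with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"ragged page shapes in {path}: {sorted(shapes)}")
        frames = tf.asarray()
        res = tf.pages[0].tags.get("XResolution")
    if frames.ndim == 2:
        frames = frames[None]

    times = None
    meta_px = None
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        meta_px = meta.get("pixel_size")
        if meta.get("times") is not None:
            times = np.asarray(meta["times"], dtype=float)

    if pixel_size is None:
        if meta_px is not None:
            pixel_size = float(meta_px)
        elif res is not None and res.value[0] not in (0, 1):
            # TIFF stores pixels per unit; invert to unit per pixel
            num, den = res.value
            pixel_size = den / num
        else:
            logger.warning("no pixel size for %s; defaulting to 1.0 um/px", path)
            pixel_size = 1.0
    return FrameStack(frames, pixel_size=pixel_size, times=times)


def write_stack(path, stack: FrameStack) -> None:
    """Write a FrameStack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "pixel_size": stack.pixel_size,
        "times": list(map(float, stack.times)),
    }))


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------

def save_displacement(path, field: DisplacementField) -> None:
    """Serialize a displacement field as float32 TIFF pages u, v, valid."""
    path = Path(path)
    pages = np.stack([field.u, field.v, field.valid.astype(float)]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "page_order": ["u", "v", "valid"],
        "source_index": field.source_index,
        "target_index": field.target_index,
    }))


def _load_displacement_text(path: Path, shape: tuple[int, int] | None) -> DisplacementField:
    lines = path.read_text().splitlines()
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise ValueError(f"{path}: empty displacement file")
    lineno, header = content[0]
    try:
        w, h = (int(tok) for tok in header.split())
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: expected header 'width height', got {header!r}"
        ) from None
    if shape is not None and (h, w) != tuple(shape):
        raise ValueError(
            f"{path}: dimension mismatch: expected {tuple(shape)} (H, W), "
            f"found ({h}, {w})"
        )
    rows = content[1:]
    if len(rows) != 2 * h:
        raise ValueError(
            f"{path}: expected {2 * h} data rows (u block then v block), "
            f"found {len(rows)}"
        )
    blocks = []
    for block_rows in (rows[:h], rows[h:]):
        block = np.empty((h, w), dtype=float)
        for r, (lineno, ln) in enumerate(block_rows):
            vals = ln.split()
            if len(vals) != w:
                raise ValueError(
                    f"{path}:{lineno}: expected {w} values, found {len(vals)}"
                )
            try:
                block[r] = [float(v) for v in vals]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed number") from None
        blocks.append(block)
    return DisplacementField(blocks[0], blocks[1])


def load_displacement(path, shape: tuple[int, int] | None = None) -> DisplacementField:
    """Load a displacement field from TIFF serialization or raw text.

    TIFF files must follow the u/v/valid page order written by
    :func:`save_displacement`.  Text files follow the raw pixel-by-pixel
    dialect (``width height`` header, u block, v block).  ``shape`` (H, W),
    when given, is checked against the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such displacement file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(path).astype(float)
        if pages.ndim != 3 or pages.shape[0] < 2:
            raise ValueError(f"{path}: expected pages u, v[, valid]")
        valid = pages[2] > 0.5 if pages.shape[0] > 2 else None
        src, tgt = 0, 1
        sc = _sidecar(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
            src = meta.get("source_index", 0)
            tgt = meta.get("target_index", 1)
        field = DisplacementField(pages[0], pages[1], valid,
                                  source_index=src, target_index=tgt)
        if shape is not None and field.shape != tuple(shape):
            raise ValueError(
                f"{path}: dimension mismatch: expected {tuple(shape)}, "
                f"found {field.shape}"
            )
        return field
    return _load_displacement_text(path, shape)


# ---------------------------------------------------------------------------
# Strain fields
# ---------------------------------------------------------------------------

def save_strain(path, field: StrainField, pixel_size: float = 1.0) -> None:
    """Serialize a strain field as float32 TIFF pages eps_xx, eps_yy, eps_xy."""
    path = Path(path)
    xx = np.where(field.valid, field.eps_xx, np.nan)
    yy = np.where(field.valid, field.eps_yy, np.nan)
    xy = np.where(field.valid, field.eps_xy, np.nan)
    tifffile.imwrite(path, np.stack([xx, yy, xy]).astype(np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "page_order": ["eps_xx", "eps_yy", "eps_xy"],
        "kind": field.kind,
        "interval": list(field.interval),
        "pixel_size": pixel_size,
    }))


def load_strain(path) -> StrainField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such strain file: {path}")
    pages = tifffile.imread(path).astype(float)
    if pages.ndim != 3 or pages.shape[0] != 3:
        raise ValueError(f"{path}: expected 3 pages eps_xx, eps_yy, eps_xy")
    kind, interval = "step_eng", (0.0, 1.0)
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        kind = meta.get("kind", kind)
        interval = tuple(meta.get("interval", interval))
    return StrainField(pages[0], pages[1], pages[2], kind=kind, interval=interval)
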