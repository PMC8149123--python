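"""Image-stack container and TIFF / results I/O.

The canonical in-memory container is :class:`ImageStack4D`: a (t, z, y, x)
array with physical metadata (pixel size, z step, frame interval). Stacks are
written as multi-page TIFF with the metadata embedded as JSON in the image
description, so a write/read round-trip is lossless, including dtype.

Result tables go to CSV (UTF-8, header row), fits/summaries to JSON, and
``write_results`` emits a manifest with SHA-256 content hashes so identical
runs can be compared byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

log = logging.getLogger(__name__)

_META_KEYS = ("axes", "pixel_size_um", "z_step_um", "frame_interval_s", "channel")


@dataclass
class ImageStack4D:
    """Fluorescence movie indexed (t, z, y, x) with physical metadata.

    Parameters
    ----------
    data
        Intensity array, shape (t, z, y, x); finite and non-negative.
    pixel_size_um
        Lateral pixel size in micrometres.
    z_step_um
        Axial spacing between z planes in micrometres.
    frame_interval_s
        Time between frames in seconds.
    channel
        Free-text channel label.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0
    frame_interval_s: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"stack must be 4D (t, z, y, x), got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise FormatError(f"all stack dimensions must be >= 1, got {self.data.shape}")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0 or self.z_step_um <= 0:
            raise FormatError("pixel_size_um, z_step_um and frame_interval_s must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("stack intensities must be finite")
        if np.issubdtype(self.data.dtype, np.floating) and float(self.data.min()) < 0:
            raise FormatError("stack intensities must be >= 0")

    # convenience accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.data.shape)

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_s


def write_stack(stack: ImageStack4D, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF (pages ordered T fastest over Z).

    Metadata is stored as a JSON image description and restored verbatim by
    :func:`read_stack`.
    """
    path = Path(path)
    meta = {
        "axes": "TZYX",
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel": stack.channel,
        "shape": list(stack.shape),
    }
    t, z, y, x = stack.shape
    tifffile.imwrite(path, stack.data.reshape(t * z, y, x), description=json.dumps(meta))
    return path


def read_stack(path: str | Path, *, axes: str = "TZYX", **overrides) -> ImageStack4D:
    """Read a multi-page TIFF into an :class:`ImageStack4D`.

    Parameters
    ----------
    path
        TIFF written by :func:`write_stack` or any multi-page TIFF.
    axes
        Page ordering for plain TIFFs: ``"TZYX"`` (time fastest across pages,
        the default export convention) or ``"ZTYX"``.
    overrides
        ``n_z``, ``n_frames``, ``pixel_size_um``, ``z_step_um``,
        ``frame_interval_s``, ``channel`` — used when the file carries no
        metadata. A 3D series with ``n_z`` unset gets a singleton z axis.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            arr = series.asarray()
            desc = tif.pages[0].description or ""
    except (OSError, ValueError, IndexError) as exc:  # pragma: no cover - passthrough
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    meta: dict = {}
    if desc.strip().startswith("{"):
        try:
            parsed = json.loads(desc)
            meta = {k: parsed[k] for k in _META_KEYS if k in parsed}
            if "shape" in parsed:
                meta["shape"] = parsed["shape"]
        except (json.JSONDecodeError, TypeError):
            meta = {}

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        shape = meta.get("shape")
        if shape is not None and len(shape) == 4:
            arr = arr.reshape(shape)
        else:
            n_z = int(overrides.pop("n_z", 0) or 0)
            n_t = int(overrides.pop("n_frames", 0) or 0)
            pages = arr.shape[0]
            if n_z and n_t and n_z * n_t != pages:
                raise FormatError(
                    f"{pages} pages cannot be reshaped to t={n_t}, z={n_z}")
            if n_z == 0 and n_t == 0:
                n_z, n_t = 1, pages
            elif n_z == 0:
                n_z = pages // n_t
            elif n_t == 0:
                n_t = pages // n_z
            if n_z * n_t != pages:
                raise FormatError(f"{pages} pages not divisible into t={n_t} x z={n_z}")
            if axes.upper().startswith("TZ"):
                # time fastest-varying across pages: page index = z * n_t + t
                arr = arr.reshape(n_z, n_t, *arr.shape[1:]).transpose(1, 0, 2, 3)
            else:
                arr = arr.reshape(n_t, n_z, *arr.shape[1:])
    elif arr.ndim != 4:
        raise FormatError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")

    kwargs = {}
    for key in ("pixel_size_um", "z_step_um", "frame_interval_s", "channel"):
        if key in overrides:
            kwargs[key] = overrides[key]
        elif key in meta:
            kwargs[key] = meta[key]
        else:
            if key != "channel":
                log.warning("%s missing from %s; using default", key, path.name)
    overrides_left = set(overrides) - {"pixel_size_um", "z_step_um", "frame_interval_s",
                                       "channel", "n_z", "n_frames"}
    if overrides_left:
        raise FormatError(f"unknown read_stack overrides: {sorted(overrides_left)}")
    return ImageStack4D(arr, **kwargs)


# ---------------------------------------------------------------------------
# results writer


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def dump_json(obj, path: str | Path) -> Path:
    """Write a JSON file with deterministic key order and formatting."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(out_dir: str | Path, *, tables: dict[str, pd.DataFrame] | None = None,
                  fits: dict[str, dict] | None = None,
                  annotations: dict[str, dict] | None = None) -> dict:
    """Write tables (CSV), fits and annotations (JSON) plus a hash manifest.

    Re-running on identical inputs reproduces identical bytes, so manifests
    from two runs can be compared directly. Returns the manifest dict; it is
    also written to ``manifest.json`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {out_dir}: {exc}") from exc

    written: list[Path] = []
    for name, df in (tables or {}).items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
    for group, items in (("fit", fits), ("annotation", annotations)):
        for name, obj in (items or {}).items():
            p = out_dir / f"{name}.json"
            dump_json(obj, p)
            written.append(p)

    manifest = {
        "files": sorted(
            ({"path": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
             for p in written),
            key=lambda d: d["path"],
        )
    }
    dump_json(manifest, out_dir / "manifest.json")
    return manifest
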