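"""Multi-page TIFF stack I/O with JSON metadata sidecars.

Volumes travel as plain multi-page TIFFs readable by any viewer; geometry,
camera model, seeds and the ordered processing history live in a JSON
sidecar next to the TIFF (``<stem>.json``).  Every processing stage appends
exactly one history record, so an output volume's provenance chain
reconstructs the command sequence that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["StackIOError", "StackMetadata", "read_stack", "write_stack", "sidecar_path"]


class StackIOError(RuntimeError):
    """Raised for unreadable, unwritable, or unsupported stack files."""


@dataclass
class StackMetadata:
    """Sidecar metadata: grid geometry, acquisition parameters, provenance."""

    voxel_um: tuple[float, float, float] | None = None  # (z, y, x)
    geometry: dict = field(default_factory=dict)
    camera: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def append_stage(self, stage: str, parameters: dict) -> None:
        from lsfmkit import __version__

        self.history.append(
            {"stage": stage, "parameters": parameters, "software_version": __version__}
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["voxel_um"] is not None:
            d["voxel_um"] = list(d["voxel_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StackMetadata":
        voxel = d.get("voxel_um")
        return cls(
            voxel_um=tuple(voxel) if voxel is not None else None,
            geometry=d.get("geometry", {}),
            camera=d.get("camera", {}),
            seeds=d.get("seeds", {}),
            history=d.get("history", []),
            extra=d.get("extra", {}),
        )


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def read_stack(path: str | Path) -> tuple[np.ndarray, StackMetadata]:
    """Read a multi-page TIFF and its JSON sidecar.

    A missing sidecar yields default metadata with a warning; a corrupt or
    non-TIFF file raises :class:`StackIOError`.
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"no such file: {path}")
    try:
        volume = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types for bad input
        raise StackIOError(f"not a readable TIFF: {path}") from exc
    if volume.dtype not in (np.uint8, np.uint16, np.float32):
        raise StackIOError(f"unsupported bit depth {volume.dtype} in {path}")
    side = sidecar_path(path)
    if side.exists():
        meta = StackMetadata.from_dict(json.loads(side.read_text()))
    else:
        warnings.warn(f"no metadata sidecar for {path}; applying defaults", stacklevel=2)
        meta = StackMetadata()
    return volume, meta


def write_stack(
    volume: np.ndarray,
    metadata: StackMetadata,
    path: str | Path,
    dtype: str = "uint16",
    clamp: bool = True,
) -> None:
    """Write a volume as multi-page TIFF plus JSON sidecar.

    16-bit (and 8-bit) casts are clamped to the representable range when
    ``clamp`` is set; otherwise an out-of-range volume raises.
    """
    path = Path(path)
    arr = np.asarray(volume)
    if dtype == "uint16":
        limit = 65535
    elif dtype == "uint8":
        limit = 255
    elif dtype == "float32":
        limit = None
    else:
        raise StackIOError(f"unsupported output depth {dtype!r}")
    if limit is not None:
        if clamp:
            arr = np.clip(np.round(arr.astype(float)), 0, limit)
        elif arr.min() < 0 or arr.max() > limit:
            raise StackIOError(
                f"value range [{arr.min()}, {arr.max()}] exceeds {dtype} without clamp"
            )
        arr = arr.astype(dtype)
    else:
        arr = arr.astype(np.float32)
    try:
        tifffile.imwrite(path, arr)
    except OSError as exc:
        raise StackIOError(f"cannot write {path}") from exc
    sidecar_path(path).write_text(json.dumps(metadata.to_dict(), indent=2, sort_keys=True))
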