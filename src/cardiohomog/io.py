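"""TIFF + JSON-sidecar I/O for label volumes and channel stacks.

Volumes are written as multi-page TIFF (one page per z-slice, rows = y,
columns = x) next to a JSON sidecar carrying the voxel size, the axis
convention, and — for label volumes — the label dictionary.  The sidecar
makes every file self-describing; reading refuses to guess when it is
missing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

from .volumes import CHANNEL_NAMES, LABEL_NAMES, ChannelStack, LabelVolume

_AXES_NOTE = "pages=z, rows=y, cols=x; in-memory arrays are indexed [x, y, z]"


class SidecarError(IOError):
    """Raised when a TIFF lacks its JSON metadata sidecar."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _to_pages(arr: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))


def _from_pages(arr: np.ndarray) -> np.ndarray:
    return np.transpose(arr, (2, 1, 0))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_labels(labels: LabelVolume, path: Union[str, Path]) -> Path:
    """Write a label volume as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, _to_pages(labels.labels.astype(np.uint8)))
    sidecar = {
        "kind": "labels",
        "voxel_size_nm": labels.voxel_size,
        "axes": _AXES_NOTE,
        "label_dictionary": {str(k): v for k, v in LABEL_NAMES.items()},
        "meta": _jsonable({k: v for k, v in labels.meta.items()
                           if k in ("spec", "achieved", "alignment")}),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def write_stack(stack: ChannelStack, path: Union[str, Path]) -> Path:
    """Write a channel stack as a (C, Z, Y, X) multi-page TIFF + sidecar."""
    path = Path(path)
    names = list(stack.channels)
    data = np.stack([_to_pages(stack.channels[n]) for n in names])
    tifffile.imwrite(path, data.astype(np.float32))
    sidecar = {
        "kind": "channels",
        "voxel_size_nm": stack.voxel_size,
        "axes": "C then " + _AXES_NOTE,
        "channels": names,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise SidecarError(
            f"missing JSON sidecar {sc.name}: cannot recover voxel size, "
            "axis convention or label dictionary for {path.name}".format(path=path))
    return json.loads(sc.read_text())


def read_labels(path: Union[str, Path]) -> LabelVolume:
    path = Path(path)
    meta = _load_sidecar(path)
    if meta.get("kind") != "labels":
        raise ValueError(f"{path} is not a label volume (kind={meta.get('kind')!r})")
    data = tifffile.imread(path)
    return LabelVolume(labels=_from_pages(data),
                       voxel_size=float(meta["voxel_size_nm"]),
                       meta=meta.get("meta", {}))


def read_stack(path: Union[str, Path]) -> ChannelStack:
    path = Path(path)
    meta = _load_sidecar(path)
    if meta.get("kind") != "channels":
        raise ValueError(f"{path} is not a channel stack (kind={meta.get('kind')!r})")
    data = tifffile.imread(path)
    names = meta["channels"]
    if data.shape[0] != len(names):
        raise ValueError(
            f"channel count mismatch: sidecar lists {len(names)}, file has "
            f"{data.shape[0]}")
    return ChannelStack(
        channels={n: _from_pages(data[i]) for i, n in enumerate(names)},
        voxel_size=float(meta["voxel_size_nm"]),
    )


def read_volume(path: Union[str, Path]):
    """Dispatch on the sidecar's kind: labels or channels."""
    meta = _load_sidecar(Path(path))
    if meta.get("kind") == "labels":
        return read_labels(path)
    if meta.get("kind") == "channels":
        return read_stack(path)
    raise ValueError(f"unknown volume kind {meta.get('kind')!r}")
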