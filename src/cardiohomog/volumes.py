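"""Shared voxel-volume containers and the tissue-domain label dictionary.

Axis convention (fixed across the whole package): arrays are indexed
``[x, y, z]`` with

* x — transverse direction (in the cleft plane, normal to the fiber axis),
* y — longitudinal direction (myocyte fiber axis),
* z — normal direction (depth; interlaminar-cleft normal).

Voxels are isotropic; ``voxel_size`` is the edge length in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np

# Tissue-domain label codes.  Cleft voxels (code 3) are extracellular space:
# every analysis that reports the extracellular fraction V_e counts code 3
# toward it, while keeping the cleft separable for cleft-aware analyses.
BACKGROUND = 0
MYOCYTE = 1
EXTRACELLULAR = 2
CLEFT = 3
VESSEL = 4
FIBROBLAST = 5
MYOFIBROBLAST = 6

LABEL_NAMES: Dict[int, str] = {
    BACKGROUND: "background",
    MYOCYTE: "myocyte",
    EXTRACELLULAR: "extracellular",
    CLEFT: "cleft",
    VESSEL: "vessel",
    FIBROBLAST: "fibroblast",
    MYOFIBROBLAST: "myofibroblast",
}

#: Fluorescence channels, in canonical order.
CHANNEL_NAMES = ("WGA", "DAPI", "Cx43", "aSMA", "vimentin")

#: Axis names, in array-index order.
AXIS_NAMES = ("x", "y", "z")

#: Map from conduction-direction symbol to array axis:
#: l = longitudinal (fiber, y), t = transverse (x), n = normal (z).
DIRECTION_AXES = {"l": 1, "t": 0, "n": 2}


@dataclass
class LabelVolume:
    """A 3D voxel grid assigning each voxel exactly one tissue domain."""

    labels: np.ndarray
    voxel_size: float = 200.0  # nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def counts(self) -> Dict[int, int]:
        """Voxel count per label code (only codes that occur)."""
        codes, n = np.unique(self.labels, return_counts=True)
        return {int(c): int(k) for c, k in zip(codes, n)}

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class ChannelStack:
    """Co-registered 3D intensity grids for the five fluorescence channels."""

    channels: Mapping[str, np.ndarray] = field(default_factory=dict)
    voxel_size: float = 200.0  # nm

    def __post_init__(self) -> None:
        chans = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}
        shapes = {v.shape for v in chans.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel grids disagree in shape: {shapes}")
        for name, arr in chans.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not a 3D grid")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        self.channels = chans
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def map(self, fn) -> "ChannelStack":
        """Apply ``fn(name, array) -> array`` to every channel."""
        return ChannelStack(
            channels={k: fn(k, v) for k, v in self.channels.items()},
            voxel_size=self.voxel_size,
        )
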