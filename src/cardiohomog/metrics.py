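"""Volume fractions of tissue domains and the fibrosis degree.

The fibrosis degree of a region is the excess, relative to control, of
the summed volume fractions of the fibrotic tissue constituents —
extracellular space *excluding* interlaminar clefts, fibroblasts and
myofibroblasts:

    F = (V_e − V_cleft + V_fibro + V_myofibro)_region
      − (V_e − V_cleft + V_fibro + V_myofibro)_control

Clefts are excluded because their low WGA signal indicates only marginal
collagen content.  The degree may optionally be normalized by the
control's non-fibrotic volume fraction for comparisons across tissue
types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .volumes import (
    CLEFT,
    EXTRACELLULAR,
    FIBROBLAST,
    LABEL_NAMES,
    MYOCYTE,
    MYOFIBROBLAST,
    VESSEL,
    LabelVolume,
)


@dataclass(frozen=True)
class VolumeFractions:
    """Percentages of the tissue domains; cleft is nested inside V_e."""

    V_myo: float
    V_e: float  # includes V_cleft
    V_cleft: float
    V_vessel: float
    V_fibro: float
    V_myofibro: float

    def __post_init__(self) -> None:
        top = self.V_myo + self.V_e + self.V_vessel + self.V_fibro + self.V_myofibro
        if abs(top - 100.0) > 0.01:
            raise ValueError(f"top-level fractions sum to {top:.4f}, not 100")
        if not (0.0 <= self.V_cleft <= self.V_e + 1e-12):
            raise ValueError("V_cleft must lie in [0, V_e]")

    def fibrotic_sum(self) -> float:
        """V_e − V_cleft + V_fibro + V_myofibro (the Eq.-1 summand)."""
        return self.V_e - self.V_cleft + self.V_fibro + self.V_myofibro

    def as_dict(self) -> Dict[str, float]:
        return {
            "V_myo": self.V_myo,
            "V_e": self.V_e,
            "V_cleft": self.V_cleft,
            "V_vessel": self.V_vessel,
            "V_fibro": self.V_fibro,
            "V_myofibro": self.V_myofibro,
        }


@dataclass(frozen=True)
class FibrosisResult:
    degree: float  # percentage points
    normalized: Optional[float] = None  # dimensionless fraction of control non-fibrotic volume
    region: str = ""
    control: str = "control"


def volume_fractions(labels: LabelVolume) -> VolumeFractions:
    """Per-domain voxel count / total voxel count × 100.

    Cleft voxels count toward V_e and are additionally reported as
    V_cleft.  Background voxels (code 0, e.g. from rotation cropping)
    are excluded from the total so fractions describe tissue only.
    """
    counts = labels.counts()
    total = sum(n for code, n in counts.items() if code != 0)
    if total == 0:
        raise ValueError("label volume contains no tissue voxels")

    def pct(code: int) -> float:
        return 100.0 * counts.get(code, 0) / total

    return VolumeFractions(
        V_myo=pct(MYOCYTE),
        V_e=pct(EXTRACELLULAR) + pct(CLEFT),
        V_cleft=pct(CLEFT),
        V_vessel=pct(VESSEL),
        V_fibro=pct(FIBROBLAST),
        V_myofibro=pct(MYOFIBROBLAST),
    )


def fibrosis_degree(
    region: VolumeFractions,
    control: VolumeFractions,
    region_label: str = "",
    normalize: bool = False,
) -> FibrosisResult:
    """Fibrosis degree of ``region`` relative to ``control`` (see module doc)."""
    degree = region.fibrotic_sum() - control.fibrotic_sum()
    normalized = None
    if normalize:
        non_fibrotic = 100.0 - control.fibrotic_sum()
        normalized = degree / non_fibrotic
    return FibrosisResult(degree=degree, normalized=normalized,
                          region=region_label)


def fractions_table(
    samples: Iterable[LabelVolume],
    ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """One row of volume fractions per labelled stack."""
    rows: List[Dict[str, float]] = []
    idx: List[str] = []
    for i, lab in enumerate(samples):
        rows.append(volume_fractions(lab).as_dict())
        idx.append(str(i))
    frame = pd.DataFrame(rows)
    frame.index = list(ids) if ids is not None else idx
    return frame


def group_fibrosis(
    region_samples: Iterable[VolumeFractions],
    control: VolumeFractions,
    region_label: str = "",
) -> Dict[str, float]:
    """Per-sample fibrosis degrees vs a control aggregate, summarized mean ± SD.

    This matches group-level statistics where every stack is evaluated
    against the control reference and the degrees are then averaged; a
    means-of-means evaluation is simply :func:`fibrosis_degree` on the
    group-mean fractions.
    """
    degrees = np.array(
        [fibrosis_degree(s, control, region_label).degree for s in region_samples]
    )
    return {
        "mean": float(degrees.mean()),
        "sd": float(degrees.std(ddof=1)) if degrees.size > 1 else float("nan"),
        "n": int(degrees.size),
    }
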