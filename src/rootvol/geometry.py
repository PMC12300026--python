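"""Geometric primitives of the root-volume model.

The projected outline of a molar root on a panoramic radiograph (PR) is
idealised as an ellipse whose axes are the measured root length (most apical
point to crestal bone margin) and the widest mesio-distal extent perpendicular
to it.  With semiaxes ``a = length/2`` and ``b = width/2`` the projected
surface is ``A = pi * a * b``.  A molar's total root surface is the sum of the
mesial and distal root ellipses.  The corresponding 3-D solid is a cuboid
(more precisely an elliptic cylinder treated as such): volume = base surface
times bucco-lingual depth.

All lengths are mm, surfaces mm², volumes mm³; no unit conversion happens
here.  Values are computed in full precision — rounding to the two decimals
used in printed tables is a formatting concern, not a geometric one.

The a/b (length/width) assignment is purely conventional: the ellipse area is
symmetric in its axes, so swapping length and width leaves every result
unchanged.  A width exceeding the length is geometrically legal but usually
indicates transposed columns, so it triggers :class:`TransposedAxesWarning`
rather than an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

from .errors import DomainError, TransposedAxesWarning

__all__ = [
    "Modality",
    "RootMeasurement2D",
    "RootMeasurement3D",
    "ToothMeasurement",
    "ellipse_surface",
    "tooth_surface",
    "cuboid_volume",
]


class Modality(str, Enum):
    """Imaging modality a measurement came from."""

    PR = "PR"
    CBCT = "CBCT"


def _check_positive_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite, got {value!r}")
    if not np.all(arr > 0):
        raise DomainError(f"{name} must be strictly positive, got {value!r}")
    return arr


@dataclass(frozen=True)
class RootMeasurement2D:
    """Projected length and width (mm) of one root from one radiograph."""

    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        _check_positive_finite("length_mm", self.length_mm)
        _check_positive_finite("width_mm", self.width_mm)

    @property
    def surface_mm2(self) -> float:
        return ellipse_surface(self.length_mm, self.width_mm)


@dataclass(frozen=True)
class RootMeasurement3D(RootMeasurement2D):
    """Adds the bucco-lingual (vestibulo-oral) depth available from CBCT."""

    depth_mm: float

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_positive_finite("depth_mm", self.depth_mm)


RootMeasurement = Union[RootMeasurement2D, RootMeasurement3D]


@dataclass(frozen=True)
class ToothMeasurement:
    """Mesial and distal root measurements of one molar from one modality."""

    mesial: RootMeasurement
    distal: RootMeasurement
    modality: Modality = Modality.PR

    def __post_init__(self) -> None:
        mesial_3d = isinstance(self.mesial, RootMeasurement3D)
        distal_3d = isinstance(self.distal, RootMeasurement3D)
        if mesial_3d != distal_3d:
            raise DomainError(
                "mesial and distal measurements must share a kind "
                "(both 2D or both 3D)"
            )
        if mesial_3d and Modality(self.modality) is not Modality.CBCT:
            raise DomainError("depth measurements are only available from CBCT")

    @property
    def has_depth(self) -> bool:
        return isinstance(self.mesial, RootMeasurement3D)


def ellipse_surface(length_mm, width_mm):
    """Elliptical surface ``pi * (length/2) * (width/2)`` in mm².

    Accepts scalars or numpy arrays (broadcast elementwise).  Warns with
    :class:`TransposedAxesWarning` when a width exceeds its length.

    >>> round(ellipse_surface(2.0, 2.0), 6) == round(math.pi, 6)
    True
    """
    length = _check_positive_finite("length_mm", length_mm)
    width = _check_positive_finite("width_mm", width_mm)
    if np.any(width > length):
        warnings.warn(
            "width_mm exceeds length_mm; length/width columns may be transposed",
            TransposedAxesWarning,
            stacklevel=2,
        )
    result = math.pi * (length / 2.0) * (width / 2.0)
    if np.ndim(length_mm) == 0 and np.ndim(width_mm) == 0:
        return float(result)
    return result


def tooth_surface(tooth: ToothMeasurement) -> float:
    """Total root surface: mesial plus distal ellipse, mm²."""
    return ellipse_surface(tooth.mesial.length_mm, tooth.mesial.width_mm) + (
        ellipse_surface(tooth.distal.length_mm, tooth.distal.width_mm)
    )


def cuboid_volume(surface_mm2, depth_mm):
    """Cuboid volume ``surface * depth`` in mm³ (scalar or elementwise)."""
    surface = _check_positive_finite("surface_mm2", surface_mm2)
    depth = _check_positive_finite("depth_mm", depth_mm)
    result = surface * depth
    if np.ndim(surface_mm2) == 0 and np.ndim(depth_mm) == 0:
        return float(result)
    return result
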