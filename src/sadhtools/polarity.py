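"""Quadrant-based centrosome-orientation scoring for wound-edge cells.

In a scratch wound-healing assay a migrating cell is scored as correctly
oriented when its centrosome lies in front of the nucleus within the 90
degree quadrant facing the wound, i.e. the angle between the
nucleus-to-centrosome vector and the wound direction is strictly below 45
degrees.  Under random centrosome positioning the expected score is the
quadrant's arc fraction, 90/360 = 25%, which is the assay's absolute
minimum baseline.

Geometry is 2-D (the assay scores projected positions) and only the
direction of the centrosome relative to the nucleus matters, not its
distance.  The boundary at exactly 45 degrees is excluded (half-open
convention; the boundary has measure zero under any continuous model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CellGeometry",
    "OrientationScore",
    "PolarityError",
    "DegenerateGeometryError",
    "classify_oriented",
    "score_population",
    "random_baseline",
    "QUADRANT_HALF_ANGLE_DEG",
]

QUADRANT_HALF_ANGLE_DEG = 45.0
_COS_THRESHOLD = np.cos(np.deg2rad(QUADRANT_HALF_ANGLE_DEG))


class PolarityError(ValueError):
    pass


class DegenerateGeometryError(PolarityError):
    pass


@dataclass(frozen=True)
class CellGeometry:
    """Nucleus centroid, centrosome position and wound direction (unit
    vector pointing from the cell into the wound)."""

    nucleus_centroid: tuple[float, float]
    centrosome: tuple[float, float]
    wound_direction: tuple[float, float]


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = float(np.hypot(*v))
    if norm == 0:
        raise DegenerateGeometryError(f"{what} has zero length")
    return v / norm


def classify_oriented(cell: CellGeometry) -> bool:
    """True iff the nucleus-to-centrosome direction lies strictly within
    45 degrees of the wound direction."""
    v = np.asarray(cell.centrosome, float) - np.asarray(
        cell.nucleus_centroid, float
    )
    if float(np.hypot(*v)) == 0:
        raise DegenerateGeometryError(
            "centrosome coincides with the nucleus centroid"
        )
    v = _unit(v, "nucleus-to-centrosome vector")
    w = _unit(np.asarray(cell.wound_direction, float), "wound direction")
    # strict inequality: exactly 45 degrees is scored as not oriented
    return bool(float(np.dot(v, w)) > _COS_THRESHOLD)


@dataclass(frozen=True)
class OrientationScore:
    n_cells: int
    n_oriented: int
    fraction: float


def score_population(cells: Sequence[CellGeometry]) -> OrientationScore:
    """Fraction of cells whose centrosome lies in the wound-facing quadrant."""
    if not cells:
        raise PolarityError("no cells to score")
    n_oriented = sum(classify_oriented(c) for c in cells)
    return OrientationScore(
        n_cells=len(cells),
        n_oriented=n_oriented,
        fraction=n_oriented / len(cells),
    )


def random_baseline(
    n_cells: int, seed: Optional[int] = 0
) -> OrientationScore:
    """Score of a population with centrosome angles uniform on the circle.

    The expected fraction is the quadrant arc over the full circle,
    90/360 = 0.25; this is the random-positioning minimum of the assay.
    """
    if n_cells < 1:
        raise PolarityError("n_cells must be >= 1")
    from .synth import make_orientation_population

    cells = make_orientation_population(n_cells, concentration=0.0, seed=seed)
    return score_population(cells)
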