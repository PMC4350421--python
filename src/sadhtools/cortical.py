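"""Cortical Localisation Index (CLI) of a fluorescent signal.

The CLI quantifies enrichment of a fluorescence signal at the cell cortex
relative to the cytoplasm.  Given a single-cell mask per z-plane, the mask
is split into a thin cortical band hugging the cell edge (default
thickness 0.625 um) and the remaining interior ("cytoplasm"), and

    CLI = (i / (i + I)) / (a / (a + A))

where ``i`` and ``I`` are the summed background-subtracted intensities of
band and cytoplasm and ``a`` and ``A`` their pixel areas.  CLI = 1 for a
uniformly distributed signal; a membrane-enriched signal gives CLI > 1.
In the thin-band limit a << A the CLI converges to the ratio of mean band
intensity over mean cytoplasm intensity.

The per-cell CLI is the unweighted mean over z-planes (three in the
standard live-imaging protocol).

The band is constructed by morphological erosion of the mask with a disc
footprint of radius round(thickness / pixel_size) pixels (minimum 1), i.e.
the band is measured inward from the mask edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "CellPlane",
    "CellMask",
    "CorticalPartition",
    "CliResult",
    "CorticalError",
    "CellTooSmallError",
    "BlankCellError",
    "partition_cell",
    "compute_cli",
    "cli_for_cell",
    "DEFAULT_BAND_THICKNESS_UM",
]

DEFAULT_BAND_THICKNESS_UM = 0.625


class CorticalError(ValueError):
    pass


class CellTooSmallError(CorticalError):
    pass


class BlankCellError(CorticalError):
    pass


@dataclass
class CellPlane:
    """One z-plane of fluorescence intensities.

    ``pixel_size`` is in um per pixel; ``background`` is a constant offset
    subtracted (and clamped at zero) before any intensity sum.
    """

    intensities: np.ndarray
    pixel_size: float
    background: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise CorticalError("intensities must be a non-empty 2-D grid")
        if self.pixel_size <= 0:
            raise CorticalError("pixel_size must be positive")

    def corrected(self) -> np.ndarray:
        return np.clip(self.intensities - self.background, 0.0, None)


@dataclass
class CellMask:
    """Binary single-cell region congruent with a plane's intensities."""

    region: np.ndarray

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        if self.region.ndim != 2 or not self.region.any():
            raise CorticalError("mask must be a non-empty 2-D binary grid")


@dataclass
class CorticalPartition:
    cortical_band: np.ndarray
    cytoplasm: np.ndarray
    band_thickness_um: float
    band_px: int


@dataclass
class CliResult:
    per_plane: list[float]
    cli: float
    i: float  # band intensity summed over planes
    I: float  # cytoplasm intensity summed over planes
    a: int  # band pixel count summed over planes
    A: int  # cytoplasm pixel count summed over planes


def partition_cell(
    mask: CellMask,
    pixel_size: float,
    band_thickness: float = DEFAULT_BAND_THICKNESS_UM,
) -> CorticalPartition:
    """Split a cell mask into cortical band and cytoplasm.

    The band is mask minus the mask eroded by round(band_thickness /
    pixel_size) pixels (disc footprint, minimum radius 1); the cytoplasm is
    the eroded remainder.  Raises :class:`CellTooSmallError` if erosion
    empties the interior.
    """
    if band_thickness <= 0:
        raise CorticalError("band_thickness must be positive")
    if pixel_size <= 0:
        raise CorticalError("pixel_size must be positive")
    band_px = max(1, round(band_thickness / pixel_size))
    interior = ndimage.binary_erosion(
        mask.region, structure=disk(band_px), border_value=0
    )
    if not interior.any():
        raise CellTooSmallError(
            f"erosion by {band_px} px empties the cell interior"
        )
    band = mask.region & ~interior
    return CorticalPartition(
        cortical_band=band,
        cytoplasm=interior,
        band_thickness_um=band_thickness,
        band_px=band_px,
    )


def compute_cli(plane: CellPlane, part: CorticalPartition) -> float:
    """CLI of one plane: (i/(i+I)) / (a/(a+A)).

    ``i``/``I`` are summed background-subtracted intensities over band and
    cytoplasm; ``a``/``A`` their pixel counts.
    """
    img = plane.corrected()
    if img.shape != part.cortical_band.shape:
        raise CorticalError("plane and partition shapes differ")
    i = float(img[part.cortical_band].sum())
    big_i = float(img[part.cytoplasm].sum())
    a = int(part.cortical_band.sum())
    big_a = int(part.cytoplasm.sum())
    if i + big_i == 0:
        raise BlankCellError("blank cell: total intensity is zero")
    return (i / (i + big_i)) / (a / (a + big_a))


def cli_for_cell(
    planes: Sequence[CellPlane],
    masks: Sequence[CellMask],
    band_thickness: float = DEFAULT_BAND_THICKNESS_UM,
) -> CliResult:
    """Per-plane CLI averaged over z-planes (arithmetic mean)."""
    if len(planes) != len(masks):
        raise CorticalError(
            f"{len(planes)} planes but {len(masks)} masks"
        )
    if not planes:
        raise CorticalError("need at least one plane")
    per_plane: list[float] = []
    tot_i = tot_I = 0.0
    tot_a = tot_A = 0
    for plane, mask in zip(planes, masks):
        part = partition_cell(mask, plane.pixel_size, band_thickness)
        per_plane.append(compute_cli(plane, part))
        img = plane.corrected()
        tot_i += float(img[part.cortical_band].sum())
        tot_I += float(img[part.cytoplasm].sum())
        tot_a += int(part.cortical_band.sum())
        tot_A += int(part.cytoplasm.sum())
    return CliResult(
        per_plane=per_plane,
        cli=float(np.mean(per_plane)),
        i=tot_i,
        I=tot_I,
        a=tot_a,
        A=tot_A,
    )
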