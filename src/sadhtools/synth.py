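"""Synthetic-data generators for every pipeline stage.

Each generator draws from the statistical model its downstream analysis
assumes and returns its ground truth alongside the data, so parameter
recovery is directly assertable:

* :func:`make_proteome` — decoy proteins from uniform residue frequencies
  (rejection-sampled so no decoy carries a consensus match) plus sequences
  with SADH motifs planted at recorded sites;
* :func:`make_cell_image` — a disc-shaped cell with a uniform cytoplasm,
  a cortical band of elevated mean intensity, additive Gaussian noise and
  several z-planes, together with the closed-form CLI of the noiseless
  image;
* :func:`make_frap_trace` — single-exponential recovery with chosen rate
  constant, mobile fraction and post-bleach floor, sampled at a regular
  interval with additive Gaussian noise;
* :func:`make_orientation_population` — centrosome directions from a von
  Mises distribution centred on the wound normal; concentration 0 is
  exactly the uniform null.

All randomness flows through an explicit integer seed; identical seeds
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cortical import CellMask, CellPlane, partition_cell
from .frap import FrapTrace
from .motifs import (
    STANDARD_RESIDUES,
    MotifDefinition,
    ProteinRecord,
    compile_consensus,
    scan_protein,
)
from .polarity import CellGeometry

__all__ = [
    "GeneratorConfig",
    "SynthError",
    "make_proteome",
    "make_cell_image",
    "make_frap_trace",
    "make_orientation_population",
    "sample_motif_instance",
    "analytic_cli",
    "enrichment_for_cli",
]


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Common knobs shared by the generators; identical configs give
    bit-identical outputs."""

    seed: int = 0
    noise_sd: float = 0.0


# ---------------------------------------------------------------- proteome


def sample_motif_instance(
    motif: MotifDefinition, rng: np.random.Generator
) -> str:
    """One concrete peptide satisfying every position class (never X)."""
    out = []
    for cls in motif.positions:
        choices = sorted(cls - {"X"})
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(STANDARD_RESIDUES), size=length)
    return "".join(STANDARD_RESIDUES[i] for i in idx)


def make_proteome(
    n_decoys: int,
    planted: Sequence[tuple[str, int]] = (("simplified", 5),),
    decoy_length: int = 200,
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[list[ProteinRecord], dict[str, list[tuple[int, int, str]]]]:
    """Decoy proteins plus proteins carrying planted SADH motifs.

    ``planted`` lists (motif variant, number of carrier proteins).  Decoys
    are drawn from uniform residue frequencies and redrawn until they carry
    no consensus match (full or simplified); carriers get one motif
    instance at a random recorded position and are redrawn until the scan
    finds exactly the planted site.

    Returns (records, ground truth) where ground truth maps protein id to
    a list of (start, end, motif variant) 1-based sites.

    The uniform residue background is a simple null, not a model of a real
    proteome's composition.
    """
    rng = np.random.default_rng(seed)
    motifs = {v: compile_consensus(v) for v in ("simplified", "full")}
    records: list[ProteinRecord] = []
    truth: dict[str, list[tuple[int, int, str]]] = {}

    def clean(seq: str) -> bool:
        probe = ProteinRecord(id="probe", sequence=seq)
        return all(not scan_protein(probe, m) for m in motifs.values())

    for d in range(n_decoys):
        for _ in range(max_tries):
            seq = _random_sequence(rng, decoy_length)
            if clean(seq):
                break
        else:
            raise SynthError("could not draw a motif-free decoy")
        pid = f"decoy_{d:04d}"
        records.append(ProteinRecord(id=pid, sequence=seq))
        truth[pid] = []

    counter = 0
    for variant, count in planted:
        motif = motifs.get(variant) or compile_consensus(variant)
        m = len(motif)
        if decoy_length < m:
            raise SynthError(
                f"decoy_length {decoy_length} shorter than motif ({m})"
            )
        for _ in range(count):
            for _ in range(max_tries):
                seq = _random_sequence(rng, decoy_length)
                start = int(rng.integers(1, decoy_length - m + 2))
                seq = (
                    seq[: start - 1]
                    + sample_motif_instance(motif, rng)
                    + seq[start - 1 + m :]
                )
                probe = ProteinRecord(id="probe", sequence=seq)
                if [x.start for x in scan_protein(probe, motif)] == [start]:
                    break
            else:
                raise SynthError("could not plant a unique motif site")
            pid = f"planted_{variant}_{counter:04d}"
            counter += 1
            records.append(ProteinRecord(id=pid, sequence=seq))
            truth[pid] = [(start, start + m - 1, variant)]
    return records, truth


# ------------------------------------------------------------- cell image


def analytic_cli(enrichment: float, a: int, A: int) -> float:
    """Closed-form CLI of a noiseless cell whose band mean intensity is
    ``enrichment`` times the cytoplasm mean, with band/cytoplasm areas
    a and A: ((e a)/(e a + A)) / (a/(a + A))."""
    e = float(enrichment)
    return (e * a / (e * a + A)) / (a / (a + A))


def enrichment_for_cli(target_cli: float, a: int, A: int) -> float:
    """Invert :func:`analytic_cli`: the enrichment factor that yields a
    given CLI for band/cytoplasm areas a and A."""
    f = a / (a + A)
    x = target_cli * f
    if not 0 < x < 1:
        raise SynthError(
            f"CLI {target_cli} unreachable with a/(a+A) = {f:.3g}"
        )
    return x * A / (a * (1.0 - x))


def make_cell_image(
    radius_px: int = 40,
    enrichment: float = 2.0,
    band_px: int = 3,
    base_intensity: float = 100.0,
    noise_sd: float = 0.0,
    n_planes: int = 3,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> tuple[list[CellPlane], list[CellMask], dict]:
    """A disc cell with a cortical band of elevated intensity over z-planes.

    The mask is a rasterized disc; the band/cytoplasm split uses the same
    erosion rule as the analysis (band width ``band_px`` pixels), so the
    returned analytic CLI is exact for the noiseless image.  Band pixels
    have mean intensity ``enrichment * base_intensity``, cytoplasm pixels
    ``base_intensity``; Gaussian noise of sd ``noise_sd * base_intensity``
    is added per plane.

    Returns (planes, masks, truth) with truth carrying the analytic CLI,
    band/cytoplasm areas and the generating parameters.
    """
    if band_px < 1 or radius_px <= band_px:
        raise SynthError("need radius_px > band_px >= 1")
    if enrichment < 1:
        raise SynthError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    n = 2 * radius_px + 5
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    region = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
    mask = CellMask(region=region)
    part = partition_cell(mask, pixel_size=1.0, band_thickness=float(band_px))
    a = int(part.cortical_band.sum())
    A = int(part.cytoplasm.sum())
    noiseless = np.zeros((n, n))
    noiseless[part.cytoplasm] = base_intensity
    noiseless[part.cortical_band] = enrichment * base_intensity
    planes = []
    masks = []
    for _ in range(n_planes):
        img = noiseless + rng.normal(
            0.0, noise_sd * base_intensity, size=noiseless.shape
        )
        planes.append(
            CellPlane(
                intensities=np.clip(img, 0.0, None),
                pixel_size=pixel_size,
                background=0.0,
            )
        )
        masks.append(CellMask(region=region.copy()))
    truth = {
        "analytic_cli": analytic_cli(enrichment, a, A),
        "enrichment": enrichment,
        "band_area_px": a,
        "cytoplasm_area_px": A,
        "band_px": band_px,
        "radius_px": radius_px,
        "base_intensity": base_intensity,
        "noise_sd": noise_sd,
        "pixel_size": pixel_size,
        "seed": seed,
    }
    return planes, masks, truth


# ------------------------------------------------------------- FRAP trace


def make_frap_trace(
    k: float,
    Mf: float,
    Y0: float = 0.1,
    dt: float = 3.0,
    n_frames: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_pre: int = 5,
    background: float = 50.0,
    scale: float = 1000.0,
) -> tuple[FrapTrace, dict]:
    """Single-exponential FRAP recovery sampled at a regular interval.

    Pre-bleach frames sit at normalized intensity 1; post-bleach frames
    follow y(t) = Y0 + (Ymax - Y0)(1 - e^{-kt}) with Ymax = Y0 +
    Mf (1 - Y0).  Gaussian noise of sd ``noise_sd`` is added in normalized
    units, then the trace is mapped back to raw counts with the given
    background offset and scale.  Sampling intervals of 3-10 s emulate the
    live-imaging protocol, but any positive ``dt`` is accepted.
    """
    if k <= 0:
        raise SynthError("rate constant k must be positive")
    if not 0 < Mf <= 1:
        raise SynthError("mobile fraction must be in (0, 1]")
    if not 0 <= Y0 < 1:
        raise SynthError("post-bleach floor Y0 must be in [0, 1)")
    if dt <= 0 or n_frames < 5 or n_pre < 3:
        raise SynthError("need dt > 0, >= 5 post frames, >= 3 pre frames")
    rng = np.random.default_rng(seed)
    ymax = Y0 + Mf * (1.0 - Y0)
    t_pre = np.arange(-n_pre, 0) * dt
    t_post = np.arange(n_frames) * dt
    y_pre = np.ones(n_pre)
    y_post = Y0 + (ymax - Y0) * (1.0 - np.exp(-k * t_post))
    y = np.concatenate([y_pre, y_post])
    y = y + rng.normal(0.0, noise_sd, size=y.shape)
    raw = background + scale * y
    trace = FrapTrace(
        times=np.concatenate([t_pre, t_post]),
        intensities=raw,
        bleach_index=n_pre,
        background=background,
    )
    truth = {
        "k": k,
        "t_half": float(np.log(2.0) / k),
        "Mf": Mf,
        "Y0": Y0,
        "Ymax": ymax,
        "dt": dt,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return trace, truth


# ----------------------------------------------------------- orientation


def make_orientation_population(
    n: int,
    concentration: float = 0.0,
    seed: Optional[int] = 0,
    wound_direction: tuple[float, float] = (1.0, 0.0),
) -> list[CellGeometry]:
    """Cells with centrosome directions von Mises-distributed around the
    wound normal; concentration (kappa) 0 reduces exactly to the uniform
    null, large kappa concentrates all centrosomes toward the wound."""
    if n < 1:
        raise SynthError("n must be >= 1")
    if concentration < 0:
        raise SynthError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    w = np.asarray(wound_direction, float)
    norm = float(np.hypot(*w))
    if norm == 0:
        raise SynthError("wound_direction must be non-zero")
    w = w / norm
    mu = float(np.arctan2(w[1], w[0]))
    if concentration == 0:
        angles = rng.uniform(-np.pi, np.pi, size=n)
    else:
        angles = rng.vonmises(mu, concentration, size=n)
    cells = [
        CellGeometry(
            nucleus_centroid=(0.0, 0.0),
            centrosome=(float(np.cos(a)), float(np.sin(a))),
            wound_direction=(float(w[0]), float(w[1])),
        )
        for a in angles
    ]
    return cells
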