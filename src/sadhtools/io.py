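"""Readers and writers for the pipeline's plain-text formats.

Sequences travel as FASTA (Biopython), variants and geometries as TSV with
a header row (pandas), FRAP traces as CSV, images as single-channel TIFF
or whitespace-delimited numeric grids, and nested results as JSON.
Sequence coordinates in outputs are 1-based inclusive; image coordinates
are 0-based row/column.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .frap import FrapTrace
from .motifs import MotifMatch, ProteinRecord, VariantSpec
from .polarity import CellGeometry

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_variants_tsv",
    "write_matches_tsv",
    "read_trace_csv",
    "write_trace_csv",
    "read_image",
    "write_image",
    "read_mask",
    "read_geometries_tsv",
    "write_geometries_tsv",
    "write_json",
]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """FASTA records as ProteinRecord; the description after the id, if
    any, is taken as the species."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id) :].strip()
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), species=desc)
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.species)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_variants_tsv(path: str | Path) -> list[VariantSpec]:
    """TSV with columns protein_id, position, ref, alt and optional label."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantSpec(
                protein_id=str(row.protein_id),
                position=int(row.position),
                ref=str(row.ref),
                alt=str(row.alt),
                label=str(getattr(row, "label", "") or ""),
            )
        )
    return out


def write_matches_tsv(
    matches: Sequence[MotifMatch], path: str | Path
) -> None:
    """One row per match; start/end are 1-based inclusive."""
    df = pd.DataFrame(
        [
            {
                "protein_id": m.protein_id,
                "start": m.start,
                "end": m.end,
                "peptide": m.peptide,
                "repeat_label": m.repeat_label or "",
            }
            for m in matches
        ],
        columns=["protein_id", "start", "end", "peptide", "repeat_label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_trace_csv(
    path: str | Path, bleach_index: int, background: float | None = None
) -> FrapTrace:
    """CSV with columns time_s, intensity and optional background."""
    df = pd.read_csv(path)
    bg = background
    if bg is None:
        bg = float(df["background"].iloc[0]) if "background" in df else 0.0
    return FrapTrace(
        times=df["time_s"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        bleach_index=bleach_index,
        background=bg,
    )


def write_trace_csv(trace: FrapTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "intensity": trace.intensities,
            "background": trace.background,
        }
    ).to_csv(path, index=False)


def read_image(path: str | Path) -> np.ndarray:
    """Single-channel image: TIFF by extension, else a whitespace-
    delimited numeric grid."""
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(str(p)), dtype=float)
    return np.loadtxt(p, dtype=float, ndmin=2)


def write_image(img: np.ndarray, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(p), np.asarray(img, dtype=np.float32))
    else:
        np.savetxt(p, np.asarray(img), fmt="%.6g")


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0.5


def read_geometries_tsv(path: str | Path) -> list[CellGeometry]:
    """TSV columns: nucleus_x, nucleus_y, centrosome_x, centrosome_y,
    wound_dx, wound_dy."""
    df = pd.read_csv(path, sep="\t")
    return [
        CellGeometry(
            nucleus_centroid=(float(r.nucleus_x), float(r.nucleus_y)),
            centrosome=(float(r.centrosome_x), float(r.centrosome_y)),
            wound_direction=(float(r.wound_dx), float(r.wound_dy)),
        )
        for r in df.itertuples(index=False)
    ]


def write_geometries_tsv(
    cells: Sequence[CellGeometry], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "nucleus_x": c.nucleus_centroid[0],
                "nucleus_y": c.nucleus_centroid[1],
                "centrosome_x": c.centrosome[0],
                "centrosome_y": c.centrosome[1],
                "wound_dx": c.wound_direction[0],
                "wound_dy": c.wound_direction[1],
            }
            for c in cells
        ]
    ).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")
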