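"""Synthetic reference fixtures for the SADH motif module.

The published SCRIB, DMTN/ABLIM and ortholog sequences are shown only as
figure panels and are not redistributed here.  Every record in this module
is therefore a SYNTHETIC stand-in, generated deterministically, that
reproduces the quantitative geometry the prose does state:

* a 1657-residue SCRIB-like protein carrying three 25-aa spectrin-binding
  repeats (75 aa total, < 5% of the sequence), each ending in a full
  SADH consensus, giving exactly three simplified-consensus matches in the
  C-terminal region;
* residue numbering consistent with the pathology variants R1322W, A1315T
  and P1332L: the full 11-mer consensus of repeat 2 occupies 1322-1332, so
  its simplified 8-residue core is 1325-1332, A1315 lies inside the 25-aa
  repeat but outside the core, and R1322 is the leading [+] position;
* a seven-peptide panel in which exactly the four canonical SADH carriers
  (DMTN, ABLIM1/2/3 stand-ins) match the simplified consensus while three
  near-miss peptides (MYO10, MPP7, AFDN stand-ins) each violate one
  constrained position;
* an ortholog panel where vertebrate sequences carry SADH motifs and the
  fly/worm sequences carry none.

Background residues are drawn uniformly and rejection-checked so that no
accidental consensus match exists outside the planted sites.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .motifs import (
    STANDARD_RESIDUES,
    MotifDefinition,
    MotifMatch,
    ProteinRecord,
    VariantSpec,
    compile_consensus,
    scan_protein,
)

__all__ = [
    "SCRIB_LENGTH",
    "SCRIB_REPEAT_WINDOWS",
    "SCRIB_CTER_SPAN",
    "scrib_record",
    "scrib_cter_record",
    "pathology_variants",
    "sadh_peptide_panel",
    "ortholog_panel",
    "label_repeats",
]

SCRIB_LENGTH = 1657
#: Three 25-residue spectrin-binding repeat windows (1-based inclusive);
#: repeat 2 is positioned so its full consensus ends at P1332, and repeat 3
#: models the alternative-exon repeat in the distal C-terminus.
SCRIB_REPEAT_WINDOWS: tuple[tuple[int, int], ...] = (
    (1240, 1264),
    (1308, 1332),
    (1556, 1580),
)
#: C-terminal region used as two-hybrid bait (1223-1630).
SCRIB_CTER_SPAN: tuple[int, int] = (1223, 1630)

# One fixed full-consensus instance [+]-X-X-Y-[+]-X-phi-A-A-phi-P whose
# last 8 residues also satisfy the simplified core Y-[KR]-X-[FL]-A-A-[ILV]-P.
_CORE11 = "RQSYRTFAAIP"


def _background(rng: np.random.Generator, length: int) -> list[str]:
    idx = rng.integers(0, len(STANDARD_RESIDUES), size=length)
    return [STANDARD_RESIDUES[i] for i in idx]


def _clean(seq: str, motifs: tuple[MotifDefinition, ...]) -> bool:
    probe = ProteinRecord(id="probe", sequence=seq)
    return all(not scan_protein(probe, m) for m in motifs)


def _expected_starts(motif: MotifDefinition) -> list[int]:
    offset = 11 - len(motif)
    return [hi - 10 + offset for _, hi in SCRIB_REPEAT_WINDOWS]


@lru_cache(maxsize=None)
def scrib_record() -> ProteinRecord:
    """Synthetic 1657-aa SCRIB-like protein with three planted SADH repeats.

    Deterministic: the first seed whose background carries no spurious
    consensus match is used, so repeated calls are identical.
    """
    simplified = compile_consensus("simplified")
    full = compile_consensus("full")
    for seed in range(1000):
        rng = np.random.default_rng(seed)
        residues = _background(rng, SCRIB_LENGTH)
        for _, hi in SCRIB_REPEAT_WINDOWS:
            start = hi - 11  # 0-based index of the 11-mer start
            residues[start : start + 11] = list(_CORE11)
        residues[1315 - 1] = "A"  # reference residue of A1315T
        seq = "".join(residues)
        rec = ProteinRecord(id="SCRIB_HUMAN_synthetic", sequence=seq,
                            species="Homo sapiens")
        ok = all(
            [m.start for m in scan_protein(rec, motif)] == _expected_starts(motif)
            for motif in (simplified, full)
        )
        if ok:
            return rec
    raise RuntimeError("could not build a clean synthetic SCRIB fixture")


def scrib_cter_record() -> ProteinRecord:
    """The C-terminal bait region (residues 1223-1630) of the synthetic
    SCRIB, as its own record; contains all three SADH motifs."""
    lo, hi = SCRIB_CTER_SPAN
    full = scrib_record()
    return ProteinRecord(
        id="SCRIB_HUMAN_synthetic_Cter",
        sequence=full.sequence[lo - 1 : hi],
        species="Homo sapiens",
    )


def pathology_variants() -> list[VariantSpec]:
    """The three pathology missense variants in full-protein coordinates:
    R1322W (somatic, lung cancer), A1315T and P1332L (spina bifida)."""
    pid = scrib_record().id
    return [
        VariantSpec(pid, 1322, "R", "W", label="R1322W"),
        VariantSpec(pid, 1315, "A", "T", label="A1315T"),
        VariantSpec(pid, 1332, "P", "L", label="P1332L"),
    ]


#: Synthetic 25-aa peptide panel: four canonical SADH carriers whose core
#: satisfies Y-[KR]-X-[FL]-A-A-[ILV]-P, and three near-miss peptides each
#: violating exactly one constrained position (marked in comments).
_PANEL_CORES = {
    "DMTN_synthetic": ("YKGLAAIP", True),
    "ABLIM1_synthetic": ("YRDFAALP", True),
    "ABLIM2_synthetic": ("YKEFAAVP", True),
    "ABLIM3_synthetic": ("YRSLAAIP", True),
    "MYO10_synthetic": ("YQGLAAIP", False),  # Q not in [KR]
    "MPP7_synthetic": ("YKGLASIP", False),  # S breaks the AA doublet
    "AFDN_synthetic": ("FKGLAAIP", False),  # F replaces the anchor Y
}


@lru_cache(maxsize=None)
def sadh_peptide_panel() -> dict[str, tuple[ProteinRecord, bool]]:
    """Seven synthetic 25-aa peptides: id -> (record, carries_canonical_motif).

    Exactly the four canonical peptides match the simplified consensus.
    """
    simplified = compile_consensus("simplified")
    full = compile_consensus("full")
    panel: dict[str, tuple[ProteinRecord, bool]] = {}
    rng = np.random.default_rng(20150209)
    for name, (core, canonical) in _PANEL_CORES.items():
        while True:
            residues = _background(rng, 25)
            residues[12:20] = list(core)
            seq = "".join(residues)
            rec = ProteinRecord(id=name, sequence=seq, species="Homo sapiens")
            hits = scan_protein(rec, simplified)
            want = [13] if canonical else []
            if [m.start for m in hits] == want and not scan_protein(rec, full):
                panel[name] = (rec, canonical)
                break
    return panel


_ORTHOLOG_PLAN = [
    # (species, clade, number of planted simplified motifs)
    ("Homo sapiens", "vertebrate", 3),
    ("Mus musculus", "vertebrate", 3),
    ("Gallus gallus", "vertebrate", 3),
    ("Xenopus tropicalis", "vertebrate", 3),
    ("Danio rerio", "vertebrate", 2),
    ("Drosophila melanogaster", "invertebrate", 0),
    ("Caenorhabditis elegans", "invertebrate", 0),
]


@lru_cache(maxsize=None)
def ortholog_panel() -> tuple[list[ProteinRecord], dict[str, str]]:
    """Synthetic SCRIB-ortholog C-terminal set: vertebrates carry planted
    SADH motifs, fly/worm stand-ins carry none.  Returns (records,
    species -> clade map)."""
    simplified = compile_consensus("simplified")
    full = compile_consensus("full")
    records: list[ProteinRecord] = []
    clades: dict[str, str] = {}
    rng = np.random.default_rng(42)
    for species, clade, n_motifs in _ORTHOLOG_PLAN:
        tag = species.split()[0][:4].upper()
        length = 400
        while True:
            residues = _background(rng, length)
            starts = [40 + 120 * i for i in range(n_motifs)]
            for s in starts:
                residues[s : s + 8] = list("YKGLAAIP")
            seq = "".join(residues)
            rec = ProteinRecord(
                id=f"SCRIB_{tag}_synthetic", sequence=seq, species=species
            )
            found = [m.start for m in scan_protein(rec, simplified)]
            if found == [s + 1 for s in starts] and not scan_protein(rec, full):
                records.append(rec)
                clades[species] = clade
                break
    return records, clades


def label_repeats(
    matches: list[MotifMatch],
    windows: tuple[tuple[int, int], ...] = SCRIB_REPEAT_WINDOWS,
) -> list[MotifMatch]:
    """Attach 'repeat N' labels to matches falling inside repeat windows."""
    out = []
    for m in matches:
        label = None
        for n, (lo, hi) in enumerate(windows, start=1):
            if lo <= m.start and m.end <= hi:
                label = f"repeat {n}"
                break
        out.append(
            MotifMatch(m.protein_id, m.start, m.end, m.peptide, repeat_label=label)
        )
    return out
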