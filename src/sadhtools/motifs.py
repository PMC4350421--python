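"""SADH consensus-motif scanning and missense-variant impact analysis.

The SADH motif (SCRIB/ABLIMs/DMTN Homology) is a short vertebrate-specific
spectrin-binding consensus found in the divergent C-terminal region of the
polarity protein SCRIB, in dematin (DMTN) and in the three ABLIM proteins.
Two operational definitions are supported:

* the **full** 11-position consensus ``[+]-X-X-Y-[+]-X-phi-A-A-phi-P``,
  where ``[+]`` is a positively charged residue, ``X`` any residue and
  ``phi`` a hydrophobic residue;
* the **simplified** 8-position core ``Y-[KR]-X-[FL]-A-A-[ILV]-P`` used for
  database scanning, which is the quantitative workhorse here.

This module scans protein sequences for either consensus, classifies
missense variants by whether they destroy a consensus match, and computes
motif coverage and mutation-enrichment statistics over a protein.

Coordinates are 1-based inclusive throughout, matching protein-mutation
nomenclature such as R1322W.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "STANDARD_RESIDUES",
    "ProteinRecord",
    "MotifDefinition",
    "MotifMatch",
    "VariantSpec",
    "VariantImpact",
    "EnrichmentResult",
    "ProteomeScan",
    "MotifError",
    "UnknownMotifVariantError",
    "InvalidSequenceError",
    "DuplicateProteinIdError",
    "RefMismatchError",
    "IntervalError",
    "EmptyInputError",
    "compile_consensus",
    "scan_protein",
    "scan_proteome",
    "apply_variant",
    "motif_coverage",
    "mutation_enrichment",
    "conservation_table",
    "merge_intervals",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Unconstrained positions accept any standard residue and the unknown code X;
# X in an input sequence never satisfies a constrained class (conservative).
_ANY = frozenset(STANDARD_RESIDUES + "X")
_POSITIVE = frozenset("KR")  # [+]; H excluded, matching the simplified [KR]
_HYDROPHOBIC = frozenset("FLIVMAWY")  # phi in the full consensus

_SIMPLIFIED_CLASSES = (
    frozenset("Y"),
    _POSITIVE,
    _ANY,
    frozenset("FL"),
    frozenset("A"),
    frozenset("A"),
    frozenset("ILV"),
    frozenset("P"),
)
_FULL_CLASSES = (
    _POSITIVE,
    _ANY,
    _ANY,
    frozenset("Y"),
    _POSITIVE,
    _ANY,
    _HYDROPHOBIC,
    frozenset("A"),
    frozenset("A"),
    _HYDROPHOBIC,
    frozenset("P"),
)


class MotifError(ValueError):
    """Base class for motif-module errors."""


class UnknownMotifVariantError(MotifError):
    pass


class InvalidSequenceError(MotifError):
    pass


class DuplicateProteinIdError(MotifError):
    pass


class RefMismatchError(MotifError):
    pass


class IntervalError(MotifError):
    pass


class EmptyInputError(MotifError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates.

    The sequence is uppercased on construction; the alphabet is restricted
    to the 20 standard residues plus ``X`` for unknown.
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidSequenceError(f"{self.id}: empty sequence")
        bad = set(seq) - set(STANDARD_RESIDUES + "X")
        if bad:
            raise InvalidSequenceError(
                f"{self.id}: non-standard residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered list of per-position residue classes."""

    name: str
    positions: tuple[frozenset[str], ...]
    variant: str

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, sequence: str, start: int) -> bool:
        """True if the window starting at 1-based ``start`` satisfies every
        position class.  ``X`` in the sequence only satisfies unconstrained
        positions."""
        i = start - 1
        if i < 0 or i + len(self.positions) > len(sequence):
            return False
        return all(
            sequence[i + j] in cls for j, cls in enumerate(self.positions)
        )


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    peptide: str
    repeat_label: Optional[str] = None

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class VariantSpec:
    protein_id: str
    position: int  # 1-based
    ref: str
    alt: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise MotifError(f"{self.label or self.position}: ref == alt")


@dataclass(frozen=True)
class VariantImpact:
    variant: VariantSpec
    category: str  # outside_motif | motif_retained | motif_lost
    affected_match: Optional[MotifMatch] = None


@dataclass(frozen=True)
class EnrichmentResult:
    n_mutations_total: int
    n_mutations_in_motif: int
    motif_residues: int
    protein_length: int
    observed_fraction: float
    expected_fraction: float
    p_value: float


@dataclass(frozen=True)
class ProteomeScan:
    """Per-protein motif matches plus the count of proteins with >= 1 hit."""

    matches: Mapping[str, tuple[MotifMatch, ...]]
    n_proteins_with_match: int


def compile_consensus(variant: str) -> MotifDefinition:
    """Build the SADH consensus of the requested flavour.

    ``simplified`` gives the 8-position core Y-[KR]-X-[FL]-A-A-[ILV]-P;
    ``full`` gives the 11-position [+]-X-X-Y-[+]-X-phi-A-A-phi-P.
    """
    if variant == "simplified":
        return MotifDefinition("SADH-simplified", _SIMPLIFIED_CLASSES, variant)
    if variant == "full":
        return MotifDefinition("SADH-full", _FULL_CLASSES, variant)
    raise UnknownMotifVariantError(
        f"unknown motif variant {variant!r}; expected 'full' or 'simplified'"
    )


def scan_protein(
    record: ProteinRecord, motif: MotifDefinition
) -> list[MotifMatch]:
    """All consensus matches in a protein, in ascending start order.

    Every window whose residues all belong to their position classes is
    reported; overlapping matches are all reported.  A sequence shorter
    than the motif yields an empty list.
    """
    m = len(motif)
    seq = record.sequence
    out: list[MotifMatch] = []
    for start in range(1, len(seq) - m + 2):
        if motif.matches_at(seq, start):
            out.append(
                MotifMatch(
                    protein_id=record.id,
                    start=start,
                    end=start + m - 1,
                    peptide=seq[start - 1 : start - 1 + m],
                )
            )
    return out


def scan_proteome(
    records: Sequence[ProteinRecord], motif: MotifDefinition
) -> ProteomeScan:
    """Scan many proteins; ids must be unique."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateProteinIdError(f"duplicate protein ids: {dupes}")
    matches = {r.id: tuple(scan_protein(r, motif)) for r in records}
    n_hit = sum(1 for v in matches.values() if v)
    return ProteomeScan(matches=matches, n_proteins_with_match=n_hit)


def apply_variant(
    record: ProteinRecord, variant: VariantSpec, motif: MotifDefinition
) -> VariantImpact:
    """Classify a missense variant by its effect on consensus matches.

    The wild-type sequence is scanned, then the mutated sequence is
    re-scanned at each pre-variant match start.  ``motif_lost`` means the
    variant position lies inside a wild-type match whose window no longer
    matches after substitution; ``outside_motif`` means no wild-type match
    overlaps the position; otherwise ``motif_retained``.
    """
    seq = record.sequence
    pos = variant.position
    if not 1 <= pos <= len(seq):
        raise RefMismatchError(
            f"{record.id}: position {pos} outside 1..{len(seq)}"
        )
    actual = record.residue(pos)
    if actual != variant.ref:
        raise RefMismatchError(
            f"{record.id} position {pos}: sequence has {actual}, "
            f"variant says ref {variant.ref}"
        )
    pre = [m for m in scan_protein(record, motif) if m.contains(pos)]
    if not pre:
        return VariantImpact(variant=variant, category="outside_motif")
    mutated = seq[: pos - 1] + variant.alt + seq[pos:]
    lost = [m for m in pre if not motif.matches_at(mutated, m.start)]
    if lost:
        return VariantImpact(
            variant=variant, category="motif_lost", affected_match=lost[0]
        )
    return VariantImpact(
        variant=variant, category="motif_retained", affected_match=pre[0]
    )


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge overlapping 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _validate_intervals(
    intervals: Sequence[tuple[int, int]], protein_length: int
) -> None:
    for lo, hi in intervals:
        if lo > hi:
            raise IntervalError(f"inverted interval [{lo}, {hi}]")
        if lo < 1 or hi > protein_length:
            raise IntervalError(
                f"interval [{lo}, {hi}] outside 1..{protein_length}"
            )


def motif_coverage(
    repeat_windows: Sequence[tuple[int, int]], protein_length: int
) -> float:
    """Fraction of the protein covered by the motif repeat windows.

    Windows are merged before counting, so overlap is never double-counted.
    For SCRIB the three 25-residue repeats over 1657 aa give 75/1657.
    """
    if protein_length < 1:
        raise IntervalError("protein_length must be >= 1")
    _validate_intervals(repeat_windows, protein_length)
    merged = merge_intervals(repeat_windows)
    covered = sum(hi - lo + 1 for lo, hi in merged)
    return covered / protein_length


def mutation_enrichment(
    mutation_positions: Sequence[int],
    repeat_windows: Sequence[tuple[int, int]],
    protein_length: int,
) -> EnrichmentResult:
    """Are missense mutations enriched in the motif windows?

    The null model places each mutation uniformly along the protein, so a
    mutation lands in a window with probability equal to the coverage
    fraction.  The p-value is the one-sided exact binomial upper tail
    P(X >= observed) with n = total mutations.
    """
    if not mutation_positions:
        raise EmptyInputError("no mutation positions supplied")
    for p in mutation_positions:
        if not 1 <= p <= protein_length:
            raise IntervalError(f"mutation position {p} outside protein")
    _validate_intervals(repeat_windows, protein_length)
    merged = merge_intervals(repeat_windows)
    covered = sum(hi - lo + 1 for lo, hi in merged)
    n = len(mutation_positions)
    k = sum(
        1 for p in mutation_positions if any(lo <= p <= hi for lo, hi in merged)
    )
    expected = covered / protein_length
    # P(X >= k) under Binomial(n, expected)
    p_value = float(stats.binom.sf(k - 1, n, expected)) if k > 0 else 1.0
    return EnrichmentResult(
        n_mutations_total=n,
        n_mutations_in_motif=k,
        motif_residues=covered,
        protein_length=protein_length,
        observed_fraction=k / n,
        expected_fraction=expected,
        p_value=min(p_value, 1.0),
    )


def conservation_table(
    orthologs: Sequence[ProteinRecord],
    motif: MotifDefinition,
    clades: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-species motif presence across an ortholog set.

    Returns one row per record with the species, number of matches and a
    boolean ``present`` (>= 1 match).  If ``clades`` maps species to clade
    labels, a ``clade`` column is added so presence can be aggregated (e.g.
    vertebrates vs invertebrates).
    """
    if not orthologs:
        raise EmptyInputError("need at least one ortholog record")
    rows = []
    for rec in orthologs:
        hits = scan_protein(rec, motif)
        rows.append(
            {
                "protein_id": rec.id,
                "species": rec.species or rec.id,
                "n_matches": len(hits),
                "present": bool(hits),
            }
        )
    df = pd.DataFrame(rows)
    if clades is not None:
        df["clade"] = df["species"].map(clades)
    return df
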