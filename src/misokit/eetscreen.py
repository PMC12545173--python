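"""Haem-binding motif screen for multi-haem c-type cytochromes (MHCs).

c-type cytochromes bind haem covalently at CXnCH motifs.  A protein with more
than one CXnCH motif (spacer length n between 2 and 5) is classified as a
multi-haem cytochrome; candidates for extracellular electron transfer (EET)
to insoluble iron(III) oxides additionally require at least four of the
canonical short-spacer CXXCH motifs and an outer-membrane or extracellular
localization (localization is consumed as an external annotation, not
predicted here).

Matching policy: non-overlapping, leftmost scan preferring the shortest
spacer (the regex default for a lazy bounded quantifier).  The ambiguity
character X may occupy spacer positions but never matches the anchoring C or
H residues, which are required literally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

LOCALIZATIONS = frozenset({
    "extracellular", "outer_membrane", "periplasmic",
    "cytoplasmic_membrane", "cytoplasmic", "unknown",
})

#: Localizations compatible with electron transfer to extracellular acceptors.
EET_LOCALIZATIONS = frozenset({"extracellular", "outer_membrane"})


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    localization: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"{self.id}: unknown localization "
                             f"{self.localization!r}")


@dataclass(frozen=True)
class MotifScan:
    """Non-overlapping CXnCH matches in one sequence (1-based starts)."""

    positions: tuple[int, ...]
    n_min: int
    n_max: int

    @property
    def count(self) -> int:
        return len(self.positions)


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in AMINO_ALPHABET:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1}")
    return seq


def count_heme_motifs(seq: str, n_min: int = 2, n_max: int = 5) -> MotifScan:
    """Count CXnCH haem-binding motifs with spacer length n_min..n_max.

    The scan is greedy left-to-right over non-overlapping matches, preferring
    the shortest spacer at each start position.
    """
    if not 0 <= n_min <= n_max:
        raise ValueError("require 0 <= n_min <= n_max")
    seq = _validate_sequence(seq)
    spacer = "".join(sorted(AMINO_ALPHABET))
    pattern = re.compile(f"C[{spacer}]{{{n_min},{n_max}}}?CH")
    positions = tuple(m.start() + 1 for m in pattern.finditer(seq))
    return MotifScan(positions=positions, n_min=n_min, n_max=n_max)


def count_cxxch(seq: str) -> int:
    """Count of the canonical short-spacer CXXCH motif (n = 2 exactly)."""
    return count_heme_motifs(seq, 2, 2).count


def classify_mhc(record: "ProteinRecord | str", n_min: int = 2, n_max: int = 5,
                 min_motifs: int = 2) -> tuple[bool, int]:
    """Return (is_mhc, motif count); MHC means more than one CXnCH motif."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    n = count_heme_motifs(seq, n_min, n_max).count
    return n >= min_motifs, n


@dataclass(frozen=True)
class EETCall:
    """Outcome of the extracellular-EET candidate screen for one protein."""

    candidate: bool
    indeterminate: bool  # localization unknown: cannot be called a candidate
    n_cxxch: int
    localization: str


def flag_eet_candidate(record: ProteinRecord, min_motifs: int = 4) -> EETCall:
    """Flag proteins with >= ``min_motifs`` CXXCH motifs and an outer-membrane
    or extracellular localization.  Unknown localization yields an
    indeterminate (never positive) call."""
    n = count_cxxch(record.sequence)
    if record.localization == "unknown":
        return EETCall(candidate=False, indeterminate=True, n_cxxch=n,
                       localization=record.localization)
    candidate = n >= min_motifs and record.localization in EET_LOCALIZATIONS
    return EETCall(candidate=candidate, indeterminate=False, n_cxxch=n,
                   localization=record.localization)


def scan_proteome(records: Sequence[ProteinRecord],
                  localizations: Mapping[str, str] | None = None,
                  n_min: int = 2, n_max: int = 5,
                  mhc_min_motifs: int = 2,
                  eet_min_motifs: int = 4) -> pd.DataFrame:
    """Screen a proteome; one row per protein.

    ``localizations`` (protein id -> localization) overrides the records'
    own annotation; proteins absent from the table keep theirs.  Columns:
    id, length, n_motifs (CXnCH), n_cxxch, is_mhc, localization,
    eet_candidate, eet_indeterminate.
    """
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate protein identifiers: {', '.join(dupes)}")
    rows = []
    for rec in records:
        loc = (localizations or {}).get(rec.id, rec.localization)
        rec = ProteinRecord(rec.id, rec.sequence, loc)
        is_mhc, n = classify_mhc(rec, n_min, n_max, mhc_min_motifs)
        call = flag_eet_candidate(rec, eet_min_motifs)
        rows.append(dict(id=rec.id, length=len(rec.sequence), n_motifs=n,
                         n_cxxch=call.n_cxxch, is_mhc=is_mhc,
                         localization=loc, eet_candidate=call.candidate,
                         eet_indeterminate=call.indeterminate))
    columns = ["id", "length", "n_motifs", "n_cxxch", "is_mhc",
               "localization", "eet_candidate", "eet_indeterminate"]
    return pd.DataFrame(rows, columns=columns)
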