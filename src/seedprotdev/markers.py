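"""Allergen marker-peptide selection.

For targeted detection of a food allergen (e.g. a pecan 2S albumin in a food
matrix) one wants tryptic peptides that are (a) practical for MS assays —
fully tryptic with no missed cleavages and 7-25 residues long, (b) present
in the mature protein, i.e. not within a cleaved signal sequence, and (c)
specific: not shared with homologous allergens of related species (a pecan
marker shared with a walnut vicilin cannot distinguish the two nuts in a
mixed sample).

``select_marker_peptides`` applies these rules and returns a per-candidate
ledger rather than a filtered list, so that each exclusion is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .digest import Peptide, ProteinRecord, digest
from .masses import ModificationSet, compute_mz


@dataclass(frozen=True)
class PeptideIon:
    """A peptide with modifications, charge and theoretical monoisotopic m/z."""

    sequence: str
    mods: ModificationSet
    charge: int
    mz: float

    @classmethod
    def from_sequence(
        cls, sequence: str, charge: int, mods: ModificationSet | None = None
    ) -> "PeptideIon":
        mods = mods if mods is not None else ModificationSet()
        return cls(
            sequence=sequence,
            mods=mods,
            charge=charge,
            mz=compute_mz(sequence, charge, mods),
        )


@dataclass(frozen=True)
class MarkerCriteria:
    """Rules for accepting a tryptic peptide as an allergen marker.

    Defaults follow the recommendation for food-allergen detection assays:
    no missed cleavages and 7-25 residues. ``il_equivalence`` treats Ile and
    Leu as identical during the specificity screen (they are isobaric and
    indistinguishable by precursor mass).
    """

    min_len: int = 7
    max_len: int = 25
    missed_cleavages: int = 0
    exclude_signal: bool = True
    il_equivalence: bool = False
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(
                f"need 0 < min_len <= max_len, got {self.min_len}, {self.max_len}"
            )


def _il_collapse(seq: str) -> str:
    return seq.replace("I", "L")


def spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Whether two 1-based inclusive residue intervals share any residue."""
    return a[0] <= b[1] and b[0] <= a[1]


def is_nonspecific(
    peptide_seq: str,
    homologs: Iterable[ProteinRecord],
    il_equivalence: bool = False,
) -> bool:
    """Whether the peptide occurs as a substring of any homolog sequence.

    Substring matching is deliberately stricter than digest-to-digest
    comparison: a shared sequence tract makes the peptide non-specific
    regardless of the cleavage context in the homolog.
    """
    query = _il_collapse(peptide_seq) if il_equivalence else peptide_seq
    for hom in homologs:
        subject = _il_collapse(hom.sequence) if il_equivalence else hom.sequence
        if query in subject:
            return True
    return False


def select_marker_peptides(
    target: ProteinRecord,
    homologs: Iterable[ProteinRecord] = (),
    criteria: MarkerCriteria | None = None,
) -> pd.DataFrame:
    """Candidate marker peptides of *target* with a per-rule pass/fail ledger.

    Digests *target* with ``criteria.missed_cleavages`` missed cleavages and
    keeps every peptide with length in ``[min_len, max_len]`` as a candidate.
    Each candidate row records:

    ``signal_overlap``
        peptide shares >= 1 residue with the annotated signal span;
    ``nonspecific``
        peptide sequence occurs in a homolog (see :func:`is_nonspecific`);
    ``passes_all``
        no exclusion applies (signal overlap only excludes when
        ``criteria.exclude_signal``);
    ``mz_2plus`` / ``mz_3plus``
        theoretical m/z at 2+ and 3+ with carbamidomethyl-Cys.

    Rows are sorted by start coordinate; an empty frame is a valid result.
    """
    criteria = criteria if criteria is not None else MarkerCriteria()
    homologs = list(homologs)
    cam = ModificationSet(carbamidomethyl=True)
    rows = []
    for pep in digest(
        target,
        max_missed=criteria.missed_cleavages,
        proline_rule=criteria.proline_rule,
    ):
        if not (criteria.min_len <= len(pep.sequence) <= criteria.max_len):
            continue
        signal_overlap = target.signal_span is not None and spans_overlap(
            (pep.start, pep.end), target.signal_span
        )
        nonspecific = is_nonspecific(
            pep.sequence, homologs, il_equivalence=criteria.il_equivalence
        )
        passes = not nonspecific and not (criteria.exclude_signal and signal_overlap)
        rows.append(
            {
                "peptide": pep.sequence,
                "start": pep.start,
                "end": pep.end,
                "length": len(pep.sequence),
                "missed_cleavages": pep.missed_cleavages,
                "mz_2plus": round(compute_mz(pep.sequence, 2, cam), 4),
                "mz_3plus": round(compute_mz(pep.sequence, 3, cam), 4),
                "signal_overlap": signal_overlap,
                "nonspecific": nonspecific,
                "passes_all": passes,
            }
        )
    ledger = pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "start",
            "end",
            "length",
            "missed_cleavages",
            "mz_2plus",
            "mz_3plus",
            "signal_overlap",
            "nonspecific",
            "passes_all",
        ],
    )
    return ledger.sort_values(["start", "end"], ignore_index=True)
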