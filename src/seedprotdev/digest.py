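"""In-silico tryptic digestion with peptide coordinates.

Trypsin cleaves C-terminal to lysine and arginine; by default the classical
proline rule is applied (no cleavage when the following residue is proline).
Unlike generic cleavage helpers, the digest here tracks 1-based inclusive
residue coordinates of each peptide in its parent, which downstream marker
selection needs to test overlap with a signal-peptide span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .masses import check_sequence


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with the annotations marker selection uses.

    signal_span is the 1-based inclusive residue interval of a cleavable
    N-terminal signal peptide, or ``None`` when the protein has none (or the
    annotation is unknown).
    """

    id: str
    sequence: str
    signal_span: tuple[int, int] | None = None
    go_ids: frozenset[str] = field(default_factory=frozenset)
    source_set: str = "target"

    def __post_init__(self) -> None:
        check_sequence(self.sequence)
        if self.signal_span is not None:
            lo, hi = self.signal_span
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(
                    f"signal span {self.signal_span} outside protein "
                    f"{self.id} of length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with 1-based inclusive coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices *after* which trypsin cleaves.

    A site at index i means the bond between sequence[i] and sequence[i+1]
    is cleaved. The C-terminus is never a site.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    protein: ProteinRecord | str,
    max_missed: int = 0,
    proline_rule: bool = True,
) -> list[Peptide]:
    """All fully-tryptic peptides with at most *max_missed* missed cleavages.

    Peptides are returned ordered by start coordinate, then by end. For
    ``max_missed=0`` the peptides tile the sequence: concatenated in order
    they reconstruct it exactly.
    """
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    check_sequence(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = cleavage_sites(sequence, proline_rule=proline_rule)
    # Fragment boundaries: [0, site+1..., len]
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(
                Peptide(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides
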