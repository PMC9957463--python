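"""Monoisotopic masses and modification-aware peptide m/z.

The mass scale used throughout the package is monoisotopic. Residue masses
are the standard values for the 20 canonical amino acids; modifications are
restricted to the two relevant for alkylated tryptic digests of seed
proteins: carbamidomethylation of cysteine (iodoacetamide alkylation, fixed)
and cyclization of an N-terminal glutamine to pyroglutamate (variable).
"""

from __future__ import annotations

from dataclasses import dataclass

PROTON_MASS = 1.0072765
WATER_MASS = 18.010565
CARBAMIDOMETHYL_MASS = 57.021464  # fixed on every Cys after IAA alkylation
PYROGLUTAMATE_MASS = -17.026549  # N-terminal Gln -> pyroGlu (loss of NH3)

#: Monoisotopic residue masses (Da) of the 20 canonical amino acids.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)


def check_sequence(sequence: str) -> str:
    """Validate a peptide/protein sequence: non-empty, uppercase, canonical.

    Returns the sequence unchanged; raises ``ValueError`` naming the first
    offending position otherwise.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i} of sequence"
            )
    return sequence


@dataclass(frozen=True)
class ModificationSet:
    """Modifications applied to a peptide.

    carbamidomethyl
        When true (the default, matching an iodoacetamide-alkylated digest),
        +57.021464 Da is added for every cysteine.
    pyroglutamate
        When true, -17.026549 Da for cyclization of the N-terminal residue;
        only valid when that residue is glutamine.
    """

    carbamidomethyl: bool = True
    pyroglutamate: bool = False

    def delta(self, sequence: str) -> float:
        d = 0.0
        if self.carbamidomethyl:
            d += CARBAMIDOMETHYL_MASS * sequence.count("C")
        if self.pyroglutamate:
            if not sequence.startswith("Q"):
                raise ValueError(
                    "pyroglutamate modification requires an N-terminal Gln; "
                    f"sequence starts with {sequence[0]!r}"
                )
            d += PYROGLUTAMATE_MASS
        return d


def peptide_mass(sequence: str, mods: ModificationSet | None = None) -> float:
    """Neutral monoisotopic mass (Da) of a peptide with modifications.

    The mass is the sum of residue masses plus one water plus the
    modification deltas of *mods* (no modifications if ``None``).
    """
    check_sequence(sequence)
    m = sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER_MASS
    if mods is not None:
        m += mods.delta(sequence)
    return m


def compute_mz(sequence: str, z: int, mods: ModificationSet | None = None) -> float:
    """m/z (Th) of the protonated peptide at charge *z*: (M + z*mp) / z."""
    if z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (peptide_mass(sequence, mods) + z * PROTON_MASS) / z


def ppm_deviation(observed: float, theoretical: float) -> float:
    """Signed deviation of *observed* from *theoretical* in parts per million."""
    return (observed - theoretical) / theoretical * 1e6
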