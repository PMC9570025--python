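"""Monoisotopic mass arithmetic for mature venom peptides.

Masses are computed for the neutral peptide (residue masses + water) and
reported as the singly protonated ion [M+H]+ observed in MALDI-TOF spectra.
Two post-translational modifications are supported:

* C-terminal amidation (the free acid -OH is replaced by -NH2,
  a shift of N + H - O = -0.984016 Da), signalled in the precursor by a
  Gly residue that is consumed during processing;
* disulfide bridges (each bridge removes two hydrogens, -2.015650 Da).

Two independent computation routes are provided: a residue-mass sum
(:func:`peptide_neutral_mass`) and an elemental-composition route
(:func:`elemental_composition` + :func:`mass_from_composition`). Both are
derived from the same CODATA element masses but accumulate differently;
they are cross-checked against each other and against Biopython in the
test suite.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "ELEMENT_MASS",
    "RESIDUE_FORMULA",
    "ResidueMassTable",
    "MaturePeptide",
    "peptide_neutral_mass",
    "mh_plus",
    "elemental_composition",
    "mass_from_composition",
    "count_disulfides",
]

# CODATA/IUPAC monoisotopic element masses (Da)
ELEMENT_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

# Residue (internal, water-free) formulas of the 20 standard amino acids.
RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

STANDARD_RESIDUES = frozenset(RESIDUE_FORMULA)


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(ELEMENT_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus the constants of the mass model.

    The defaults are derived from elemental compositions at full floating
    point precision, so the residue-sum route and the composition route
    agree to machine precision rather than to table rounding.
    """

    residue_masses: dict[str, float] = field(
        default_factory=lambda: {
            aa: _formula_mass(f) for aa, f in RESIDUE_FORMULA.items()
        }
    )
    water_mass: float = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]  # 18.010565
    proton_mass: float = 1.00727646688
    # -O +N +H: carboxylic acid -> amide
    amidation_delta: float = (
        ELEMENT_MASS["N"] + ELEMENT_MASS["H"] - ELEMENT_MASS["O"]
    )  # -0.984016
    # each bridge removes two hydrogens
    disulfide_delta: float = -2 * ELEMENT_MASS["H"]  # -2.015650


DEFAULT_TABLE = ResidueMassTable()


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(
                f"unknown residue {aa!r} at position {i} in {sequence!r}"
            )


def peptide_neutral_mass(sequence: str, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Monoisotopic neutral mass of an unmodified linear peptide (Da)."""
    _check_sequence(sequence)
    return sum(table.residue_masses[aa] for aa in sequence) + table.water_mass


def mh_plus(
    sequence: str,
    amidated: bool = False,
    n_disulfides: int = 0,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Monoisotopic [M+H]+ of a peptide with amidation/disulfide PTMs (Da)."""
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be non-negative")
    if n_disulfides > sequence.count("C") // 2:
        raise ValueError(
            f"{n_disulfides} disulfides require >= {2 * n_disulfides} Cys, "
            f"sequence has {sequence.count('C')}"
        )
    m = peptide_neutral_mass(sequence, table) + table.proton_mass
    if amidated:
        m += table.amidation_delta
    m += n_disulfides * table.disulfide_delta
    return m


def elemental_composition(
    sequence: str, amidated: bool = False, n_disulfides: int = 0
) -> dict[str, int]:
    """Elemental composition of the neutral (modified) peptide.

    Amidation replaces one oxygen by N + H; each disulfide removes two
    hydrogens. Serves as the independent oracle for the residue-sum route.
    """
    _check_sequence(sequence)
    comp: Counter[str] = Counter({"H": 2, "O": 1})  # water
    for aa in sequence:
        comp.update(RESIDUE_FORMULA[aa])
    if amidated:
        comp["O"] -= 1
        comp["N"] += 1
        comp["H"] += 1
    if n_disulfides:
        if n_disulfides > sequence.count("C") // 2:
            raise ValueError("more disulfides than cysteine pairs")
        comp["H"] -= 2 * n_disulfides
    if any(n < 0 for n in comp.values()):
        raise ValueError("negative element count after modification")
    return dict(comp)


def mass_from_composition(composition: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental composition (Da)."""
    return sum(ELEMENT_MASS[el] * n for el, n in composition.items())


def count_disulfides(sequence: str) -> int:
    """Number of disulfide bridges assuming all cysteines are paired.

    Venom peptide scaffolds are fully oxidised; an odd cysteine is left
    unpaired (floor rule).
    """
    _check_sequence(sequence)
    return sequence.count("C") // 2


@dataclass(frozen=True)
class MaturePeptide:
    """A predicted bioactive product of precursor processing."""

    source_id: str
    sequence: str
    amidated: bool = False
    n_disulfides: int = 0
    derivation: str = ""
    predicted_mh: float = field(default=math.nan)

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.n_disulfides > self.sequence.count("C") // 2:
            raise ValueError("n_disulfides exceeds cysteine pairs")
        if math.isnan(self.predicted_mh):
            object.__setattr__(
                self,
                "predicted_mh",
                mh_plus(self.sequence, self.amidated, self.n_disulfides),
            )
        if self.predicted_mh <= 0:
            raise ValueError("predicted [M+H]+ must be positive")
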