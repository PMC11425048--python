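"""Physical constants and monoisotopic residue masses.

All masses are monoisotopic and in Daltons. Residue masses come from
pyteomics so they agree with the rest of the field's tooling.
"""

from pyteomics import mass as _mass

#: Mass of a proton (charge carrier), Da.
PROTON: float = 1.007276466

#: Monoisotopic mass of water (peptide termini H + OH), Da.
WATER: float = 18.0105646

#: Monoisotopic residue masses for the 20 canonical amino acids, Da.
AA_MASS: dict[str, float] = {
    aa: _mass.std_aa_mass[aa]
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Canonical residue alphabet in fixed (alphabetical) order; index into this
#: list is the integer code used by feature encoders.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

# Common modification deltas, Da (convenience for configs and tests).
CARBAMIDOMETHYL: float = 57.021464   # fixed, C
OXIDATION: float = 15.994915         # variable, M
PHOSPHO: float = 79.966331           # variable, S/T/Y
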