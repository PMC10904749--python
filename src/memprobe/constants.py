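"""Physical constants, pinned in one place.

All energies are kcal/mol, lengths Angstrom, temperatures Kelvin.
"""

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987e-3

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214e23

#: Litres per cubic Angstrom.
LITRE_PER_A3 = 1e-27

#: Atomic masses (amu) by element symbol; pseudo-beads are carbon.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
}


def mass_of(element: str) -> float:
    return ATOMIC_MASS[element.upper()]
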