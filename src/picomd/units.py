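"""Physical constants and unit conventions.

The engine works in Å (length), fs (time), Dalton (mass), kJ/mol (energy),
Kelvin (temperature) and elementary charges.  Velocities are Å/fs, forces
kJ/mol/Å.  Kinetic energy is ``0.5 * m * v**2 * KE_FACTOR`` because
1 Da·(Å/fs)² = 1.66054e-27 kg · 1e10 m²/s² = 1.66054e-17 J, which times
Avogadro's number is 1e4 kJ/mol.
"""

#: Boltzmann constant, kJ/(mol·K)
KB = 0.00831446

#: Coulomb constant e²/(4πε₀), kJ·Å/mol (per pair of elementary charges)
COULOMB = 1389.35458

#: 1 Da·(Å/fs)² expressed in kJ/mol (kinetic-energy conversion)
KE_FACTOR = 1.0e4

#: Force conversion: a gradient in kJ/mol/Å acting on a mass in Da gives an
#: acceleration in Å/fs² after multiplying with this factor (inverse of
#: KE_FACTOR).
ACC_FACTOR = 1.0e-4

#: 1 Da/Å³ expressed in g/ml (g/cm³)
DALTON_PER_A3_TO_G_ML = 1.66053907

#: 1 kJ/mol/Å³ expressed in bar
KJ_PER_MOL_A3_TO_BAR = 16605.39067

#: Standard atomic masses, Dalton
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "F": 18.998, "BR": 79.904, "I": 126.904,
}

#: Mass of a water molecule, Dalton
WATER_MASS = 15.999 + 2 * 1.008
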