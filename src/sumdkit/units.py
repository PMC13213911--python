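"""Physical constants in the package's fixed unit system.

Units package-wide: length Å, time ps, mass amu, energy kcal/mol,
charge elementary charge e, temperature K.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Coulomb prefactor k_e, kcal Å / (mol e²) — the AKMA/CHARMM convention.
COULOMB_K = 332.0637

#: 1 kcal/mol expressed in the internal dynamical energy unit amu Å²/ps².
#: Accelerations are F[kcal/mol/Å] * KCAL_TO_AKMA / m[amu]  →  Å/ps².
KCAL_TO_AKMA = 418.4

#: fs → ps
FS = 1.0e-3
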