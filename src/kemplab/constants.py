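"""Physical constants in the unit system used throughout the package.

Energies are kcal/mol, lengths Å, times fs, masses amu, charges in units of
the elementary charge, temperatures in K.
"""

#: Gas constant, kcal mol^-1 K^-1.  Also Boltzmann's constant per mole.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Alias used in the simulation code (kB in molar energy units).
KB_KCAL = GAS_CONSTANT_KCAL

#: Coulomb constant, kcal Å mol^-1 e^-2.
COULOMB_KCAL = 332.06

#: hc/kB in cm K — converts a wavenumber to a temperature-reduced quantity
#: u = (hc/kB) * nu / T.
HC_OVER_KB_CM_K = 1.43877

# Unit bridge between energy (kcal/mol) and dynamics (Å, fs, amu):
# E[J/mol] = E[kcal/mol]*4184; v^2[m^2/s^2] = 2E/m with m[kg/mol] = m[amu]*1e-3;
# 1 m^2/s^2 = 1e-10 Å^2/fs^2, hence E/m in kcal/mol/amu -> v^2 in Å^2/fs^2
# carries a factor 4184/1e-3*1e-10 = 4.184e-4.
KCAL_PER_AMU_TO_A2_FS2 = 4.184e-4
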