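"""Physical constants and unit conversions.

Internal unit system (MD convention): length nm, time ps, mass g/mol,
energy kJ/mol, charge in elementary charges.  Forces reported to users in
pN, pressures in pN/nm^2 (= MPa).
"""

# Boltzmann constant, kJ mol^-1 K^-1
KB_KJ_MOL_K = 8.314462618e-3

# SI
KB_SI = 1.380649e-23          # J/K
E_CHARGE = 1.602176634e-19    # C
EPS0_SI = 8.8541878128e-12    # F/m
N_AVOGADRO = 6.02214076e23    # 1/mol

# 1 kJ/mol/nm expressed in pN: (1e3 J / N_A) per 1e-9 m = 1.66054e-12 N
KJ_MOL_NM_TO_PN = 1e3 / N_AVOGADRO / 1e-9 * 1e12

# B-DNA geometry / composition
BP_MASS_G_MOL = 660.0     # average mass of one base pair, g/mol
BP_RISE_NM = 0.34         # axial rise per base pair, nm
HELICAL_PITCH_NM = 3.4    # one full turn (10 bp), nm
DNA_DIAMETER_NM = 2.0     # standard B-DNA diameter, nm
PHOSPHATES_PER_PITCH = 20  # 10 bp x 2 strands

# linear mass density of B-DNA, g mol^-1 nm^-1
DNA_LINEAR_MASS_G_MOL_NM = BP_MASS_G_MOL / BP_RISE_NM

# SPC-like water dipole magnitude, e nm (~2.27 D)
WATER_DIPOLE_E_NM = 0.0473
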