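"""Physical constants (CODATA 2018 exact values).

These are module-level and deliberately not configurable: every quantity in
the package is expressed in an SI-coherent internal system (J, mol, K, m; the
segment length scale is Angstrom inside the equation of state) and the
constants tie those scales together.
"""

#: Molar gas constant, J mol^-1 K^-1
R = 8.31446261815324

#: Boltzmann constant, J K^-1
K_B = 1.380649e-23

#: Avogadro constant, mol^-1
N_A = 6.02214076e23

#: Reference (ambient) pressure for liquid-phase properties, Pa
P_REF = 101325.0
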