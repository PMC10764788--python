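"""Unit conventions.

Potential energies are expressed in units of k_B*T at the reference
temperature (300 K by default); lengths in angstrom, time in femtoseconds,
mass in g/mol.  The only place mechanical energy units appear is inside the
Langevin integrator, which needs k_B*T in g*A^2/(fs^2*mol).
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB_KJ_PER_MOL_K = 8.314462618e-3

#: 1 kJ/mol expressed in g * A^2 / (fs^2 * mol)
KJ_PER_MOL_TO_MECH = 1e-4

FS_PER_NS = 1e6


def kbt_mech(temperature: float) -> float:
    """k_B*T in mechanical units, g*A^2/(fs^2*mol).

    At 300 K this is ~2.494e-4.
    """
    return KB_KJ_PER_MOL_K * temperature * KJ_PER_MOL_TO_MECH
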