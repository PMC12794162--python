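"""Unit conversions.

Internal convention: atomic units throughout the physics (energies in Hartree,
dipoles / fields / potentials in a.u., distances in Bohr). File formats use nm
for coordinates; spectra are reported on an eV grid with paired wavelengths in
nm. Conversions happen only at these boundaries.
"""

HARTREE_TO_EV = 27.211386
"""1 Hartree in eV."""

EV_TO_NM = 1239.84193
"""hc in eV*nm: lambda[nm] = EV_TO_NM / E[eV]."""

NM_TO_BOHR = 18.897259886
"""1 nm in Bohr radii."""


def hartree_to_ev(e):
    return e * HARTREE_TO_EV


def ev_to_hartree(e):
    return e / HARTREE_TO_EV


def ev_to_nm(e):
    return EV_TO_NM / e


def nm_to_ev(lam):
    return EV_TO_NM / lam


def nm_to_hartree(lam):
    return ev_to_hartree(nm_to_ev(lam))


def hartree_to_nm(e):
    return ev_to_nm(hartree_to_ev(e))


def nm_to_bohr(x):
    return x * NM_TO_BOHR
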