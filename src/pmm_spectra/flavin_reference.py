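"""Literature anchor values for the lumiflavin / CvFAP system.

These numbers parameterize the synthetic generators and serve as inputs to
the worked examples: gas-phase TD-DFT peak positions of the five bent
lumiflavin conformers, PMM peak positions per conformational basin of the
fatty-acid photodecarboxylase (CvFAP) simulation, experimental absorption
maxima, and the basin populations of the apo-enzyme trajectory. Wavelengths
in nm; populations are fractions.
"""

#: gas-phase conformer peaks: label -> (lambda1, lambda2, I_rel).
#: B1 is planar (d1 = 0), B5 bent by 20 degrees.
GAS_PHASE_PEAKS = {
    "B1": (436.2, 342.8, 0.76),
    "B2": (436.7, 344.0, 0.83),
    "B3": (437.2, 343.6, 0.83),
    "B4": (439.2, 345.8, 0.91),
    "B5": (441.0, 347.0, 0.97),
}

#: first-essential-mode projections (nm) and bend angles (degrees) of the
#: five representative conformers.
CONFORMER_PROJECTIONS = {
    "B1": (-0.06, 0.0),
    "B2": (-0.04, 3.0),
    "B3": (0.00, 10.0),
    "B4": (0.02, 18.0),
    "B5": (0.06, 20.0),
}

#: PMM peaks per conformational basin in the protein environment:
#: basin -> (lambda1, lambda2).
PMM_BASIN_PEAKS = {
    "planar": (458.0, 352.0),
    "partially_bent": (458.0, 351.0),
    "bent": (462.0, 355.0),
}

#: PMM peaks for lumiflavin in water (planar reference environment).
PMM_WATER_PEAKS = (443.0, 346.0)

#: experimental absorption maxima: system -> (lambda1, lambda2, I_rel).
EXPERIMENTAL_PEAKS = {
    "cvfap_apo": (466.0, 389.0, 1.01),
    "cvfap_holo": (466.0, 391.0, 0.96),
    "lumiflavin_water": (443.0, 370.0, 0.86),
}

#: basin populations of the apo-CvFAP trajectory (planar, partially bent, bent).
BASIN_POPULATIONS = {
    "planar": 0.27,
    "partially_bent": 0.44,
    "bent": 0.29,
}

#: gas-phase references used per basin for the PMM step.
BASIN_CONFORMERS = {
    "planar": "B1",
    "partially_bent": "B3",
    "bent": "B5",
}
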