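"""Unit conventions.

All internal arithmetic uses cm, s and mol/cm^3.  Under the dilute-solution
convention 1 mOsmol/kg == 1 mOsmol/L == 1e-6 mol/cm^3, and likewise
1 mM == 1e-6 mol/cm^3, so osmolality and millimolar solute concentrations
share a single conversion factor.  Permeabilities are carried in cm/s and
reported on the 1e-6 cm/s scale conventional for oocyte assays.
"""

#: mol/cm^3 per mOsmol/kg (== per mM)
MOSM_TO_MOL_PER_CM3: float = 1e-6

#: molar volume of water, cm^3/mol
V_W: float = 18.0

#: reporting scale for permeabilities (values printed as P x 1e6)
P_REPORT_SCALE: float = 1e-6

#: diameters are exchanged in mm in CSV files, held in cm internally
MM_PER_CM: float = 10.0
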