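# Column dictionary for the canonical gas-exchange CSV.
# Keys are canonical column names; values document meaning and unit.
# A user schema file for `mesolim ingest` instead maps *source* column
# names to these canonical names, e.g. `gm: gm_value`.
study_id: opaque study identifier (mandatory)
species: species name
pft: plant functional type label (mandatory; fern, evergreen_gymnosperm,
  evergreen_angiosperm, deciduous_angiosperm, C3_perennial_herb,
  C3_annual_herb, other)
gm_value: mesophyll conductance in gm_units (mandatory)
gm_units: one of mol_m2_s, mol_m2_s_bar, umol_m2_s_Pa (mandatory)
method: estimation method (isotope, fluorescence, curve_fitting, other)
T_meas: measurement temperature, degC
PPFD: measurement irradiance, umol m-2 s-1
CO2_meas: measurement CO2 concentration, umol mol-1
pressure: atmospheric pressure, kPa (optional)
elevation: site elevation, m (optional; used when pressure is missing)
An: light-saturated net photosynthesis, umol m-2 s-1
gs_c: stomatal conductance to CO2, mol m-2 s-1
Ci: intercellular CO2 concentration, umol mol-1
Ca: ambient CO2 concentration, umol mol-1
Anp: net photosynthesis at Cc = Ci (infinite gm), umol m-2 s-1
already_standardised: true when the source reports gm at 25 degC
Sc: chloroplast surface area exposed to intercellular airspaces, m2 m-2
Sm: mesophyll surface area exposed to intercellular airspaces, m2 m-2
Tcw: cell wall thickness, um
LMA: leaf dry mass per area, g m-2
leaf_thickness: um
density: g cm-3
porosity: fraction
N_area: leaf nitrogen per area, g m-2
K_area: leaf potassium per area, g m-2
rubisco: Rubisco content, g m-2
Vcmax_Cc: maximum carboxylation rate from An-Cc curves, umol m-2 s-1
stomatal_density: mm-2
stomatal_length: um
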