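# Temperature-response parameterisations of mesophyll conductance.
#
# Transcribed from the primary measurement literature: a peaked Arrhenius
# response measured on Nicotiana tabacum (the default) and a weaker simple
# Arrhenius response measured on Arabidopsis thaliana.  Energies in J mol-1,
# entropy in J mol-1 K-1, scaling constant c dimensionless.  All responses
# are renormalised in code so that the scaling factor equals 1 exactly at
# T_ref = 25 degC; only the shape of each curve matters downstream.
version: 1
responses:
  tobacco:
    family: peaked_arrhenius
    T_ref: 25.0
    params:
      c: 20.01
      Ha: 49600.0
      Hd: 437400.0
      dS: 1400.0
  arabidopsis:
    family: arrhenius
    T_ref: 25.0
    params:
      Ea: 20200.0
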