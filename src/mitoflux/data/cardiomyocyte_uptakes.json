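{
  "_note": "Approximate default cardiomyocyte boundary uptakes (umol/min/gDW). Fuels are supplied in slight excess so that the oxygen bound limits overall flux. Editable: transcribe exact values from the published supplementary annotation file when available.",
  "EX_glc_D": {"lower": -0.8},
  "EX_hdca": {"lower": -0.45},
  "EX_lac_L": {"lower": -0.6},
  "EX_bhb": {"lower": -0.2},
  "EX_acac": {"lower": -0.1},
  "EX_glu_L": {"lower": -0.15},
  "EX_asp_L": {"lower": -0.05},
  "EX_gln_L": {"lower": -0.1},
  "EX_ala_L": {"lower": -0.1},
  "EX_o2": {"lower": -19.5}
}
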