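# Osmoadaptation gene catalog: strategy -> gene symbol -> KEGG KO aliases.
# The KO mappings are editable data; gene symbols are the primary keys
# used for presence/absence profiling.
potassium_uptake:
  trkA: [K03499]
  trkH: [K03498]
sodium_solute_symporter:
  sss: [K03307]
compatible_solute_uptake:
  opuA: [K05845, K05846]
  opuC: [K05847]
  opuD: [K05020]
  opuBD: [K05848]
  betT: [K02168]
glycerol_utilization:
  glpK: [K00864]
  glpA: [K00111]
  glpB: [K00112]
  glpC: [K00113]
trehalose_biosynthesis:
  glgA: [K00703]
  glgC: [K00975]
  treX: [K01214]
ectoine_biosynthesis:
  asd: [K00133]
  ectB: [K00836]
  lysC: [K00928]
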