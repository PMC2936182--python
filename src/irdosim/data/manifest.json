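{
 "version": 1,
 "generator": "scripts/build_material_tables.py",
 "files": {
  "water": "water.csv",
  "dry_air": "dry_air.csv",
  "Ir": "Ir.csv",
  "Pt": "Pt.csv",
  "steel316L": "steel316L.csv",
  "ir192_spectrum": "ir192_spectrum.csv"
 },
 "densities_g_cm3": {
  "water": 0.998,
  "dry_air": 0.001205,
  "Ir": 22.56,
  "Pt": 21.45,
  "steel316L": 8.06,
  "core_alloy_Ir70Pt30": 21.76,
  "cable_steel": 5.6
 },
 "notes": [
  "water/dry_air totals and mu_en are standard reference grids",
  "metal tables: Klein-Nishina incoherent plus photoelectric+coherent scaled in Z between Fe and Pb anchors (few-percent accuracy)",
  "dry-air density is the sea-level value 1.205e-3 g/cm3"
 ]
}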