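[
  {"name": "IBU", "role": "API", "Mw": 206.28, "rho": 1.11,
   "Tg": -44.68, "Tm": 75.08, "dHfus_kJ_mol": 24.68, "dCp_J_mol_K": 70.91,
   "temperature_unit": "C"},
  {"name": "KOLVA64", "role": "polymer", "Mw": 65000, "rho": 1.22,
   "Tg": 109.3, "temperature_unit": "C"},
  {"name": "KOL17PF", "role": "polymer", "Mw": 11000, "rho": 1.23,
   "Tg": 132.0, "temperature_unit": "C"},
  {"name": "HPMCAS", "role": "polymer", "Mw": 18000, "rho": 1.30,
   "Tg": 122.5, "temperature_unit": "C"},
  {"name": "EPO", "role": "polymer", "Mw": 47000, "rho": 1.14,
   "Tg": 57.2, "temperature_unit": "C"}
]
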