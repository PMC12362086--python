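[
  {"name": "IBU", "m_seg": 2.52, "sigma": 4.43, "eps_k": 374.65,
   "eps_assoc_k": 879.42, "kappa_assoc": 0.03, "N_assoc": 2.00},
  {"name": "KOLVA64", "m_seg": 2420.99, "sigma": 2.95, "eps_k": 205.27,
   "eps_assoc_k": 0.00, "kappa_assoc": 0.02, "N_assoc": 653.00},
  {"name": "KOL17PF", "m_seg": 407.00, "sigma": 2.71, "eps_k": 205.60,
   "eps_assoc_k": 0.00, "kappa_assoc": 0.02, "N_assoc": 89.88},
  {"name": "HPMCAS", "m_seg": 895.70, "sigma": 2.91, "eps_k": 316.87,
   "eps_assoc_k": 2454.87, "kappa_assoc": 0.02, "N_assoc": 111.00},
  {"name": "EPO", "m_seg": 1645.00, "sigma": 3.74, "eps_k": 258.89,
   "eps_assoc_k": 0.00, "kappa_assoc": 0.02, "N_assoc": 848.00}
]
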