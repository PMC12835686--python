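{
  "description": "Control-state vessel table for the cerebral vascular network: diameters, lengths, tabulated compartment resistances, vessel counts, and capacitances. Rows with per_side=true exist on both the left and right side.",
  "units": {
    "diameter_um": "micrometers",
    "length_cm": "cm",
    "resistance": "dyn s/cm^5 (whole compartment)",
    "capacitance": "cm^5/dyn",
    "distensibility": "cm^2/dyn"
  },
  "viscosity_poise": 0.04,
  "arterial_distensibility": 4.01e-7,
  "venous_distensibility_factor": 8.0,
  "intracranial_pressure_mmhg": 9.5,
  "venous_outflow_pressure_mmhg": 9.5,
  "compartments": [
    {"id": "ICA",   "region": "shared",    "per_side": true,  "diameter_um": 4100, "length_cm": 13.15, "resistance": 758,    "number": 1,        "capacitance": 6.9680e-7, "has_capacitor": true,  "vasoactive": false},
    {"id": "BA",    "region": "shared",    "per_side": false, "diameter_um": 3400, "length_cm": 4.92,  "resistance": 600,    "number": 1,        "capacitance": 1.7928e-7, "has_capacitor": true,  "vasoactive": false},
    {"id": "MCA",   "region": "middle",    "per_side": true,  "diameter_um": 2800, "length_cm": 7.25,  "resistance": 1922,   "number": 1,        "capacitance": 1.7917e-7, "has_capacitor": true,  "vasoactive": false},
    {"id": "PCA1",  "region": "posterior", "per_side": true,  "diameter_um": 2000, "length_cm": 1.0,   "resistance": 1019,   "number": 1,        "capacitance": 1.2609e-8, "has_capacitor": true,  "vasoactive": false},
    {"id": "PCA2",  "region": "posterior", "per_side": true,  "diameter_um": 2000, "length_cm": 4.72,  "resistance": 4808,   "number": 1,        "capacitance": 5.9514e-8, "has_capacitor": true,  "vasoactive": false},
    {"id": "ACA1",  "region": "anterior",  "per_side": true,  "diameter_um": 1500, "length_cm": 1.57,  "resistance": 5054,   "number": 1,        "capacitance": 1.1135e-8, "has_capacitor": true,  "vasoactive": false},
    {"id": "ACA2",  "region": "anterior",  "per_side": true,  "diameter_um": 1500, "length_cm": 0.672, "resistance": 2163,   "number": 1,        "capacitance": 4.7661e-9, "has_capacitor": true,  "vasoactive": false},
    {"id": "PCoA",  "region": "shared",    "per_side": true,  "diameter_um": 720,  "length_cm": 2.0,   "resistance": 1213,   "number": 1,        "capacitance": 3.2682e-9, "has_capacitor": true,  "vasoactive": false},
    {"id": "ACoA",  "region": "shared",    "per_side": false, "diameter_um": 800,  "length_cm": 0.5,   "resistance": 1989,   "number": 1,        "capacitance": 1.0087e-9, "has_capacitor": true,  "vasoactive": false},
    {"id": "LA_m",  "region": "middle",    "per_side": true,  "diameter_um": 681,  "length_cm": 7.19,  "resistance": 6784,   "number": 80,       "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "SA_m",  "region": "middle",    "per_side": true,  "diameter_um": 148,  "length_cm": 2.76,  "resistance": 11943,  "number": 7746,     "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "CAP_m", "region": "middle",    "per_side": true,  "diameter_um": 6.47, "length_cm": 0.115, "resistance": 11421,  "number": 93646000, "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "SV_m",  "region": "middle",    "per_side": true,  "diameter_um": 319,  "length_cm": 2.76,  "resistance": 561,    "number": 7746,     "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "LV_m",  "region": "middle",    "per_side": true,  "diameter_um": 1463, "length_cm": 7.19,  "resistance": 319,    "number": 80,       "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "LA_a",  "region": "anterior",  "per_side": true,  "diameter_um": 679,  "length_cm": 6.79,  "resistance": 20236,  "number": 26,       "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "SA_a",  "region": "anterior",  "per_side": true,  "diameter_um": 148,  "length_cm": 2.76,  "resistance": 37618,  "number": 2464,     "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "CAP_a", "region": "anterior",  "per_side": true,  "diameter_um": 6.47, "length_cm": 0.115, "resistance": 35957,  "number": 29745000, "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "SV_a",  "region": "anterior",  "per_side": true,  "diameter_um": 319,  "length_cm": 2.76,  "resistance": 1766,   "number": 2464,     "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "LV_a",  "region": "anterior",  "per_side": true,  "diameter_um": 1459, "length_cm": 6.79,  "resistance": 950,    "number": 26,       "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "LA_p",  "region": "posterior", "per_side": true,  "diameter_um": 681,  "length_cm": 7.21,  "resistance": 16473,  "number": 33,       "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "SA_p",  "region": "posterior", "per_side": true,  "diameter_um": 148,  "length_cm": 2.76,  "resistance": 28923,  "number": 3198,     "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "CAP_p", "region": "posterior", "per_side": true,  "diameter_um": 6.47, "length_cm": 0.115, "resistance": 27660,  "number": 38668000, "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "SV_p",  "region": "posterior", "per_side": true,  "diameter_um": 319,  "length_cm": 2.76,  "resistance": 1358,   "number": 3198,     "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "LV_p",  "region": "posterior", "per_side": true,  "diameter_um": 1463, "length_cm": 7.21,  "resistance": 774,    "number": 33,       "capacitance": null, "has_capacitor": false, "vasoactive": false},
    {"id": "COLam", "region": "middle",    "per_side": true,  "diameter_um": 317,  "length_cm": 0.4379, "resistance": 140480, "number": 5,       "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "COLpm", "region": "middle",    "per_side": true,  "diameter_um": 354,  "length_cm": 0.6213, "resistance": 160610, "number": 4,       "capacitance": null, "has_capacitor": false, "vasoactive": true},
    {"id": "V",     "region": "shared",    "per_side": false, "diameter_um": 5553, "length_cm": 7.0,   "resistance": 240,    "number": 1,        "capacitance": 5.4428e-6, "has_capacitor": true,  "vasoactive": false},
    {"id": "VS",    "region": "shared",    "per_side": false, "diameter_um": 6071, "length_cm": 10.0,  "resistance": 240,    "number": 1,        "capacitance": 9.2934e-6, "has_capacitor": true,  "vasoactive": false}
  ]
}
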