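{
  "_comment": "Offline cache for the chemical-information adapter: query name (lower-case) -> IUPAC name, molar mass (g/mol), optional boiling point (°C). Synthetic cache fixture standing in for a remote chemical-database adapter; values from standard reference data.",
  "dcm": {"iupac_name": "dichloromethane", "molar_mass": 84.93, "boiling_point": 39.6},
  "dichloromethane": {"iupac_name": "dichloromethane", "molar_mass": 84.93, "boiling_point": 39.6},
  "thf": {"iupac_name": "oxolane", "molar_mass": 72.11, "boiling_point": 66.0},
  "tetrahydrofuran": {"iupac_name": "oxolane", "molar_mass": 72.11, "boiling_point": 66.0},
  "sodium hydroxide": {"iupac_name": "sodium hydroxide", "molar_mass": 40.0},
  "naoh": {"iupac_name": "sodium hydroxide", "molar_mass": 40.0},
  "hydrochloric acid": {"iupac_name": "hydrochloric acid", "molar_mass": 36.46},
  "hcl": {"iupac_name": "hydrochloric acid", "molar_mass": 36.46},
  "sodium bicarbonate": {"iupac_name": "sodium hydrogen carbonate", "molar_mass": 84.01},
  "sodium sulfate": {"iupac_name": "disodium sulfate", "molar_mass": 142.04},
  "magnesium sulfate": {"iupac_name": "magnesium sulfate", "molar_mass": 120.37},
  "potassium carbonate": {"iupac_name": "dipotassium carbonate", "molar_mass": 138.21},
  "benzaldehyde": {"iupac_name": "benzaldehyde", "molar_mass": 106.12, "boiling_point": 178.7},
  "aniline": {"iupac_name": "aniline", "molar_mass": 93.13, "boiling_point": 184.1},
  "acetic anhydride": {"iupac_name": "acetyl acetate", "molar_mass": 102.09, "boiling_point": 139.8},
  "p-toluenesulfonyl chloride": {"iupac_name": "4-methylbenzenesulfonyl chloride", "molar_mass": 190.65},
  "tscl": {"iupac_name": "4-methylbenzenesulfonyl chloride", "molar_mass": 190.65},
  "benzylidene glucopyranoside": {"iupac_name": "methyl 4,6-O-benzylidene-alpha-D-glucopyranoside", "molar_mass": 282.29},
  "malonic acid": {"iupac_name": "propanedioic acid", "molar_mass": 104.06},
  "morpholine": {"iupac_name": "morpholine", "molar_mass": 87.12, "boiling_point": 129.0},
  "1-fluoro-4-nitrobenzene": {"iupac_name": "1-fluoro-4-nitrobenzene", "molar_mass": 141.1, "boiling_point": 205.0}
}
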