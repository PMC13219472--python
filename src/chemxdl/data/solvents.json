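{
  "_comment": "Local solvent table: common laboratory solvents with boiling point (°C) and density (g/mL) at ~20 °C; values from standard handbook data, rounded.",
  "solvents": {
    "water": {"boiling_point": 100.0, "density": 1.0},
    "methanol": {"boiling_point": 64.7, "density": 0.792},
    "ethanol": {"boiling_point": 78.4, "density": 0.789},
    "isopropanol": {"boiling_point": 82.6, "density": 0.786},
    "n-butanol": {"boiling_point": 117.7, "density": 0.81},
    "acetone": {"boiling_point": 56.1, "density": 0.791},
    "acetonitrile": {"boiling_point": 81.6, "density": 0.786},
    "dichloromethane": {"boiling_point": 39.6, "density": 1.326},
    "chloroform": {"boiling_point": 61.2, "density": 1.489},
    "carbon tetrachloride": {"boiling_point": 76.7, "density": 1.594},
    "diethyl ether": {"boiling_point": 34.6, "density": 0.713},
    "tetrahydrofuran": {"boiling_point": 66.0, "density": 0.889},
    "2-methyltetrahydrofuran": {"boiling_point": 80.2, "density": 0.854},
    "1,4-dioxane": {"boiling_point": 101.1, "density": 1.033},
    "ethyl acetate": {"boiling_point": 77.1, "density": 0.902},
    "toluene": {"boiling_point": 110.6, "density": 0.867},
    "benzene": {"boiling_point": 80.1, "density": 0.876},
    "xylene": {"boiling_point": 139.0, "density": 0.864},
    "hexane": {"boiling_point": 68.7, "density": 0.655},
    "n-heptane": {"boiling_point": 98.4, "density": 0.684},
    "pentane": {"boiling_point": 36.1, "density": 0.626},
    "cyclohexane": {"boiling_point": 80.7, "density": 0.779},
    "petroleum ether": {"boiling_point": 42.0, "density": 0.64},
    "dimethylformamide": {"boiling_point": 153.0, "density": 0.944},
    "dimethylacetamide": {"boiling_point": 165.1, "density": 0.937},
    "dimethyl sulfoxide": {"boiling_point": 189.0, "density": 1.1},
    "n-methyl-2-pyrrolidone": {"boiling_point": 202.0, "density": 1.028},
    "pyridine": {"boiling_point": 115.2, "density": 0.982},
    "triethylamine": {"boiling_point": 88.9, "density": 0.726},
    "acetic acid": {"boiling_point": 117.9, "density": 1.049},
    "formic acid": {"boiling_point": 100.8, "density": 1.22},
    "nitromethane": {"boiling_point": 101.2, "density": 1.137},
    "1,2-dichloroethane": {"boiling_point": 83.5, "density": 1.253},
    "chlorobenzene": {"boiling_point": 131.7, "density": 1.106},
    "anisole": {"boiling_point": 153.7, "density": 0.995},
    "ethylene glycol": {"boiling_point": 197.3, "density": 1.113},
    "glycerol": {"boiling_point": 290.0, "density": 1.261},
    "tert-butanol": {"boiling_point": 82.4, "density": 0.775},
    "methyl tert-butyl ether": {"boiling_point": 55.2, "density": 0.74},
    "1,2-dimethoxyethane": {"boiling_point": 85.0, "density": 0.868},
    "ethylbenzene": {"boiling_point": 136.2, "density": 0.867}
  },
  "aliases": {
    "meoh": "methanol",
    "etoh": "ethanol",
    "ipa": "isopropanol",
    "2-propanol": "isopropanol",
    "mecn": "acetonitrile",
    "acn": "acetonitrile",
    "dcm": "dichloromethane",
    "methylene chloride": "dichloromethane",
    "et2o": "diethyl ether",
    "ether": "diethyl ether",
    "thf": "tetrahydrofuran",
    "2-methf": "2-methyltetrahydrofuran",
    "dioxane": "1,4-dioxane",
    "etoac": "ethyl acetate",
    "ea": "ethyl acetate",
    "dmf": "dimethylformamide",
    "dmac": "dimethylacetamide",
    "dmso": "dimethyl sulfoxide",
    "nmp": "n-methyl-2-pyrrolidone",
    "tea": "triethylamine",
    "et3n": "triethylamine",
    "acoh": "acetic acid",
    "mtbe": "methyl tert-butyl ether",
    "dme": "1,2-dimethoxyethane",
    "tbuoh": "tert-butanol"
  }
}
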