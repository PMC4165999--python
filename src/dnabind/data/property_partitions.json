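[
  {
    "property": "hydrophobicity",
    "class1": "RKEDQN",
    "class2": "GASTPHY",
    "class3": "CLVIMFW"
  },
  {
    "property": "normalized_vdw_volume",
    "class1": "GASTPDC",
    "class2": "NVEQIL",
    "class3": "MHKFRYW"
  },
  {
    "property": "polarity",
    "class1": "LIFWCMVY",
    "class2": "PATGS",
    "class3": "HQRKNED"
  },
  {
    "property": "polarizability",
    "class1": "GASDT",
    "class2": "CPNVEQIL",
    "class3": "KMHFRYW"
  },
  {
    "property": "charge",
    "class1": "KR",
    "class2": "ANCQGHILMFPSTWYV",
    "class3": "DE"
  },
  {
    "property": "secondary_structure",
    "class1": "EALMQKRH",
    "class2": "VIYCWFT",
    "class3": "GNPSD"
  },
  {
    "property": "solvent_accessibility",
    "class1": "ALFCGIVW",
    "class2": "RKQEND",
    "class3": "MSPTHY"
  },
  {
    "property": "surface_tension",
    "class1": "GQDNAHR",
    "class2": "KTSEC",
    "class3": "ILMFPWYV"
  }
]
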