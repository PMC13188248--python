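{
  "comment": "Editable synthetic consensus templates for the domain grammar. All residues outside zinc-coordinating positions avoid C and H so that the zinc-finger grammar scanner never fires inside a linker, Myb, RT, RLE or knuckle template. Replace any template or threshold to retune the detectors; profiles are position-specific log-odds matrices rebuilt from these strings at load time.",
  "znf": {
    "first_pair": {
      "CxC": "CAC",
      "CxxC": "CAEC",
      "CxxxC": "CAEKC",
      "CPCC": "CPCC"
    },
    "mid": "GKAFSRSDELTQ",
    "tail": "IRT"
  },
  "myb": "WTKEEDRLLAELVNKFGPKRWSLI",
  "rle": "KGRNEAWLQPDVTSFY",
  "knuckle": "GQKWNPSTRVELDA",
  "rt_motifs": [
    "GWQTPELRNAFS",
    "LVPKGSTEWRAF",
    "ANDFRQPEYTSW",
    "FADDLSQTWRGN",
    "QGIPQGSVLSPT",
    "YVDDLVLAGNTR",
    "KSLEGWTPVNRQ",
    "RETNWGLPQAFD"
  ],
  "rt_linkers": {
    "A": [
      "PEVRKWGDAF",
      "TNYGSWPLRD",
      "FKEQWAVNST",
      "MSWPRLGYNE",
      "DQTVNFWKAS",
      "YWRGEPASLN",
      "KNLDFTQWGE"
    ],
    "D": [
      "NWTSGQPLRE",
      "AFDKLNQSTV",
      "GWPENRSTLA",
      "QDVFYNWAGT",
      "RSLPMETKWN",
      "TGANQDWFVP",
      "EVLRYWSNTG"
    ]
  },
  "inter_znf_linker": "GSTNQPLE",
  "threshold_fraction": {
    "myb": 0.6,
    "rle": 0.6,
    "knuckle": 0.6,
    "rt": 0.6
  }
}
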