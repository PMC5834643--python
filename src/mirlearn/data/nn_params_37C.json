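{
  "comment": "Nearest-neighbor RNA free-energy parameters at 37 C (kcal/mol). Watson-Crick stack values follow Xia et al. 1998, G-U wobble stacks follow Mathews et al. 1999 (Turner-style set). Stacks are keyed 'p1:p2' where p1=(5' base, paired base) of the outer pair and p2 of the inner pair read into the helix: 5'-X1 X2-3' / 3'-Y1 Y2-5' is 'X1Y1:X2Y2'. Loop penalties are Jacobson-Stockmayer extrapolated beyond the tabulated sizes.",
  "temperature_c": 37.0,
  "RT": 0.61633,
  "init_penalty": 4.09,
  "au_end_penalty": 0.45,
  "stacks": {
    "AU:AU": -0.93, "AU:CG": -2.24, "AU:GC": -2.08, "AU:UA": -1.10, "AU:GU": -0.55, "AU:UG": -1.36,
    "CG:AU": -2.11, "CG:CG": -3.26, "CG:GC": -2.36, "CG:UA": -2.08, "CG:GU": -1.41, "CG:UG": -2.11,
    "GC:AU": -2.35, "GC:CG": -3.42, "GC:GC": -3.26, "GC:UA": -2.24, "GC:GU": -1.53, "GC:UG": -2.51,
    "UA:AU": -1.33, "UA:CG": -2.35, "UA:GC": -2.11, "UA:UA": -0.93, "UA:GU": -1.00, "UA:UG": -1.27,
    "GU:AU": -1.27, "GU:CG": -2.51, "GU:GC": -2.11, "GU:UA": -1.36, "GU:GU": -0.50, "GU:UG": 1.29,
    "UG:AU": -1.00, "UG:CG": -1.53, "UG:GC": -1.41, "UG:UA": -0.55, "UG:GU": 0.30, "UG:UG": -0.50
  },
  "hairpin_loop": {"3": 5.4, "4": 5.6, "5": 5.7, "6": 5.4, "7": 6.0, "8": 5.5, "9": 6.4},
  "bulge_loop": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal_loop": {"2": 1.5, "3": 1.6, "4": 1.7, "5": 1.8, "6": 2.0},
  "loop_extrapolation_coef": 1.75,
  "max_loop_size": 30,
  "multiloop": {"closing": 3.4, "branch": 0.4, "unpaired": 0.0}
}
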