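{
 "scales": {
  "hydropathicity": {
   "citation": "Kyte & Doolittle (1982) J Mol Biol 157:105-132",
   "values": {
    "A": 1.8,
    "C": 2.5,
    "D": -3.5,
    "E": -3.5,
    "F": 2.8,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "K": -3.9,
    "L": 3.8,
    "M": 1.9,
    "N": -3.5,
    "P": -1.6,
    "Q": -3.5,
    "R": -4.5,
    "S": -0.8,
    "T": -0.7,
    "V": 4.2,
    "W": -0.9,
    "Y": -1.3
   }
  },
  "hydrophobicity": {
   "citation": "Eisenberg et al. (1984) consensus hydrophobicity scale",
   "values": {
    "A": 0.62,
    "C": 0.29,
    "D": -0.9,
    "E": -0.74,
    "F": 1.19,
    "G": 0.48,
    "H": -0.4,
    "I": 1.38,
    "K": -1.5,
    "L": 1.06,
    "M": 0.64,
    "N": -0.78,
    "P": 0.12,
    "Q": -0.85,
    "R": -2.53,
    "S": -0.18,
    "T": -0.05,
    "V": 1.08,
    "W": 0.81,
    "Y": 0.26
   }
  },
  "lipophilicity": {
   "citation": "Fauchere & Pliska (1983) side-chain pi (log P contribution)",
   "values": {
    "A": 0.31,
    "C": 1.54,
    "D": -0.77,
    "E": -0.64,
    "F": 1.79,
    "G": 0.0,
    "H": 0.13,
    "I": 1.8,
    "K": -0.99,
    "L": 1.7,
    "M": 1.23,
    "N": -0.6,
    "P": 0.72,
    "Q": -0.22,
    "R": -1.01,
    "S": -0.04,
    "T": 0.26,
    "V": 1.22,
    "W": 2.25,
    "Y": 0.96
   }
  },
  "water_octanol_partition": {
   "citation": "Fauchere & Pliska (1983) octanol/water partition pi values",
   "values": {
    "A": 0.31,
    "C": 1.54,
    "D": -0.77,
    "E": -0.64,
    "F": 1.79,
    "G": 0.0,
    "H": 0.13,
    "I": 1.8,
    "K": -0.99,
    "L": 1.7,
    "M": 1.23,
    "N": -0.6,
    "P": 0.72,
    "Q": -0.22,
    "R": -1.01,
    "S": -0.04,
    "T": 0.26,
    "V": 1.22,
    "W": 2.25,
    "Y": 0.96
   }
  },
  "amphiphilicity": {
   "citation": "Mitaku et al. (2002) amphiphilicity index (AAindex MITS020101)",
   "values": {
    "A": 0.0,
    "C": 0.17,
    "D": 0.0,
    "E": 1.27,
    "F": 0.35,
    "G": 0.0,
    "H": 1.45,
    "I": 0.13,
    "K": 3.67,
    "L": 0.13,
    "M": 1.43,
    "N": 0.0,
    "P": 0.0,
    "Q": 1.25,
    "R": 2.45,
    "S": 0.0,
    "T": 0.0,
    "V": 0.13,
    "W": 1.97,
    "Y": 2.24
   }
  },
  "steric_bulk": {
   "citation": "Charton (1981) steric parameter (AAindex CHAM810101)",
   "values": {
    "A": 0.52,
    "C": 0.62,
    "D": 0.76,
    "E": 0.68,
    "F": 0.7,
    "G": 0.0,
    "H": 0.7,
    "I": 1.02,
    "K": 0.68,
    "L": 0.98,
    "M": 0.78,
    "N": 0.76,
    "P": 0.36,
    "Q": 0.68,
    "R": 0.68,
    "S": 0.53,
    "T": 0.63,
    "V": 0.76,
    "W": 0.7,
    "Y": 0.7
   }
  },
  "side_chain_bulk": {
   "citation": "Zimmerman et al. (1968) bulkiness (AAindex ZIMJ680102)",
   "values": {
    "A": 11.5,
    "C": 13.46,
    "D": 11.68,
    "E": 13.57,
    "F": 19.8,
    "G": 3.4,
    "H": 13.69,
    "I": 21.4,
    "K": 15.71,
    "L": 21.4,
    "M": 16.25,
    "N": 12.82,
    "P": 17.43,
    "Q": 14.45,
    "R": 14.28,
    "S": 9.47,
    "T": 15.77,
    "V": 21.57,
    "W": 21.67,
    "Y": 18.03
   }
  }
 },
 "hbond": {
  "citation": "side-chain H-bond donors minus acceptors; backbone excluded",
  "values": {
   "A": 0,
   "C": 1,
   "D": -4,
   "E": -4,
   "F": 0,
   "G": 0,
   "H": 0,
   "I": 0,
   "K": 3,
   "L": 0,
   "M": -1,
   "N": 0,
   "P": 0,
   "Q": 0,
   "R": 5,
   "S": 0,
   "T": 0,
   "V": 0,
   "W": 1,
   "Y": 0
  }
 },
 "mass": {
  "citation": "average residue masses (Da), free-acid/free-amine termini add one water",
  "water": 18.0153,
  "values": {
   "A": 71.0788,
   "C": 103.1388,
   "D": 115.0886,
   "E": 129.1155,
   "F": 147.1766,
   "G": 57.0519,
   "H": 137.1411,
   "I": 113.1594,
   "K": 128.1741,
   "L": 113.1594,
   "M": 131.1926,
   "N": 114.1038,
   "P": 97.1167,
   "Q": 128.1307,
   "R": 156.1875,
   "S": 87.0782,
   "T": 101.1051,
   "V": 99.1326,
   "W": 186.2132,
   "Y": 163.176
  }
 },
 "chou_fasman": {
  "citation": "Chou & Fasman (1978) conformational propensities; coil uses the turn parameter",
  "helix": {
   "A": 1.42,
   "C": 0.7,
   "D": 1.01,
   "E": 1.51,
   "F": 1.13,
   "G": 0.57,
   "H": 1.0,
   "I": 1.08,
   "K": 1.16,
   "L": 1.21,
   "M": 1.45,
   "N": 0.67,
   "P": 0.57,
   "Q": 1.11,
   "R": 0.98,
   "S": 0.77,
   "T": 0.83,
   "V": 1.06,
   "W": 1.08,
   "Y": 0.69
  },
  "sheet": {
   "A": 0.83,
   "C": 1.19,
   "D": 0.54,
   "E": 0.37,
   "F": 1.38,
   "G": 0.75,
   "H": 0.87,
   "I": 1.6,
   "K": 0.74,
   "L": 1.3,
   "M": 1.05,
   "N": 0.89,
   "P": 0.55,
   "Q": 1.1,
   "R": 0.93,
   "S": 0.75,
   "T": 1.19,
   "V": 1.7,
   "W": 1.37,
   "Y": 1.47
  },
  "coil": {
   "A": 0.66,
   "C": 1.19,
   "D": 1.46,
   "E": 0.74,
   "F": 0.6,
   "G": 1.56,
   "H": 0.95,
   "I": 0.47,
   "K": 1.01,
   "L": 0.59,
   "M": 0.6,
   "N": 1.56,
   "P": 1.52,
   "Q": 0.98,
   "R": 0.95,
   "S": 1.43,
   "T": 0.96,
   "V": 0.5,
   "W": 0.96,
   "Y": 1.14
  }
 },
 "pka": {
  "citation": "EMBOSS iep pKa set",
  "nterm": 8.6,
  "cterm": 3.6,
  "sidechain": {
   "C": 8.5,
   "D": 3.9,
   "E": 4.1,
   "H": 6.5,
   "K": 10.8,
   "R": 12.5,
   "Y": 10.1
  },
  "basic": [
   "H",
   "K",
   "R"
  ]
 }
}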