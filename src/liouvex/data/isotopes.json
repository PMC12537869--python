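{
  "1H":  {"spin": 0.5, "gamma": 267522187.44},
  "2H":  {"spin": 1.0, "gamma": 41066279.1},
  "13C": {"spin": 0.5, "gamma": 67282840.0},
  "14N": {"spin": 1.0, "gamma": 19337792.0},
  "15N": {"spin": 0.5, "gamma": -27116188.0},
  "17O": {"spin": 2.5, "gamma": -36280800.0},
  "19F": {"spin": 0.5, "gamma": 251814800.0},
  "29Si": {"spin": 0.5, "gamma": -53190000.0},
  "31P": {"spin": 0.5, "gamma": 108394000.0},
  "e-":  {"spin": 0.5, "gamma": -176085963023.0}
}
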