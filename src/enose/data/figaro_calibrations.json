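{
  "version": 1,
  "description": "Figaro MOS sensor power-law sensitivity constants Rs = A*C^alpha, per sensor model and gas, digitized from the manufacturer datasheet sensitivity curves by log-log regression. Entries with available=false are gases the datasheet does not characterize for that model.",
  "models": {
    "TGS-2611E00": {
      "methane":   {"A": 29.37996766, "alpha": -0.3948275158, "available": true},
      "isobutane": {"A": 8.715280172, "alpha": -0.009612300255, "available": true},
      "hydrogen":  {"A": 26.35859083, "alpha": -0.3145073661, "available": true},
      "propane":   {"available": false},
      "ethanol":   {"A": 8.592741295, "alpha": 0.0, "available": true},
      "air":       {"A": 8.584894051, "alpha": 0.0, "available": true},
      "co":        {"available": false}
    },
    "TGS-2611C00": {
      "methane":   {"A": 38.98893094, "alpha": -0.4294309742, "available": true},
      "isobutane": {"A": 48.40386618, "alpha": -0.3910578991, "available": true},
      "hydrogen":  {"A": 41.48221372, "alpha": -0.3609195915, "available": true},
      "propane":   {"available": false},
      "ethanol":   {"A": 55.17922683, "alpha": -0.3750828308, "available": true},
      "air":       {"A": 8.584894051, "alpha": 0.0, "available": true},
      "co":        {"available": false}
    },
    "TGS-2610C00": {
      "methane":   {"A": 62.22614045, "alpha": -0.5290784226, "available": true},
      "isobutane": {"A": 76.61767488, "alpha": -0.58687488, "available": true},
      "hydrogen":  {"A": 83.58818144, "alpha": -0.5147845058, "available": true},
      "propane":   {"A": 79.41376581, "alpha": -0.52781418, "available": true},
      "ethanol":   {"A": 127.3119505, "alpha": -0.5258350324, "available": true},
      "air":       {"A": 10.54330923, "alpha": -0.001766784452, "available": true},
      "co":        {"available": false}
    },
    "TGS-2620": {
      "methane":   {"A": 79.49594193, "alpha": -0.4602952512, "available": true},
      "isobutane": {"A": 26.88377546, "alpha": -0.5979539273, "available": true},
      "hydrogen":  {"A": 17.6124846, "alpha": -0.5785034943, "available": true},
      "propane":   {"available": false},
      "ethanol":   {"A": 35.89744669, "alpha": -0.7083796675, "available": true},
      "air":       {"A": 17.58233645, "alpha": 0.0, "available": true},
      "co":        {"available": true, "A": 47.99739024, "alpha": -0.6086910204}
    }
  }
}
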