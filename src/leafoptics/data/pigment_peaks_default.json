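{
  "name": "table6-default",
  "grid": {"start": 400, "stop": 800, "step": 1},
  "peaks": [
    {"pigment": "Chla", "j": 1, "v": 0.80, "h": 0.153, "w": 51, "A_p": 432, "delta": -13, "raf": "400-434"},
    {"pigment": "Chla", "j": 2, "v": 1.00, "h": 0.016, "w": 113, "A_p": 580, "delta": 11},
    {"pigment": "Chla", "j": 3, "v": 0.78, "h": 0.008, "w": 182, "A_p": 618, "delta": 9},
    {"pigment": "Chla", "j": 4, "v": 0.37, "h": 0.049, "w": 25, "A_p": 664, "delta": 15, "raf": "659-699"},
    {"pigment": "Chlb", "j": 1, "v": 0.45, "h": 0.254, "w": 60, "A_p": 458, "delta": 4, "p_invivo": 468, "raf": "442-495"},
    {"pigment": "Chlb", "j": 2, "v": 0.75, "h": 0.017, "w": 42, "A_p": 602, "delta": 9, "p_invivo": 612},
    {"pigment": "Chlb", "j": 3, "v": 0.44, "h": 0.106, "w": 57, "A_p": 650, "delta": 11, "raf": "639-683"},
    {"pigment": "Cars", "j": 1, "v": 0.5, "h": 0.067, "w": 56, "A_p": 443, "delta": 39, "raf": "447-517"},
    {"pigment": "Ants", "j": 1, "v": 0.45, "h": 0.099, "w": 100, "A_p": 530, "delta": 14, "raf": "494-594"}
  ]
}
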