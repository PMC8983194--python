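{
 "description": "Deep-groove ball-bearing endurance data (millions of revolutions), Type I generalized progressive hybrid censoring, threshold T=110 (all m planned failures observed).",
 "n": 23,
 "m": 15,
 "k": 9,
 "T": "110",
 "R": [2, 0, 0, 0, 0, 0, 0, 0, 3, 0, 0, 0, 0, 0, 3],
 "y": ["17.88", "28.92", "33.00", "42.12", "45.60", "48.80", "51.84", "51.96", "54.12", "55.56", "67.80", "68.88", "98.64", "105.12", "105.84"],
 "D_star": 15,
 "R_star": [2, 0, 0, 0, 0, 0, 0, 0, 3, 0, 0, 0, 0, 0, 3],
 "R_tau": 0,
 "T_star": "105.84",
 "case": "AFTER_M"
}
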