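{
 "description": "Deep-groove ball-bearing endurance data (millions of revolutions), Type I generalized progressive hybrid censoring, threshold T=50 (termination before the k-th failure).",
 "n": 23,
 "m": 15,
 "k": 9,
 "T": "50",
 "R": [2, 0, 0, 0, 0, 0, 0, 0, 3, 0, 0, 0, 0, 0, 3],
 "y": ["17.88", "28.92", "33.00", "42.12", "45.60", "48.80", "51.84", "51.96", "54.12"],
 "D_star": 9,
 "R_star": [2, 0, 0, 0, 0, 0, 0, 0, 12],
 "R_tau": 0,
 "T_star": "54.12",
 "case": "BEFORE_K"
}
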