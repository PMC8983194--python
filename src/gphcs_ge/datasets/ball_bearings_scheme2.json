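{
 "description": "Deep-groove ball-bearing endurance data (millions of revolutions), Type I generalized progressive hybrid censoring, threshold T=80 (termination at T between the k-th and m-th failures).",
 "n": 23,
 "m": 15,
 "k": 9,
 "T": "80",
 "R": [2, 0, 0, 0, 0, 0, 0, 0, 3, 0, 0, 0, 0, 0, 3],
 "y": ["17.88", "28.92", "33.00", "42.12", "45.60", "48.80", "51.84", "51.96", "54.12", "55.56", "67.80", "68.88"],
 "D_star": 12,
 "R_star": [2, 0, 0, 0, 0, 0, 0, 0, 3, 0, 0, 0],
 "R_tau": 6,
 "T_star": "80",
 "case": "BETWEEN"
}
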