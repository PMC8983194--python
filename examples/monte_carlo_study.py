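"""A small Monte-Carlo study cell: estimator quality under censoring.

Runs 300 replications of the (k=25, m=50, n=60), T=1.5, scheme-1 design at
truth GE(2, 1.2) and prints bias, MSE and interval coverage for the ML
estimators.  (The full benchmark grid uses 1000 replications over
(k,m) x T x scheme; see gphcs_ge.study.run_grid and the study CLI.)
"""

from gphcs_ge import StudyConfig, run_cell

cfg = StudyConfig(replications=300, root_seed=0)
cell = run_cell(cfg, k=25, m=50, T=1.5, scheme=1)

print(f"replications used: {cell.n_used} (failed fits: {cell.n_failed})")
print(f"{'estimand':9s} {'mean':>8s} {'bias':>8s} {'MSE':>8s} {'AL':>8s} {'CP':>6s}")
for est in ("alpha", "lambda", "S", "H"):
    pm = cell.point[(est, "ML")]
    im = cell.interval[(est, "ML")]
    print(f"{est:9s} {pm['mean']:8.4f} {pm['EB']:8.4f} {pm['MSE']:8.4f} "
          f"{im['AL']:8.4f} {im['CP']:6.3f}")

print()
print("CP is the fraction of 95% intervals covering the truth (alpha=2,")
print("lambda=1.2, S(0.6)=0.7366, H(0.6)=0.8140); values near 0.95 mean the")
print("asymptotic intervals are well calibrated at this sample size.")
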