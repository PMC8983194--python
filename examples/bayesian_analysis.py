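"""Bayesian analysis of the ball-bearing data with two priors.

Runs the MH-within-Gibbs sampler (N = 11000, burn-in 1000) on the T = 50
dataset under an informative gamma prior and the noninformative limit, and
prints posterior means with 95% credible intervals.
"""

from gphcs_ge import (
    MCMCConfig,
    PriorSpec,
    credible_intervals,
    load_ball_bearings,
    mh_within_gibbs,
    posterior_point_estimates,
)

_, sample = load_ball_bearings(1)
priors = {
    "informative Gamma(1,2) x Gamma(1,2)": PriorSpec(1, 2, 1, 2),
    "noninformative 1/(alpha*lambda)": PriorSpec(),
}

for label, prior in priors.items():
    draws = mh_within_gibbs(sample, prior, MCMCConfig(N=11_000, B=1_000, seed=7))
    a, l, S, H = posterior_point_estimates(draws, 50.0)
    ci = credible_intervals(draws, 50.0, 0.05)
    print(label)
    print(f"  acceptance rates: alpha {draws.accept_rate_alpha:.2f}, "
          f"lambda {draws.accept_rate_lambda:.2f}")
    for name, mean, iv in zip(("alpha", "lambda", "S(50)", "H(50)"),
                              (a, l, S, H), ci):
        print(f"  {name:7s} = {mean:7.4f}  95% CrI ({iv.lower:.4f}, {iv.upper:.4f})")
    print()

print("The informative prior has mean 0.5 for both parameters, so it pulls")
print("the posterior strongly toward small values on these 9 failures; the")
print("noninformative posterior centers near the maximum likelihood fit.")
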