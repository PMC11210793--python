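"""Bootstrap estimation statistics: effect size of a compound vs the null.

Compares pooled worm positions under a test compound against the symmetric
solvent condition: the point estimate is the plain difference of means; the
95% CI comes from 5,000 bootstrap resamples, and the CI converts to an exact
two-sided p-value via the bootstrap ECDF.
"""

import chemotax as ct

test = ct.sample_endpoint_positions(
    ct.PositionModel(drift_mu=7.5, spread_sigma=10.0, n_worms=750, seed=1)
)
null = ct.sample_endpoint_positions(
    ct.PositionModel(drift_mu=0.0, spread_sigma=10.0, n_worms=1000, seed=2)
)

eff = ct.bootstrap_mean_difference(test.z, null.z, n_resamples=5000, seed=7,
                                   label="demo compound")
print(f"mean difference: {eff.mean_difference:+.2f} mm")
print(f"95% CI:          [{eff.ci_low:+.2f}, {eff.ci_high:+.2f}] mm")
print(f"p-value:         {eff.p_value:.4g}")
print(f"significant:     {eff.significant}")

# multiple-testing control across a screen's worth of p-values
pvals = [eff.p_value, 0.03, 0.2, 0.8, 0.001]
for p, rec in zip(pvals, ct.benjamini_hochberg(pvals, fdr=0.05)):
    print(f"  raw p={p:<8.4g} adjusted={rec.adjusted_p:.4g} rejected={rec.rejected}")
# A CI excluding zero (equivalently p < 0.05) calls the compound chemoactive;
# BH step-up keeps the false discovery rate of the whole screen at 5%.
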