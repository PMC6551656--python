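"""Two-group differential methylation on a simulated AML-like cohort.

Simulates 28 mutant vs 112 wildtype methylomes with hypermethylation
(+0.2 beta) planted at 10% of 10,000 probes, applies probe QC, runs the
empirical-Bayes moderated t-test and prints what was found.
"""

import methylotype as mt

beta, detp, sheet, truth = mt.simulate_cohort(
    n_wt=28, n_mut=112, n_probes=10_000, frac_dmp=0.1, delta=0.2, seed=1
)
manifest = mt.simulate_manifest(
    10_000, seed=2, sex_fraction=0.03,
    mask_fractions={"cross_reactive": 0.02, "snp_overlap": 0.02},
)

filtered, report = mt.filter_probes(beta, detp, manifest)
print(f"QC: {report.n_input} -> {report.n_retained} probes, removed {report.counts}")

fit = mt.fit_groups(filtered, sheet["idh_status"])
prior = mt.estimate_prior(fit.s2, fit.df)
table = mt.moderated_test(fit, prior)

sig = table[table["adj_p"] < 0.05]
print(f"prior: d0={prior.d0:.1f}, s0^2={prior.s0_sq:.2g}")
print(f"{len(sig)} significant probes; {(sig.direction == 'hyper').sum()} hyper, "
      f"{(sig.direction == 'hypo').sum()} hypo")
print(f"mean delta beta of significant hyper probes: "
      f"{sig.loc[sig.direction == 'hyper', 'delta_beta'].mean():.3f}")

strat = mt.stratify_by_feature(table, manifest, filtered, sheet["idh_status"])
print("\nper-feature summary of significant probes (delta = MUT - WT):")
print(strat[["n_probes", "delta_beta", "welch_p"]].to_string())

# The delta beta near the planted 0.2 and the strong hyper excess show the
# moderated test recovering the planted hypermethylation; every island
# relation category carries the shift because it was planted uniformly.
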