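"""Progeny ratio tests and cohort tallies on synthetic data.

Simulates genotyped WZ x WZ progenies, tests them against the Mendelian
3:1 (WZ/ZZ : WW) expectation, then samples a native population at the
stable structure and recovers alpha from its intersex fraction.
"""

from wzpop import (
    Genotype,
    chi_square_gof,
    estimate_alpha_from_cohort,
    progeny_ratio_report,
    simulate_cross,
    simulate_native_population,
    tally_cohort,
)

# three lab progenies of ~80 genotyped offspring each
progenies = {
    f"P{i}": simulate_cross(Genotype.WZ, Genotype.WZ, n=80, alpha=0.04, seed=100 + i)
    for i in (1, 2, 3)
}
report = progeny_ratio_report(progenies)
print(report[["progeny", "n", "obs_WZ/ZZ", "obs_WW", "chi2", "p"]].to_string(index=False))
# Under the true 3:1 null the chi-square p-values are large: the observed
# WW share is consistent with one quarter of the progeny.

print()
res = chi_square_gof((66, 17), (3, 1))
print(f"counts (66, 17) vs 3:1 -> chi2 = {res.chi2:.3f}, p = {res.p:.2f}")

# a native population sampled at the stable structure
recs = simulate_native_population(n=10_000, alpha=0.04, seed=7)
s = tally_cohort(recs)
alpha_hat = estimate_alpha_from_cohort(s.n_intersex / s.n)
print(f"\nnative cohort n={s.n}: F:M = {s.fm_ratio:.2f}, "
      f"intersex = {100 * s.n_intersex / s.n:.2f}%, WW% = {s.ww_percent}")
print(f"alpha estimate (2 x intersex fraction): {alpha_hat:.3f}")
# Near the stable structure the intersex fraction is about alpha/2, so
# doubling it recovers the generating alpha = 0.04.
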