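"""Type individual hosts as N, S or Mix carriers.

Chromatogram peak heights at diagnostic sites classify each individual
(secondary peak >= 25% of the major peak = both strains present); deep
read counts expose a cryptic ~8.6% minor strain that Sanger peaks miss.
"""

import symbiostrain as st
from symbiostrain.genotyping import call_individuals

pair = st.gen_strain_pair(st.StrainPairModel(1, 20_000, 0.65, seed=9))

individuals, _, peaks = st.simulate_individuals(
    79, (0.45, 0.45, 0.10), pair.sites,
    st.IndividualSpec(cryptic_fraction=0.0859, noise_sd=0.05), seed=10,
)
fragment_calls = call_individuals(peaks, tau=0.25)
consistency = st.amplicon_consistency(fragment_calls)
consensus = fragment_calls.groupby("individual")["consensus"].first()
cohort = st.cohort_frequencies(consensus, label="field sample")

print(f"cohort n = {cohort.n}; counts {cohort.counts}")
print(f"S-type frequency {cohort.s_frequency:.2%} "
      f"(S or Mix: {cohort.s_or_mix_frequency:.2%})")
print(f"cross-amplicon consistency: {consistency.rate:.2%}")

# the cryptic co-infection is invisible above, but a deep pileup of one
# "pure S" individual recovers it:
deep = st.simulate_pool_pileup(pair.sites, st.PoolSpec("deep", 1 - 0.0859, 100, seed=11))
est = st.estimate_mixture_fraction(deep)
print(f"deep-sequenced S individual: minor (N) strain fraction "
      f"{100 * (1 - est.fraction):.2f}% "
      f"[{100 * (1 - est.ci_high):.2f}, {100 * (1 - est.ci_low):.2f}]")
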