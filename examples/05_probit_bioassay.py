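"""Fit an LC-P (log-concentration probit) mortality line.

Simulates a stem-dip style assay — 5 imidacloprid concentrations,
triplicate cups of 20 nymphs — and recovers the lethal concentrations
with 95% Fieller confidence limits.
"""

import symbiostrain as st

records = st.simulate_dose_response(
    lc50=10.0, slope=2.0, doses=[1.0, 3.16, 10.0, 31.6, 100.0],
    n_per_dose=20, n_replicates=3, seed=12,
)
fit = st.fit_probit(records)

print(f"LC-P line: probit(mortality) = {fit.intercept:.3f} "
      f"+ {fit.slope:.3f} x log10(concentration)")
for lc in (fit.lc10, fit.lc50, fit.lc90):
    print(f"LC{int(lc.quantile * 100):>2} = {lc.value:7.3f} mg/L "
          f"95% CL [{lc.ci_low:.3f}, {lc.ci_high:.3f}] ({lc.method})")
print(f"heterogeneity chi2 = {fit.heterogeneity_chi2:.2f} "
      f"on {fit.heterogeneity_df} df")

# LC10/LC90 bracket the screening doses used to call individuals
# susceptible (die at LC10) or resistant (survive LC90).
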