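"""Closed-form demographic estimates from genome-wide summary statistics.

Feeds the published genome-scale inputs (Watterson's theta, genome-wide FST,
synonymous divergence, population recombination rate) through the closed-form
chain: Ne from theta, scaled and absolute split times from FST, the
interspecies divergence date from dS, and the per-generation recombination
rate from rho.
"""

from krillpop import demography as dm

u = 2.64e-9          # mutations per site per generation (decapod clock)
theta_w = 0.0162     # genome-wide Watterson's theta per base
fst = 0.056          # genome-wide FST, ocean-vs-sea contrast
dS = 0.46            # synonymous divergence to the sister krill species
rho = 0.013          # population recombination rate per base

ne = dm.ne_from_theta(theta_w, u)
T = dm.split_time_from_fst(fst)
t = dm.generations(T, 1.53e6)
years = dm.divergence_time_years(dS, 1.5, u)
r, cm_mb = dm.rec_rate_from_rho(rho, 1.02e6)

print(f"Ne = theta/4u                : {ne:,.0f} diploids")
print(f"scaled split time T          : {T:.5f}  (dimensionless)")
print(f"generations since split      : {t:,.0f}  (T * 4 * Ne, Ne = 1.53e6)")
print(f"species divergence           : {years / 1e6:.0f} million years (dS clock)")
print(f"recombination rate           : {r:.2e} /bp/gen = {cm_mb:.2f} cM/Mb")
print()
print("Ne is the long-term effective size under mutation-drift equilibrium;")
print("t dates the between-basin population split on the coalescent clock.")
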