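"""Maintenance-energy estimation from chemostat data.

At steady state the specific growth rate equals the dilution rate D, so
the ATP production rate (uptake x ATP yield) is linear in D: the slope
is the growth-associated maintenance GAM (mmol ATP per gDCW of biomass)
and the intercept the non-growth-associated maintenance NGAM (mmol ATP
per gDCW per hour).  Here we simulate 20 noisy glycerol-chemostat
measurements (18.5 ATP per glycerol fully oxidized) and recover both.
"""

from fluxkit import estimate_maintenance, make_chemostat_data

TRUTH_GAM, TRUTH_NGAM, ATP_YIELD = 86.7881, 7.8625, 18.5

df = make_chemostat_data(gam=TRUTH_GAM, ngam=TRUTH_NGAM, atp_yield=ATP_YIELD,
                         sigma=0.02, seed=7)
print(f"{len(df)} simulated chemostat points, 2% relative noise; first three:")
print(df.head(3).to_string(index=False))

params = estimate_maintenance(list(zip(df.dilution_rate, df.uptake)),
                              atp_yield=ATP_YIELD)
print(f"\nrecovered GAM  = {params.gam:8.3f} (truth {TRUTH_GAM}, "
      f"error {100*abs(params.gam-TRUTH_GAM)/TRUTH_GAM:.1f}%)")
print(f"recovered NGAM = {params.ngam:8.3f} (truth {TRUTH_NGAM}, "
      f"error {100*abs(params.ngam-TRUTH_NGAM)/TRUTH_NGAM:.1f}%)")
print("both land within a few percent — the linear fit is well conditioned "
      "once the dilution rates span a reasonable range.")
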