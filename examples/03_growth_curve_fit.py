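"""Concentration dependence of growth and the apparent rate constants.

Simulates an all-GMPCPP concentration series for the plus end and fits a
1/SEM-weighted line, reporting the apparent on-rate constant (slope, in
dimers per second per uM per microtubule) and the apparent critical
concentration (x-intercept).  At full scale (50 x 600 s per point) the
slope is ~3.5 dimers/s/uM/MT; the small ensembles here run in seconds and
are noisier.
"""

from mtelong import FITTED_PARAMS, gmpcpp_series_fit

ms, fit = gmpcpp_series_fit(
    FITTED_PARAMS, "plus", n_replicates=15, duration=400.0, rng_seed=4
)

print("tubulin_uM  rate_nm_s  sd")
for m in ms:
    print(f"{m.condition['tubulin_uM']:>10.3g}  {m.mean_rate:>8.3f}  {m.sd:.3f}")
print(f"\nslope    = {fit.slope:.3f} nm s^-1 uM^-1")
print(f"kon_app  = {fit.kon_app:.2f} dimers s^-1 uM^-1 MT^-1")
print(f"cc_app   = {fit.cc_app * 1000:.0f} nM")
print(
    "\nkon_app is well below 13 x kon (9.6): only a fraction of landings\n"
    "occur at corner sites that retain the new subunit."
)
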