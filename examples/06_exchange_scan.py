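"""Nucleotide exchange mitigates plus-end poisoning by GDP-tubulin.

Scans the terminal nucleotide exchange rate at two GDP-tubulin fractions
(1.25 uM tubulin, interface-acting mechanism).  Without exchange, a
GDP-bound dimer landing on a GMPCPP tip resides for minutes and stalls
its protofilament; replacing its exposed nucleotide with GMPCPP from
solution lets growth resume, so faster exchange yields faster growth at
any fixed GDP-tubulin fraction.
"""

from mtelong import FITTED_PARAMS, exchange_scan

result = exchange_scan(
    k_exch_grid=[0.0, 0.2, 0.4, 0.8],
    gdp_fractions=[0.25, 0.4],
    params=FITTED_PARAMS,
    tubulin_uM=1.25,
    n_replicates=12,
    duration=300.0,
    rng_seed=9,
)
table = result.surface.pivot(index="gdp_frac", columns="k_exch", values="mean_nm_s")
print("plus-end growth rate (nm/s) vs exchange rate (columns, s^-1):")
print(table.round(2).to_string())
print(
    "\nRows are GDP-tubulin fractions; growth increases monotonically with\n"
    "the exchange rate as poisoned tips are rescued."
)
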