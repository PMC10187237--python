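"""Simulate GMPCPP microtubule growth at both ends.

Runs kinetic Monte Carlo ensembles at 1.25 uM all-GMPCPP tubulin with the
fitted parameter set and reports the mean elongation rate of each end.
The plus end grows roughly twice as fast as the minus end because its
on-rate constant is ~2.4-fold higher while both ends share the same
interaction affinities (and hence the same critical concentration).
"""

from mtelong import FITTED_PARAMS, growth_point

for end in ("plus", "minus"):
    m = growth_point(
        FITTED_PARAMS, end, tubulin_uM=1.25, n_replicates=20, duration=600.0, rng_seed=1
    )
    print(f"{end:>5}-end: {m.mean_rate:.2f} +/- {m.sd:.2f} nm/s  (n={m.n})")

print(
    "\nEach rate is the mean of per-trajectory slopes of mean protofilament\n"
    "length vs time; +/- is the ensemble standard deviation."
)
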