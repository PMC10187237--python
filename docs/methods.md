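# Methods

## Model overview

`mtelong` simulates elongation of one microtubule end as a continuous-time
Markov chain over a protofilament-resolved lattice. Each of the 13
protofilaments is a gap-free column of αβ-tubulin dimers; each dimer
carries the nucleotide of its β-tubulin exchangeable site, either GMPCPP
(the GTP-like state, written CPP) or GDP. Three reactions fire one at a
time (Gillespie direct method):

* **association** — a dimer from solution lands on a protofilament tip at
  rate `kon·[tubulin]` per protofilament. The landing dimer's nucleotide
  is drawn from the GDP-tubulin fraction of the pool at firing time; both
  species share the same on-rate constant, so this is exactly equivalent
  to two parallel species channels.
* **dissociation** — the terminal dimer of a protofilament leaves at
  `koff = kon·KD`, where the site affinity KD depends on its lattice
  contacts and on the governing nucleotide (below). Seed subunits never
  dissociate.
* **nucleotide exchange** — the exposed exchangeable site of a terminal
  *plus-end* dimer loses its nucleotide at `k_exch_gdp` (GDP-bound) or
  `affinity_ratio × k_exch_gdp` (GMPCPP-bound; the weaker-binding
  nucleotide leaves faster in proportion to the affinity ratio), and is
  replaced by CPP or GDP in proportion to the free nucleotide
  concentrations. The minus end has no exchange channels: its terminal
  exchangeable site is buried in the lattice.

GTP/GMPCPP hydrolysis is deliberately absent: the model targets
GMPCPP/GDP mixture experiments in which the lattice is locked in a
GTP-like state and catastrophe is suppressed. Tubulin conformational
states are not modelled. The solution is an infinite reservoir (single
microtubules cannot deplete micromolar tubulin or millimolar nucleotide).

## Mechanisms of nucleotide action

The *governing nucleotide* of a terminal dimer — the one that sets its
dissociation affinity — encodes the two competing mechanisms:

* `interface_acting`: the nucleotide buried at the dimer's longitudinal
  interface with the lattice. At the plus end this is the nucleotide of
  the subunit *below* the tip; at the minus end it is the tip's own.
* `self_acting`: the dimer's own nucleotide at either end.

At the minus end both rules select the same nucleotide, so minus-end
trajectories are bitwise identical across mechanisms for a common seed (a
property the tests assert). A GDP-governed interface is weaker by the
multiplicative `gdp_factor`, applied to the longitudinal term only, so
corner and bucket sites inherit exactly the same fold-weakening.

## Lattice registry and site affinities

Sites are named by contact count: *longitudinal-only* (tip contact only),
*corner* (one lateral neighbour), *bucket* (two lateral neighbours), with

```
KD(w) = KD_long · (KD_corner / KD_long)^w
```

where `w` is the total lateral contact weight — bond energies are
additive, so `w = 0, 1, 2` give `KD_long`, `KD_corner`,
`KD_corner²/KD_long`.

On the twelve regular B-lattice interfaces lateral partners sit at the
same dimer layer (the true ~0.9 nm helical stagger is small against the
8 nm dimer): position `(pf, L)` gains a full contact from a neighbour
whose stack covers layer `L`. Consequently a *blunt* region has
bucket-stabilised tips but longitudinal-only landing sites — new layers
must nucleate via a transient longitudinal-only intermediate.

The seam is different. In the 13-protofilament three-start lattice the
helix rises 12 nm per turn against a 8 nm dimer, leaving a half-dimer
registry mismatch at the seam. We render this as a lateral partner
straddling two layers: a seam position collects two half-weight contacts,
one per overlapped layer (e.g. a half contact when the partner stack
covers the lower straddled layer, the other half when it also covers the
upper). The half-stagger makes the seam a weak but persistent step source
that seeds helical growth. The seam offset is configuration
(`LatticeParams.seam_offset`, in dimer layers, fractional values allowed;
default 0.5) and its sign is mirrored at the minus end — the orientation
of seam interactions is the one lattice rule that changes between ends.
This registry was chosen on geometric grounds and because it reproduces
the measured absolute growth rates at both ends (see Limitations for
where it falls short); zero- and integer-offset registries remain
available through configuration.

The lattice is gap-free by construction: association only onto tips,
dissociation only from tips, no internal vacancies, no protofilament
number changes, no sheet/tube closure.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `kon_plus` | plus-end on-rate constant, per protofilament | 0.74 | µM⁻¹ s⁻¹ |
| `kon_minus` | minus-end on-rate constant | 0.31 | µM⁻¹ s⁻¹ |
| `kd_long` | longitudinal-only affinity (CPP-governed) | 86 | µM |
| `kd_corner` | corner affinity (CPP-governed) | 0.025 | µM |
| `gdp_factor` | fold-weakening of a GDP-governed interface | 3500 | — |
| `mechanism` | `interface_acting` / `self_acting` | interface | — |
| `k_exch_gdp` | GDP off-rate from a terminal exchangeable site | 0 (off) | s⁻¹ |
| `affinity_ratio` | KD(GMPCPP)/KD(GDP) for nucleotide binding | 12.5 | — |
| `n_protofilaments` | wall size | 13 | — |
| `seam_offset` | seam registry shift | 0.5 | dimer layers |
| `dimer_rise` | dimer length along a protofilament | 8 | nm |
| seed depth | immutable all-CPP seed layers | 10 | layers |

The default kinetic set (`FITTED_PARAMS`) reproduces measured GMPCPP
growth; `FIG_EXPLORATORY_PARAMS` (`kon = 1.0` both ends, `KD_long = 100`
µM, `KD_corner = 0.1` µM, `gdp_factor = 3000`) is an illustrative set that
supports elongation near 1 µM and is used for the mechanism-discrimination
experiment. Derived rates at 1.25 µM: plus-end on-rate 0.93 s⁻¹/pf,
`koff` 64 s⁻¹ (long), 0.019 s⁻¹ (corner), 2.2×10⁵ and 65 s⁻¹ for their
GDP-governed counterparts. Note a small internal tension in the source
rate tables: the GDP corner affinity implied by `gdp_factor` is
87.5 µM, while the printed corner-GDP off-rates back-compute to ≈88 µM
(printed KD 87). We compute from `gdp_factor`; the discrepancy is below
1%.

Mixtures are specified either by free GDP concentration at 1000 µM total
nucleotide (the GDP-tubulin fraction then follows the competitive
partition with `affinity_ratio`) or directly by GDP-tubulin fraction (the
free concentrations are back-calculated consistently).

## Simulation protocol and observables

Production ensembles are 50 independent replicates of 600 s per condition
(calibration uses 50 × 300 s), sampled at 1 s intervals, matching
1 frame/s imaging. Replicate `i` of master seed `s` always receives the
same counter-based substream (`SeedSequence(s, spawn_key=(i,))`), so
ensembles are order-independent and reusable as common random numbers.

Trajectory length is the *mean* protofilament length above the seed
(`8/13` nm per dimer gained), matching what optical microscopy averages
over the tip. A growth rate is the ordinary least-squares slope of mean
length vs time over `[30 s, end]`; the first 30 s are dropped because the
artificially blunt seed briefly misrepresents tip structure (a
steady-state taper has more corner sites than a blunt end). Ensemble
statistics are the mean and standard deviation of per-trajectory slopes
(n = 50); single-replicate ensembles report SD 0 with a logged warning.

Concentration series are fit by weighted least squares (weights 1/SEM)
with the apparent on-rate constant reported both as the nm/s-per-µM slope
and converted to dimers s⁻¹ µM⁻¹ per microtubule, and the apparent
critical concentration as the x-intercept. Mixture curves are normalized
by the 0%-GDP condition.

## Binding models and fits

The analytical layer implements: the competitive nucleotide partition
(exact form with absolute KDs, and the simplified form valid for
`[GMPCPP] ≫ KD_CPP` — the relative error of the simplification is bounded
by `KD_CPP/[GMPCPP]`); the affine minus-end growth law
(`slope 0.9 nm s⁻¹ µM⁻¹`, `intercept −0.05 nm/s`, stored as data and
replaceable by a fresh concentration-series fit); the 6-Thio-GTP quench
isotherm `y = B − A·L/(L + KD)`; the competition model
`y = C + A·N/(N + KD_nuc·(1 + S/KD_6T))` with the amplitude and reporter
KD externally constrained; and quadrature propagation of relative SEMs for
the inner-filter-corrected fluorescence ratio.

All fits minimise `Σ((y − ŷ)/SEM)²` via `scipy.optimize.curve_fit` with
`absolute_sigma=False`, so estimates *and* standard errors are invariant
to uniform rescaling of the SEM weights; 95% intervals are Wald intervals
from the covariance at the optimum. Negative predicted growth rates are
kept signed for fitting and clamped to zero only for display.

## Calibration

Both calibration procedures are single-free-parameter by design.
`fit_kon_minus` minimises the SEM-weighted squared error between
ensemble-mean simulated minus-end rates and a target concentration series,
holding the affinities at their plus-end values; because every candidate
reuses the same seeds (common random numbers) the loss is deterministic
and a bounded Brent search converges in ~10–25 evaluations. The loss
profile is returned for inspection and non-convexity warnings are logged.
`exchange_scan` evaluates a grid of `k_exch_gdp` across GDP-tubulin
fractions at the plus end and, given a target suppression curve, selects
the grid point with minimal weighted distance.

## Synthetic data

No numerical experimental dataset accompanies the measurements this
package models, so the `datasets` module generates all tabular inputs.
Each generator evaluates its truth model (growth law, isotherm, or
competition model), perturbs the per-condition mean with Gaussian noise of
standard deviation `CV·|mean|/√n` (the SEM of `n` hypothetical replicates;
default CV 5%, n 50 per condition, emulating the tens of growth events per
condition of the real assays), and embeds the truth parameters, seed and
generator version in a `#`-prefixed JSON header. What passing recovery
tests show is that the *fitting layer* is correct and well-calibrated
under the stated noise model; they cannot show that real data satisfy that
noise model (real growth-rate scatter is not exactly Gaussian, SEMs are
themselves estimates, and plate-reader drift is not simulated).

## Numerical choices

* Exact SSA rather than fixed time steps: off-rates span 10⁻³–10⁵ s⁻¹, so
  any fixed step would be either unstable or wasteful.
* The numba kernel rebuilds the full per-protofilament rate table each
  step (39 channels at most); at this size full recomputation is cheaper
  than the bookkeeping risk of incremental updates. A pure-Python
  reference path (`enumerate_events`/`gillespie_step`) implements the
  identical event system and is cross-validated statistically; engine
  exactness is tested against a matrix-exponential solution of the
  two-protofilament toy system.
* Trajectory storage is preallocated from a Poisson bound on arrivals
  (mean + 12 SD, doubled), so the kernel never reallocates.
* Zero-rate channels (e.g. exchange at rate 0) consume no random numbers;
  disabling a channel leaves trajectories bitwise unchanged.
* Derived replicate seeds are 32-bit; the numba RNG is seeded per
  trajectory.
* Degenerate inputs fail loudly: zero-SEM weights, singular designs, flat
  concentration series (undefined critical concentration → NaN plus a
  warning), underdetermined fits.

## Known limitations

* **Low-concentration convexity.** With strict same-layer contacts, new
  layers away from the seam must nucleate through a longitudinal-only
  intermediate, so simulated growth is superlinear in tubulin
  concentration below ~0.5 µM instead of affine. The weighted linear fit
  of a 0.25–1.5 µM series therefore overestimates the apparent critical
  concentration (~150–250 nM vs the measured ~50 nM) and slightly
  overestimates the apparent on-rate constant (~3.5 vs ~3 dimers s⁻¹ µM⁻¹
  MT⁻¹ at the plus end). Absolute rates at ≥1 µM and both minus-end
  constants are reproduced within a few percent. A registry with stronger
  persistent step sources would linearise the low range but overshoots
  measured absolute rates roughly 1.7-fold; the discrepancy localises to
  how lattice geometry sustains corner sites at very low flux.
* No hydrolysis, catastrophe/rescue, mechanical force, lattice defects,
  or protofilament-number variation; no hybrid self+interface mechanisms.
* Exchange is allowed at every non-seed terminal plus-end subunit
  regardless of its site class; the alternative (long-only sites excluded)
  is indistinguishable at the level of the data modelled here.
* The seam stagger magnitude is a convention, not a measured input; it is
  exposed as configuration.
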