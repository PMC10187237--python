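"""Standard in-silico experiments built from the simulator.

These are the canned protocols the analyses and worked examples run:
GMPCPP concentration series with their apparent-rate fits, mixed-nucleotide
suppression curves, and single-condition ensemble growth points.  Problem
sizes default to the production settings (50 replicates of 600 s per
condition).
"""

from __future__ import annotations

from typing import Optional, Sequence

from .engine import SimConfig, run_ensemble
from .lattice import LatticeParams
from .observables import (
    GrowthCurveFit,
    GrowthMeasurement,
    concentration_series_fit,
    ensemble_growth,
)
from .rates import KineticParams, SolutionState

__all__ = [
    "DEFAULT_CONCENTRATIONS_UM",
    "growth_point",
    "concentration_series",
    "gmpcpp_series_fit",
    "mixture_suppression_curve",
]

#: five tubulin concentrations spanning the measured 0.25-1.5 uM range
DEFAULT_CONCENTRATIONS_UM = (0.25, 0.5625, 0.875, 1.1875, 1.5)


def growth_point(
    params: KineticParams,
    end: str,
    tubulin_uM: float,
    gdp_frac: float = 0.0,
    n_replicates: int = 50,
    duration: float = 600.0,
    rng_seed: int = 0,
    lattice: Optional[LatticeParams] = None,
) -> GrowthMeasurement:
    """Ensemble growth rate for one condition."""
    solution = SolutionState.from_gdp_tubulin_fraction(
        tubulin_uM, gdp_frac, params.affinity_ratio
    )
    cfg = SimConfig(
        params=params,
        solution=solution,
        end=end,
        duration=duration,
        n_replicates=n_replicates,
        rng_seed=rng_seed,
        lattice=lattice or LatticeParams(),
    )
    return ensemble_growth(
        run_ensemble(cfg),
        condition=dict(end=end, mechanism=params.mechanism, tubulin_uM=tubulin_uM,
                       gdp_frac=gdp_frac, k_exch=params.k_exch_gdp),
    )


def concentration_series(
    params: KineticParams,
    end: str,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    n_replicates: int = 50,
    duration: float = 600.0,
    rng_seed: int = 0,
    lattice: Optional[LatticeParams] = None,
) -> list[GrowthMeasurement]:
    """All-GMPCPP growth rates over a tubulin concentration series."""
    return [
        growth_point(params, end, c, 0.0, n_replicates, duration,
                     rng_seed + 1000 * j, lattice)
        for j, c in enumerate(concentrations)
    ]


def gmpcpp_series_fit(
    params: KineticParams,
    end: str,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    n_replicates: int = 50,
    duration: float = 600.0,
    rng_seed: int = 0,
    lattice: Optional[LatticeParams] = None,
) -> tuple[list[GrowthMeasurement], GrowthCurveFit]:
    """Concentration series plus its SEM-weighted linear fit.

    The fit reports the apparent on-rate constant both as the nm/s-per-uM
    slope and converted to dimers s^-1 uM^-1 per microtubule.
    """
    lattice = lattice or LatticeParams()
    ms = concentration_series(params, end, concentrations, n_replicates,
                              duration, rng_seed, lattice)
    fit = concentration_series_fit(ms, nm_per_dimer=lattice.length_per_subunit)
    return ms, fit


def mixture_suppression_curve(
    params: KineticParams,
    end: str,
    gdp_fractions: Sequence[float],
    tubulin_uM: float,
    n_replicates: int = 50,
    duration: float = 600.0,
    rng_seed: int = 0,
    lattice: Optional[LatticeParams] = None,
) -> list[GrowthMeasurement]:
    """Growth rates over a series of GDP-tubulin fractions at fixed tubulin.

    Per-fraction seed substreams are fixed by position, so two calls with
    different mechanisms or exchange rates share random numbers
    condition-by-condition.
    """
    return [
        growth_point(params, end, tubulin_uM, f, n_replicates, duration,
                     rng_seed + 1000 * j, lattice)
        for j, f in enumerate(gdp_fractions)
    ]
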