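"""Growth-rate observables: trajectory slopes, ensemble statistics,
concentration-series fits and normalised mixed-nucleotide curves.

Simulated growth rates are ordinary least-squares slopes of mean
protofilament length versus time, taken per trajectory and then averaged
over the ensemble (matching standard-deviation error bars over replicates).
The default fit window starts at 30 s to skip the transient created by the
artificially blunt seed, which briefly over-supplies bucket sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import Trajectory

__all__ = [
    "GrowthMeasurement",
    "GrowthCurveFit",
    "trajectory_growth_rate",
    "ensemble_growth",
    "concentration_series_fit",
    "normalized_mixture_curve",
    "measurements_to_frame",
    "DEFAULT_FIT_START",
]

logger = logging.getLogger(__name__)

#: seconds discarded at the start of each trajectory before slope fitting
DEFAULT_FIT_START = 30.0


@dataclass(frozen=True)
class GrowthMeasurement:
    """Mean +/- SD growth rate (nm/s) of one condition over n replicates."""

    mean_rate: float
    sd: float
    n: int
    condition: dict = field(default_factory=dict)

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)


@dataclass(frozen=True)
class GrowthCurveFit:
    """Weighted linear fit of growth rate versus tubulin concentration.

    ``slope`` and ``intercept`` are in the units of the supplied rates
    (nm/s per uM and nm/s for simulated data); ``cc_app`` is the apparent
    critical concentration, the x-intercept ``-intercept/slope`` (uM).
    ``kon_app`` is the slope converted to dimers s^-1 uM^-1 per microtubule
    when a nm-per-dimer conversion was supplied.
    """

    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    cc_app: float
    kon_app: Optional[float] = None

    def predict(self, conc):
        return self.slope * np.asarray(conc) + self.intercept


def trajectory_growth_rate(
    traj: Trajectory, window: tuple[float, Optional[float]] = (DEFAULT_FIT_START, None)
) -> float:
    """OLS slope (nm/s) of mean length versus time over ``window``."""
    t0, t1 = window
    if t1 is None:
        t1 = float(traj.times[-1])
    if not (traj.times[0] <= t0 < t1 <= traj.times[-1] + 1e-9):
        raise ValueError(f"window {window} outside trajectory span")
    mask = (traj.times >= t0) & (traj.times <= t1)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    t = traj.times[mask]
    y = traj.mean_length[mask]
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)


def ensemble_growth(
    trajs: Sequence[Trajectory],
    window: tuple[float, Optional[float]] = (DEFAULT_FIT_START, None),
    condition: Optional[dict] = None,
) -> GrowthMeasurement:
    """Mean and SD of per-trajectory slopes."""
    if len(trajs) == 0:
        raise ValueError("need at least one trajectory")
    rates = np.array([trajectory_growth_rate(tr, window) for tr in trajs])
    if len(rates) == 1:
        logger.warning("single trajectory: reporting SD = 0 by convention")
        sd = 0.0
    else:
        sd = float(rates.std(ddof=1))
    return GrowthMeasurement(float(rates.mean()), sd, len(rates), condition or {})


def concentration_series_fit(
    measurements,
    nm_per_dimer: Optional[float] = None,
    weighted: bool = True,
) -> GrowthCurveFit:
    """Weighted linear fit of growth rate versus concentration.

    Parameters
    ----------
    measurements
        Either a sequence of :class:`GrowthMeasurement` whose conditions
        carry ``tubulin_uM``, or a DataFrame with columns
        ``tubulin_uM``, ``rate`` and optionally ``sem``.
    nm_per_dimer
        If given, also report the slope as an apparent on-rate constant in
        dimers s^-1 uM^-1 per microtubule (``slope / nm_per_dimer``); pass
        ``dimer_rise / n_protofilaments`` for rates measured in nm/s.
    weighted
        Weight points by 1/SEM where SEMs are available (default).
    """
    if isinstance(measurements, pd.DataFrame):
        conc = measurements["tubulin_uM"].to_numpy(float)
        rate = measurements["rate"].to_numpy(float)
        sem = measurements["sem"].to_numpy(float) if "sem" in measurements else None
    else:
        conc = np.array([m.condition["tubulin_uM"] for m in measurements], float)
        rate = np.array([m.mean_rate for m in measurements], float)
        sem = np.array([m.sem for m in measurements], float)
    if len(conc) < 3:
        raise ValueError("need at least 3 concentrations")
    if len(np.unique(conc)) < 2:
        raise ValueError("singular design: concentrations do not vary")

    if weighted and sem is not None and np.all(sem > 0):
        w = 1.0 / sem
    else:
        w = np.ones_like(conc)
    # np.polyfit weights multiply the residuals, i.e. w = 1/sigma
    coef, cov = np.polyfit(conc, rate, 1, w=w, cov="unscaled")
    slope, intercept = float(coef[0]), float(coef[1])
    slope_se, intercept_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    if abs(slope) < 1e-12:
        warnings.warn("flat concentration series: critical concentration undefined")
        cc = float("nan")
    else:
        cc = -intercept / slope
    kon_app = slope / nm_per_dimer if nm_per_dimer else None
    return GrowthCurveFit(slope, intercept, slope_se, intercept_se, cc, kon_app)


def normalized_mixture_curve(
    measurements: Sequence[GrowthMeasurement],
    reference: GrowthMeasurement,
) -> list[GrowthMeasurement]:
    """Divide each mean and SD by the reference mean (reference maps to 1)."""
    if reference.mean_rate <= 0:
        raise ValueError("reference mean rate must be positive")
    ref = reference.mean_rate
    return [
        GrowthMeasurement(m.mean_rate / ref, m.sd / ref, m.n, dict(m.condition))
        for m in measurements
    ]


def measurements_to_frame(measurements: Sequence[GrowthMeasurement]) -> pd.DataFrame:
    """Tabulate measurements; condition keys become columns."""
    rows = []
    for m in measurements:
        row = dict(m.condition)
        row.update(mean_rate=m.mean_rate, sd=m.sd, n=m.n)
        rows.append(row)
    return pd.DataFrame(rows)
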