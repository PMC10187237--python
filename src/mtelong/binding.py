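"""Closed-form binding and growth models with weighted fits.

Covers the analytical layer that links nucleotide mixtures to growth:

* competitive nucleotide binding — in a GDP/GMPCPP mix at fixed total
  nucleotide, the GMPCPP-tubulin concentration follows a competitive
  inhibition partition governed by the relative affinity
  r = KD(GMPCPP)/KD(GDP);
* the minus-end growth law — an affine function of GMPCPP-tubulin
  concentration (slope 0.9 nm s^-1 uM^-1, intercept -0.05 nm/s from the
  all-GMPCPP control fit), composed with the partition to give growth rate
  versus free GDP with r as the only free parameter;
* tryptophan-quenching binding assays — a 6-Thio-GTP quench isotherm and a
  competition (unquenching) model for unlabelled nucleotides;
* SEM propagation for the inner-filter-corrected fluorescence ratio.

All fits minimise sum(((y - model)/SEM)^2); parameter uncertainties come
from the covariance at the optimum and are invariant to uniform rescaling
of the SEM weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .lattice import ConfigurationError
from .rates import TOTAL_NUCLEOTIDE_UM

__all__ = [
    "NucleotideMix",
    "BindingParams",
    "FitResult",
    "cpp_tubulin_concentration",
    "minus_growth_prediction",
    "fit_affinity_ratio",
    "quench_isotherm",
    "fit_isotherm",
    "competition_model",
    "fit_competition",
    "propagate_sem",
    "GROWTH_SLOPE",
    "GROWTH_INTERCEPT",
]

#: all-GMPCPP minus-end growth law: GR (nm/s) = slope * [CPP-tubulin] + intercept
GROWTH_SLOPE = 0.9
GROWTH_INTERCEPT = -0.05


@dataclass(frozen=True)
class NucleotideMix:
    """GDP/GMPCPP mixture at fixed total nucleotide (uM)."""

    gdp_conc: float
    total: float = TOTAL_NUCLEOTIDE_UM

    def __post_init__(self) -> None:
        if not 0 <= self.gdp_conc <= self.total:
            raise ConfigurationError("gdp_conc must be within [0, total]")

    @property
    def cpp_conc(self) -> float:
        return self.total - self.gdp_conc


@dataclass(frozen=True)
class BindingParams:
    """Parameters of the fluorescence binding models.

    ``amp_A`` is the quench amplitude, ``base_B`` the unquenched baseline,
    ``floor_C`` the quenched baseline of the competition model, ``kd_6t``
    the 6-Thio-GTP affinity and ``kd_nuc`` the competitor affinity (uM).
    """

    amp_A: float
    base_B: float
    kd_6t: float
    kd_nuc: Optional[float] = None
    floor_C: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kd_6t <= 0 or (self.kd_nuc is not None and self.kd_nuc <= 0):
            raise ConfigurationError("dissociation constants must be > 0")
        if self.amp_A > self.base_B:
            raise ConfigurationError("quench amplitude cannot exceed the baseline")


class FitResult(NamedTuple):
    """Point estimates with standard errors and 95% intervals."""

    params: dict
    stderr: dict
    ci95: dict


def _fit(model, x, y, sem, p0, names, bounds=(-np.inf, np.inf)):
    if len(np.atleast_1d(y)) < len(p0):
        raise ValueError("fewer data points than free parameters")
    sigma = np.asarray(sem, float) if sem is not None else None
    popt, pcov = optimize.curve_fit(
        model, x, y, p0=p0, sigma=sigma, absolute_sigma=False, bounds=bounds, maxfev=20000
    )
    if not np.all(np.isfinite(pcov)):
        raise RuntimeError("fit did not converge: singular covariance")
    se = np.sqrt(np.diag(pcov))
    params = dict(zip(names, map(float, popt)))
    stderr = dict(zip(names, map(float, se)))
    ci95 = {k: (params[k] - 1.96 * stderr[k], params[k] + 1.96 * stderr[k]) for k in names}
    return FitResult(params, stderr, ci95)


def _columns(data, xcol="x_uM"):
    if isinstance(data, pd.DataFrame):
        x = data[xcol].to_numpy(float)
        y = data["y"].to_numpy(float)
        sem = data["sem"].to_numpy(float) if "sem" in data else None
    else:
        x, y, sem = data
        x, y = np.asarray(x, float), np.asarray(y, float)
        sem = None if sem is None else np.asarray(sem, float)
    if sem is not None and np.any(sem <= 0):
        raise ValueError("SEM weights must be strictly positive")
    return x, y, sem


# ---------------------------------------------------------------------------
# competitive nucleotide binding and the minus-end growth law


def cpp_tubulin_concentration(
    tub_total: float,
    mix: NucleotideMix,
    affinity_ratio: float,
    kd_cpp: Optional[float] = None,
) -> float:
    """GMPCPP-tubulin concentration (uM) in a GDP/GMPCPP mix.

    Default is the simplified partition, valid when [GMPCPP] >> KD(GMPCPP):
    ``tub_total * cpp / (cpp + gdp * r)`` with r = KD_CPP/KD_GDP.  Supplying
    an absolute ``kd_cpp`` (uM) switches to the exact competitive-binding
    form ``tub_total * cpp / (cpp + kd_cpp * (1 + gdp / kd_gdp))`` with
    ``kd_gdp = kd_cpp / r``.
    """
    if affinity_ratio <= 0:
        raise ConfigurationError("affinity_ratio must be > 0")
    cpp, gdp = mix.cpp_conc, mix.gdp_conc
    if cpp == 0 and gdp == 0:
        raise ValueError("no nucleotide in solution")
    if kd_cpp is not None:
        kd_gdp = kd_cpp / affinity_ratio
        return tub_total * cpp / (cpp + kd_cpp * (1.0 + gdp / kd_gdp))
    return tub_total * cpp / (cpp + gdp * affinity_ratio)


def minus_growth_prediction(
    tub_total: float,
    gdp_conc: float,
    affinity_ratio: float,
    slope: float = GROWTH_SLOPE,
    intercept: float = GROWTH_INTERCEPT,
    total_nucleotide: float = TOTAL_NUCLEOTIDE_UM,
    clamp: bool = False,
) -> float:
    """Predicted minus-end growth rate (nm/s) in a GDP/GMPCPP mix.

    Only GMPCPP-tubulin contributes to minus-end growth; its concentration
    comes from the competitive partition and feeds the affine growth law.
    The raw (possibly negative) value is returned for fitting; ``clamp``
    floors it at zero for display.
    """
    mix = NucleotideMix(gdp_conc, total_nucleotide)
    gr = slope * cpp_tubulin_concentration(tub_total, mix, affinity_ratio) + intercept
    if clamp and gr < 0:
        warnings.warn("predicted rate negative; clamped to 0 for display")
        return 0.0
    return gr


def fit_affinity_ratio(
    data,
    tub_total: float,
    slope: float = GROWTH_SLOPE,
    intercept: float = GROWTH_INTERCEPT,
    total_nucleotide: float = TOTAL_NUCLEOTIDE_UM,
) -> FitResult:
    """Fit r = KD(GMPCPP)/KD(GDP) to minus-end growth versus free [GDP].

    The growth-law slope and intercept are fixed; r is the single free
    parameter.  ``data`` is a DataFrame with columns ``x_uM`` (free GDP,
    uM), ``y`` (nm/s) and optionally ``sem``, or an ``(x, y, sem)`` tuple.
    """
    x, y, sem = _columns(data)
    if len(x) < 3:
        raise ValueError("need at least 3 GDP concentrations")

    def model(gdp, ratio):
        cpp = total_nucleotide - gdp
        return slope * tub_total * cpp / (cpp + gdp * ratio) + intercept

    return _fit(model, x, y, sem, p0=[10.0], names=["affinity_ratio"], bounds=(1e-6, np.inf))


# ---------------------------------------------------------------------------
# fluorescence binding assays


def quench_isotherm(ligand, amp_A: float, base_B: float, kd_6t: float):
    """Tryptophan fluorescence versus [6-Thio-GTP] (quenching isotherm):
    ``y = B - A * L / (L + KD)``; ``B - A`` is the fully quenched floor."""
    ligand = np.asarray(ligand, float)
    return base_B - amp_A * ligand / (ligand + kd_6t)


def fit_isotherm(data) -> FitResult:
    """1/SEM-weighted fit of the quench isotherm for (A, B, KD_6T)."""
    x, y, sem = _columns(data)
    span = float(y.max() - y.min())
    p0 = [max(span, 1e-3), float(y.max()), max(float(np.median(x)), 1e-3)]
    return _fit(
        quench_isotherm, x, y, sem, p0=p0, names=["amp_A", "base_B", "kd_6t"],
        bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]),
    )


def competition_model(
    nuc, six_thio: float, amp_A: float, floor_C: float, kd_nuc: float, kd_6t: float
):
    """Unquenching of 6-Thio-GTP fluorescence by a competing nucleotide:
    ``y = C + A * N / (N + KD_nuc * (1 + S/KD_6T))`` at fixed [6-Thio-GTP] S.
    """
    nuc = np.asarray(nuc, float)
    return floor_C + amp_A * nuc / (nuc + kd_nuc * (1.0 + six_thio / kd_6t))


def fit_competition(data, amp_A: float, kd_6t: float, six_thio: float = 3.0) -> FitResult:
    """Weighted fit of the competition model for (KD_nuc, C).

    ``amp_A`` and ``kd_6t`` are fixed inputs: the amplitude is constrained
    by the measured quench at the working 6-Thio-GTP concentration and the
    reporter affinity comes from the isotherm fit.
    """
    if amp_A is None or kd_6t is None:
        raise ValueError("amp_A and kd_6t must be externally constrained")
    x, y, sem = _columns(data)

    def model(nuc, kd_nuc, floor_C):
        return competition_model(nuc, six_thio, amp_A, floor_C, kd_nuc, kd_6t)

    p0 = [max(float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, 1e-3), float(y.min())]
    return _fit(model, x, y, sem, p0=p0, names=["kd_nuc", "floor_C"],
                bounds=([1e-9, -np.inf], [np.inf, np.inf]))


def propagate_sem(
    bsa_stats: tuple[float, float],
    tub_stats: tuple[float, float],
    blank_stats: tuple[float, float],
) -> float:
    """SEM of the inner-filter-corrected ratio (tubulin / BSA signal).

    Each argument is ``(mean, sem)``.  Relative errors add in quadrature
    and scale the ratio of means:
    ``sqrt((s_B/m_B)^2 + (s_T/m_T)^2 + (s_0/m_0)^2) * (m_T/m_B)``.
    """
    rel = []
    for mean, sem in (bsa_stats, tub_stats, blank_stats):
        if mean == 0:
            raise ValueError("mean of zero: relative error undefined")
        rel.append((sem / mean) ** 2)
    return float(np.sqrt(sum(rel)) * (tub_stats[0] / bsa_stats[0]))
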