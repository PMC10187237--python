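"""Kinetic rules mapping lattice topology and nucleotide state to rates.

Two competing mechanisms for how the exchangeable-site nucleotide controls
tubulin:tubulin interaction strength are implemented:

* ``self_acting`` (cis): the nucleotide bound to the terminal dimer sets
  that dimer's own lattice affinity.
* ``interface_acting`` (trans): the nucleotide buried at the longitudinal
  interface between two dimers sets the strength of that interface.

At the minus end the terminal dimer's exchangeable nucleotide *is* the
interfacial nucleotide, so the two mechanisms coincide there by
construction; only plus-end behaviour discriminates them.

Rates follow the standard single-filament kinetic scheme: association is
``kon * [tubulin]`` with the same rate constant for GMPCPP- and GDP-bound
tubulin, and dissociation is ``koff = kon * KD`` with the site affinity KD
set by the number of contacts (longitudinal-only, corner, bucket) and the
governing nucleotide.  A GDP-governed longitudinal interface is weaker by
the multiplicative ``gdp_factor``; the lateral bond factor is unchanged, so
corner and bucket affinities inherit the weakening through the base KD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .lattice import ConfigurationError, Nucleotide, SiteClass, TipSite

__all__ = [
    "Mechanism",
    "KineticParams",
    "SolutionState",
    "governing_nucleotide",
    "site_affinity",
    "association_rate",
    "dissociation_rate",
    "exchange_events",
    "FIG_EXPLORATORY_PARAMS",
    "FITTED_PARAMS",
]

# mechanism flags
SELF_ACTING = "self_acting"
INTERFACE_ACTING = "interface_acting"
Mechanism = str

#: total nucleotide concentration used throughout (uM)
TOTAL_NUCLEOTIDE_UM = 1000.0


@dataclass(frozen=True)
class KineticParams:
    """Biochemical parameter set for one simulation.

    Parameters
    ----------
    kon_plus, kon_minus
        Bimolecular on-rate constants (uM^-1 s^-1 per protofilament).
    kd_long
        Affinity of a longitudinal-only site (uM), GMPCPP-governed.
    kd_corner
        Affinity of a corner site (one longitudinal + one lateral contact,
        uM), GMPCPP-governed.
    gdp_factor
        Fold-weakening of a GDP-governed longitudinal interface
        (dimensionless, >= 1).
    mechanism
        ``"self_acting"`` or ``"interface_acting"``.
    k_exch_gdp
        Base nucleotide off-rate from a terminal GDP-bound exchangeable
        site (s^-1); 0 disables exchange.
    affinity_ratio
        KD(GMPCPP)/KD(GDP) for nucleotide binding to unpolymerised tubulin;
        the GMPCPP off-rate from a terminal site is ``affinity_ratio``-fold
        faster than the GDP off-rate.
    """

    kon_plus: float = 0.74
    kon_minus: float = 0.31
    kd_long: float = 86.0
    kd_corner: float = 0.025
    gdp_factor: float = 3500.0
    mechanism: Mechanism = INTERFACE_ACTING
    k_exch_gdp: float = 0.0
    affinity_ratio: float = 12.5

    def __post_init__(self) -> None:
        for name in ("kon_plus", "kon_minus", "kd_long", "kd_corner", "affinity_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.gdp_factor < 1:
            raise ConfigurationError("gdp_factor must be >= 1")
        if self.kd_corner >= self.kd_long:
            raise ConfigurationError("kd_corner must be < kd_long")
        if self.k_exch_gdp < 0:
            raise ConfigurationError("k_exch_gdp must be >= 0")
        if self.mechanism not in (SELF_ACTING, INTERFACE_ACTING):
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")

    def kon(self, end: str) -> float:
        return self.kon_plus if end == "plus" else self.kon_minus

    @property
    def kd_bucket(self) -> float:
        """Bucket-site affinity from bond-energy additivity of the second
        lateral contact: KD_corner^2 / KD_long (uM)."""
        return self.kd_corner**2 / self.kd_long

    def with_mechanism(self, mechanism: Mechanism) -> "KineticParams":
        return replace(self, mechanism=mechanism)


#: arbitrary exploratory parameter set that supports elongation at ~1 uM
FIG_EXPLORATORY_PARAMS = KineticParams(
    kon_plus=1.0, kon_minus=1.0, kd_long=100.0, kd_corner=0.1, gdp_factor=3000.0
)

#: parameters fitted to GMPCPP growth-rate measurements
FITTED_PARAMS = KineticParams(
    kon_plus=0.74, kon_minus=0.31, kd_long=86.0, kd_corner=0.025, gdp_factor=3500.0
)


@dataclass(frozen=True)
class SolutionState:
    """Unpolymerised tubulin pool and its nucleotide occupancy.

    The pool is an infinite reservoir: single microtubules cannot deplete
    micromolar tubulin or millimolar nucleotide.

    Attributes
    ----------
    tubulin_total
        Total unpolymerised tubulin (uM).
    cpp_conc, gdp_conc
        Free GMPCPP and GDP concentrations (uM); they sum to the total
        nucleotide concentration (1000 uM in all standard conditions).
    frac_gdp_tubulin
        Fraction of the tubulin pool that is GDP-bound.
    """

    tubulin_total: float
    cpp_conc: float = TOTAL_NUCLEOTIDE_UM
    gdp_conc: float = 0.0
    frac_gdp_tubulin: float = 0.0

    def __post_init__(self) -> None:
        if self.tubulin_total < 0 or self.cpp_conc < 0 or self.gdp_conc < 0:
            raise ConfigurationError("concentrations must be >= 0")
        if not 0.0 <= self.frac_gdp_tubulin <= 1.0:
            raise ConfigurationError("frac_gdp_tubulin must be in [0, 1]")

    @property
    def cpp_tubulin(self) -> float:
        return self.tubulin_total * (1.0 - self.frac_gdp_tubulin)

    @property
    def gdp_tubulin(self) -> float:
        return self.tubulin_total * self.frac_gdp_tubulin

    @property
    def frac_cpp_nucleotide(self) -> float:
        total = self.cpp_conc + self.gdp_conc
        if total <= 0:
            raise ConfigurationError("no free nucleotide in solution")
        return self.cpp_conc / total

    @classmethod
    def from_gdp_tubulin_fraction(
        cls,
        tubulin_total: float,
        frac_gdp_tubulin: float,
        affinity_ratio: float = 12.5,
        total_nucleotide: float = TOTAL_NUCLEOTIDE_UM,
    ) -> "SolutionState":
        """Construct from a target GDP-tubulin fraction.

        Back-calculates the free GDP concentration that yields the requested
        GDP-tubulin fraction under competitive nucleotide binding with the
        given affinity ratio r = KD_CPP/KD_GDP:
        ``f = g r / ((N - g) + g r)``  =>  ``g = N f / (r (1 - f) + f)``.
        """
        f = frac_gdp_tubulin
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError("frac_gdp_tubulin must be in [0, 1]")
        gdp = total_nucleotide * f / (affinity_ratio * (1.0 - f) + f) if f < 1 else total_nucleotide
        return cls(tubulin_total, total_nucleotide - gdp, gdp, f)

    @classmethod
    def from_nucleotide_mix(
        cls,
        tubulin_total: float,
        gdp_conc: float,
        affinity_ratio: float = 12.5,
        total_nucleotide: float = TOTAL_NUCLEOTIDE_UM,
    ) -> "SolutionState":
        """Construct from a GDP/GMPCPP mix at fixed total nucleotide.

        The GDP-tubulin fraction follows the simplified competitive-binding
        partition (valid for [GMPCPP] >> KD_CPP).
        """
        if not 0.0 <= gdp_conc <= total_nucleotide:
            raise ConfigurationError("gdp_conc must be within the nucleotide total")
        cpp = total_nucleotide - gdp_conc
        denom = cpp + gdp_conc * affinity_ratio
        f = gdp_conc * affinity_ratio / denom if denom > 0 else 0.0
        return cls(tubulin_total, cpp, gdp_conc, f)


def governing_nucleotide(
    mechanism: Mechanism, end: str, self_nt: Nucleotide, interfacial_nt: Nucleotide
) -> Nucleotide:
    """Nucleotide that sets a terminal dimer's lattice affinity.

    Interface-acting: the interfacial nucleotide; self-acting: the dimer's
    own nucleotide.  At the minus end the two inputs are identical by
    construction so the result is mechanism-independent.
    """
    if mechanism == INTERFACE_ACTING:
        return interfacial_nt
    return self_nt


_BASE_KD = {
    SiteClass.long_only: lambda p: p.kd_long,
    SiteClass.corner: lambda p: p.kd_corner,
    SiteClass.bucket: lambda p: p.kd_bucket,
}


def site_affinity(site_class: SiteClass, governing_nt: Nucleotide, params: KineticParams) -> float:
    """Interaction affinity KD (uM) of a site under its governing nucleotide."""
    try:
        kd = _BASE_KD[SiteClass(site_class)](params)
    except (KeyError, ValueError) as err:
        raise ValueError(f"unknown site class {site_class!r}") from err
    if governing_nt == Nucleotide.GDP:
        kd *= params.gdp_factor
    return kd


def affinity_from_weight(lateral_weight: float, governing_nt: Nucleotide, params: KineticParams) -> float:
    """Affinity KD (uM) for an arbitrary lateral contact weight.

    Lateral bonds are energy-additive: ``KD = KD_long * f**w`` with
    ``f = KD_corner/KD_long`` per full lateral contact.  Integer weights
    recover the named classes (0 long-only, 1 corner, 2 bucket); seam
    positions carry half weights.  GDP weakening multiplies the
    longitudinal term, so it is a single factor regardless of ``w``.
    """
    if lateral_weight < 0:
        raise ValueError("lateral weight must be >= 0")
    kd = params.kd_long * (params.kd_corner / params.kd_long) ** lateral_weight
    if governing_nt == Nucleotide.GDP:
        kd *= params.gdp_factor
    return kd


def association_rate(
    params: KineticParams, end: str, solution: SolutionState, nt: Nucleotide
) -> float:
    """First-order landing rate (s^-1 per protofilament) of one tubulin species.

    The same on-rate constant applies to GMPCPP- and GDP-tubulin; only the
    species concentration differs, so the total landing rate is
    ``kon * tubulin_total``.
    """
    conc = solution.cpp_tubulin if nt == Nucleotide.CPP else solution.gdp_tubulin
    return params.kon(end) * conc


def dissociation_rate(tip_entry: TipSite, params: KineticParams, end: str) -> float:
    """Off-rate (s^-1) of a terminal dimer, koff = kon * KD."""
    nt = governing_nucleotide(params.mechanism, end, tip_entry.self_nt, tip_entry.interfacial_nt)
    return params.kon(end) * affinity_from_weight(tip_entry.lateral_weight, nt, params)


def exchange_events(
    tip_entry: TipSite, params: KineticParams, solution: SolutionState, end: str
) -> list[tuple[Nucleotide, float]]:
    """Nucleotide-exchange channels for one terminal plus-end dimer.

    The exchangeable site is solvent-exposed only on the terminal plus-end
    dimer (at the minus end it is already buried), so the minus end gets no
    channels.  The rate-limiting step is dissociation of the bound
    nucleotide: total rate ``k_exch_gdp`` for a GDP-bound site and
    ``affinity_ratio * k_exch_gdp`` for a GMPCPP-bound one.  The replacement
    is drawn from solution in proportion to the fractional concentration of
    each nucleotide.
    """
    if end != "plus" or params.k_exch_gdp <= 0:
        return []
    total = params.k_exch_gdp
    if tip_entry.self_nt == Nucleotide.CPP:
        total *= params.affinity_ratio
    p_cpp = solution.frac_cpp_nucleotide
    out = []
    if p_cpp > 0:
        out.append((Nucleotide.CPP, total * p_cpp))
    if p_cpp < 1:
        out.append((Nucleotide.GDP, total * (1.0 - p_cpp)))
    return out
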