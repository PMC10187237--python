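"""Protofilament-resolved representation of a growing microtubule end.

A microtubule is modelled as ``n_protofilaments`` gap-free columns of
alpha/beta-tubulin dimers.  Each dimer carries the nucleotide bound at its
beta-tubulin exchangeable site (GMPCPP, a slowly hydrolysable GTP analogue,
or GDP).  The lattice answers the topology questions the kinetic rules
need: where the next landing site on each protofilament is, how much
lateral contact a position has, and which nucleotide sits at the
longitudinal interface between the terminal dimer and the rest of the
lattice.

Lateral registry
----------------
Layers are integer dimer heights.  On the twelve regular B-lattice
interfaces, lateral partners sit at the same dimer layer (the true helical
stagger of ~0.9 nm is small against the 8 nm dimer), so position
``(pf, L)`` gains one full lateral contact from neighbour ``q`` when that
neighbour occupies layer ``L`` (``height[q] >= L + 1``).  The seam is
different: lateral partners there are offset by half a dimer (the 12 nm
rise of the three-start monomer helix exceeds the 8 nm dimer by 4 nm), so
a seam position straddles two partner layers and collects two half-weight
contacts, one per overlapped layer.  Contact weights are energy-additive:
a site's affinity is ``KD_long * (KD_corner/KD_long)**w`` where ``w`` is
the total lateral weight, which reduces to the named long-only / corner /
bucket classes at ``w = 0, 1, 2``.  The seam offset sign is mirrored at
the minus end (the orientation of interactions across the seam is the
stated rule change for minus-end growth).
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Nucleotide",
    "SiteClass",
    "LatticeParams",
    "Subunit",
    "TipSite",
    "EndLattice",
    "init_lattice",
    "classify_landing_site",
    "tip_sites",
    "ConfigurationError",
]


class Nucleotide(enum.IntEnum):
    """Exchangeable-site nucleotide of a tubulin dimer."""

    CPP = 0  # GMPCPP, the GTP-like state
    GDP = 1


class SiteClass(enum.IntEnum):
    """Binding-site type by lateral contact weight.

    Every site has one longitudinal contact (addition is onto a tip);
    ``long_only`` adds no lateral contact, ``corner`` one, ``bucket`` two.
    Fractional seam weights are assigned to the nearest class (``bucket``
    from weight 1.5 up, ``corner`` from 0.5 up).
    """

    long_only = 0
    corner = 1
    bucket = 2

    @classmethod
    def from_weight(cls, w: float) -> "SiteClass":
        if w >= 1.5:
            return cls.bucket
        if w >= 0.5:
            return cls.corner
        return cls.long_only


class ConfigurationError(ValueError):
    """Raised for an invalid lattice or simulation configuration."""


@dataclass(frozen=True)
class LatticeParams:
    """Geometry of the microtubule wall.

    Parameters
    ----------
    n_protofilaments
        Number of protofilaments (13 for the canonical wall; 1 is allowed
        for single-filament closed-form checks).
    seam_offset
        Lateral registry shift across the seam interface, in dimer layers.
        The default 0.5 is the half-dimer stagger of the 13-protofilament
        three-start lattice; fractional values split the seam contact into
        two partial-weight contacts on the straddled layers.  The sign is
        mirrored at the minus end.
    dimer_rise
        Axial length of one alpha/beta dimer along a protofilament (nm).
        Mean end length advances by ``dimer_rise / n_protofilaments`` per
        subunit gained.
    """

    n_protofilaments: int = 13
    seam_offset: float = 0.5
    dimer_rise: float = 8.0

    def __post_init__(self) -> None:
        if self.n_protofilaments < 1:
            raise ConfigurationError("n_protofilaments must be >= 1")
        if self.dimer_rise <= 0:
            raise ConfigurationError("dimer_rise must be > 0")

    @property
    def length_per_subunit(self) -> float:
        """Mean-length increment (nm) contributed by one dimer."""
        return self.dimer_rise / self.n_protofilaments


@dataclass(frozen=True)
class Subunit:
    """One alpha/beta dimer in the lattice."""

    protofilament: int
    layer: int
    nucleotide: Nucleotide


@dataclass(frozen=True)
class TipSite:
    """Terminal (dissociable) subunit of one protofilament.

    ``interfacial_nt`` is the exchangeable-site nucleotide buried at the
    terminal subunit's longitudinal bond with the lattice: at the plus end
    the nucleotide of the subunit *below* the tip, at the minus end the tip
    subunit's *own* nucleotide (an arriving dimer's nucleotide becomes the
    new interface there).  ``lateral_weight`` is the exact contact weight;
    ``site_class`` the nearest named class.
    """

    pf: int
    layer: int
    site_class: SiteClass
    self_nt: Nucleotide
    interfacial_nt: Nucleotide
    lateral_weight: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.lateral_weight is None:
            object.__setattr__(self, "lateral_weight", float(self.site_class))


def _crossing_terms(shift: float) -> tuple[int, float]:
    """Decompose a registry shift into (base, frac) contact terms.

    A crossing with shift ``s`` puts the lateral partner of layer ``L`` at
    ``L + s``, overlapping dimer layers ``floor(L+s)`` (weight ``1-frac``)
    and ``floor(L+s)+1`` (weight ``frac``).  Contact with layer ``X``
    exists when the neighbour stack covers it (``height > X``), so the two
    terms test ``height >= L + base`` and ``height >= L + base + 1`` with
    ``base = floor(s) + 1``.
    """
    base = math.floor(shift) + 1
    frac = shift - math.floor(shift)
    return int(base), float(frac)


class EndLattice:
    """State of one growing microtubule end.

    Each protofilament is a contiguous stack of dimers; the bottom
    ``seed_layers`` layers are an immutable all-GMPCPP seed that never
    dissociates or exchanges its nucleotide (mimicking a stabilised seed).
    """

    def __init__(self, params: LatticeParams, end: str, seed_layers: int):
        if end not in ("plus", "minus"):
            raise ConfigurationError(f"end must be 'plus' or 'minus', got {end!r}")
        if seed_layers < 2:
            raise ConfigurationError("seed_layers must be >= 2")
        self.params = params
        self._end = end
        self.seed_layers = int(seed_layers)
        n = params.n_protofilaments
        self.heights = np.full(n, self.seed_layers, dtype=np.int64)
        # nucleotide storage grows on demand; seed layers are CPP (0)
        self._nt = np.zeros((n, self.seed_layers + 64), dtype=np.uint8)

    @property
    def end(self) -> str:
        return self._end

    @property
    def n_pf(self) -> int:
        return self.params.n_protofilaments

    # -- storage -----------------------------------------------------------

    def _ensure_capacity(self, layers: int) -> None:
        if layers > self._nt.shape[1]:
            extra = np.zeros((self.n_pf, layers + 256), dtype=np.uint8)
            extra[:, : self._nt.shape[1]] = self._nt
            self._nt = extra

    def nucleotide(self, pf: int, layer: int) -> Nucleotide:
        if not 0 <= layer < self.heights[pf]:
            raise IndexError(f"no subunit at pf={pf}, layer={layer}")
        return Nucleotide(int(self._nt[pf, layer]))

    # -- registry ----------------------------------------------------------

    def _seam_shift(self) -> float:
        s = self.params.seam_offset
        return s if self._end == "plus" else -s

    def crossing_terms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-protofilament (base, frac) contact terms toward the right
        ((pf+1) % n) and left neighbour; the seam sits between
        protofilament n-1 and 0."""
        n = self.n_pf
        base_r = np.ones(n, dtype=np.int64)
        frac_r = np.zeros(n, dtype=np.float64)
        base_l = np.ones(n, dtype=np.int64)
        frac_l = np.zeros(n, dtype=np.float64)
        if n >= 2:
            s = self._seam_shift()
            base_r[n - 1], frac_r[n - 1] = _crossing_terms(s)
            base_l[0], frac_l[0] = _crossing_terms(-s)
        return base_r, frac_r, base_l, frac_l

    def lateral_weight(self, pf: int, layer: int) -> float:
        """Total lateral contact weight of position ``(pf, layer)``."""
        n = self.n_pf
        if n == 1:
            return 0.0
        base_r, frac_r, base_l, frac_l = self.crossing_terms()
        w = 0.0
        q = (pf + 1) % n
        w += self._crossing_weight(q, layer, base_r[pf], frac_r[pf])
        if n > 2:
            q = (pf - 1) % n
            w += self._crossing_weight(q, layer, base_l[pf], frac_l[pf])
        return w

    def _crossing_weight(self, q: int, layer: int, base: int, frac: float) -> float:
        h = self.heights[q]
        w = 0.0
        if h >= layer + base:
            w += 1.0 - frac
        if frac > 0 and h >= layer + base + 1:
            w += frac
        return w

    # -- mutation (used by the engine) -------------------------------------

    def add_subunit(self, pf: int, nucleotide: Nucleotide) -> None:
        h = int(self.heights[pf])
        self._ensure_capacity(h + 1)
        self._nt[pf, h] = int(nucleotide)
        self.heights[pf] = h + 1

    def remove_subunit(self, pf: int) -> None:
        h = int(self.heights[pf])
        if h <= self.seed_layers:
            raise ValueError(f"cannot remove seed subunit on pf {pf}")
        self.heights[pf] = h - 1

    def set_tip_nucleotide(self, pf: int, nucleotide: Nucleotide) -> None:
        h = int(self.heights[pf])
        if h <= self.seed_layers:
            raise ValueError(f"cannot exchange nucleotide on seed pf {pf}")
        self._nt[pf, h - 1] = int(nucleotide)

    # -- queries -----------------------------------------------------------

    def subunits(self):
        for pf in range(self.n_pf):
            for layer in range(int(self.heights[pf])):
                yield Subunit(pf, layer, Nucleotide(int(self._nt[pf, layer])))

    def n_subunits(self) -> int:
        return int(self.heights.sum())

    def mean_length(self) -> float:
        """Mean protofilament length above the seed, in nm."""
        grown = self.heights - self.seed_layers
        return float(grown.sum()) * self.params.dimer_rise / self.n_pf

    def check_invariants(self) -> None:
        """Debug check: heights never below the seed, seed composition intact."""
        if (self.heights < self.seed_layers).any():
            raise AssertionError("protofilament shrank into the seed")
        if (self._nt[:, : self.seed_layers] != int(Nucleotide.CPP)).any():
            raise AssertionError("seed nucleotide mutated")

    # -- serialization -----------------------------------------------------

    def to_csv(self, path_or_buf=None):
        """Snapshot as CSV with columns pf, layer, nucleotide."""
        buf = io.StringIO()
        buf.write("pf,layer,nucleotide\n")
        for s in self.subunits():
            buf.write(f"{s.protofilament},{s.layer},{s.nucleotide.name}\n")
        text = buf.getvalue()
        if path_or_buf is None:
            return text
        with open(path_or_buf, "w") as fh:
            fh.write(text)
        return None


def init_lattice(params: LatticeParams, end: str, seed_layers: int = 10) -> EndLattice:
    """Create a blunt all-GMPCPP lattice of ``seed_layers`` immutable layers."""
    return EndLattice(params, end, seed_layers)


def classify_landing_site(lattice: EndLattice, pf: int) -> SiteClass:
    """Class of the next addition site on protofilament ``pf``.

    On a blunt stretch the landing sites are longitudinal-only (the
    neighbours have not yet reached the landing layer); a site flanked by
    one (two) strictly taller neighbour(s) is a corner (bucket).
    """
    if not 0 <= pf < lattice.n_pf:
        raise IndexError(f"protofilament index {pf} out of range")
    layer = int(lattice.heights[pf])
    return SiteClass.from_weight(lattice.lateral_weight(pf, layer))


def tip_sites(lattice: EndLattice) -> list[TipSite]:
    """One entry per protofilament with a dissociable terminal subunit.

    Seed-only protofilaments are omitted.  The contact weight is computed
    for the occupied terminal position, so on a blunt stretch every tip is
    a bucket (equal-height neighbours flank it) even though the landing
    sites above are longitudinal-only.
    """
    out: list[TipSite] = []
    for pf in range(lattice.n_pf):
        h = int(lattice.heights[pf])
        if h <= lattice.seed_layers:
            continue
        layer = h - 1
        w = lattice.lateral_weight(pf, layer)
        self_nt = lattice.nucleotide(pf, layer)
        if lattice.end == "plus":
            interfacial = lattice.nucleotide(pf, layer - 1)
        else:
            interfacial = self_nt
        out.append(TipSite(pf, layer, SiteClass.from_weight(w), self_nt, interfacial, w))
    return out
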