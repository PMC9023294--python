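"""Caspar-Klug lattice arithmetic and genome packing density.

An icosahedral capsid lattice is described by two non-negative integer
steps (h, k) on the hexagonal net; the triangulation number
T = h^2 + hk + k^2 counts the subdivision of each icosahedral face and the
shell carries 60*T subunits.  The capsid lumen is approximated as a sphere,
and the packed genome is related to an equivalent hexagonally close-packed
bundle of B-DNA duplexes through the interaxial spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

#: Axial rise of B-form DNA, nm per base pair.
RISE_PER_BP_NM = 0.34


class LatticeError(ValueError):
    """Raised for (h, k) pairs that do not describe a capsid lattice."""


class Handedness(str, Enum):
    LAEVO = "laevo"
    DEXTRO = "dextro"
    ACHIRAL = "achiral"


def t_number(h: int, k: int) -> int:
    """Triangulation number T = h^2 + hk + k^2 of the (h, k) lattice.

    Raises :class:`LatticeError` for negative steps or h == k == 0.
    """
    if h != int(h) or k != int(k):
        raise LatticeError(f"lattice steps must be integers, got ({h}, {k})")
    h, k = int(h), int(k)
    if h < 0 or k < 0:
        raise LatticeError(f"lattice steps must be non-negative, got ({h}, {k})")
    if h == 0 and k == 0:
        raise LatticeError("(0, 0) is not a lattice")
    return h * h + h * k + k * k


def lattice_handedness(h: int, k: int, *, h_gt_k: str = "laevo") -> Handedness:
    """Chirality label of the (h, k) walk.

    Lattices with h == k, h == 0 or k == 0 are mirror-symmetric (achiral).
    Which chiral label attaches to h > k is a convention, not arithmetic;
    ``h_gt_k`` selects it (default ``"laevo"``, so (4, 2) is laevo).
    """
    if h == k or h == 0 or k == 0:
        return Handedness.ACHIRAL
    other = "dextro" if h_gt_k == "laevo" else "laevo"
    return Handedness(h_gt_k) if h > k else Handedness(other)


@dataclass(frozen=True)
class CapsidLattice:
    """A validated (h, k) capsid lattice with derived T-number and handedness."""

    h: int
    k: int
    t_number: int = field(default=0)
    handedness: Handedness = field(default=Handedness.ACHIRAL)

    def __post_init__(self) -> None:
        t = t_number(self.h, self.k)
        object.__setattr__(self, "t_number", t)
        object.__setattr__(self, "handedness", lattice_handedness(self.h, self.k))

    @classmethod
    def from_hk(cls, h: int, k: int) -> "CapsidLattice":
        return cls(h=h, k=k)


def enumerate_lattices(t: int, h_max: int) -> list[CapsidLattice]:
    """All (h, k) with 0 <= h, k <= h_max realizing triangulation number ``t``.

    Both chiral mates (h, k) and (k, h) are returned.  Ordered by
    (h descending, k ascending).  Empty when ``t`` is not realizable.
    """
    if t < 1 or h_max < 1:
        raise ValueError("t and h_max must be positive")
    found = [
        CapsidLattice.from_hk(h, k)
        for h in range(h_max + 1)
        for k in range(h_max + 1)
        if (h, k) != (0, 0) and h * h + h * k + k * k == t
    ]
    return sorted(found, key=lambda lat: (-lat.h, lat.k))


def subunit_count(lattice: CapsidLattice | int) -> int:
    """Number of capsid protein subunits, 60 * T (quasi-equivalence)."""
    t = lattice.t_number if isinstance(lattice, CapsidLattice) else int(lattice)
    if t < 1:
        raise ValueError("T-number must be positive")
    return 60 * t


def internal_volume(inner_radius: float) -> float:
    """Spherical approximation of the capsid lumen volume, nm^3.

    ``inner_radius`` is the lumen radius in nm (inside any internal
    protein layer).  The sphere is an approximation; measured lumen
    volumes may be supplied directly wherever a volume is accepted.
    """
    if inner_radius <= 0:
        raise ValueError(f"inner_radius must be positive, got {inner_radius}")
    return 4.0 / 3.0 * math.pi * inner_radius**3


@dataclass(frozen=True)
class PackingResult:
    """Genome packing density and the hexagonal spacing it implies."""

    density: float  # bp / nm^3
    spacing_equivalent: float  # nm between duplex axes, hexagonal packing
    copies_assumed: int

    def rounded(self, ndigits: int = 2) -> float:
        """Density rounded for display; full precision stays in ``density``."""
        return round(self.density, ndigits)


def spacing_to_density(spacing: float, rise_per_bp: float = RISE_PER_BP_NM) -> float:
    """Packing density (bp/nm^3) of hexagonally packed duplexes at ``spacing`` nm.

    Each duplex occupies a hexagonal prism of cross-section
    (sqrt(3)/2) * spacing^2 per ``rise_per_bp`` nm of axial rise, so
    density = 1 / ((sqrt(3)/2) * spacing^2 * rise_per_bp).
    """
    if spacing <= 0 or rise_per_bp <= 0:
        raise ValueError("spacing and rise_per_bp must be positive")
    return 1.0 / (math.sqrt(3.0) / 2.0 * spacing**2 * rise_per_bp)


def density_to_spacing(density: float, rise_per_bp: float = RISE_PER_BP_NM) -> float:
    """Interaxial spacing (nm) implied by a packing density; inverse of
    :func:`spacing_to_density`."""
    if density <= 0 or rise_per_bp <= 0:
        raise ValueError("density and rise_per_bp must be positive")
    return math.sqrt(1.0 / (math.sqrt(3.0) / 2.0 * density * rise_per_bp))


def packing_density(
    genome_length: int, copies: int, internal_volume: float
) -> PackingResult:
    """Genome packing density for ``copies`` genomes in a lumen of
    ``internal_volume`` nm^3.

    density = copies * genome_length / internal_volume (bp/nm^3), with the
    equivalent hexagonal interaxial spacing filled in when density > 0.
    """
    if internal_volume <= 0:
        raise ValueError("internal_volume must be positive")
    if genome_length < 0:
        raise ValueError("genome_length must be non-negative")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    density = copies * genome_length / internal_volume
    spacing = density_to_spacing(density) if density > 0 else math.inf
    return PackingResult(density=density, spacing_equivalent=spacing, copies_assumed=copies)


@dataclass
class CapsidModel:
    """Geometric description of one capsid variant.

    A measured ``internal_volume`` (nm^3) takes precedence; otherwise the
    lumen volume is derived from ``inner_radius`` as a sphere.
    """

    genome_length: int
    genome_copies: int = 1
    outer_diameter: float | None = None  # nm
    inner_radius: float | None = None  # nm
    internal_volume: float | None = None  # nm^3

    def __post_init__(self) -> None:
        if self.internal_volume is None:
            if self.inner_radius is None:
                raise ValueError("need inner_radius or internal_volume")
            self.internal_volume = internal_volume(self.inner_radius)
        if self.internal_volume <= 0:
            raise ValueError("internal_volume must be positive")
        if (
            self.inner_radius is not None
            and self.outer_diameter is not None
            and self.inner_radius > self.outer_diameter / 2
        ):
            raise ValueError("inner_radius exceeds outer radius")

    def packing(self) -> PackingResult:
        return packing_density(self.genome_length, self.genome_copies, self.internal_volume)
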