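"""Genome base composition and the hypermodified-genome mass model.

Every A or T on one strand of a duplex genome marks an A:T base pair, and
every A:T pair carries exactly one thymidine that can host a bulky covalent
modification.  Given the genome length, the number of A:T pairs, an average
mass per unmodified base pair and the mass added per modified thymidine,
the model computes the unmodified genome mass, the mass added by
modification at a given substitution fraction, and the relative mass
increase -- and composes with a packing density to express how much of the
capsid volume budget the modification consumes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from Bio import SeqIO

from .capsid_geometry import PackingResult

#: Average mass of an unmodified base pair, Da.
BP_MASS_DA = 618.0
#: Mass added per fully modified thymidine, Da.
MOD_MASS_DA = 1044.0

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class GenomeComposition:
    """Single-strand base counts with the A:T base-pair tally.

    ``AT_bp`` counts A plus T on the given strand: each such base implies
    one A:T pair in the duplex.  IUPAC ambiguity codes are tallied in
    ``counts["ambiguous"]`` and excluded from ``AT_bp``.
    """

    length: int
    counts: dict[str, int]
    T_percent: float
    AT_bp: int

    @property
    def at_fraction(self) -> float:
        return self.AT_bp / self.length


def base_composition(sequence: str) -> GenomeComposition:
    """Base composition of a nucleotide sequence (case-insensitive).

    Raises on an empty sequence or on any non-IUPAC character, naming the
    first offending position.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    tally = Counter(seq)
    bad = set(tally) - _IUPAC
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(f"non-IUPAC character {seq[pos]!r} at position {pos}")
    counts = {b: tally.get(b, 0) for b in "ACGT"}
    counts["ambiguous"] = len(seq) - sum(counts.values())
    if counts["ambiguous"]:
        warnings.warn(
            f"{counts['ambiguous']} ambiguity codes excluded from the A:T pair count"
        )
    return GenomeComposition(
        length=len(seq),
        counts=counts,
        T_percent=100.0 * counts["T"] / len(seq),
        AT_bp=counts["A"] + counts["T"],
    )


def read_fasta(path) -> str:
    """Concatenate all records of a FASTA file into one sequence string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(f"{len(records)} records in {path}; concatenating")
    return "".join(str(rec.seq) for rec in records)


@dataclass(frozen=True)
class MassModel:
    """Mass budget of a genome carrying thymidine hypermodifications."""

    length: int
    AT_bp: int
    substitution_fraction: float
    bp_mass: float = BP_MASS_DA
    mod_mass: float = MOD_MASS_DA

    @property
    def unmodified_mass(self) -> float:
        """Mass of the naked duplex, Da."""
        return self.length * self.bp_mass

    @property
    def added_mass(self) -> float:
        """Mass contributed by the modifications, Da."""
        return self.AT_bp * self.mod_mass * self.substitution_fraction

    @property
    def total_mass(self) -> float:
        return self.unmodified_mass + self.added_mass

    @property
    def relative_increase(self) -> float:
        """Added mass as a fraction of the unmodified genome mass."""
        return self.added_mass / self.unmodified_mass

    def summary(self) -> dict:
        """Display-rounded summary (masses on the 1e6 Da scale, 2 decimals)."""
        return {
            "length_bp": self.length,
            "AT_bp": self.AT_bp,
            "substitution_percent": round(100 * self.substitution_fraction),
            "unmodified_mass_MDa": round(self.unmodified_mass / 1e6, 2),
            "added_mass_MDa": round(self.added_mass / 1e6, 2),
            "total_mass_MDa": round(self.total_mass / 1e6, 2),
            "relative_increase_percent": round(100 * self.relative_increase),
        }


def mass_model(
    length: int,
    AT_bp: int,
    substitution_fraction: float,
    bp_mass: float = BP_MASS_DA,
    mod_mass: float = MOD_MASS_DA,
) -> MassModel:
    """Build a validated :class:`MassModel`."""
    if not 0 <= AT_bp <= length:
        raise ValueError(f"AT_bp must lie in [0, length], got {AT_bp} of {length}")
    if not 0 <= substitution_fraction <= 1:
        raise ValueError("substitution_fraction must be in [0, 1]")
    if bp_mass <= 0 or mod_mass <= 0:
        raise ValueError("masses must be positive")
    return MassModel(
        length=length,
        AT_bp=AT_bp,
        substitution_fraction=substitution_fraction,
        bp_mass=bp_mass,
        mod_mass=mod_mass,
    )


def modified_density_report(
    mass: MassModel,
    packing: PackingResult,
    reference_density: float | None = None,
) -> dict:
    """Joint mass/volume report for a packed, modified genome.

    Expresses the packing both as bp/nm^3 and as mass density (Da/nm^3)
    with and without the modification, plus the "unmodified-bp-equivalent"
    density total mass / bp_mass / volume.  If ``reference_density`` (a
    canonical bp/nm^3 packing to compare against) is given, the report flags
    when the equivalent density exceeds it.
    """
    bp_density = packing.density
    report = {
        "copies": packing.copies_assumed,
        "bp_density_bp_per_nm3": bp_density,
        "mass_density_unmodified_da_per_nm3": bp_density * mass.bp_mass,
        "mass_density_modified_da_per_nm3": bp_density
        * mass.bp_mass
        * (1 + mass.relative_increase),
        "bp_equivalent_density_bp_per_nm3": bp_density * (1 + mass.relative_increase),
        "flags": [],
    }
    if (
        reference_density is not None
        and report["bp_equivalent_density_bp_per_nm3"] > reference_density
    ):
        report["flags"].append("exceeds_reference_density")
    return report
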