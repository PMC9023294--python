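"""Mass-ladder and core-fragment decomposition of hypermodified nucleosides.

ESI-MS of a nucleoside digest can reveal a family of related ions whose
masses form an arithmetic progression -- a mass ladder whose common
difference is the mass of a repeating distal residue (e.g. a sugar of an
oligosaccharide modification).  MS/MS of each ladder member may share a
common cleaved fragment (the "core": base plus spacer), each parent also
showing the complementary counterpart fragment (parent - core).  From the
ladder and the core one infers the spacer mass, the repeating residue mass
and the total mass added per modified base.

All m/z values are treated as printed nominal masses; no charge-state
deconvolution or adduct correction is attempted.  A single per-mass
``tolerance`` governs matching; comparisons between two measured masses
(fragment vs fragment, or a parent-minus-core difference vs a fragment)
use twice the tolerance since two measurement errors combine.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

#: Nominal mass of the thymidine nucleoside, Da.
THYMIDINE_MASS = 242.0

DEFAULT_TOLERANCE = 0.5


@dataclass
class MsPeakSet:
    """Parent ion m/z values with per-parent MS/MS fragment lists."""

    parents: list[float]
    fragments: dict[float, list[float]] = field(default_factory=dict)
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.parents):
            raise ValueError("parent m/z values must be positive")
        for parent, frags in self.fragments.items():
            if parent not in self.parents:
                raise ValueError(f"fragment list for unlisted parent {parent}")
            if any(f <= 0 for f in frags):
                raise ValueError("fragment m/z values must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @classmethod
    def from_json(cls, path, tolerance: float = DEFAULT_TOLERANCE) -> "MsPeakSet":
        with open(path) as fh:
            obj = json.load(fh)
        fragments = {float(k): [float(x) for x in v] for k, v in obj.get("fragments", {}).items()}
        return cls(
            parents=[float(p) for p in obj["parents"]],
            fragments=fragments,
            tolerance=float(obj.get("tolerance", tolerance)),
        )

    def to_json(self, path) -> None:
        obj = {
            "parents": self.parents,
            "fragments": {repr(k): v for k, v in self.fragments.items()},
            "tolerance": self.tolerance,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class LadderResult:
    """A maximal arithmetic progression of parent masses."""

    members: list[float]  # ascending
    residue_mass: float  # mean consecutive difference
    length: int

    def __post_init__(self) -> None:
        if self.length != len(self.members) or self.length < 2:
            raise ValueError("a ladder needs >= 2 members")


def is_arithmetic(masses: list[float], tolerance: float) -> bool:
    """True when every consecutive difference lies within ``tolerance`` of
    the mean difference (the progression's residue mass)."""
    if len(masses) < 2:
        return False
    d = np.diff(sorted(masses))
    return bool(np.all(np.abs(d - d.mean()) <= tolerance + 1e-12))


def detect_ladders(
    peaks: MsPeakSet, min_length: int = 2, tolerance: float | None = None
) -> list[LadderResult]:
    """All maximal mass ladders among the parent ions.

    A ladder is a subset of parents whose sorted consecutive differences all
    lie within ``tolerance`` of their mean; maximal means no strict superset
    of its members is itself a ladder.  Returned sorted by length
    (descending) then residue mass.  Search grows chains from every ordered
    pair, pruning steps deviating more than 2x tolerance from the seed step
    (sound: within-tolerance-of-mean implies within 2x tolerance pairwise),
    and verifies the exact criterion on each candidate.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    tol = peaks.tolerance if tolerance is None else tolerance
    parents = sorted(set(peaks.parents))
    n = len(parents)
    satisfying: set[tuple[float, ...]] = set()

    def grow(chain: list[float], start: int) -> None:
        if len(chain) >= min_length and is_arithmetic(chain, tol):
            satisfying.add(tuple(chain))
        step0 = chain[1] - chain[0]
        for idx in range(start, n):
            if abs((parents[idx] - chain[-1]) - step0) <= 2 * tol:
                grow(chain + [parents[idx]], idx + 1)

    for i, j in itertools.combinations(range(n), 2):
        grow([parents[i], parents[j]], j + 1)

    maximal = [
        c
        for c in satisfying
        if not any(set(c) < set(other) for other in satisfying)
    ]
    results = [
        LadderResult(
            members=list(c),
            residue_mass=float(np.diff(c).mean()),
            length=len(c),
        )
        for c in maximal
    ]
    return sorted(results, key=lambda lad: (-lad.length, lad.residue_mass))


@dataclass
class CoreDecomposition:
    """A shared MS/MS core fragment with verified parent complements."""

    core_mass: float
    complements: dict[float, float]  # parent -> matched (parent - core) fragment
    spacer_mass: float  # core - thymidine
    base_mass: float
    per_base_addition: float  # largest parent - thymidine
    status: str = "ok"  # "ok" or "no-common-core"

    @classmethod
    def empty(cls) -> "CoreDecomposition":
        return cls(
            core_mass=float("nan"),
            complements={},
            spacer_mass=float("nan"),
            base_mass=THYMIDINE_MASS,
            per_base_addition=float("nan"),
            status="no-common-core",
        )


def _match(value: float, candidates: list[float], tol: float) -> float | None:
    """Closest candidate within ``tol`` of ``value``, else None."""
    if not candidates:
        return None
    best = min(candidates, key=lambda c: abs(c - value))
    return best if abs(best - value) <= tol else None


def find_core(
    peaks: MsPeakSet, tolerance: float | None = None, base_mass: float = THYMIDINE_MASS
) -> CoreDecomposition:
    """Identify the fragment shared by every parent's MS/MS spectrum.

    A candidate core must (a) match a fragment in every parent's list within
    2x tolerance and (b) pass complement verification: for every parent, the
    counterpart mass parent - core must also appear among that parent's
    fragments (within 2x tolerance).  Among verified candidates the one with
    the smallest total matching deviation wins.  The spacer mass is
    core - base (thymidine, 242 Da nominal) and the total addition per
    modified base is max(parent) - base.
    """
    tol = peaks.tolerance if tolerance is None else tolerance
    with_frags = [p for p in peaks.parents if peaks.fragments.get(p)]
    if len(with_frags) < 2:
        return CoreDecomposition.empty()

    first, *rest = with_frags
    best: tuple[float, CoreDecomposition] | None = None
    for candidate in peaks.fragments[first]:
        matches = [candidate]
        for p in rest:
            m = _match(candidate, peaks.fragments[p], 2 * tol)
            if m is None:
                break
            matches.append(m)
        else:
            core = float(np.mean(matches))
            complements: dict[float, float] = {}
            deviation = float(np.sum(np.abs(np.array(matches) - core)))
            for p in with_frags:
                c = _match(p - core, peaks.fragments[p], 2 * tol)
                if c is None:
                    break
                complements[p] = c
                deviation += abs((p - core) - c)
            else:
                if best is None or deviation < best[0]:
                    best = (
                        deviation,
                        CoreDecomposition(
                            core_mass=core,
                            complements=complements,
                            spacer_mass=core - base_mass,
                            base_mass=base_mass,
                            per_base_addition=max(peaks.parents) - base_mass,
                        ),
                    )
    return best[1] if best is not None else CoreDecomposition.empty()


@dataclass
class ResidueLibrary:
    """Known residue masses for classifying ladder steps (user-extensible)."""

    entries: dict[str, float] = field(
        default_factory=lambda: {
            "hexose": 162.0,
            "hexosamine": 161.0,
            "N-acetylhexosamine": 203.0,
        }
    )

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.entries.values()):
            raise ValueError("residue masses must be positive")

    def add(self, name: str, mass: float) -> None:
        if name in self.entries:
            raise ValueError(f"duplicate residue name {name!r}")
        if mass <= 0:
            raise ValueError("residue masses must be positive")
        self.entries[name] = mass


def classify_residue(
    mass: float, library: ResidueLibrary | None = None, tolerance: float = DEFAULT_TOLERANCE
) -> str:
    """Name of the nearest library residue within ``tolerance``, else "unknown".

    Ties break on smaller absolute deviation, then alphabetical name.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    library = library or ResidueLibrary()
    ranked = sorted(library.entries.items(), key=lambda kv: (abs(kv[1] - mass), kv[0]))
    name, ref = ranked[0]
    return name if abs(ref - mass) <= tolerance else "unknown"


def modification_mass_summary(
    decomp: CoreDecomposition,
    ladder: LadderResult,
    tolerance: float = DEFAULT_TOLERANCE,
    library: ResidueLibrary | None = None,
) -> dict:
    """Combine ladder and core evidence into a per-base modification report.

    The ladder length bounds the number of distal residues from below
    (length - 1 steps seen).  The unexplained mass of the largest parent,
    max(parent) - core - (min residues) * residue, is reduced by the best
    integer multiple of the residue mass; a nonzero remainder flags the
    internal structure as unresolved rather than asserting a composition.
    """
    if decomp.status != "ok":
        raise ValueError("cannot summarize a no-common-core decomposition")
    min_residues = ladder.length - 1
    top = max(ladder.members)
    unexplained = top - decomp.core_mass - min_residues * ladder.residue_mass
    best_k = max(0, round(unexplained / ladder.residue_mass))
    remainder = unexplained - best_k * ladder.residue_mass
    flags = []
    if abs(remainder) > tolerance:
        flags.append("structure_unresolved")
    return {
        "per_base_addition_da": decomp.per_base_addition,
        "residue_mass_da": ladder.residue_mass,
        "residue_classification": classify_residue(
            ladder.residue_mass, library, tolerance
        ),
        "min_residue_count": min_residues,
        "spacer_mass_da": decomp.spacer_mass,
        "core_mass_da": decomp.core_mass,
        "unexplained_mass_da": unexplained,
        "best_additional_residues": best_k,
        "remainder_da": remainder,
        "flags": flags,
    }
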