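"""Synthetic data generators for every pipeline stage.

Each generator emulates the statistical structure of one experimental
input -- a random genome of given length and AT fraction, a calibrated
HPLC peak-area table with multiplicative noise and a hidden thymidine
substitution, a Gaussian-shell radial density profile, and a ladder-
structured MS peak set -- so parameter-recovery tests can run against
known ground truth without any external data.

Defaults correspond to the YerA41 study conditions: a 145,577 bp genome at
AT fraction 0.6771, 56% thymidine substitution, 5% multiplicative noise,
genome shells at 530/500/467/431 A (spacings 30/33/36 A), and an MS ladder
with core 346, residue 184 and parents 918/1102/1286.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ms_ladder import THYMIDINE_MASS, MsPeakSet
from .nucleoside_composition import STANDARD_CONC_UM
from .radial_layers import RadialProfile


@dataclass
class GeneratorConfig:
    """Ground-truth parameters shared by the generators.

    Fractions are dimensionless in [0, 1]; radii and sigmas in Angstrom;
    masses in Da.  ``ms_counts`` are distal-residue counts per ladder
    member; ``ms_offset`` is an extra core-proximal mass so parent masses
    need not be integer residue multiples of the core.
    """

    seed: int = 0
    genome_length: int = 145_577
    at_fraction: float = 0.6771
    true_composition: dict[str, float] | None = None  # deoxy molar fractions
    substitution_fraction: float = 0.56
    comigration: dict[str, float] = field(
        default_factory=lambda: {"dA": 0.5, "dG": 0.5}
    )
    area_noise_cv: float = 0.05
    shell_radii: tuple[float, ...] = (530.0, 500.0, 467.0, 431.0)
    shell_sigma: float = 6.0
    profile_noise_cv: float = 0.05
    ms_spacer: float = 104.0
    ms_offset: float = 204.0
    ms_residue: float = 184.0
    ms_counts: tuple[int, ...] = (2, 3, 4)
    ms_jitter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("at_fraction", "substitution_fraction", "area_noise_cv", "profile_noise_cv"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if any(np.diff(self.shell_radii) >= 0):
            raise ValueError("shell_radii must be strictly decreasing")
        if any(c < 1 for c in self.ms_counts):
            raise ValueError("ms_counts must be >= 1")

    @property
    def deoxy_composition(self) -> dict[str, float]:
        """Unmodified deoxynucleoside molar fractions (default: from AT fraction)."""
        if self.true_composition is not None:
            comp = dict(self.true_composition)
        else:
            at, gc = self.at_fraction, 1 - self.at_fraction
            comp = {"dA": at / 2, "T": at / 2, "dC": gc / 2, "dG": gc / 2}
        total = sum(comp.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"true_composition must sum to 1, sums to {total}")
        return comp

    @property
    def ms_core(self) -> float:
        """Core fragment mass: thymidine plus spacer."""
        return THYMIDINE_MASS + self.ms_spacer


def make_genome(config: GeneratorConfig) -> str:
    """I.i.d. random genome with P(A) = P(T) = at_fraction / 2."""
    rng = np.random.default_rng(config.seed)
    at, gc = config.at_fraction, 1 - config.at_fraction
    p = [at / 2, at / 2, gc / 2, gc / 2]
    bases = rng.choice(np.frombuffer(b"ATCG", dtype="S1"), size=config.genome_length, p=p)
    return bases.tobytes().decode("ascii")


def write_fasta(sequence: str, path, name: str = "synthetic_genome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


def make_chromatogram(config: GeneratorConfig) -> pd.DataFrame:
    """Simulated calibrated HPLC peak-area table (a nucleoside table).

    Per-nucleoside detector responses are drawn log-uniformly and applied
    to both the sample and the 50 uM standard, so the ratio method must
    cancel them.  The modified-thymidine amount is removed from the T peak
    and co-migrates with other peaks (default split between dA and dG, as
    glyco-thymidine species elute near those nucleosides), keeping the
    class total constant.  Sample areas carry multiplicative Gaussian noise
    with coefficient of variation ``area_noise_cv``.
    """
    rng = np.random.default_rng(config.seed)
    amounts = dict(config.deoxy_composition)
    moved = config.substitution_fraction * amounts["T"]
    amounts["T"] -= moved
    for nuc, share in config.comigration.items():
        amounts[nuc] += moved * share
    rows = []
    for nuc in ("dA", "dG", "dC", "T"):
        response = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
        noise = 1.0 + config.area_noise_cv * rng.standard_normal()
        rows.append(
            {
                "nucleoside": nuc,
                "class": "deoxy",
                "sample_area": response * amounts[nuc] * 100.0 * max(noise, 0.0),
                "standard_area": response * STANDARD_CONC_UM,
            }
        )
    return pd.DataFrame(rows)


def make_profile(config: GeneratorConfig) -> RadialProfile:
    """Sum-of-Gaussians radial profile on a 1 A grid with multiplicative noise."""
    radii = np.asarray(config.shell_radii, dtype=float)
    seps = -np.diff(radii)
    if len(seps) and seps.min() < 2 * config.shell_sigma:
        warnings.warn("shells closer than 2 sigma; peaks may merge")
    rng = np.random.default_rng(config.seed)
    grid = np.arange(0.0, radii.max() + 6 * config.shell_sigma + 20.0)
    density = np.zeros_like(grid)
    for c in radii:
        density += np.exp(-0.5 * ((grid - c) / config.shell_sigma) ** 2)
    if config.profile_noise_cv > 0:
        density *= 1.0 + config.profile_noise_cv * rng.standard_normal(grid.shape)
    return RadialProfile(radius=grid, density=density)


def make_ms(config: GeneratorConfig) -> MsPeakSet:
    """Ladder-structured MS peak set with per-parent core/counterpart fragments.

    Parent masses are base + spacer + offset + count * residue for each
    count; each parent's MS/MS list holds the core (base + spacer) and the
    counterpart parent - core.  Uniform jitter up to ``ms_jitter`` is added
    independently to every mass.
    """
    if not config.ms_counts:
        raise ValueError("ms_counts must be nonempty")
    rng = np.random.default_rng(config.seed)

    def jit(x: float) -> float:
        if config.ms_jitter == 0:
            return float(x)
        return float(x + rng.uniform(-config.ms_jitter, config.ms_jitter))

    core = config.ms_core
    parents, fragments = [], {}
    for count in config.ms_counts:
        true_parent = core + config.ms_offset + count * config.ms_residue
        parent = jit(true_parent)
        parents.append(parent)
        fragments[parent] = [jit(core), jit(true_parent - core)]
    return MsPeakSet(parents=parents, fragments=fragments)
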