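# Methods

This note documents the models, estimators and numerical choices behind
phagepack, what the synthetic generators emulate, and what the tests do and
do not demonstrate about real data.

## Capsid geometry and packing density

An icosahedral lattice is specified by integer steps (h, k) ≥ 0, not both
zero; the triangulation number is T = h² + hk + k² and the shell carries
60·T subunits. Chirality: lattices with h = k, h = 0 or k = 0 are achiral;
for h ≠ k the (h, k) and (k, h) walks are mirror images. Which mirror is
called *laevo* is a labelling convention, not arithmetic — published T = 28
capsids disagree — so the convention is a parameter
(`lattice_handedness(..., h_gt_k=...)`), defaulting to h > k → laevo so
that (4, 2) is laevo, matching the YerA41 assignment from HK97-fold
fitting.

The capsid lumen is modelled as a sphere, V = (4/3)πr³. Measured lumen
volumes (e.g. ~620 × 10³ nm³ for YerA41-B) may be supplied directly and
take precedence over a radius; the sphere is an approximation offered for
when only a diameter is known, and is documented as such rather than
asserted to be how any published volume was obtained.

Packing density is ρ = copies·L/V in bp/nm³. It is interconverted with the
interaxial spacing d of a hexagonally close-packed bundle of duplexes:
each duplex claims a hexagonal prism of cross-section (√3/2)d², and with an
axial rise h_rise (default 0.34 nm/bp for B-DNA, overridable) one base pair
occupies (√3/2)·d²·h_rise nm³, so ρ = 1/((√3/2)d²h_rise). The conversion
and its inverse round-trip to 1e-9 relative tolerance (tested). Densities
are displayed rounded to 2 decimals; full precision is kept internally.

## Radial shell detection

Input is a 1-D radial density trace (radius in Å on a strictly increasing
grid, density in arbitrary units), as produced by rotational averaging of a
central slice of a capsid map. Shells are local maxima that
(a) exceed a prominence of `min_prominence` (default 0.1) times the
profile's dynamic range max − min, and (b) are separated by at least
`min_separation` (default 15 Å; the defaults cleanly separate shells
~30 Å apart). Using the dynamic range rather than the raw maximum makes
detection exactly invariant to uniform scaling and to DC offsets.

Before peak-finding the trace is smoothed with a Savitzky–Golay filter
(quadratic, window 7 samples ≈ 7 Å; `smooth_window=0` disables). Each
detected apex is then refined by quadratic interpolation through the
smoothed maximum and its two neighbours. Smoothing preserves a quadratic
apex exactly, so on noise-free Gaussian shells the refined radii are
accurate to well under 0.5 Å; under 5% multiplicative noise it roughly
halves the apex jitter, keeping the mean absolute spacing error of the
synthetic 30/33/36 Å benchmark near 0.65 Å.

Labelling a shell as capsid wall, internal protein or genome cannot be done
from the 1-D trace alone; callers may pass explicit labels, and the default
rule labels the outermost shell(s) as protein (configurable count) and the
rest as genome. The spacing report converts only genome–genome spacings to
densities; a protein→genome gap is not an interduplex distance.

The published 30/33/36 Å spacings come from a real cryo-EM map; this module
validates recovery on synthetic Gaussian-shell profiles built to those
spacings, which shows the detector works, not that the deposited map would
yield exactly those numbers.

## Nucleoside composition and substitution fraction

Each nucleoside's molar amount is sample_area / standard_area, a
single-point calibration against an equimolar (50 µM) standard mixture
that cancels per-nucleoside detector response exactly; no standard curve is
fitted. Percentages are normalized to 100 separately within the
deoxyribonucleoside and ribonucleoside classes, because ribonucleoside
signal in this system traces to ribosome contamination of the lysate, not
the genome. Pairing diagnostics flag `T_deficit` when T/dA < 1 − tol and
`GC_imbalance` when |dC − dG| exceeds tol of their mean (default tol 0.25).

The substitution fraction is f = 1 − T_obs/T_exp, clamped to [0, 1], where
T_exp is the genome-predicted thymidine percentage (from a FASTA when
available, else a supplied constant such as 34) and T_obs the measured one.
The estimator assumes modified thymidine leaves the T peak but remains in
the analysed mixture (it co-elutes with other nucleosides), so the class
total is conserved; under that assumption the inversion is exact, which the
zero-noise synthetic tests confirm. Display rounding: one decimal for
percentages, whole percent for the substitution figure; the pipeline feeds
the whole-percent figure into the mass model, mirroring how the published
chain propagates 56%.

## MS mass-ladder decomposition

All m/z values are treated as printed nominal masses; no charge-state,
adduct or isotope handling (the data this targets are reasoned about at
integer resolution, default tolerance 0.5). Comparisons of a computed
quantity against one measured mass use the tolerance; comparisons between
two measured masses (clustering shared fragments across spectra, and
checking parent − core against an observed fragment) use twice the
tolerance, since two independent measurement errors combine.

A ladder is a maximal subset of parent masses whose sorted consecutive
differences all lie within tolerance of their mean (the residue mass);
maximal means no strict superset also qualifies. The search grows chains
from every ordered pair, pruning any step that deviates more than twice the
tolerance from the seed step — a sound bound, since all differences of a
qualifying chain lie within 2×tol of each other — and verifies the exact
criterion on every candidate. The test suite checks equivalence against
exhaustive subset enumeration on hundreds of random peak sets.

The core finder proposes every fragment of one spectrum that has a match in
all others, and accepts a candidate only if every parent also shows the
complementary fragment parent − core; among verified candidates the one
with the smallest total matching deviation wins. From a verified core:
spacer = core − 242 (thymidine nucleoside nominal mass, kept as a named
constant), and the total addition per modified base is
max(parent) − 242. The residue mass is classified against a small
extensible library (hexose 162, hexosamine 161, N-acetylhexosamine 203);
the YerA41 residue at 184 matches none and is reported "unknown". The
summary deliberately reports the unexplained mass of the largest parent and
its best integer-residue fit with remainder (flagging
`structure_unresolved` when nonzero) rather than asserting an internal
composition the data do not determine — the ladder length only bounds the
residue count from below.

## Genome mass model

On one strand, every A or T implies one A:T pair in the duplex, so
AT_bp = count(A) + count(T); this convention reproduces the published A:T
pair count from the genome's length and T fraction. IUPAC ambiguity codes
are tallied separately and conservatively excluded from AT_bp (with a
warning). The mass budget is

- unmodified mass = L · m_bp (m_bp default 618 Da/bp, average),
- added mass = AT_bp · m_mod · f (m_mod default 1044 Da per modified
  thymidine; one modifiable thymidine per A:T pair),
- relative increase = added/unmodified,

all linear in their parameters (tested). The density report composes the
mass model with a packing result: mass densities in Da/nm³ with and without
modification, and an "unmodified-bp-equivalent" density
ρ·(1 + relative increase) that can be compared against a canonical
close-packing reference (config, default 0.54 bp/nm³, the 2.5 nm-spacing
regime).

## Synthetic data

Generator defaults are the study conditions: genome length 145,577 bp at AT
fraction 0.6771 (chosen so 34% T and ~98,567 A:T pairs are ordinary draws),
substitution 0.56, 5% multiplicative noise on areas and profiles, shells at
530/500/467/431 Å with σ = 6 Å, and an MS family with spacer 104
(core 346 = 242 + 104), residue 184, core-proximal offset 204 and residue
counts 2–4, which reproduces the 918/1102/1286 parents exactly.

- **Genome**: i.i.d. bases, P(A) = P(T) = AT/2. Real genomes have
  dinucleotide structure and local skew; tests against this generator
  validate counting and sampling arithmetic, not robustness to genomic
  structure (which the counting stages do not depend on).
- **Chromatogram**: per-nucleoside responses drawn log-uniform on
  [0.5, 2] and applied to sample and standard alike (so the ratio method
  must cancel them); multiplicative Gaussian noise with the stated CV;
  the modified-T amount is moved to co-migrating peaks (default split
  between dA and dG, as the glyco-thymidine species co-elute there),
  keeping class totals constant. Peak overlap/integration errors of real
  chromatography are not modelled.
- **Profile**: equal-height Gaussians on a 1 Å grid with multiplicative
  noise; a warning is issued when shells sit closer than 2σ. Real profiles
  have radially varying background and unequal shell occupancy.
- **MS**: parents base + spacer + offset + count·residue; fragments
  {core, parent − core}; optional uniform jitter per mass. Real spectra
  contain many unrelated peaks; robustness to distractors is exercised via
  the random peak sets of the ladder-equivalence tests.

All generators are deterministic under their seed.

## Problem sizes and tolerances in the test suite

Parameter-recovery tests use 50 noise replicates for shells, 200 simulated
chromatograms, 100 genome draws at full length (145,577 bp) and 500 random
peak sets — sizes at which the Monte-Carlo error of each checked statistic
is an order of magnitude below its acceptance band, while the whole suite
runs in seconds. Recovery bands: spacing MAE < 1.5 Å; composition MAE
< 1 percentage point pooled over the four deoxynucleosides (the dominant
peak alone has an analytic MAE of ~1.05 pp at 5% CV, so a per-nucleoside
bound at 1 pp would be unattainable under the stated noise); substitution
fraction ±0.02 (noise-free, exact inversion) and ±0.05 in the mean at 5%
CV; geometry round-trips at 1e-9 relative.

## Known limitations

- No 3-D map handling: radial profiles must be extracted upstream.
- No chromatographic signal processing: peak areas are inputs.
- Nominal-mass MS reasoning only; high-resolution data can tighten the
  tolerance parameter but gain no exact-mass chemistry.
- The substitution estimator attributes the entire T deficit to
  modification; degradation or integration bias would inflate it.
- The mass model uses average masses and one modifiable thymidine per A:T
  pair; it ignores termini, packaged proteins and counterions.
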