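"""Base composition and the hypermodified-genome mass budget."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagepack.capsid_geometry import packing_density
from phagepack.genome_mass_model import (
    base_composition,
    mass_model,
    modified_density_report,
    read_fasta,
)
from phagepack.synthetic import GeneratorConfig, make_genome, write_fasta

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@pytest.mark.parametrize(
    "seq,length,t_pct,at_bp",
    [("ATAT", 4, 50.0, 4), ("GGCC", 4, 0.0, 0), ("acgt", 4, 25.0, 2)],
)
def test_base_composition_examples(seq, length, t_pct, at_bp):
    comp = base_composition(seq)
    assert comp.length == length
    assert comp.T_percent == pytest.approx(t_pct)
    assert comp.AT_bp == at_bp


def test_base_composition_errors():
    with pytest.raises(ValueError, match="empty"):
        base_composition("")
    with pytest.raises(ValueError, match="position 2"):
        base_composition("ACXGT")


def test_ambiguity_codes_counted_separately():
    with pytest.warns(UserWarning, match="ambiguity"):
        comp = base_composition("ATNNGC")
    assert comp.counts["ambiguous"] == 2
    assert comp.AT_bp == 2
    assert sum(comp.counts.values()) == comp.length


@given(seed=st.integers(0, 2**16))
@settings(derandomize=True, max_examples=20, deadline=None)
def test_revcomp_concatenation_balances_a_and_t(seed):
    seq = make_genome(GeneratorConfig(seed=seed, genome_length=500, at_fraction=0.6))
    revcomp = seq.translate(_COMPLEMENT)[::-1]
    comp = base_composition(seq + revcomp)
    assert comp.counts["A"] == comp.counts["T"]


def test_generated_genome_recovers_at_fraction():
    """AT_bp/length of a simulated genome matches the generator's AT fraction
    within 3 binomial standard deviations."""
    for seed in range(10):
        cfg = GeneratorConfig(seed=seed, genome_length=50_000, at_fraction=0.6771)
        comp = base_composition(make_genome(cfg))
        se = np.sqrt(0.6771 * (1 - 0.6771) / cfg.genome_length)
        assert abs(comp.at_fraction - 0.6771) < 3 * se


def test_mass_model_full_substitution():
    """All 98,567 A:T pairs modified: 89.97 MDa duplex + 102.9 MDa additions."""
    mm = mass_model(145_577, 98_567, 1.0)
    assert mm.unmodified_mass == pytest.approx(89.97e6, rel=1e-3)
    assert mm.added_mass == pytest.approx(102.9e6, rel=1e-3)
    assert mm.summary()["unmodified_mass_MDa"] == 89.97
    assert mm.summary()["added_mass_MDa"] == 102.9


def test_mass_model_56_percent_substitution():
    """At 56% substitution the additions are 57.63 MDa, 64% of the duplex mass."""
    mm = mass_model(145_577, 98_567, 0.56)
    assert mm.added_mass == pytest.approx(57.63e6, rel=1e-3)
    assert mm.relative_increase == pytest.approx(0.64, abs=5e-3)
    assert mm.summary()["added_mass_MDa"] == 57.63
    assert mm.summary()["relative_increase_percent"] == 64


def test_mass_model_zero_fraction():
    mm = mass_model(145_577, 98_567, 0.0)
    assert mm.added_mass == 0.0
    assert mm.relative_increase == 0.0


def test_mass_model_validation():
    with pytest.raises(ValueError):
        mass_model(100, 200, 0.5)
    with pytest.raises(ValueError):
        mass_model(100, 50, 1.5)
    with pytest.raises(ValueError):
        mass_model(100, 50, 0.5, bp_mass=0.0)


@given(
    fraction=st.floats(0.0, 1.0),
    at_bp=st.integers(0, 100_000),
    mod_mass=st.floats(100.0, 2000.0),
)
@settings(derandomize=True, max_examples=50)
def test_mass_model_linearity(fraction, at_bp, mod_mass):
    base = mass_model(145_577, at_bp, fraction, mod_mass=mod_mass)
    assert mass_model(145_577, at_bp, fraction / 2, mod_mass=mod_mass).added_mass == (
        pytest.approx(base.added_mass / 2)
    )
    assert mass_model(145_577, at_bp, fraction, mod_mass=2 * mod_mass).added_mass == (
        pytest.approx(2 * base.added_mass)
    )


def test_relative_increase_independent_of_volume_and_copies():
    mm = mass_model(145_577, 98_567, 0.56)
    r1 = modified_density_report(mm, packing_density(145_577, 1, 620_000))
    r2 = modified_density_report(mm, packing_density(145_577, 2, 620_000))
    ratio1 = r1["bp_equivalent_density_bp_per_nm3"] / r1["bp_density_bp_per_nm3"]
    ratio2 = r2["bp_equivalent_density_bp_per_nm3"] / r2["bp_density_bp_per_nm3"]
    assert ratio1 == pytest.approx(ratio2) == pytest.approx(1 + mm.relative_increase)


def test_modified_density_report_values():
    """One copy at 56% substitution packs like ~0.39 unmodified-bp/nm^3."""
    mm = mass_model(145_577, 98_567, 0.56)
    rep = modified_density_report(mm, packing_density(145_577, 1, 620_000))
    assert rep["bp_equivalent_density_bp_per_nm3"] == pytest.approx(0.386, abs=5e-3)
    two = modified_density_report(mm, packing_density(145_577, 2, 620_000), 0.54)
    assert two["bp_equivalent_density_bp_per_nm3"] == pytest.approx(0.77, abs=0.01)
    assert two["flags"] == ["exceeds_reference_density"]
    none_mod = modified_density_report(
        mass_model(145_577, 98_567, 0.0), packing_density(145_577, 1, 620_000)
    )
    assert none_mod["bp_equivalent_density_bp_per_nm3"] == pytest.approx(
        none_mod["bp_density_bp_per_nm3"]
    )


def test_fasta_reading(tmp_path):
    seq = make_genome(GeneratorConfig(seed=1, genome_length=1000))
    path = tmp_path / "genome.fasta"
    write_fasta(seq, path)
    assert read_fasta(path) == seq
    multi = tmp_path / "multi.fasta"
    multi.write_text(">a\nACGT\n>b\nTTTT\n")
    with pytest.warns(UserWarning, match="concatenating"):
        assert read_fasta(multi) == "ACGTTTTT"
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(ValueError):
        read_fasta(empty)
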