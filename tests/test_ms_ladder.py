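"""Mass-ladder detection, core decomposition and residue classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagepack.ms_ladder import (
    MsPeakSet,
    ResidueLibrary,
    classify_residue,
    detect_ladders,
    find_core,
    is_arithmetic,
    modification_mass_summary,
)
from phagepack.synthetic import GeneratorConfig, make_ms


def brute_force_ladders(parents, tolerance, min_length=2):
    """Oracle: exhaustively enumerate maximal near-arithmetic subsets.

    A subset qualifies when its sorted consecutive differences all lie
    within ``tolerance`` of their mean; maximal subsets are those with no
    qualifying strict superset.
    """
    parents = sorted(set(parents))
    qualifying = []
    for size in range(min_length, len(parents) + 1):
        for combo in itertools.combinations(parents, size):
            d = np.diff(combo)
            if np.all(np.abs(d - d.mean()) <= tolerance + 1e-12):
                qualifying.append(frozenset(combo))
    return {
        q for q in qualifying if not any(q < other for other in qualifying)
    }


def test_published_ladder():
    """918/1102/1286 form one ladder with a 184 Da repeating residue."""
    peaks = MsPeakSet(parents=[918.0, 1102.0, 1286.0])
    ladders = detect_ladders(peaks)
    assert len(ladders) == 1
    assert ladders[0].members == [918.0, 1102.0, 1286.0]
    assert ladders[0].residue_mass == pytest.approx(184.0)
    assert ladders[0].length == 3


def test_singleton_has_no_ladder():
    assert detect_ladders(MsPeakSet(parents=[918.0])) == []


def test_ladders_match_brute_force_on_structured_list():
    parents = [100.0, 150.0, 184.0, 300.0, 334.0, 368.0, 518.0]
    peaks = MsPeakSet(parents=parents)
    got = {frozenset(lad.members) for lad in detect_ladders(peaks)}
    assert got == brute_force_ladders(parents, peaks.tolerance)


@given(
    parents=st.lists(
        st.floats(100.0, 2000.0), min_size=2, max_size=12, unique=True
    ),
    tol=st.sampled_from([0.5, 1.0, 5.0]),
)
@settings(derandomize=True, max_examples=150, deadline=None)
def test_ladders_equal_exhaustive_enumeration(parents, tol):
    peaks = MsPeakSet(parents=parents, tolerance=tol)
    got = {frozenset(lad.members) for lad in detect_ladders(peaks)}
    assert got == brute_force_ladders(parents, tol)


def test_ladder_ordering_and_residue_mean():
    peaks = MsPeakSet(parents=[100.0, 200.0, 300.0, 1000.0, 1050.0])
    ladders = detect_ladders(peaks)
    lengths = [lad.length for lad in ladders]
    assert lengths == sorted(lengths, reverse=True)
    assert ladders[0].members == [100.0, 200.0, 300.0]
    for lad in ladders:
        assert lad.residue_mass == pytest.approx(float(np.diff(lad.members).mean()))
        assert is_arithmetic(lad.members, peaks.tolerance)


def test_input_order_invariance(yera_peaks):
    shuffled = MsPeakSet(
        parents=list(reversed(yera_peaks.parents)),
        fragments={p: list(reversed(f)) for p, f in yera_peaks.fragments.items()},
    )
    assert detect_ladders(shuffled)[0].members == detect_ladders(yera_peaks)[0].members
    assert find_core(shuffled).core_mass == find_core(yera_peaks).core_mass


def test_find_core_published_decomposition(yera_peaks):
    """Shared 346 fragment with verified 572/756/940 counterparts."""
    decomp = find_core(yera_peaks)
    assert decomp.status == "ok"
    assert decomp.core_mass == pytest.approx(346.0)
    assert decomp.complements == {918.0: 572.0, 1102.0: 756.0, 1286.0: 940.0}
    assert decomp.spacer_mass == pytest.approx(104.0)  # 346 - thymidine 242
    assert decomp.per_base_addition == pytest.approx(1044.0)  # 1286 - 242


def test_find_core_single_parent_is_no_common_core():
    peaks = MsPeakSet(parents=[918.0], fragments={918.0: [346.0, 572.0]})
    assert find_core(peaks).status == "no-common-core"


def test_find_core_requires_complement_verification():
    """A shared fragment without its counterpart in every spectrum is rejected."""
    peaks = MsPeakSet(
        parents=[918.0, 1102.0, 1286.0],
        fragments={
            918.0: [346.0],  # counterpart 572 missing
            1102.0: [346.0, 756.0],
            1286.0: [346.0, 940.0],
        },
    )
    assert find_core(peaks).status == "no-common-core"


def test_find_core_complements_always_verified():
    """Whenever a core is returned, every parent has a matching counterpart."""
    for seed in range(10):
        peaks = make_ms(GeneratorConfig(seed=seed, ms_jitter=0.25))
        decomp = find_core(peaks)
        assert decomp.status == "ok"
        for parent, comp in decomp.complements.items():
            assert any(
                abs(f - comp) < 1e-9 for f in peaks.fragments[parent]
            )
            assert abs((parent - decomp.core_mass) - comp) <= 2 * peaks.tolerance


def test_jitter_robust_recovery():
    """Recovery of core/spacer/addition stays within tolerance under jitter."""
    for seed in range(5):
        peaks = make_ms(GeneratorConfig(seed=seed, ms_jitter=0.3))
        decomp = find_core(peaks)
        assert decomp.status == "ok"
        assert decomp.core_mass == pytest.approx(346.0, abs=0.5)
        assert decomp.spacer_mass == pytest.approx(104.0, abs=0.5)
        assert decomp.per_base_addition == pytest.approx(1044.0, abs=0.5)
        ladders = detect_ladders(peaks)
        assert ladders and ladders[0].residue_mass == pytest.approx(184.0, abs=0.5)


@pytest.mark.parametrize(
    "mass,expected",
    [(184.0, "unknown"), (162.0, "hexose"), (161.4, "hexosamine"), (203.2, "N-acetylhexosamine")],
)
def test_classify_residue(mass, expected):
    assert classify_residue(mass, tolerance=0.5) == expected


def test_classify_residue_tie_breaks():
    lib = ResidueLibrary(entries={"a": 100.0, "b": 100.0})
    assert classify_residue(100.0, lib, tolerance=0.5) == "a"  # alphabetical on tie
    with pytest.raises(ValueError):
        classify_residue(-1.0)
    with pytest.raises(ValueError):
        ResidueLibrary(entries={"x": -5.0})


def test_modification_summary_published_values(yera_peaks):
    decomp = find_core(yera_peaks)
    ladder = detect_ladders(yera_peaks)[0]
    report = modification_mass_summary(decomp, ladder)
    assert report["per_base_addition_da"] == pytest.approx(1044.0)
    assert report["residue_mass_da"] == pytest.approx(184.0)
    assert report["residue_classification"] == "unknown"
    assert report["min_residue_count"] == 2
    assert report["spacer_mass_da"] == pytest.approx(104.0)
    assert report["core_mass_da"] == pytest.approx(346.0)
    # 1286 - 346 - 2*184 = 572; best extra-residue fit k=3 leaves 20 Da
    assert report["unexplained_mass_da"] == pytest.approx(572.0)
    assert report["best_additional_residues"] == 3
    assert report["remainder_da"] == pytest.approx(20.0)
    assert report["flags"] == ["structure_unresolved"]


def test_modification_summary_length_two_ladder():
    peaks = MsPeakSet(
        parents=[530.0, 714.0],
        fragments={530.0: [346.0, 184.0], 714.0: [346.0, 368.0]},
    )
    decomp = find_core(peaks)
    ladder = detect_ladders(peaks)[0]
    report = modification_mass_summary(decomp, ladder)
    assert report["min_residue_count"] == 1
    # 714 - 346 - 1*184 = 184 -> one further residue, nothing unresolved
    assert report["best_additional_residues"] == 1
    assert report["remainder_da"] == pytest.approx(0.0)
    assert report["flags"] == []


def test_peak_set_json_round_trip(tmp_path, yera_peaks):
    path = tmp_path / "peaks.json"
    yera_peaks.to_json(path)
    loaded = MsPeakSet.from_json(path)
    assert loaded.parents == yera_peaks.parents
    assert loaded.fragments == yera_peaks.fragments


def test_peak_set_validation():
    with pytest.raises(ValueError):
        MsPeakSet(parents=[-1.0])
    with pytest.raises(ValueError):
        MsPeakSet(parents=[100.0], fragments={200.0: [50.0]})
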