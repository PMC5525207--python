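"""Counting, Eq.-1/Eq.-2 normalizations, net charge and hydrophobicity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmhflank import (
    OrientedTMH,
    UndefinedProfileError,
    absolute_relative_occurrence,
    background_level,
    count_occurrences,
    flank_average,
    get_scale,
    hydrophobicity_profile,
    net_charge_profile,
    relative_percentage,
    residue_percentage,
    windowed_hydropathy,
)


def seg(core, inside="", outside="", accession="X", idx=0, n_tmh=1):
    return OrientedTMH(
        accession=accession,
        tmh_index=idx,
        core=core,
        inside_flank=inside,
        outside_flank=outside,
        pass_class="single" if n_tmh == 1 else "multi",
        regime="central",
        inside_truncation="full",
        outside_truncation="full",
        n_tmh=n_tmh,
    )


def test_count_occurrences_single_segment():
    s = count_occurrences([seg("ACA", inside="K", outside="D")])
    # core center index (3-1)//2 = 1: positions K=-2 A=-1 C=0 A=+1 D=+2
    assert list(s.positions) == [-2, -1, 0, 1, 2]
    assert s.class_counts("A").tolist() == [0, 1, 0, 1, 0]
    assert s.class_counts("K").tolist() == [1, 0, 0, 0, 0]
    assert s.coverage.tolist() == [1, 1, 1, 1, 1]


def test_count_occurrences_ragged_coverage():
    s = count_occurrences([seg("AAA"), seg("AAAAA")])
    # centers at index 1 and 2; spans -1..1 and -2..2
    assert s.coverage.tolist() == [1, 2, 2, 2, 1]
    assert s.n_segments == 2


def test_nonstandard_residue_counts_coverage_only():
    s = count_occurrences([seg("AXA")])
    assert s.coverage.tolist() == [1, 1, 1]
    assert s.counts.sum(axis=0).tolist() == [1, 0, 1]
    with pytest.raises(ValueError, match="nonstandard"):
        count_occurrences([seg("AXA")], strict=True)


def test_worked_example_eq1_eq2():
    """91 E at +12 and 22 E at -12 among 1705 full-coverage sequences with
    615 E total give p = 0.053 / 0.013 and q (as a fraction) = 0.148 / 0.036."""
    segments = []
    for i in range(1705):
        core = ["L"] * 25  # positions -12..+12, center index 12
        if i < 91:
            core[24] = "E"  # position +12
        if i < 22:
            core[0] = "E"  # position -12
        if i < 502:
            core[12] = "E"  # position 0; total E = 91 + 22 + 502 = 615
        segments.append(seg("".join(core), accession=f"S{i}"))
    s = count_occurrences(segments)
    assert s.total_counts()["E"] == 615
    p = absolute_relative_occurrence(s, "E")
    q = relative_percentage(s, "E")
    assert round(p.value_at(12), 3) == 0.053
    assert round(p.value_at(-12), 3) == 0.013
    assert round(q.value_at(12) / 100.0, 3) == 0.148
    assert round(q.value_at(-12) / 100.0, 3) == 0.036


def test_relative_percentage_sums_to_100():
    rng = np.random.default_rng(7)
    segments = [
        seg("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=21)),
            inside="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(0, 10)))),
            accession=f"S{i}")
        for i in range(40)
    ]
    s = count_occurrences(segments)
    for aa, total in s.total_counts().items():
        if total == 0:
            with pytest.raises(UndefinedProfileError):
                relative_percentage(s, aa)
            continue
        q = relative_percentage(s, aa)
        assert q.values.sum() == pytest.approx(100.0)


def test_absolute_relative_occurrence_denominator_is_max_column():
    s = count_occurrences([seg("AAA"), seg("AAAAA")])
    p = absolute_relative_occurrence(s, "A")
    # max column total is 2; the edge columns hold 1 occurrence
    assert p.value_at(-2) == pytest.approx(0.5)
    assert p.value_at(0) == pytest.approx(1.0)


def test_background_and_flank_average_windows():
    # Constant-valued profile: background equals the constant; a profile too
    # narrow for the distal windows raises.
    segments = [seg("L" * 25, inside="E" * 20, outside="E" * 20)]
    s = count_occurrences(segments)
    q = relative_percentage(s, "E")
    assert background_level(q) == pytest.approx(q.value_at(30))
    inside_avg, outside_avg = flank_average(q)
    assert inside_avg == pytest.approx(np.mean([q.value_at(p) for p in range(-20, -9)]))
    assert outside_avg == pytest.approx(np.mean([q.value_at(p) for p in range(10, 21)]))
    narrow = count_occurrences([seg("L" * 25)])
    with pytest.raises(UndefinedProfileError):
        background_level(relative_percentage(narrow, "L"))


def test_net_charge_sign_flip_under_conjugation():
    """Swapping K<->D and R<->E in every segment negates the profile."""
    segments = [seg("KLRDELKKA", inside="KK", outside="DE")]
    swapped = [
        seg(
            s0.core.translate(str.maketrans("KRDE", "DEKR")),
            inside=s0.inside_flank.translate(str.maketrans("KRDE", "DEKR")),
            outside=s0.outside_flank.translate(str.maketrans("KRDE", "DEKR")),
        )
        for s0 in segments
    ]
    c1 = net_charge_profile(count_occurrences(segments))
    c2 = net_charge_profile(count_occurrences(swapped))
    assert np.allclose(c1.values, -c2.values)


def test_net_charge_known_value():
    s = count_occurrences([seg("KKK"), seg("KDE")])
    c = net_charge_profile(s)
    # position -1: K,K -> +2/2 ; 0: K,D -> 0/2 ; +1: K,E -> 0/2
    assert c.values.tolist() == [1.0, 0.0, 0.0]


# ---------------------------------------------------------------------------
# hydrophobicity
# ---------------------------------------------------------------------------

def test_windowed_hydropathy_homopolymer_is_constant():
    kd = get_scale("kyte_doolittle")
    vals = windowed_hydropathy("L" * 9, kd, window=3)
    assert np.allclose(vals, kd["L"])


def test_windowed_hydropathy_window_one_is_identity():
    kd = get_scale("kyte_doolittle")
    seq = "ACDEFGHIKLMNPQRSTVWY"
    vals = windowed_hydropathy(seq, kd, window=1)
    assert np.allclose(vals, [kd[a] for a in seq])


def test_windowed_hydropathy_brute_force_oracle():
    kd = get_scale("kyte_doolittle")
    seq = "MKTLLVAGGDDWYPRS"
    for window in (3, 5, 7):
        got = windowed_hydropathy(seq, kd, window=window)
        half = window // 2
        for i in range(len(seq)):
            lo, hi = max(0, i - half), min(len(seq), i + half + 1)
            expected = np.mean([kd[a] for a in seq[lo:hi]])
            assert got[i] == pytest.approx(expected)


def test_windowed_hydropathy_unknown_residue_excluded():
    kd = get_scale("kyte_doolittle")
    vals = windowed_hydropathy("AXA", kd, window=3)
    assert vals[1] == pytest.approx(kd["A"])  # X dropped from the window
    with pytest.raises(ValueError):
        windowed_hydropathy("AXA", kd, window=3, strict=True)


def test_hydrophobicity_profile_spans_flanks():
    kd = get_scale("kyte_doolittle")
    prof = hydrophobicity_profile([seg("L" * 21, inside="K" * 5, outside="D" * 5)], kd)
    assert prof.positions.min() == -15 and prof.positions.max() == 15
    # deep-core positions are pure leucine windows
    assert prof.mean[list(prof.positions).index(0)] == pytest.approx(kd["L"])


def test_residue_percentage_arithmetic():
    assert round(residue_percentage(582, 47568), 2) == 1.22
    assert round(residue_percentage(520, 47568), 2) == 1.09
    assert round(residue_percentage(560, 53238), 2) == 1.05


@settings(max_examples=20, deadline=None)
@given(st.lists(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
                min_size=1, max_size=10))
def test_column_sums_never_exceed_coverage(cores):
    s = count_occurrences([seg(c, accession=f"S{i}") for i, c in enumerate(cores)])
    s.validate()
    assert (s.counts.sum(axis=0) == s.coverage).all()  # no nonstandard letters
    assert s.coverage.max() <= len(cores)
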