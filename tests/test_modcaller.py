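"""Event classification: terminal windows, internal calls, profiles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmod.aligner import place_read
from mirmod.modcaller import (
    INTERNAL,
    MOD3P,
    MOD5P,
    EventCaller,
    ModEvent,
    assign_events,
    build_profiles,
    classify_internal,
)
from tests.conftest import OTHER, different_base


def _events_for(read, ref, db, sample="s1", depth=1, weight=1.0):
    placements = place_read(read, ref)
    assert placements, "probe read failed to place"
    return assign_events(placements[0], weight, ref, db, sample, depth)


def _mature(toy_ref):
    return toy_ref.matures["toy-miR-1-5p"][0]


def test_nontemplated_double_tail_is_one_mod3p_event_at_plus1(toy_ref, toy_db):
    hp = toy_ref.hairpins["toy-mir-1"]
    mat = _mature(toy_ref)
    tail = different_base(hp[40], hp[41]) * 2
    (e,) = _events_for(mat + tail, toy_ref, toy_db, depth=7)
    assert (e.mod_class, e.pattern, e.offset, e.depth) == (MOD3P, tail, 1, 7.0)
    assert e.ref_base == ""  # pure tail


def test_internal_edit_eleven_nt_upstream_of_3p_end(toy_ref, toy_db):
    # 23-nt mature: index 22 is the 3' end, index 11 lies 11 nt upstream
    mat = _mature(toy_ref)
    assert mat[11] == "A"
    read = mat[:11] + "G" + mat[12:]
    (e,) = _events_for(read, toy_ref, toy_db)
    assert (e.mod_class, e.index, e.pattern, e.ref_base) == (INTERNAL, 11, "G", "A")


def test_templated_extension_generates_no_event(toy_ref, toy_db):
    hp = toy_ref.hairpins["toy-mir-1"]
    mat = _mature(toy_ref)
    assert _events_for(mat + hp[40], toy_ref, toy_db) == []


def test_nontemplated_base_seven_nt_downstream_is_not_mod3p(toy_ref, toy_db):
    hp = toy_ref.hairpins["toy-mir-1"]
    mat = _mature(toy_ref)
    read = mat + hp[40:46] + different_base(hp[46])
    events = _events_for(read, toy_ref, toy_db)
    assert all(e.mod_class != MOD3P for e in events)


def _sweep_3p(toy_ref, toy_db, offset):
    """Read with exactly one non-templated base at `offset` about the 3' end."""
    hp = toy_ref.hairpins["toy-mir-1"]
    mat = _mature(toy_ref)
    if offset >= 1:
        probe = different_base(hp[40 + offset - 1])
        read = mat + hp[40 : 40 + offset - 1] + probe
    else:
        idx = 22 + offset
        read = mat[:idx] + different_base(mat[idx]) + mat[idx + 1 :]
    return _events_for(read, toy_ref, toy_db)


def _sweep_5p(toy_ref, toy_db, offset):
    hp = toy_ref.hairpins["toy-mir-1"]
    mat = _mature(toy_ref)
    if offset <= -1:
        upstream = hp[17 + offset : 17]
        probe = different_base(upstream[0])
        read = probe + upstream[1:] + mat
    else:
        read = mat[:offset] + different_base(mat[offset]) + mat[offset + 1 :]
    return _events_for(read, toy_ref, toy_db)


def test_3p_window_sweep_covers_exactly_minus5_to_plus6(toy_ref, toy_db):
    hits = {
        off
        for off in range(-10, 11)
        for e in _sweep_3p(toy_ref, toy_db, off)
        if e.mod_class == MOD3P
    }
    assert hits == set(range(-5, 7))


def test_5p_window_sweep_covers_exactly_minus8_to_plus5(toy_ref, toy_db):
    hits = {
        off
        for off in range(-10, 11)
        for e in _sweep_5p(toy_ref, toy_db, off)
        if e.mod_class == MOD5P
    }
    assert hits == set(range(-8, 6))


def test_substitution_in_3p_window_absorbed_with_ref_base(toy_ref, toy_db):
    (e,) = _sweep_3p(toy_ref, toy_db, -3)
    mat = _mature(toy_ref)
    assert e.mod_class == MOD3P and e.offset == -3
    assert e.ref_base == mat[19]


def test_insufficient_mature_overlap_yields_no_events(toy_ref, toy_db):
    hp = toy_ref.hairpins["toy-mir-1"]
    read = hp[0:17]  # flank-only: zero overlap with the mature
    placements = place_read(read, toy_ref)
    assert placements
    assert assign_events(placements[0], 1.0, toy_ref, toy_db, "s1") == []
    caller = EventCaller(toy_ref, toy_db)
    assert caller.process(placements[0], 1.0, "s1", 4) is None
    assert caller.unattributed_depth == 4.0


@pytest.mark.parametrize(
    "modified,total,ref,alt,label",
    [
        (70, 100, "C", "T", "SNP"),  # boundary ratio 0.70 is inclusive
        (69, 100, "C", "T", "other_internal"),
        (30, 100, "A", "G", "ADAR_edit"),
        (30, 100, "C", "A", "other_internal"),
        (80, 100, "A", "G", "SNP"),  # high-ratio A->G is a SNP, not an edit
    ],
)
def test_internal_classification_rules(modified, total, ref, alt, label):
    events = [ModEvent("m1", "s1", INTERNAL, alt, ref, 9, 9, float(modified))]
    coverage = {("m1", 9): float(total)}
    (call,) = classify_internal(events, coverage)
    assert call.label == label
    assert call.ratio == pytest.approx(modified / total)


def test_internal_depths_pool_across_samples():
    events = [
        ModEvent("m1", "s1", INTERNAL, "T", "C", 9, 9, 40.0),
        ModEvent("m1", "s2", INTERNAL, "T", "C", 9, 9, 30.0),
    ]
    (call,) = classify_internal(events, {("m1", 9): 100.0})
    assert call.modified_depth == 70.0 and call.label == "SNP"


def test_zero_coverage_at_event_position_is_an_error():
    events = [ModEvent("m1", "s1", INTERNAL, "T", "C", 9, 9, 1.0)]
    with pytest.raises(ValueError, match="coverage"):
        classify_internal(events, {})


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    modified=st.integers(min_value=1, max_value=100),
    thr_lo=st.floats(min_value=0.05, max_value=0.95),
    thr_hi=st.floats(min_value=0.05, max_value=0.95),
)
def test_raising_threshold_never_creates_a_snp(modified, thr_lo, thr_hi):
    thr_lo, thr_hi = min(thr_lo, thr_hi), max(thr_lo, thr_hi)
    events = [ModEvent("m1", "s1", INTERNAL, "T", "C", 3, 3, float(modified))]
    coverage = {("m1", 3): 100.0}
    (lo,) = classify_internal(events, coverage, snp_threshold=thr_lo)
    (hi,) = classify_internal(events, coverage, snp_threshold=thr_hi)
    assert not (lo.label != "SNP" and hi.label == "SNP")


def test_profile_conservation_and_per_sample_symmetry():
    ev = [
        ModEvent("m1", "s1", MOD3P, "T", "", 23, 1, 5.0),
        ModEvent("m1", "s2", MOD3P, "T", "", 23, 1, 5.0),
        ModEvent("m2", "s1", MOD5P, "A", "", -1, -1, 2.0),
        ModEvent("m2", "s2", MOD5P, "A", "", -1, -1, 2.0),
    ]
    profile = build_profiles(ev, ["s1", "s2"], matures=["m1", "m2"])
    glob = profile.table(None)
    assert glob.to_numpy().sum() == profile.total_depth == 14.0
    assert (glob["s1"] == glob["s2"]).all()
    t3 = profile.table(MOD3P)
    assert t3.loc[("T", 1), "s1"] == 5.0
    # per-miRNA slices partition the global totals
    split = sum(
        profile.for_mirna(m).table(None).to_numpy().sum() for m in ("m1", "m2")
    )
    assert split == profile.total_depth


def test_profile_for_unknown_mirna_raises():
    profile = build_profiles([], ["s1"], matures=["m1"])
    with pytest.raises(KeyError, match="m9"):
        profile.for_mirna("m9")
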