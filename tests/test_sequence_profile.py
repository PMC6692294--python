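import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprekit.coil_ensemble import FragmentLibrary
from sprekit.sequence_profile import (
    SPREProfile,
    ZIMMERMAN_BULKINESS,
    bulkiness_profile,
    compare_and_flag,
    enumerate_windows,
    normalize_prediction,
    predict_profile,
)

CANONICAL = "".join(sorted(ZIMMERMAN_BULKINESS))


def make_profile(sequence, values, errors=None, role="HA", first=1):
    errors = errors if errors is not None else [0.0] * len(values)
    rows = [
        {"residue_index": first + i, "role": role, "value": v, "error": e}
        for i, (v, e) in enumerate(zip(values, errors))
    ]
    return SPREProfile(sequence=sequence, data=pd.DataFrame(rows))


# --- windows -----------------------------------------------------------------

def test_enumerate_windows_eleven_mer():
    wins = enumerate_windows("AAAVVAVVAAA")
    assert len(wins) == 7
    assert wins[0] == (3, "AAAVV")
    assert wins[-1] == (9, "VVAAA")
    centers = [c for c, _ in wins]
    for terminal in (1, 2, 10, 11):
        assert terminal not in centers


def test_enumerate_windows_minimum_length():
    assert enumerate_windows("AAGAA") == [(3, "AAGAA")]
    with pytest.raises(ValueError, match="at least 5"):
        enumerate_windows("AAGA")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.text(alphabet=CANONICAL, min_size=5, max_size=30))
def test_enumerate_windows_combinatorics(seq):
    wins = enumerate_windows(seq)
    assert len(wins) == len(seq) - 4
    for center, core in wins:
        assert core == seq[center - 3:center + 2]
        assert 3 <= center <= len(seq) - 2


# --- prediction --------------------------------------------------------------

def test_polyalanine_profile_is_flat():
    lib = FragmentLibrary()
    prof = predict_profile("A" * 20, lib, n=3, seed=2, roles=("CA",))
    assert list(prof.defined_residues("CA")) == list(range(3, 19))
    vals = prof.role_series("CA")["value"]
    assert vals.nunique() == 1
    assert len(lib) == 1  # one fragment record serves every window


def test_profile_depends_only_on_window():
    lib = FragmentLibrary()
    a = predict_profile("AAAAAGGGGG", lib, n=3, seed=2, roles=("CA",))
    b = predict_profile("AAAAAGGGGW", lib, n=3, seed=2, roles=("CA",))
    # residue 5's window (3..7) is identical in both sequences
    assert (
        a.role_series("CA").loc[5, "value"] == b.role_series("CA").loc[5, "value"]
    )


def test_profile_deterministic():
    a = predict_profile("AAGAAGG", FragmentLibrary(), n=3, seed=9, roles=("CA",))
    b = predict_profile("AAGAAGG", FragmentLibrary(), n=3, seed=9, roles=("CA",))
    pd.testing.assert_frame_equal(a.data, b.data)


def test_profile_tsv_round_trip(tmp_path):
    prof = make_profile("AAGAAGG", [1.0, 2.0, 3.0], [0.1, 0.2, 0.3], first=3)
    p = tmp_path / "prof.tsv"
    prof.to_tsv(p)
    back = SPREProfile.from_tsv(p, "AAGAAGG")
    pd.testing.assert_frame_equal(prof.data, back.data, check_dtype=False)


# --- normalization -----------------------------------------------------------

def test_normalize_identity():
    prof = make_profile("AAGAAGG", [1.0, 2.0, 3.0, 4.0], first=2)
    res = normalize_prediction(prof, prof, "HA")
    assert res.slope == pytest.approx(1.0, abs=1e-12)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    pd.testing.assert_frame_equal(res.normalized.data, prof.data)


def test_normalize_exact_linear_recovery():
    pred = make_profile("AAGAAGG", [1.0, 2.0, 3.0, 5.0], first=2)
    exp = make_profile("AAGAAGG", [0.5 * v - 1.5 for v in [1.0, 2.0, 3.0, 5.0]], first=2)
    res = normalize_prediction(pred, exp, "HA")
    assert res.slope == pytest.approx(0.5, rel=1e-12)
    assert res.intercept == pytest.approx(-1.5, rel=1e-12)
    np.testing.assert_allclose(
        res.normalized.role_series("HA")["value"],
        exp.role_series("HA")["value"],
        rtol=1e-12, atol=1e-12,
    )


def test_normalize_idempotent():
    rng = np.random.default_rng(3)
    vals = rng.uniform(1, 5, 8)
    pred = make_profile("AAGAAGGAAG", list(vals), first=2)
    exp = make_profile("AAGAAGGAAG", list(2.0 * vals + 1.0 + rng.normal(0, 0.1, 8)), first=2)
    once = normalize_prediction(pred, exp, "HA")
    twice = normalize_prediction(once.normalized, exp, "HA")
    assert twice.slope == pytest.approx(1.0, rel=1e-9)
    assert twice.intercept == pytest.approx(0.0, abs=1e-9)


def test_normalize_degenerate_inputs():
    pred = make_profile("AAGAAGG", [2.0, 2.0, 2.0, 2.0], first=2)
    exp = make_profile("AAGAAGG", [1.0, 2.0, 3.0, 4.0], first=2)
    with pytest.raises(ValueError, match="constant"):
        normalize_prediction(pred, exp, "HA")
    small_p = make_profile("AAGAAGG", [1.0, 2.0], first=2)
    small_e = make_profile("AAGAAGG", [1.0, 2.0], first=2)
    with pytest.raises(ValueError, match=">= 3"):
        normalize_prediction(small_p, small_e, "HA")


def test_normalize_sequence_mismatch():
    a = make_profile("AAGAA", [1.0, 2.0, 3.0])
    b = make_profile("AAGAG", [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="different sequences"):
        normalize_prediction(a, b, "HA")


# --- flagging ----------------------------------------------------------------

def test_compare_and_flag_no_deviation():
    seq = "A" * 12
    vals = list(np.linspace(1, 4, 10))
    norm = make_profile(seq, vals, first=2)
    exp = make_profile(seq, vals, [0.1] * 10, first=2)
    report = compare_and_flag(norm, exp, "HA")
    assert report.regions == []
    assert np.allclose(report.deviations, 0.0)


def test_compare_and_flag_recovers_implanted_region():
    seq = "A" * 80
    rng = np.random.default_rng(8)
    base = 5.0 + rng.uniform(-0.5, 0.5, 76)
    exp_vals = base.copy()
    exp_vals[51:57] -= 5 * 0.2  # residues 52..57 depressed by 5 error-units
    norm = make_profile(seq, list(base), first=1)
    exp = make_profile(seq, list(exp_vals), [0.2] * 76, first=1)
    report = compare_and_flag(norm, exp, "HA", z_threshold=1.96, min_run=3)
    assert report.regions == [(52, 57, "buried")]


def test_compare_and_flag_min_run_suppresses_singletons():
    seq = "A" * 12
    vals = np.full(10, 5.0)
    exp_vals = vals.copy()
    exp_vals[4] -= 3.0  # single residue deviation
    norm = make_profile(seq, list(vals), first=2)
    exp = make_profile(seq, list(exp_vals), [0.5] * 10, first=2)
    report = compare_and_flag(norm, exp, "HA", min_run=3)
    assert report.regions == []
    assert report.deviations.loc[6] == pytest.approx(6.0)


def test_compare_and_flag_exposed_direction_and_hn_note():
    seq = "A" * 12
    vals = np.full(10, 5.0)
    exp_vals = vals.copy()
    exp_vals[3:7] += 2.0  # more accessible than predicted
    norm = make_profile(seq, list(vals), role="HN", first=2)
    exp = make_profile(seq, list(exp_vals), [0.5] * 10, role="HN", first=2)
    report = compare_and_flag(norm, exp, "HN", min_run=3)
    assert report.regions == [(5, 8, "exposed")]
    assert any("exchange" in note for note in report.notes)


def test_compare_and_flag_zero_errors_rejected():
    seq = "A" * 8
    norm = make_profile(seq, [1.0, 2.0, 3.0], first=2)
    exp = make_profile(seq, [1.0, 2.0, 3.0], [0.0, 0.0, 0.0], first=2)
    with pytest.raises(ValueError, match="zero"):
        compare_and_flag(norm, exp, "HA")


# --- bulkiness ---------------------------------------------------------------

def test_bulkiness_scale_and_window():
    polyg = bulkiness_profile("G" * 6, window=1)
    np.testing.assert_allclose(polyg, 3.40)
    assert ZIMMERMAN_BULKINESS["W"] > ZIMMERMAN_BULKINESS["G"]
    const = bulkiness_profile("V" * 9, window=5)
    np.testing.assert_allclose(const, ZIMMERMAN_BULKINESS["V"])
    with pytest.raises(ValueError, match="odd"):
        bulkiness_profile("GAV", window=2)
    with pytest.raises(ValueError, match="noncanonical"):
        bulkiness_profile("GXV")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.text(alphabet=CANONICAL, min_size=1, max_size=25),
       st.sampled_from([1, 3, 5]))
def test_bulkiness_bounded_by_scale_extremes(seq, window):
    prof = bulkiness_profile(seq, window)
    lo, hi = min(ZIMMERMAN_BULKINESS.values()), max(ZIMMERMAN_BULKINESS.values())
    assert np.all(prof >= lo - 1e-12) and np.all(prof <= hi + 1e-12)
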