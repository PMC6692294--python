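import numpy as np
import pandas as pd
import pytest

from sprekit.relaxation_pipeline import (
    NoiseEstimate,
    RecoveryCurve,
    estimate_duplicate_noise,
    fit_recovery,
    fit_spre_slope,
    mc_resample_r1_error,
    run_titration,
)
from sprekit.synthetic_data import TitrationTruth, simulate_recovery_dataset

DELAYS = np.geomspace(0.03, 3.0, 10)


def curve_from_model(r1, a=2.0, c=1.0, delays=DELAYS, noise=0.0, rng=None, conc=0.0):
    y = -a * np.exp(-r1 * delays) + c
    if noise:
        y = y + rng.normal(0, noise, size=delays.shape)
    return RecoveryCurve("p1", 1, "HA", conc, delays, y)


# --- mono-exponential fit ----------------------------------------------------

def test_noiseless_fit_exact():
    est = fit_recovery(curve_from_model(1.2, a=2.0, c=1.0))
    assert est.converged
    assert est.r1 == pytest.approx(1.2, rel=1e-6)
    assert est.amplitude == pytest.approx(2.0, rel=1e-6)
    assert est.plateau == pytest.approx(1.0, rel=1e-6)


def test_constant_intensities_not_converged():
    cv = RecoveryCurve("p1", 1, "HA", 0.0, DELAYS, np.ones_like(DELAYS))
    est = fit_recovery(cv)
    assert not est.converged


def test_too_few_delays_rejected():
    cv = RecoveryCurve("p1", 1, "HA", 0.0, np.array([0.1, 0.1, 0.2]),
                       np.array([0.5, 0.5, 0.8]))
    with pytest.raises(ValueError, match="3 distinct"):
        fit_recovery(cv)


def test_noisy_fit_median_accuracy():
    """Median fitted rate over repeated 1%-noise simulations stays within 2%."""
    rng = np.random.default_rng(12)
    rates = []
    for _ in range(200):
        est = fit_recovery(curve_from_model(1.2, noise=0.01, rng=rng))
        assert est.converged
        rates.append(est.r1)
    assert np.median(rates) == pytest.approx(1.2, rel=0.02)


def test_intensity_scale_equivariance():
    cv = curve_from_model(0.8)
    scaled = RecoveryCurve("p1", 1, "HA", 0.0, cv.delays, 100.0 * cv.intensities)
    assert fit_recovery(scaled).r1 == pytest.approx(fit_recovery(cv).r1, rel=1e-6)


# --- duplicate noise ---------------------------------------------------------

def make_dup_curve(delta, rng=None, sd=None, n_extra=0):
    delays = np.concatenate([DELAYS, [DELAYS[4]]])
    y = -2.0 * np.exp(-1.0 * delays) + 1.0
    if sd is not None:
        y = y + rng.normal(0, sd, size=delays.shape)
    else:
        y[-1] += delta
    return RecoveryCurve("p", 1, "HA", 0.0, delays, y, duplicate_pairs=((4, 10),))


def test_identical_duplicates_zero_noise():
    assert estimate_duplicate_noise([make_dup_curve(0.0)]).epsilon == 0.0


def test_single_pair_formula():
    delta = 0.42
    est = estimate_duplicate_noise([make_dup_curve(delta)])
    assert est.epsilon == pytest.approx(delta / np.sqrt(2), rel=1e-12)
    assert est.n_pairs == 1


def test_duplicate_noise_estimator_consistency():
    rng = np.random.default_rng(5)
    sigma = 0.05
    curves = [make_dup_curve(0.0, rng=rng, sd=sigma) for _ in range(1000)]
    est = estimate_duplicate_noise(curves)
    assert est.n_pairs == 1000
    assert est.epsilon == pytest.approx(sigma, rel=0.05)


def test_literal_unsquared_variant_differs():
    curves = [make_dup_curve(0.42)]
    sq = estimate_duplicate_noise(curves, squared=True)
    lit = estimate_duplicate_noise(curves, squared=False)
    assert lit.epsilon == pytest.approx(np.sqrt(0.42 / 2), rel=1e-12)
    assert lit.epsilon != sq.epsilon


def test_no_duplicates_rejected():
    cv = curve_from_model(1.0)
    with pytest.raises(ValueError, match="no duplicate"):
        estimate_duplicate_noise([cv])


# --- Monte-Carlo R1 error ----------------------------------------------------

def test_mc_error_zero_noise_is_zero():
    cv = curve_from_model(1.0)
    base = fit_recovery(cv)
    sig = mc_resample_r1_error(cv, base, NoiseEstimate(0.0, 1), seed=1)
    assert sig == 0.0


def test_mc_error_deterministic_and_scales_with_noise():
    cv = curve_from_model(1.0)
    base = fit_recovery(cv)
    s1 = mc_resample_r1_error(cv, base, NoiseEstimate(0.01, 10), n_resamples=500, seed=9)
    s1b = mc_resample_r1_error(cv, base, NoiseEstimate(0.01, 10), n_resamples=500, seed=9)
    s2 = mc_resample_r1_error(cv, base, NoiseEstimate(0.02, 10), n_resamples=500, seed=9)
    assert s1 == s1b
    assert s2 / s1 == pytest.approx(2.0, rel=0.2)


def test_mc_error_requires_converged_base():
    cv = curve_from_model(1.0)
    bad = fit_recovery(RecoveryCurve("p", 1, "HA", 0.0, DELAYS, np.ones_like(DELAYS)))
    with pytest.raises(ValueError, match="converge"):
        mc_resample_r1_error(cv, bad, NoiseEstimate(0.01, 1))


# --- weighted slope ----------------------------------------------------------

def test_exact_line_recovery():
    concs = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
    pts = [(c, 0.5 + 2.0 * c, 0.05) for c in concs]
    fit = fit_spre_slope(pts)
    assert fit.spre == pytest.approx(2.0, rel=1e-12)
    assert fit.r1_0 == pytest.approx(0.5, rel=1e-12)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-18)
    assert fit.n_points == 6


def test_equal_weights_match_ols():
    rng = np.random.default_rng(2)
    c = np.arange(6.0)
    r = 0.7 + 1.3 * c + rng.normal(0, 0.05, 6)
    wls = fit_spre_slope([(ci, ri, 0.04) for ci, ri in zip(c, r)])
    slope, intercept = np.polyfit(c, r, 1)
    assert wls.spre == pytest.approx(slope, rel=1e-10)
    assert wls.r1_0 == pytest.approx(intercept, rel=1e-10)


def test_weighting_pulls_toward_precise_points():
    pts_eq = [(0.0, 1.0, 1.0), (1.0, 2.0, 1.0), (2.0, 4.0, 1.0)]
    pts_wt = [(0.0, 1.0, 0.01), (1.0, 2.0, 0.01), (2.0, 4.0, 10.0)]
    assert fit_spre_slope(pts_wt).spre == pytest.approx(1.0, abs=0.01)
    assert fit_spre_slope(pts_eq).spre == pytest.approx(1.5, abs=1e-9)


def test_slope_input_validation():
    with pytest.raises(ValueError, match="at least 2"):
        fit_spre_slope([(0.0, 1.0, 0.1)])
    with pytest.raises(ValueError, match="distinct"):
        fit_spre_slope([(1.0, 1.0, 0.1), (1.0, 1.2, 0.1)])
    with pytest.raises(ValueError, match="> 0"):
        fit_spre_slope([(0.0, 1.0, 0.0), (1.0, 2.0, 0.1)])


# --- full pipeline -----------------------------------------------------------

def test_zero_noise_round_trip_exact():
    truth = TitrationTruth.random(4, seed=6, noise_sd=0.0)
    prof = run_titration(simulate_recovery_dataset(truth), n_resamples=5, seed=1)
    got = prof.role_series("HA")
    for res, (_, spre) in truth.residues.items():
        assert got.loc[res, "value"] == pytest.approx(spre, rel=1e-6)


def test_schema_error():
    truth = TitrationTruth.random(2, seed=1)
    table = simulate_recovery_dataset(truth).drop(columns=["conc_mM"])
    with pytest.raises(ValueError, match="conc_mM"):
        run_titration(table)


def test_single_concentration_peak_excluded(caplog):
    truth = TitrationTruth.random(3, seed=2, noise_sd=0.005)
    table = simulate_recovery_dataset(truth)
    # strip residue 2 down to one concentration
    table = table[~((table.residue_index == 2) & (table.conc_mM > 0))]
    with caplog.at_level("WARNING", logger="sprekit.relaxation_pipeline"):
        prof = run_titration(table, n_resamples=20, seed=3)
    assert 2 not in prof.defined_residues("HA")
    assert {1, 3} <= set(prof.defined_residues("HA"))
    assert any("excluded" in rec.message for rec in caplog.records)
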