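"""Sigmoid fitting, goodness of fit, ECx inversion, bands, NOEC/LOEC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raymix.design import concentration_series
from raymix.errors import DegenerateDataError
from raymix.fitting import (
    FittedCRC,
    confidence_bands,
    ecx,
    fit_crc,
    goodness_of_fit,
    model_effect,
    noec_loec,
    select_best,
)

from conftest import crc_with_ec50, make_table


# --------------------------------------------------------------------------
# model evaluation and closed-form inversion
# --------------------------------------------------------------------------


def test_model_midpoints_closed_form():
    alpha, beta = -3.2, 1.7
    assert model_effect("Logit", alpha, beta, -alpha / beta) == pytest.approx(0.5)
    x_w = (math.log(math.log(2.0)) - alpha) / beta
    assert model_effect("Weibull", alpha, beta, x_w) == pytest.approx(0.5)


def test_published_mixture_curve_half_effect_at_its_ec50():
    """The verbatim g/L Logit curve of the environmental 1:10 ray reaches
    half effect at its published EC50 (2045.35 µg/L = 2.04535e-3 g/L)."""
    crc = FittedCRC("Logit", alpha=7.4461, beta=2.7688, conc_scale="gL")
    assert crc.effect_at(2045.35) == pytest.approx(0.5, abs=2e-4)


@settings(derandomize=True, max_examples=200)
@given(
    model=st.sampled_from(["Logit", "Weibull"]),
    alpha=st.floats(-15, 15),
    beta=st.floats(0.2, 10),
    sign=st.sampled_from([1, -1]),
    scale=st.sampled_from(["ugL", "gL"]),
    x=st.floats(0.01, 0.99),
)
def test_ecx_effect_round_trip(model, alpha, beta, sign, scale, x):
    crc = FittedCRC(model, alpha=alpha, beta=beta, conc_scale=scale, alpha_sign=sign)
    c = ecx(crc, x)
    assert crc.effect_at(c) == pytest.approx(x, abs=1e-9)


def test_ecx_rejects_effect_levels_outside_unit_interval(as_published):
    for bad in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            ecx(as_published, bad)


def test_conc_scale_conversion_preserves_the_curve():
    crc = FittedCRC("Logit", alpha=7.4461, beta=2.7688, conc_scale="gL")
    back = crc.with_conc_scale("ugL")
    conc = np.logspace(1, 5, 7)
    np.testing.assert_allclose(back.effect_at(conc), crc.effect_at(conc), rtol=1e-12)
    assert ecx(back, 0.5) == pytest.approx(ecx(crc, 0.5), rel=1e-12)


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------


def test_goodness_of_fit_perfect_and_hand_example():
    r2, rmse = goodness_of_fit([0.1, 0.5, 0.9], [0.1, 0.5, 0.9], 2)
    assert (r2, rmse) == (1.0, 0.0)

    # hand arithmetic: SS_res = 0.02, SS_tot = 0.5, n = 3, m = 2
    r2, rmse = goodness_of_fit([0.0, 0.5, 1.0], [0.1, 0.5, 0.9], 2)
    assert r2 == pytest.approx(1.0 - (2 * 0.02) / (1 * 0.5), abs=1e-15)
    assert rmse == pytest.approx(math.sqrt(0.02 / 3.0), abs=1e-15)

    with pytest.raises(DegenerateDataError):
        goodness_of_fit([0.3, 0.3, 0.3], [0.1, 0.2, 0.3], 2)


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 10_000), st.integers(4, 20), st.integers(1, 3))
def test_goodness_of_fit_matches_brute_force(seed, n, m):
    """Independent elementwise-loop oracle of the two statistics."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 1, n)
    yhat = rng.uniform(0, 1, n)
    ybar = sum(y) / n
    ss_res = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    exp_r2 = 1 - ((n - 1) * ss_res) / ((n - m) * ss_tot)
    exp_rmse = math.sqrt(ss_res / n)
    r2, rmse = goodness_of_fit(y, yhat, m)
    assert r2 == pytest.approx(exp_r2, abs=1e-12)
    assert rmse == pytest.approx(exp_rmse, abs=1e-12)


def test_select_best_prefers_r2_then_rmse_then_logit():
    logit = FittedCRC("Logit", 1, 1, r2_adj=0.9963, rmse=0.024)
    weib = FittedCRC("Weibull", 1, 1, r2_adj=0.990, rmse=0.020)
    assert select_best([weib, logit]).model == "Logit"
    assert select_best([weib]) is weib

    tie_a = FittedCRC("Weibull", 1, 1, r2_adj=0.99, rmse=0.020)
    tie_b = FittedCRC("Logit", 1, 1, r2_adj=0.99, rmse=0.021)
    assert select_best([tie_a, tie_b]).model == "Weibull"  # smaller rmse wins

    exact_a = FittedCRC("Weibull", 1, 1, r2_adj=0.99, rmse=0.02)
    exact_b = FittedCRC("Logit", 2, 2, r2_adj=0.99, rmse=0.02)
    assert select_best([exact_a, exact_b]).model == "Logit"  # declared order

    from raymix.errors import NoFitError

    with pytest.raises(NoFitError):
        select_best([])


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@pytest.mark.parametrize("model", ["Logit", "Weibull"])
def test_fit_recovers_noiseless_truth(model):
    series = concentration_series(1e5, 1.0, 12)
    conc = np.array(series.concentrations)
    alpha, beta = -6.0, 2.5
    effects = model_effect(model, alpha, beta, np.log10(conc))
    table = make_table(conc, [[e] for e in effects])
    fit = fit_crc(table, model)
    assert fit.alpha == pytest.approx(alpha, abs=1e-6)
    assert fit.beta == pytest.approx(beta, abs=1e-6)
    assert fit.rmse == pytest.approx(0.0, abs=1e-9)
    assert fit.r2_adj == pytest.approx(1.0, abs=1e-9)


def test_fit_monotone_in_concentration_when_beta_positive():
    series = concentration_series(1e4, 1.0, 12)
    conc = np.array(series.concentrations)
    effects = model_effect("Logit", -5.0, 2.0, np.log10(conc))
    fit = fit_crc(make_table(conc, [[e] for e in effects]), "Logit")
    grid = np.logspace(0, 4, 50)
    vals = fit.effect_at(grid)
    assert np.all(np.diff(vals) > 0)


def test_fit_degenerate_inputs_raise():
    conc = np.array(concentration_series(1e4, 1.0, 12).concentrations)
    with pytest.raises(DegenerateDataError):
        fit_crc(make_table(conc, [[0.0]] * 12), "Logit")
    with pytest.raises(DegenerateDataError):
        fit_crc(make_table(conc[:5], [[0.1], [0.3], [0.5], [0.7], [0.9]]), "Logit")


@pytest.fixture(scope="module")
def repeated_noisy_fits():
    """200 seeded refits of the same Logit truth with OD-scale noise.

    Shared by the Wald-coverage and band-coverage checks below.
    """
    from raymix.effects import build_effect_table
    from raymix.simulate import NoiseModel, simulate_single

    truth = crc_with_ec50(375.0, beta=2.5)
    series = concentration_series(1e4, 1.0, 12)
    # iid effect-scale noise: the Wald covariance assumes independent
    # residuals, which shared control-mean error would violate
    noise = NoiseModel(sigma_od=0.0, sigma_effect=0.02)
    fits = []
    for seed in range(200):
        readings = simulate_single(
            "S", truth, series, noise=noise, rng=seed, replicates=3
        )
        table = build_effect_table(readings)["S"]
        fits.append((fit_crc(table, "Logit"), table))
    return truth, series, fits


def test_wald_intervals_cover_truth(repeated_noisy_fits):
    """Parameter estimates fall inside their own 95% Wald intervals in at
    least 90% of 200 replicated experiments."""
    from scipy import stats

    truth, _, fits = repeated_noisy_fits
    hits = 0
    for fit, _ in fits:
        assert fit.param_covariance is not None
        se = np.sqrt(np.diag(fit.param_covariance))
        tq = stats.t.ppf(0.975, fit.n_obs - fit.n_params)
        ok_a = abs(fit.alpha - truth.alpha) <= tq * se[0]
        ok_b = abs(fit.beta - truth.beta) <= tq * se[1]
        hits += ok_a and ok_b
    assert hits / len(fits) >= 0.90


def test_function_bands_cover_true_curve(repeated_noisy_fits):
    """The 95% delta-method band contains the true curve at ~95% of grid
    points on average (within Monte-Carlo slack)."""
    truth, series, fits = repeated_noisy_fits
    coverage = []
    for fit, table in fits:
        bands = confidence_bands(fit, table, level=0.95, n_grid=25)
        true_vals = truth.effect_at(bands.grid_conc)
        inside = (bands.fci_low <= true_vals) & (true_vals <= bands.fci_high)
        coverage.append(inside.mean())
    assert np.mean(coverage) >= 0.90


def test_parameter_error_shrinks_with_noise():
    """Median parameter error is monotone in the noise level (in expectation)."""
    from raymix.effects import build_effect_table
    from raymix.simulate import NoiseModel, simulate_single

    truth = crc_with_ec50(375.0, beta=2.5)
    series = concentration_series(1e4, 1.0, 12)
    med_err = []
    for sigma in (0.04, 0.01, 0.0):
        errs = []
        for seed in range(30):
            readings = simulate_single(
                "S",
                truth,
                series,
                noise=NoiseModel(sigma_od=sigma),
                rng=seed,
                replicates=3,
            )
            fit = fit_crc(build_effect_table(readings)["S"], "Logit")
            errs.append(abs(fit.alpha - truth.alpha) + abs(fit.beta - truth.beta))
        med_err.append(np.median(errs))
    assert med_err[0] > med_err[1] > med_err[2]
    assert med_err[2] == pytest.approx(0.0, abs=1e-6)


# --------------------------------------------------------------------------
# confidence bands
# --------------------------------------------------------------------------


def test_zero_noise_band_width_vanishes():
    series = concentration_series(1e4, 1.0, 12)
    conc = np.array(series.concentrations)
    effects = model_effect("Logit", -5.0, 2.0, np.log10(conc))
    table = make_table(conc, [[e, e, e] for e in effects])
    fit = fit_crc(table, "Logit")
    bands = confidence_bands(fit, table)
    assert np.all(bands.fci_high - bands.fci_low < 1e-6)
    assert np.all(bands.fci_low <= bands.fitted)
    assert np.all(bands.fitted <= bands.fci_high)


def test_observation_interval_is_a_t_interval():
    """Replicates (0.4, 0.5, 0.6): OCI = 0.5 +/- t(2, 0.975) * 0.1/sqrt(3)."""
    series = concentration_series(1e4, 1.0, 12)
    conc = np.array(series.concentrations)
    effects = [[e, e, e] for e in model_effect("Logit", -5.0, 2.0, np.log10(conc))]
    effects[5] = [0.4, 0.5, 0.6]
    table = make_table(conc, effects)
    fit = fit_crc(table, "Logit")
    bands = confidence_bands(fit, table, level=0.95)
    half = 4.302652729911275 * (0.1 / math.sqrt(3.0))
    j = int(np.argmax(bands.oci_high - bands.oci_low))  # the noisy point
    assert bands.oci_mean[j] == pytest.approx(0.5)
    assert bands.oci_high[j] - bands.oci_mean[j] == pytest.approx(half, rel=1e-9)
    assert bands.oci_mean[j] - bands.oci_low[j] == pytest.approx(half, rel=1e-9)


# --------------------------------------------------------------------------
# NOEC / LOEC
# --------------------------------------------------------------------------


def _steep_table(noise=0.0, reps=3, seed=0, ec50=500.0, beta=3.0):
    """A series whose truth satisfies the design rule E(C_L) <= 1%."""
    series = concentration_series(10000.0, 10.0, 12)
    conc = np.array(series.concentrations)
    truth = crc_with_ec50(ec50, beta=beta)
    rng = np.random.default_rng(seed)
    effects = [
        truth.effect_at(c) + rng.normal(0, noise, reps) for c in conc
    ]
    return conc, make_table(conc, effects)


def test_threshold_rule_recovers_design_endpoints():
    """With a truth meeting the 1%-at-C_L design criterion, the threshold
    rule puts the NOEC at C_L = 10 and the LOEC at the next gradient point
    18.7381 µg/L."""
    _, table = _steep_table()
    noec, loec = noec_loec(table, method="threshold", threshold=0.01)
    assert noec == pytest.approx(10.0)
    assert loec == pytest.approx(18.7381, abs=1e-4)


def test_noec_sentinels():
    conc = np.array(concentration_series(1e4, 10.0, 12).concentrations)
    flat = make_table(conc, [[0.0, 0.0] for _ in conc])
    noec, loec = noec_loec(flat, method="threshold")
    assert noec == pytest.approx(conc.max())
    assert math.isnan(loec)

    hot = make_table(conc, [[0.9, 0.9] for _ in conc])
    noec, loec = noec_loec(hot, method="threshold")
    assert math.isnan(noec)
    assert loec == pytest.approx(conc.min())


def test_dunnett_noec_flags_clear_effects():
    """Many-to-one comparison: strong high-dose effects are significant,
    flat low-dose points are not; the split lands between them."""
    conc, table = _steep_table(noise=0.005, reps=3, seed=1, ec50=1000.0, beta=4.0)
    table.control_effects = np.random.default_rng(2).normal(0, 0.005, 3)
    noec, loec = noec_loec(table, method="dunnett")
    assert loec in conc
    assert noec < loec
    # repeat runs are deterministic
    assert noec_loec(table, method="dunnett") == (noec, loec)
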