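"""Mutual information, Blahut-Arimoto capacity, parameter interpolation and
per-cell estimates, checked against independent oracles."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import chancap as cc
from chancap.noise import scaled_t_logpdf
from tests.conftest import make_two_input_channel


def grid_search_capacity(model, step=0.01):
    """Exhaustive simplex search oracle for 2- and 3-input channels."""
    n = model.n_inputs
    best = 0.0
    if n == 2:
        for a in np.arange(0.0, 1.0 + 1e-12, step):
            best = max(best, cc.mutual_information(model, np.array([a, 1 - a])))
    elif n == 3:
        for a in np.arange(0.0, 1.0 + 1e-12, step):
            for b in np.arange(0.0, 1.0 - a + 1e-12, step):
                best = max(best, cc.mutual_information(model, np.array([a, b, 1 - a - b])))
    else:
        raise ValueError("oracle supports 2 or 3 inputs")
    return best


def test_mi_zero_when_output_independent_of_input():
    model = cc.build_channel(
        np.array([100.0, 1000.0, 10000.0]),
        np.array([1.0, 1.0, 1.0]),
        np.array([0.2, 0.2, 0.2]),
        np.array([4.0, 4.0, 4.0]),
    )
    assert cc.mutual_information(model, np.full(3, 1 / 3)) == pytest.approx(0.0, abs=1e-6)


def test_mi_perfectly_separable_binary_channel_is_one_bit():
    model = make_two_input_channel(delta=100 * 0.2, sigma=0.2, nu=30.0)
    assert cc.mutual_information(model, np.array([0.5, 0.5])) == pytest.approx(1.0, abs=1e-3)


def test_mi_matches_monte_carlo_oracle():
    """Deterministic quadrature vs brute-force Monte-Carlo MI estimate."""
    sigma, nu, delta = 0.2, 200.0, 0.4  # Gaussian-limit noise, 2-sigma separation
    model = make_two_input_channel(delta=delta, sigma=sigma, nu=nu)
    p = np.array([0.5, 0.5])
    quad_mi = cc.mutual_information(model, p)

    rng = np.random.default_rng(123)
    n = 10_000_000
    labels = rng.integers(0, 2, n)
    r = labels * delta + sigma * rng.standard_t(nu, n)
    log_f0 = scaled_t_logpdf(r, sigma, nu)
    log_f1 = scaled_t_logpdf(r - delta, sigma, nu)
    log_cond = np.where(labels == 0, log_f0, log_f1)
    log_marg = np.logaddexp(log_f0 + np.log(0.5), log_f1 + np.log(0.5))
    mc_mi = float(np.mean(log_cond - log_marg) / np.log(2))
    assert quad_mi == pytest.approx(mc_mi, abs=0.005)


def test_ba_symmetric_channel_gives_uniform_input():
    model = make_two_input_channel(delta=0.5, sigma=0.2, nu=5.0)
    res = cc.optimize_input_distribution(model)
    assert res.converged
    assert np.allclose(res.p_opt, [0.5, 0.5], atol=1e-3)


def test_ba_matches_grid_search_on_three_input_channel():
    model = cc.build_channel(
        np.array([100.0, 500.0, 5000.0]),
        np.array([0.0, 0.3, 1.1]),
        np.array([0.25, 0.15, 0.1]),
        np.array([3.0, 6.0, 12.0]),
    )
    res = cc.optimize_input_distribution(model)
    assert res.capacity_bits == pytest.approx(grid_search_capacity(model), abs=1e-3)
    # the optimum cannot be worse than the uniform distribution
    assert res.capacity_bits >= cc.mutual_information(model, np.full(3, 1 / 3)) - 1e-9


def test_ba_objective_monotone_in_plain_iteration():
    model = cc.build_channel(
        np.array([100.0, 500.0, 5000.0]),
        np.array([0.0, 0.4, 1.0]),
        np.array([0.3, 0.2, 0.1]),
        np.array([4.0, 4.0, 4.0]),
    )
    res = cc.optimize_input_distribution(model, accelerate=False)
    hist = np.asarray(res.history_bits)
    assert np.all(np.diff(hist) >= -1e-12)


def test_capacity_translation_invariant():
    base = np.array([0.0, 0.35, 0.9])
    out = []
    for shift in (0.0, 5.0):
        model = cc.build_channel(
            np.array([100.0, 500.0, 5000.0]),
            base + shift,
            np.array([0.2, 0.15, 0.1]),
            np.array([5.0, 5.0, 5.0]),
        )
        out.append(cc.optimize_input_distribution(model).capacity_bits)
    assert out[0] == pytest.approx(out[1], abs=2e-4)


def test_capacity_decreases_with_noise_scale():
    caps = []
    for lam in (1.0, 2.0, 4.0):
        model = cc.build_channel(
            np.array([100.0, 500.0, 5000.0]),
            np.array([0.0, 0.4, 1.0]),
            lam * np.array([0.2, 0.15, 0.1]),
            np.array([5.0, 5.0, 5.0]),
        )
        caps.append(cc.optimize_input_distribution(model).capacity_bits)
    assert caps[0] > caps[1] - 1e-4 > caps[2] - 2e-4
    assert caps[0] > caps[2]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    mid=st.floats(min_value=0.05, max_value=0.95),
    sig_lo=st.floats(min_value=0.05, max_value=0.5),
    sig_hi=st.floats(min_value=0.05, max_value=0.5),
)
def test_interpolated_sigma_bounded_by_knots(mid, sig_lo, sig_hi):
    """Piecewise-linear interpolants never leave the knot envelope."""
    design = cc.StimulusDesign()
    noise = cc.NoiseParams(
        concentrations_nM=design.concentrations_nM,
        sigma=tuple(np.linspace(sig_lo, sig_hi, 7)),
        nu=(5.0,) * 7,
    )
    profile = cc.CellResponseProfile(
        cell_id=0,
        concentrations_nM=np.asarray(design.concentrations_nM),
        mu=np.linspace(0.0, mid, 7),
    )
    model = cc.interpolate_params(design, noise, profile, grid_size=51)
    lo, hi = min(sig_lo, sig_hi), max(sig_lo, sig_hi)
    assert np.all(model.sigma >= lo - 1e-12)
    assert np.all(model.sigma <= hi + 1e-12)
    assert np.all(np.diff(model.support_nM) > 0)


def test_interpolation_knot_identity_and_midpoint(fitted_noise, small_population):
    cfg, peaks, _ = small_population
    profile = cc.profile_from_peaks(peaks[peaks.cell_id == 0])
    model = cc.interpolate_params(cfg.design, fitted_noise, profile, grid_size=101)
    concs = np.asarray(cfg.design.concentrations_nM)
    for j, c in enumerate(concs):
        k = int(np.argmin(np.abs(model.support_nM - c)))
        assert model.support_nM[k] == pytest.approx(c, rel=1e-9)
        sig_j, nu_j = fitted_noise.at(c)
        assert model.sigma[k] == pytest.approx(sig_j, abs=1e-12)
        assert model.nu[k] == pytest.approx(nu_j, abs=1e-12)
        assert model.mu[k] == pytest.approx(profile.mu[j], abs=1e-12)
    # log-midpoint between c2 and c3 carries the arithmetic mean of the knots
    c_mid = 10 ** (0.5 * (np.log10(concs[1]) + np.log10(concs[2])))
    mu_mid = profile.interp_mu(np.array([c_mid]))[0]
    assert mu_mid == pytest.approx(0.5 * (profile.mu[1] + profile.mu[2]), abs=1e-12)
    with pytest.raises(ValueError):
        cc.interpolate_params(cfg.design, fitted_noise, profile, grid_size=3)


def test_flat_profile_has_zero_capacity(small_population):
    # constant mean AND concentration-independent noise: output carries
    # no information about the input in either estimation mode
    cfg, peaks, _ = small_population
    flat = peaks[peaks.cell_id == 0].copy()
    flat["peak_log_response"] = 1.0
    uniform_noise = cc.NoiseParams(
        concentrations_nM=cfg.design.concentrations_nM, sigma=(0.2,) * 7, nu=(5.0,) * 7
    )
    est = cc.estimate_cell_capacity(flat, uniform_noise, design=cfg.design, mode="both")
    assert est.lower_bound_bits == pytest.approx(0.0, abs=1e-3)
    assert est.interpolated_bits == pytest.approx(0.0, abs=1e-3)


def test_cell_capacity_matches_ground_truth_oracle(small_population):
    """Estimates on a known cell agree with the generator's independent
    quadrature capacity when the true noise parameters are supplied."""
    cfg, peaks, truth = small_population
    noise_true = cc.NoiseParams(
        concentrations_nM=cfg.design.concentrations_nM,
        sigma=tuple(truth.sigma),
        nu=tuple(truth.nu),
    )
    # noise-free mean profile: feed the true mu as a single pseudo-replicate pair
    i = 3
    rows = []
    for j, c in enumerate(cfg.design.concentrations_nM):
        for k in (1, 2):
            rows.append((i, 0, c, k, j * 2 + k, truth.mu[i, j], "ok"))
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "experiment_id", "concentration_nM", "replicate",
            "pulse_index", "peak_log_response", "qc_flag",
        ],
    )
    est = cc.estimate_cell_capacity(table, noise_true, design=cfg.design, mode="both")
    assert est.lower_bound_bits == pytest.approx(truth.capacity_discrete_bits[i], abs=0.02)
    assert est.interpolated_bits >= est.lower_bound_bits - 1e-3


def test_interpolated_estimate_dominates_lower_bound(small_population, fitted_noise):
    cfg, peaks, _ = small_population
    ests = cc.estimate_population_capacities(peaks, fitted_noise, design=cfg.design)
    assert len(ests) == cfg.n_cells
    lbs = np.array([e.lower_bound_bits for e in ests])
    ints = np.array([e.interpolated_bits for e in ests])
    assert np.all(ints >= lbs - 1e-3)
    assert ints.mean() > lbs.mean()
    assert np.all(lbs >= 0) and np.all(lbs <= np.log2(7) + 1e-9)


def test_grid_size_sensitivity_within_tolerance(small_population, fitted_noise):
    cfg, peaks, _ = small_population
    sub = peaks[peaks.cell_id == 1]
    caps = [
        cc.estimate_cell_capacity(
            sub, fitted_noise, design=cfg.design, mode="interpolated", grid_size=m
        ).interpolated_bits
        for m in (51, 101, 201)
    ]
    assert max(caps) - min(caps) < 0.02


@pytest.mark.parametrize(
    "mu, expected",
    [
        ([0.0, 0.0, 0.5, 1.0, 1.0, 1.0, 1.0], 500.0),  # crossing exactly at a knot
        (None, None),  # flat profile: undefined
    ],
)
def test_ec50_knot_crossing_and_flat(mu, expected):
    concs = np.asarray(cc.StimulusDesign().concentrations_nM)
    if mu is None:
        profile = cc.CellResponseProfile(cell_id=0, concentrations_nM=concs, mu=np.ones(7))
        assert cc.estimate_ec50(profile) is None
    else:
        profile = cc.CellResponseProfile(cell_id=0, concentrations_nM=concs, mu=np.asarray(mu))
        assert cc.estimate_ec50(profile) == pytest.approx(expected, rel=1e-9)


def test_ec50_log_midpoint_crossing():
    concs = np.asarray(cc.StimulusDesign().concentrations_nM)
    # normalized response crosses 0.5 halfway (in log space) between 250 and 500
    mu = np.array([0.0, 0.25, 0.75, 1.0, 1.0, 1.0, 1.0])
    profile = cc.CellResponseProfile(cell_id=0, concentrations_nM=concs, mu=mu)
    assert cc.estimate_ec50(profile) == pytest.approx(np.sqrt(250 * 500), rel=1e-6)


def test_too_coarse_output_grid_is_rejected():
    with pytest.raises(cc.capacity.GridError):
        cc.build_channel(
            np.array([100.0, 1000.0]),
            np.array([0.0, 1.0]),
            np.array([0.001, 0.001]),
            np.array([5.0, 5.0]),
            grid_points=101,  # ~100 sigma per grid step: mass check must fail
        )


def test_population_summary_statistics():
    e1 = cc.CapacityEstimate(cell_id=0, interpolated_bits=2.0)
    single = cc.summarize_population([e1])
    assert single["interpolated_bits"]["mean"] == 2.0
    assert single["interpolated_bits"]["sd"] == 0.0
    assert single["interpolated_bits"]["sd_is_degenerate"]
    e2 = cc.CapacityEstimate(cell_id=1, interpolated_bits=1.5)
    e3 = cc.CapacityEstimate(cell_id=2, interpolated_bits=2.5)
    two = cc.summarize_population([e2, e3])
    assert two["interpolated_bits"]["mean"] == pytest.approx(2.0)
    assert two["interpolated_bits"]["sd"] == pytest.approx(0.7071, abs=1e-3)
    counts = two["interpolated_bits"]["histogram"]["counts"]
    assert sum(counts) == 2
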