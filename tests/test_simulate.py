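"""Generator correctness: the synthetic data must have exactly the
statistical structure the downstream analysis assumes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chancap as cc
from chancap.simulate import _interp_channel


def test_design_validation():
    with pytest.raises(ValueError):
        cc.StimulusDesign(concentrations_nM=(100.0,))
    with pytest.raises(ValueError):
        cc.StimulusDesign(concentrations_nM=(500.0, 100.0))
    with pytest.raises(ValueError):
        cc.StimulusDesign(n_replicates=0)
    d = cc.StimulusDesign()
    assert d.n_pulses == 35
    assert d.period_s == 120.0
    # pulse order: all K replicates of c1, then c2, ... ascending
    pc = d.pulse_concentrations()
    assert pc[0] == 100.0 and pc[4] == 100.0 and pc[5] == 250.0 and pc[-1] == 10000.0
    assert float(d.pulse_index_to_concentration(6)) == 250.0


def test_config_rejects_nonfinite_and_bad_params():
    with pytest.raises(ValueError):
        cc.SimulationConfig(desensitization_rate=0.0)
    with pytest.raises(ValueError):
        cc.SimulationConfig(span_mean=float("nan"))
    with pytest.raises(ValueError):
        cc.SimulationConfig(sigma=(0.1,) * 3)


def test_noise_free_limit_reproduces_mu(quiet_config):
    peaks, truth = cc.generate_peak_table(quiet_config, true_capacity_modes=())
    concs = np.asarray(quiet_config.design.concentrations_nM)
    for i in range(quiet_config.n_cells):
        for j, c in enumerate(concs):
            vals = peaks.query("cell_id == @i and concentration_nM == @c")["peak_log_response"]
            assert np.allclose(vals, truth.mu[i, j], atol=1e-6)


def test_deterministic_decay_per_pulse():
    cfg = cc.SimulationConfig(
        n_cells=2, seed=3, sigma=(1e-12,) * 7, nu=(5.0,) * 7, desensitization_rate=0.99
    )
    peaks, _ = cc.generate_peak_table(cfg, true_capacity_modes=())
    one = peaks[peaks.cell_id == 0].sort_values("pulse_index")
    # within a concentration block the only pulse-to-pulse change is log d
    diffs = np.diff(one["peak_log_response"].to_numpy())
    k = cfg.design.n_replicates
    within_block = [d for idx, d in enumerate(diffs) if (idx + 1) % k != 0]
    assert np.allclose(within_block, np.log(0.99), atol=1e-9)


def test_residuals_match_scaled_t_distribution():
    # goodness of fit of realized residuals against the exact scaled-t CDF
    design = cc.StimulusDesign(concentrations_nM=(100.0, 1000.0), n_replicates=1000)
    cfg = cc.SimulationConfig(
        n_cells=50, design=design, sigma=(0.1, 0.1), nu=(3.0, 3.0),
        desensitization_rate=1.0, seed=11,
    )
    peaks, truth = cc.generate_peak_table(cfg, true_capacity_modes=())
    res = truth.residuals[:, 0, :].ravel()
    ks = stats.kstest(res, lambda x: stats.t.cdf(x, df=3.0, scale=0.1))
    assert ks.pvalue > 0.01
    # symmetric noise: sample mean near zero at this n
    assert abs(res.mean()) < 5 * res.std() / np.sqrt(res.size)


def test_seed_reproducibility_bit_for_bit():
    cfg = cc.SimulationConfig(n_cells=5, seed=42)
    p1, t1 = cc.generate_peak_table(cfg, true_capacity_modes=())
    p2, t2 = cc.generate_peak_table(cfg, true_capacity_modes=())
    pd.testing.assert_frame_equal(p1, p2)
    assert np.array_equal(t1.residuals, t2.residuals)
    p3, _ = cc.generate_peak_table(
        cc.SimulationConfig(n_cells=5, seed=43), true_capacity_modes=()
    )
    assert not p3["peak_log_response"].equals(p1["peak_log_response"])


def test_mu_profiles_monotone_and_capacity_bounded(small_population):
    cfg, _, truth = small_population
    assert np.all(np.diff(truth.mu, axis=1) >= -1e-12)
    n = cfg.design.n_concentrations
    assert np.all(truth.capacity_discrete_bits >= 0)
    assert np.all(truth.capacity_discrete_bits <= np.log2(n) + 1e-9)


def test_ground_truth_agrees_with_capacity_module(small_population, fitted_noise):
    """Cross-module oracle: the generator's independent quadrature capacity
    matches the Blahut-Arimoto solver run on the same true channel."""
    cfg, _, truth = small_population
    for i in (0, 5, 11):
        model = cc.build_channel(
            np.asarray(cfg.design.concentrations_nM), truth.mu[i], truth.sigma, truth.nu
        )
        res = cc.optimize_input_distribution(model)
        assert res.capacity_bits == pytest.approx(truth.capacity_discrete_bits[i], abs=1e-3)
        # mutual information at the solver's optimal P(c) equals the capacity
        assert cc.mutual_information(model, res.p_opt) == pytest.approx(
            res.capacity_bits, abs=1e-6
        )


def test_interpolated_truth_uses_same_model_class(small_population):
    cfg, _, truth = small_population
    concs = truth.concentrations_nM
    mu_g, s_g, n_g = _interp_channel(concs, truth.mu[0], truth.sigma, truth.nu, 101)
    # knots present and exact
    logc = np.log10(concs)
    grid = np.union1d(np.linspace(logc[0], logc[-1], 101), logc)
    assert mu_g.size == grid.size
    for j, c in enumerate(concs):
        k = np.argmin(np.abs(10.0**grid - c))
        assert mu_g[k] == pytest.approx(truth.mu[0, j], abs=1e-12)


def test_trace_rendering_shape_and_drift(quiet_config):
    peaks, _ = cc.generate_peak_table(quiet_config, true_capacity_modes=())
    cfg = quiet_config
    traces = cc.generate_traces(cfg, peaks)
    one = traces[traces.cell_id == 0]
    assert len(one) >= 4200  # 35 pulses at 120 s spacing, 1 frame/s
    from scipy.signal import find_peaks

    idx, _ = find_peaks(one["ratio"].to_numpy(), prominence=0.01)
    assert idx.size >= 35
    # linear drift arithmetic: baseline rise over the trace
    cfg_d = cc.SimulationConfig(
        n_cells=1, seed=9, sigma=(1e-12,) * 7, nu=(5.0,) * 7,
        drift_slope_per_frame=1e-4, pre_baseline_s=30.0, post_tail_s=60.0,
    )
    pk, _ = cc.generate_peak_table(cfg_d, true_capacity_modes=())
    tr = cc.generate_traces(cfg_d, pk)
    t = tr[tr.cell_id == 0]
    rise = 1e-4 * (len(t) - 1)
    assert rise == pytest.approx(0.42, abs=0.02)
    assert (t["ratio"].iloc[-1] - t["ratio"].iloc[0]) == pytest.approx(rise, abs=0.05)


def test_trace_rendering_rejects_too_short_period():
    design = cc.StimulusDesign(pulse_duration_s=5.0, gap_s=20.0)
    cfg = cc.SimulationConfig(n_cells=1, seed=1, design=design)
    peaks, _ = cc.generate_peak_table(cfg, true_capacity_modes=())
    with pytest.raises(ValueError, match="transient support"):
        cc.generate_traces(cfg, peaks)


def test_simulation_config_yaml_round_trip(tmp_path):
    cfg = cc.SimulationConfig(
        n_cells=7, seed=3,
        design=cc.StimulusDesign(concentrations_nM=(50.0, 500.0, 5000.0), n_replicates=4),
        sigma=(0.3, 0.2, 0.1), nu=(3.0, 4.0, 5.0),
    )
    path = tmp_path / "sim.yaml"
    cfg.to_yaml(path)
    back = cc.SimulationConfig.from_yaml(path)
    assert back == cfg
    p1, _ = cc.generate_peak_table(cfg, true_capacity_modes=())
    p2, _ = cc.generate_peak_table(back, true_capacity_modes=())
    pd.testing.assert_frame_equal(p1, p2)


def test_repeated_stimulation_generator():
    table = cc.generate_repeated_stimulation(
        n_cells=10, n_pulses=20, seed=2, sigma=0.0, desensitization_rate=0.99
    )
    assert len(table) == 200
    one = table[table.cell_id == 3].sort_values("pulse_index")["peak_log_response"]
    assert np.allclose(np.diff(one), np.log(0.99), atol=1e-12)
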