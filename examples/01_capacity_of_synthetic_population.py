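"""Estimate per-cell channel capacity on a small synthetic population.

Generates 20 cells under the default seven-concentration protocol, fits the
shared scaled-t noise, and runs both capacity estimates.  The lower bound is
capped at log2(7) = 2.81 bits by the discrete design; the interpolated
estimate relaxes that cap by interpolating (mu, sigma, nu) along the log
concentration axis, so it is the more realistic figure.
"""

import numpy as np

import chancap as cc

cfg = cc.SimulationConfig(n_cells=20, seed=1)
peaks, truth = cc.generate_peak_table(cfg)

noise = cc.fit_noise_params(peaks, min_n=20)
print("fitted noise (sigma, nu) per concentration:")
for c, s, v in zip(noise.concentrations_nM, noise.sigma, noise.nu):
    print(f"  {c:>8.0f} nM   sigma={s:.3f}  nu={v:5.1f}")

ests = cc.estimate_population_capacities(peaks, noise, design=cfg.design, mode="both")
summary = cc.summarize_population(ests)
lb, ip = summary["lower_bound_bits"], summary["interpolated_bits"]
print(f"\nlower bound : {lb['mean']:.2f} +/- {lb['sd']:.2f} bits (mean +/- sd, n={lb['n']})")
print(f"interpolated: {ip['mean']:.2f} +/- {ip['sd']:.2f} bits")

err = np.mean(
    np.abs(
        [e.lower_bound_bits for e in ests]
        - truth.capacity_discrete_bits[[e.cell_id for e in ests]]
    )
)
print(f"mean |error| vs generator ground truth (discrete): {err:.3f} bits")
print("\nA capacity of ~2 bits means the cell reliably distinguishes ~4 agonist levels.")
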