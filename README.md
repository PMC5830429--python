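# chancap — channel capacity of single-cell GPCR calcium signaling

How much information about an extracellular agonist concentration does one
cell's signaling pathway actually transmit?  `chancap` answers this for
repeated-stimulation calcium-imaging experiments on a Gq-coupled receptor
pathway (acetylcholine → M3 muscarinic receptor → Gq → PLCβ → IP₃ → Ca²⁺ in
HEK293 cells is the motivating system): each cell is stimulated with an
ascending series of agonist concentrations, several pulses per
concentration, and the per-cell **channel capacity** — the maximum mutual
information between input concentration and peak calcium response — is
estimated in bits.  A capacity of *n* bits means the cell reliably resolves
2ⁿ concentration levels; around 2 bits, a single cell distinguishes ~4
agonist levels, far more than a yes/no switch.

It is a library for interactive use from Python (see `examples/`), with a
thin `chancap` command-line interface over the same functions.

## Model

For cell *i*, concentration *c*ⱼ and replicate *k*, the log peak response is

```
r_ijk = μ_i(c_j) + e_ik(c_j)
```

where μᵢ is the cell-specific mean dose response and the noise *e* is shared
across cells but specific to each concentration, following a scaled Student
t-distribution with scale σⱼ and degrees of freedom νⱼ (log-space residuals
of calcium peaks are symmetric but heavy-tailed).  Residuals
`e_ik = r_ijk − mean_k(r_ijk)` are pooled across cells per concentration and
(σⱼ, νⱼ) fitted by maximum likelihood.

The channel is fully described by P(r|c), so the capacity is

```
C_i = max_{P(c)}  I(c; r) = max_{P(c)} Σⱼ P(cⱼ) ∫ P(r|cⱼ) log₂ [ P(r|cⱼ) / Σₗ P(cₗ)P(r|cₗ) ] dr
```

solved by Blahut–Arimoto on a quadrature-discretized output, with a
certified convergence gap below 10⁻⁴ bits.  Two estimates are reported per
cell:

* **lower bound** — input support restricted to the *N* tested
  concentrations (bounded by log₂ N ≈ 2.81 bits for the default 7-point
  design);
* **interpolated** — (μ, σ, ν) piecewise-linearly interpolated along the
  log₁₀-concentration axis, input support a fine grid over the tested range.

The package also quantifies desensitization (responses decay ≈1% per pulse
under repeated identical stimulation) and can remove it by subtracting the
per-pulse-number median residual.

A synthetic-data generator produces peak tables and raw ratio traces with
this exact structure and known per-cell true capacities, so every stage is
validated against independent oracles.

## Worked example

```python
import chancap as cc

cfg = cc.SimulationConfig(n_cells=20, seed=1)      # 7 doses x 5 pulses each
peaks, truth = cc.generate_peak_table(cfg)
noise = cc.fit_noise_params(peaks, min_n=20)       # scaled-t MLE per dose
ests = cc.estimate_population_capacities(peaks, noise, design=cfg.design)
summary = cc.summarize_population(ests)
```

Running `python examples/01_capacity_of_synthetic_population.py` (which adds
the ground-truth comparison) prints:

```
lower bound : 1.60 +/- 0.29 bits (mean +/- sd, n=20)
interpolated: 2.06 +/- 0.50 bits
mean |error| vs generator ground truth (discrete): 0.087 bits
```

The lower bound is capped by the 7-level design; the interpolated estimate
is the more realistic figure — here ~2 bits, i.e. ~4 reliably
distinguishable concentrations per cell — and per-cell estimates track the
generator's independently computed truths to well under 0.1 bits.

The same analysis from the shell:

```sh
chancap simulate --seed 1 --out run/
chancap fit-noise --peaks run/peaks.csv --out run/noise.json
chancap capacity --peaks run/peaks.csv --noise run/noise.json --mode both --out run/
chancap adaptation --peaks run/peaks.csv --out run/ --correct
# or everything at once from a YAML config:
chancap run --config run.yaml
```

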