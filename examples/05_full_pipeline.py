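"""Run the whole pipeline in one call and inspect the report.

Equivalent to `chancap run --config run.yaml` from the shell: simulate a
population, fit noise, estimate capacities, analyze adaptation, and write
every stage product plus a machine-readable report under an output
directory.  The report is byte-identical for identical config and seed.
"""

import json
from pathlib import Path

import chancap as cc
from chancap.pipeline import RunConfig, run_pipeline

out = Path("scratch/example_run")
report = run_pipeline(
    RunConfig(
        out_dir=out,
        simulation=cc.SimulationConfig(n_cells=10),
        seed=4,
        min_noise_n=20,
    )
)

print("stages:", [(s["name"], s["n_records"]) for s in report["stages"]])
ip = report["capacity_summary"]["interpolated_bits"]
print(f"population capacity (interpolated): {ip['mean']:.2f} +/- {ip['sd']:.2f} bits")
print(f"per-pulse decay: {report['adaptation_fit']['decay_per_pulse_pct']:.2f}%")
print("stage products:", sorted(p.name for p in out.iterdir()))
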