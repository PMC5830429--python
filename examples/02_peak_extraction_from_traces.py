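"""Extract peak responses from raw calcium ratio traces.

Renders synthetic Fura-2 ratio traces (35 agonist pulses on a drifting
baseline at 1 frame/s), then runs the extraction chain: background removal,
schedule-aligned peak detection with extrapolation of low-SNR peaks, and
MAD-based artifact flagging.  The recovered log peak heights are compared
with the generator's stored values.
"""

import numpy as np

import chancap as cc

cfg = cc.SimulationConfig(
    n_cells=4, seed=2, mu_baseline_mean=-1.0, span_mean=2.0,
    sigma=(0.05,) * 7, nu=(10.0,) * 7,
)
peaks, _ = cc.generate_peak_table(cfg, true_capacity_modes=())
traces = cc.generate_traces(cfg, peaks)
print(f"rendered {traces.cell_id.nunique()} traces, "
      f"{len(traces) // traces.cell_id.nunique()} frames each")

table = cc.extract_peak_table(traces, cfg.design)
print("qc flags:", table.qc_flag.value_counts().to_dict())

m = peaks.merge(table, on=["cell_id", "pulse_index"], suffixes=("_true", "_est"))
ok = m[m.qc_flag_est == "ok"]
rmse = float(np.sqrt(((ok.peak_log_response_est - ok.peak_log_response_true) ** 2).mean()))
print(f"round-trip RMSE of log peak heights: {rmse:.3f} log units "
      "(small values mean the extraction is faithful at this SNR)")
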