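"""Synthetic single-cell calcium-response data with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage (peak extraction, noise fitting, capacity estimation,
adaptation analysis) can be exercised and validated without real recordings:

* each cell has a sigmoid (Hill) mean dose-response in log-response space,
  with its half-activation point drawn uniformly across the tested
  log-concentration range — cells differ mainly in where their dynamic
  range sits on the agonist axis;
* replicate noise is additive in log space, drawn from a per-concentration
  scaled Student t-distribution shared across cells;
* repeated stimulation desensitizes the response by a constant multiplicative
  factor per pulse (about 1% by default), i.e. an additive ``log d`` ramp in
  log space along the global pulse index;
* optionally, each peak is rendered as a linear-rise/exponential-decay
  calcium transient on a slowly drifting baseline sampled at 1 frame/s, so
  the trace-level peak-extraction stage can be tested end to end.

Ground-truth per-cell capacities are computed here by an independent route
(dense scipy quadrature plus softmax-parameterized gradient ascent) so they
can serve as an oracle for the Blahut-Arimoto estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .design import StimulusDesign

LN2 = math.log(2.0)

#: Default per-concentration noise for the seven-point design: log-space
#: residuals are noisier near threshold (low concentrations, where peaks sit
#: close to background) and tighter at saturation; tails are heavy (small nu)
#: at the noisy end and closer to Gaussian at the plateau.
DEFAULT_SIGMA = (0.35, 0.30, 0.25, 0.20, 0.15, 0.12, 0.10)
DEFAULT_NU = (3.0, 3.0, 4.0, 4.0, 5.0, 6.0, 8.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic repeated-stimulation study."""

    n_cells: int = 100
    design: StimulusDesign = field(default_factory=StimulusDesign)
    # per-cell Hill mean model in log-response space:
    #   mu_i(c) = baseline_i + span_i / (1 + (ec50_i / c)^hill_i)
    mu_baseline_mean: float = -3.0  # log of a barely-visible 0.05 ratio-unit peak
    mu_baseline_sd: float = 0.3
    span_mean: float = 3.2  # log dynamic range; exp(3.2) ~ 25-fold peak growth
    span_sd: float = 0.4
    log10_ec50_range: tuple[float, float] = (2.0, 4.0)  # uniform over tested axis
    hill_range: tuple[float, float] = (1.0, 2.5)
    sigma: tuple[float, ...] = DEFAULT_SIGMA
    nu: tuple[float, ...] = DEFAULT_NU
    desensitization_rate: float = 0.99  # per-pulse multiplicative decay d
    # trace rendering
    frame_rate_hz: float = 1.0
    rise_time_s: float = 8.0
    decay_tau_s: float = 20.0
    baseline_ratio: float = 0.5
    drift_slope_per_frame: float = 5e-5
    pre_baseline_s: float = 30.0
    post_tail_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.design.n_concentrations
        sig = np.asarray(self.sigma, dtype=float)
        nu = np.asarray(self.nu, dtype=float)
        if sig.size != n or nu.size != n:
            raise ValueError("sigma and nu must have one entry per concentration")
        numeric = np.concatenate(
            [
                sig,
                nu,
                [
                    self.mu_baseline_mean,
                    self.mu_baseline_sd,
                    self.span_mean,
                    self.span_sd,
                    *self.log10_ec50_range,
                    *self.hill_range,
                    self.desensitization_rate,
                    self.frame_rate_hz,
                    self.rise_time_s,
                    self.decay_tau_s,
                    self.baseline_ratio,
                    self.drift_slope_per_frame,
                ],
            ]
        )
        if not np.all(np.isfinite(numeric)):
            raise ValueError("non-finite simulation parameter")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if np.any(sig <= 0) or np.any(nu <= 0):
            raise ValueError("sigma and nu must be positive")
        if not (0.0 < self.desensitization_rate <= 1.0):
            raise ValueError("desensitization_rate must be in (0, 1]")
        if min(self.frame_rate_hz, self.rise_time_s, self.decay_tau_s) <= 0:
            raise ValueError("trace time parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = self.design.to_dict()
        for k in ("log10_ec50_range", "hill_range", "sigma", "nu"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = StimulusDesign.from_dict(d["design"])
        for k in ("log10_ec50_range", "hill_range", "sigma", "nu"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    concentrations_nM: np.ndarray
    mu: np.ndarray  # (n_cells, N) mean log responses
    sigma: np.ndarray
    nu: np.ndarray
    desensitization_rate: float
    residuals: np.ndarray  # (n_cells, N, K) realized noise draws
    capacity_discrete_bits: np.ndarray | None = None
    capacity_interpolated_bits: np.ndarray | None = None
    hill_params: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        doc = {
            "concentrations_nM": self.concentrations_nM.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "nu": self.nu.tolist(),
            "desensitization_rate": self.desensitization_rate,
            "residuals": self.residuals.tolist(),
            "capacity_discrete_bits": (
                None if self.capacity_discrete_bits is None else self.capacity_discrete_bits.tolist()
            ),
            "capacity_interpolated_bits": (
                None
                if self.capacity_interpolated_bits is None
                else self.capacity_interpolated_bits.tolist()
            ),
            "hill_params": (
                None if self.hill_params is None else self.hill_params.to_dict(orient="list")
            ),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)
            fh.write("\n")


def hill_log_response(
    c_nM: np.ndarray, baseline: float, span: float, ec50_nM: float, hill: float
) -> np.ndarray:
    """Four-parameter log-logistic mean log response."""
    c = np.asarray(c_nM, dtype=float)
    return baseline + span / (1.0 + (ec50_nM / c) ** hill)


def _draw_cell_params(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_cells
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "baseline": rng.normal(config.mu_baseline_mean, config.mu_baseline_sd, n),
            "span": np.maximum(rng.normal(config.span_mean, config.span_sd, n), 0.1),
            "ec50_nM": 10.0 ** rng.uniform(*config.log10_ec50_range, n),
            "hill": rng.uniform(*config.hill_range, n),
        }
    )


def generate_peak_table(
    config: SimulationConfig,
    true_capacity_modes: tuple[str, ...] = ("discrete",),
    interp_grid_size: int = 101,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the per-cell peak-response table r_ijk = mu_i(c_j) + e_ik(c_j).

    Pulses follow the experimental schedule (all K replicates of c_1, then
    c_2, ... ascending) and desensitization adds ``(pulse_index - 1) log d``
    in log space.  One global seed drives everything; per-cell substreams are
    spawned deterministically so the dataset is reproducible bit-for-bit.

    ``true_capacity_modes`` selects which ground-truth capacities to compute
    ("discrete" on the tested support, "interpolated" on the fine grid).
    """
    design = config.design
    concs = np.asarray(design.concentrations_nM)
    n_c, k_rep = design.n_concentrations, design.n_replicates
    ss = np.random.SeedSequence(config.seed)
    param_seed, *cell_seeds = ss.spawn(config.n_cells + 1)
    params = _draw_cell_params(config, np.random.default_rng(param_seed))

    sigma = np.asarray(config.sigma)
    nu = np.asarray(config.nu)
    log_d = math.log(config.desensitization_rate)
    pulse_idx = np.arange(1, design.n_pulses + 1)

    mu = np.vstack(
        [
            hill_log_response(concs, p.baseline, p.span, p.ec50_nM, p.hill)
            for p in params.itertuples()
        ]
    )
    residuals = np.empty((config.n_cells, n_c, k_rep))
    rows = []
    for i, seed_i in enumerate(cell_seeds):
        rng = np.random.default_rng(seed_i)
        e = sigma[:, None] * rng.standard_t(df=nu[:, None], size=(n_c, k_rep))
        residuals[i] = e
        r = mu[i][:, None] + e + (pulse_idx.reshape(n_c, k_rep) - 1) * log_d
        for j in range(n_c):
            for k in range(k_rep):
                rows.append(
                    (i, 0, concs[j], k + 1, j * k_rep + k + 1, r[j, k], "ok")
                )
    peaks = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "experiment_id",
            "concentration_nM",
            "replicate",
            "pulse_index",
            "peak_log_response",
            "qc_flag",
        ],
    )

    truth = GroundTruth(
        concentrations_nM=concs,
        mu=mu,
        sigma=sigma,
        nu=nu,
        desensitization_rate=config.desensitization_rate,
        residuals=residuals,
        hill_params=params,
    )
    if "discrete" in true_capacity_modes:
        truth.capacity_discrete_bits = np.array(
            [true_capacity(mu[i], sigma, nu) for i in range(config.n_cells)]
        )
    if "interpolated" in true_capacity_modes:
        truth.capacity_interpolated_bits = np.array(
            [
                true_capacity(*_interp_channel(concs, mu[i], sigma, nu, interp_grid_size))
                for i in range(config.n_cells)
            ]
        )
    return peaks, truth


def _interp_channel(
    concs: np.ndarray, mu_k: np.ndarray, sig_k: np.ndarray, nu_k: np.ndarray, grid_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear (mu, sigma, nu) on the union of a uniform log10 grid
    and the tested knots — the same model class the interpolated estimator
    optimizes over, so its truth is well defined."""
    logk = np.log10(concs)
    logc = np.union1d(np.linspace(logk[0], logk[-1], grid_size), logk)
    return (
        np.interp(logc, logk, mu_k),
        np.interp(logc, logk, sig_k),
        np.interp(logc, logk, nu_k),
    )


def true_capacity(
    mu: np.ndarray,
    sigma: np.ndarray,
    nu: np.ndarray,
    min_grid: int = 3001,
    pts_per_sigma: float = 10.0,
    tol: float = 1e-7,
    maxiter: int = 400,
) -> float:
    """Channel capacity (bits) of a scaled-t additive-noise channel.

    Independent oracle route: conditional densities from ``scipy.stats.t``,
    trapezoid quadrature on a dense output grid, and direct maximization of
    I(p) over the softmax-parameterized simplex with the analytic gradient
    ``dI/da_k = p_k (D_k - I)`` (L-BFGS).  Deliberately shares no code with
    the Blahut-Arimoto estimator.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), mu.shape)
    nu = np.broadcast_to(np.asarray(nu, dtype=float), mu.shape)
    q = stats.t.ppf(0.9995, df=nu)
    lo = np.min(mu - 10.0 * sigma * q)
    hi = np.max(mu + 10.0 * sigma * q)
    # fine uniform quadrature across the density peaks, quadratically
    # coarsening through the flat heavy tails
    core_lo = float(np.min(mu - 8.0 * sigma))
    core_hi = float(np.max(mu + 8.0 * sigma))
    dr = float(sigma.min()) / pts_per_sigma
    n_core = int(np.clip(np.ceil((core_hi - core_lo) / dr) + 1, min_grid, 400001))
    s = np.linspace(0.0, 1.0, 501)[1:]
    r = np.concatenate(
        [
            (core_lo - (core_lo - lo) * s**2)[::-1],
            np.linspace(core_lo, core_hi, n_core),
            core_hi + (hi - core_hi) * s**2,
        ]
    )
    dens = stats.t.pdf(r[None, :], df=nu[:, None], loc=mu[:, None], scale=sigma[:, None])
    log_dens = np.where(dens > 0, np.log(np.where(dens > 0, dens, 1.0)), 0.0)
    row_flogf = np.trapezoid(dens * log_dens, r, axis=1)  # per-row integral f log f

    def neg_mi_and_grad(a: np.ndarray) -> tuple[float, np.ndarray]:
        a = a - a.max()
        p = np.exp(a)
        p /= p.sum()
        marg = p @ dens
        log_marg = np.where(marg > 0, np.log(np.where(marg > 0, marg, 1.0)), 0.0)
        d = row_flogf - np.trapezoid(dens * log_marg[None, :], r, axis=1)  # nats
        mi = float(p @ d)
        grad = p * (d - mi)
        return -mi, -grad

    a0 = np.zeros(mu.size)
    res = optimize.minimize(
        neg_mi_and_grad, a0, jac=True, method="L-BFGS-B", tol=tol, options={"maxiter": maxiter}
    )
    return float(max(-res.fun, 0.0) / LN2)


def generate_repeated_stimulation(
    n_cells: int,
    n_pulses: int,
    seed: int,
    concentration_nM: float = 250.0,
    mu_mean: float = -1.0,
    mu_sd: float = 1.0,
    sigma: float = 0.1,
    nu: float = 5.0,
    desensitization_rate: float = 0.99,
) -> pd.DataFrame:
    """Peak table for the repeated-identical-stimulation protocol.

    Emulates the preliminary experiment in which every cell receives the
    same agonist dose many times in a row (20+ pulses of 250 nM by default)
    to quantify reproducibility and desensitization: cell-specific mean log
    responses drawn from N(mu_mean, mu_sd), shared scaled-t replicate noise,
    and constant multiplicative per-pulse decay.
    """
    if n_cells < 1 or n_pulses < 2:
        raise ValueError("need n_cells >= 1 and n_pulses >= 2")
    if sigma < 0 or nu <= 0 or not (0.0 < desensitization_rate <= 1.0):
        raise ValueError("bad noise/desensitization parameters")
    rng = np.random.default_rng(seed)
    mu_cells = rng.normal(mu_mean, mu_sd, n_cells)
    pulse = np.arange(1, n_pulses + 1)
    log_d = math.log(desensitization_rate)
    rows = []
    for i in range(n_cells):
        e = sigma * rng.standard_t(df=nu, size=n_pulses) if sigma > 0 else np.zeros(n_pulses)
        r = mu_cells[i] + (pulse - 1) * log_d + e
        for k in range(n_pulses):
            rows.append((i, 0, concentration_nM, k + 1, k + 1, r[k], "ok"))
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "experiment_id",
            "concentration_nM",
            "replicate",
            "pulse_index",
            "peak_log_response",
            "qc_flag",
        ],
    )


def _transient(tau: np.ndarray, rise_s: float, decay_tau_s: float) -> np.ndarray:
    """Unit-peak calcium transient: linear rise, exponential decay."""
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau < rise_s)
    out[rising] = tau[rising] / rise_s
    decaying = tau >= rise_s
    out[decaying] = np.exp(-(tau[decaying] - rise_s) / decay_tau_s)
    return out


def generate_traces(config: SimulationConfig, peaks: pd.DataFrame) -> pd.DataFrame:
    """Render each peak as a calcium transient on a drifting baseline.

    Returns a long-format trace table (``time_s``, ``cell_id``, ``ratio``)
    at the configured frame rate, with a quiet pre-baseline segment and a
    post-stimulation tail.  Baseline-subtracted transient heights equal
    ``exp(peak_log_response)``.
    """
    design = config.design
    support_s = config.rise_time_s + 5.0 * config.decay_tau_s
    if design.period_s < support_s:
        raise ValueError(
            f"pulse period {design.period_s} s shorter than transient support {support_s} s"
        )
    dt = 1.0 / config.frame_rate_hz
    total_s = config.pre_baseline_s + design.n_pulses * design.period_s + config.post_tail_s
    t = np.arange(0.0, total_s, dt)
    onsets = design.pulse_onsets_s(start_s=config.pre_baseline_s)

    frames = []
    for cell_id, sub in peaks.groupby("cell_id"):
        sub = sub.sort_values("pulse_index")
        if sub["pulse_index"].tolist() != list(range(1, design.n_pulses + 1)):
            raise ValueError(f"cell {cell_id}: peaks do not cover pulses 1..{design.n_pulses}")
        amps = np.exp(sub["peak_log_response"].to_numpy())
        ratio = config.baseline_ratio + config.drift_slope_per_frame * np.arange(t.size)
        for onset, amp in zip(onsets, amps):
            ratio += amp * _transient(t - onset, config.rise_time_s, config.decay_tau_s)
        frames.append(pd.DataFrame({"time_s": t, "cell_id": cell_id, "ratio": ratio}))
    return pd.concat(frames, ignore_index=True)
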