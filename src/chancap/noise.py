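"""Heavy-tailed noise model for log-scale peak responses.

Replicate-to-replicate variability of a cell's log peak response at a fixed
agonist concentration is modeled as a zero-location scaled Student
t-distribution with per-concentration scale ``sigma`` and degrees of freedom
``nu``.  The t family captures the symmetric, heavy-tailed residual
distribution seen in repeated-stimulation calcium recordings; the noise is
shared across cells but specific to each concentration, so residuals are
pooled across cells per concentration before fitting.

The residual of replicate k of cell i at concentration c_j is the deviation
from the within-(cell, concentration) mean::

    e_ik(c_j) = r_ijk - mean_k(r_ijk)

and (sigma_j, nu_j) maximize the scaled-t likelihood of the pooled residuals.
No small-sample correction is applied for the variance deflation caused by
subtracting the group mean (a factor (K-1)/K at K replicates); the fitted
scale therefore describes the residuals as defined, not the latent noise.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

NU_BOUNDS = (0.5, 200.0)


def scaled_t_logpdf(x: np.ndarray, sigma: float, nu: float) -> np.ndarray:
    """Log-density of the zero-location scaled Student t.

    Equivalent to ``scipy.stats.t.logpdf(x, df=nu, scale=sigma)`` but cheap
    enough for dense (sigma, nu) grid evaluation.
    """
    x = np.asarray(x, dtype=float)
    z2 = (x / sigma) ** 2
    return (
        gammaln(0.5 * (nu + 1.0))
        - gammaln(0.5 * nu)
        - 0.5 * np.log(np.pi * nu)
        - np.log(sigma)
        - 0.5 * (nu + 1.0) * np.log1p(z2 / nu)
    )


def scaled_t_loglik(x: np.ndarray, sigma: float, nu: float) -> float:
    """Total log-likelihood of a residual sample under scaled-t(sigma, nu)."""
    return float(np.sum(scaled_t_logpdf(x, sigma, nu)))


@dataclass(frozen=True)
class NoiseParams:
    """Fitted per-concentration scaled-t noise parameters."""

    concentrations_nM: tuple[float, ...]
    sigma: tuple[float, ...]
    nu: tuple[float, ...]
    loglik: tuple[float, ...] = ()
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        v = np.asarray(self.nu, dtype=float)
        if not (c.size == s.size == v.size):
            raise ValueError("concentrations, sigma and nu must align")
        if np.any(s <= 0) or np.any(v <= 0):
            raise ValueError("sigma and nu must be positive")

    def at(self, concentration_nM: float) -> tuple[float, float]:
        """(sigma, nu) at a tested concentration."""
        c = np.asarray(self.concentrations_nM)
        j = np.flatnonzero(np.isclose(c, concentration_nM))
        if j.size == 0:
            raise KeyError(f"no noise parameters at {concentration_nM} nM")
        return float(self.sigma[j[0]]), float(self.nu[j[0]])

    def to_records(self) -> list[dict]:
        recs = []
        for j, c in enumerate(self.concentrations_nM):
            rec = {"concentration_nM": c, "sigma": self.sigma[j], "nu": self.nu[j]}
            if self.loglik:
                rec["loglik"] = self.loglik[j]
            if self.n:
                rec["n"] = self.n[j]
            recs.append(rec)
        return recs

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_records(cls, recs: list[dict]) -> "NoiseParams":
        recs = sorted(recs, key=lambda r: r["concentration_nM"])
        return cls(
            concentrations_nM=tuple(r["concentration_nM"] for r in recs),
            sigma=tuple(r["sigma"] for r in recs),
            nu=tuple(r["nu"] for r in recs),
            loglik=tuple(r.get("loglik", np.nan) for r in recs),
            n=tuple(int(r.get("n", 0)) for r in recs),
        )

    @classmethod
    def from_json(cls, path) -> "NoiseParams":
        with open(path) as fh:
            return cls.from_records(json.load(fh))


def compute_residuals(peaks: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Within-(cell, concentration) residuals of log peak responses.

    Parameters
    ----------
    peaks
        Peak table with columns ``cell_id``, ``concentration_nM``,
        ``peak_log_response`` and optionally ``qc_flag`` (rows flagged
        ``artifact_removed`` are excluded).
    min_replicates
        Groups with fewer retained replicates are dropped with a warning;
        a single replicate carries no information about the noise.

    Returns
    -------
    DataFrame with the retained rows plus a ``residual`` column
    (``peak_log_response`` minus the group mean) and ``group_size``.
    """
    if peaks.empty:
        raise ValueError("empty peak table")
    df = peaks.copy()
    if "qc_flag" in df.columns:
        df = df[df["qc_flag"] != "artifact_removed"]
    df = df[np.isfinite(df["peak_log_response"])]
    if df.empty:
        raise ValueError("no usable peak entries after QC filtering")

    grp = df.groupby(["cell_id", "concentration_nM"])["peak_log_response"]
    df = df.assign(
        residual=df["peak_log_response"] - grp.transform("mean"),
        group_size=grp.transform("size"),
    )
    n_small = int((df["group_size"] < min_replicates).sum())
    if n_small:
        warnings.warn(
            f"dropping {n_small} entries in groups with < {min_replicates} replicates",
            stacklevel=2,
        )
    return df[df["group_size"] >= min_replicates].reset_index(drop=True)


def _neg_loglik(theta: np.ndarray, x: np.ndarray) -> float:
    sigma, nu = np.exp(theta)
    if not (NU_BOUNDS[0] <= nu <= NU_BOUNDS[1]):
        return np.inf
    return -scaled_t_loglik(x, sigma, nu)


def fit_scaled_t(
    residuals: np.ndarray,
    min_n: int = 50,
    nu_bounds: tuple[float, float] = NU_BOUNDS,
    nu_starts: tuple[float, ...] = (2.0, 5.0, 30.0),
) -> tuple[float, float, float]:
    """Maximum-likelihood scaled-t fit of pooled residuals at one concentration.

    Optimizes the log-likelihood over ``(log sigma, log nu)`` with L-BFGS-B
    from several nu starting points, keeping the best optimum; this is
    deterministic and robust to the flat-likelihood ridge between large-nu
    fits and the Gaussian limit.

    Returns ``(sigma, nu, loglik)``.  Raises ``ValueError`` when there are too
    few residuals and ``RuntimeError`` when no start converges.
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} residuals, got {x.size}")
    spread = np.median(np.abs(x - np.median(x)))
    if spread <= 0:
        warnings.warn("degenerate (zero-spread) residuals; scale pinned near zero", stacklevel=2)
        return 1e-12, float(nu_starts[-1]), scaled_t_loglik(np.zeros(1), 1e-12, nu_starts[-1])

    log_nu_lo, log_nu_hi = np.log(nu_bounds[0]), np.log(nu_bounds[1])
    best: tuple[float, float, float] | None = None
    for nu0 in nu_starts:
        # MAD-based scale start; t MAD ~= sigma for moderate nu
        theta0 = np.array([np.log(spread), np.clip(np.log(nu0), log_nu_lo, log_nu_hi)])
        res = optimize.minimize(
            _neg_loglik,
            theta0,
            args=(x,),
            method="L-BFGS-B",
            bounds=[(np.log(spread) - 12.0, np.log(spread) + 12.0), (log_nu_lo, log_nu_hi)],
        )
        if not res.success or not np.isfinite(res.fun):
            continue
        sigma, nu = np.exp(res.x)
        if best is None or -res.fun > best[2]:
            best = (float(sigma), float(nu), float(-res.fun))
    if best is None:
        raise RuntimeError("scaled-t fit failed to converge from all starts")
    return best


def fit_noise_params(
    peaks: pd.DataFrame, min_n: int = 50, nu_bounds: tuple[float, float] = NU_BOUNDS
) -> NoiseParams:
    """Fit per-concentration noise by pooling residuals across cells."""
    res = compute_residuals(peaks)
    concs, sigmas, nus, logliks, ns = [], [], [], [], []
    for c, sub in res.groupby("concentration_nM"):
        x = sub["residual"].to_numpy()
        try:
            sigma, nu, ll = fit_scaled_t(x, min_n=min_n, nu_bounds=nu_bounds)
        except (ValueError, RuntimeError) as exc:
            logger.warning("noise fit skipped at %s nM: %s", c, exc)
            continue
        concs.append(float(c))
        sigmas.append(sigma)
        nus.append(nu)
        logliks.append(ll)
        ns.append(int(x.size))
    if not concs:
        raise RuntimeError("noise fit failed at every concentration")
    return NoiseParams(
        concentrations_nM=tuple(concs),
        sigma=tuple(sigmas),
        nu=tuple(nus),
        loglik=tuple(logliks),
        n=tuple(ns),
    )


def diagnose_fit(residuals: np.ndarray, sigma: float, nu: float, n_quantiles: int = 19) -> dict:
    """Goodness-of-fit diagnostics for one concentration's residual pool.

    Reports sample skewness and excess kurtosis, a quantile-quantile table of
    empirical vs fitted scaled-t quantiles, and the log-likelihood difference
    against a Gaussian MLE fit (positive favors the t model).
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    probs = np.linspace(0.05, 0.95, n_quantiles)
    gauss_sd = max(float(np.std(x)), 1e-300)
    out = {
        "n": int(x.size),
        "skewness": float(stats.skew(x)),
        "excess_kurtosis": float(stats.kurtosis(x)),
        "qq": {
            "prob": probs.tolist(),
            "empirical": np.quantile(x, probs).tolist(),
            "fitted_t": stats.t.ppf(probs, df=nu, scale=sigma).tolist(),
        },
        "loglik_t": scaled_t_loglik(x, sigma, nu),
        "loglik_gaussian": float(np.sum(stats.norm.logpdf(x, loc=0.0, scale=gauss_sd))),
    }
    out["loglik_t_minus_gaussian"] = out["loglik_t"] - out["loglik_gaussian"]
    return out
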