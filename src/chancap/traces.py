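"""Peak extraction from single-cell Fura-2 ratio traces.

A recording yields one 340/380 ratio time series per cell at one frame per
second.  The stimulus schedule delivers ``x = N * K`` agonist pulses (35 for
the default seven-concentration, five-replicate protocol), and the analysis
needs exactly one peak height per pulse.  The extraction proceeds in the
order of the original recording workflow:

1. background removal — the baseline rises slowly over the experiment; it is
   estimated by a morphological opening (rolling minimum followed by rolling
   maximum) with a window longer than one pulse period, lightly smoothed,
   and subtracted;
2. peak search — prominent local maxima are detected and aligned to the
   pulse schedule (or to a peak-time template from a representative trace)
   by a robust global time offset; pulses without an independently detected
   maximum — typically the early low-concentration pulses buried in
   background — are extrapolated by projecting the template and flagged;
3. reference selection — a deterministic surrogate for the interactive
   "pick the most representative trace" step: the cell with the most
   independently detected peaks (ties broken by median prominence, then by
   lowest cell id);
4. artifact removal — within each (cell, concentration) replicate group,
   heights deviating from the group median by more than a multiple of the
   median absolute deviation are excluded, which is why some groups end up
   with fewer than K replicates.

Peak heights are converted to natural-log scale (floored at a small fraction
of the trace's maximum corrected amplitude so the log is defined); all
capacities are reported in bits downstream.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .design import StimulusDesign

logger = logging.getLogger(__name__)

LOG_FLOOR_FRACTION = 1e-3
DEFAULT_MAD_THRESHOLD = 5.0


class DetectionError(RuntimeError):
    """Peak detection could not be anchored for a trace."""


class ReferenceSelectionError(RuntimeError):
    """No trace qualifies as the representative (reference) trace."""


def _check_uniform_time(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise ValueError("time spacing not uniform within 1%")
    return med


def remove_background(
    time_s: np.ndarray, ratio: np.ndarray, window_s: float = 151.0
) -> np.ndarray:
    """Subtract the slowly rising baseline from one trace.

    The baseline is estimated by a grey opening (minimum then maximum filter)
    with ``window_s`` exceeding one pulse period, so calcium transients are
    erased while monotone drift is reconstructed exactly, followed by light
    smoothing.  Returns the corrected ratio (same length).
    """
    time_s = np.asarray(time_s, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if not np.all(np.isfinite(ratio)):
        raise ValueError("ratio contains non-finite values")
    dt = _check_uniform_time(time_s)
    win = int(round(window_s / dt))
    if win >= ratio.size:
        raise ValueError(f"background window ({win} frames) longer than trace ({ratio.size})")
    win = max(win, 3)
    baseline = maximum_filter1d(
        minimum_filter1d(ratio, size=win, mode="nearest"), size=win, mode="nearest"
    )
    smooth = max(3, win // 5)
    baseline = uniform_filter1d(baseline, size=smooth, mode="nearest")
    return ratio - baseline


def _prominence_floor(corrected: np.ndarray) -> float:
    # frame-to-frame noise scale; transients vary slowly at 1 frame/s
    noise = 1.4826 * np.median(np.abs(np.diff(corrected))) / math.sqrt(2.0)
    amp = float(np.max(corrected, initial=0.0))
    return max(8.0 * noise, 0.05 * amp, 1e-9)


def _prominent_peaks(
    corrected: np.ndarray, min_prominence: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    if min_prominence is None:
        min_prominence = _prominence_floor(corrected)
    idx, props = find_peaks(corrected, prominence=min_prominence)
    return idx, props["prominences"]


def _align_offset(
    peak_times: np.ndarray, base_times: np.ndarray, t_max: float, period_s: float
) -> float:
    """Robust global time offset mapping scheduled times onto detected peaks."""
    off_hi = max(t_max - base_times[-1], period_s)
    candidates = np.arange(0.0, off_hi + 1.0, 1.0)
    tol = 0.25 * period_s
    best = (-1, np.inf, 0.0)
    for off in candidates:
        proj = base_times + off
        d = np.abs(peak_times[:, None] - proj[None, :]).min(axis=1)
        hits = int(np.sum(d < tol))
        resid = float(np.mean(d[d < tol])) if hits else np.inf
        if hits > best[0] or (hits == best[0] and resid < best[1]):
            best = (hits, resid, off)
    n_hits, _, off = best
    if n_hits < 2:
        raise DetectionError("fewer than 2 prominent peaks align with the schedule")
    # refine: median residual of matched peaks
    proj = base_times + off
    j = np.abs(peak_times[:, None] - proj[None, :]).argmin(axis=1)
    d = peak_times - proj[j]
    matched = np.abs(d) < tol
    return float(off + np.median(d[matched]))


def detect_peaks(
    time_s: np.ndarray,
    corrected: np.ndarray,
    design: StimulusDesign,
    reference_times: np.ndarray | None = None,
    min_prominence: float | None = None,
    window_s: float = 15.0,
) -> pd.DataFrame:
    """Locate one peak per scheduled pulse on a background-corrected trace.

    Prominent maxima anchor a global time offset between the pulse schedule
    (or the ``reference_times`` template) and the trace; every pulse then
    gets a record whose height is the local maximum of the corrected trace
    in a ``+/- window_s`` window around its projected time.  Pulses without
    a nearby independently detected maximum are flagged ``extrapolated``.

    Raises :class:`DetectionError` when fewer than two prominent peaks can
    anchor the template.
    """
    time_s = np.asarray(time_s, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    dt = _check_uniform_time(time_s)
    x = design.n_pulses

    if reference_times is not None:
        base = np.asarray(reference_times, dtype=float)
        if base.size != x:
            raise ValueError("reference template must have one time per pulse")
        base = base - base[0]
    else:
        base = design.pulse_onsets_s()

    idx, prom = _prominent_peaks(corrected, min_prominence)
    if idx.size < 2:
        raise DetectionError("fewer than 2 prominent peaks; template unanchorable")
    peak_times = time_s[idx]
    # crop at the right: ignore anything after the post-stimulation zone
    offset = _align_offset(peak_times, base, float(time_s[-1]), design.period_s)
    proj = base + offset

    records = []
    half = max(int(round(window_s / dt)), 1)
    for p in range(x):
        center = int(round((proj[p] - time_s[0]) / dt))
        lo = max(center - half, 0)
        hi = min(center + half + 1, corrected.size)
        if lo >= hi:
            raise DetectionError(f"projected pulse {p + 1} falls outside the trace")
        seg = corrected[lo:hi]
        m = int(np.argmax(seg))
        detected = bool(np.any(np.abs(peak_times - proj[p]) <= window_s))
        records.append(
            {
                "pulse_index": p + 1,
                "time_s": float(time_s[lo + m]),
                "height": float(seg[m]),
                "qc_flag": "ok" if detected else "extrapolated",
            }
        )
    return pd.DataFrame.from_records(records)


def select_reference_trace(
    traces: pd.DataFrame,
    design: StimulusDesign,
    window_s: float = 151.0,
    min_detected_fraction: float = 0.5,
) -> object:
    """Deterministic stand-in for the manual representative-trace choice.

    Scores every cell by (number of independently detected prominent peaks
    that align with the schedule, median peak prominence) and returns the
    best cell id, ties broken by the lowest id.  Fails when no cell detects
    at least ``min_detected_fraction`` of the expected pulses.
    """
    x = design.n_pulses
    scores = []
    for cell_id, sub in traces.groupby("cell_id"):
        sub = sub.sort_values("time_s")
        try:
            corrected = remove_background(
                sub["time_s"].to_numpy(), sub["ratio"].to_numpy(), window_s=window_s
            )
            peaks = detect_peaks(sub["time_s"].to_numpy(), corrected, design)
        except (DetectionError, ValueError):
            continue
        n_ok = int((peaks["qc_flag"] == "ok").sum())
        idx, prom = _prominent_peaks(corrected)
        med_prom = float(np.median(prom)) if prom.size else 0.0
        scores.append((n_ok, med_prom, cell_id))
    qualifying = [s for s in scores if s[0] >= min_detected_fraction * x]
    if not qualifying:
        raise ReferenceSelectionError(
            "no trace detects enough peaks to serve as reference; "
            "select one manually (e.g. the --reference CLI flag)"
        )
    qualifying.sort(key=lambda s: (-s[0], -s[1], s[2]))
    return qualifying[0][2]


def remove_artifacts(
    peaks: pd.DataFrame, mad_threshold: float = DEFAULT_MAD_THRESHOLD
) -> pd.DataFrame:
    """Flag within-group outlier peaks as recording artifacts.

    Within each (cell, concentration) replicate group of size >= 3, entries
    whose log height deviates from the group median by more than
    ``mad_threshold`` times the group median absolute deviation are flagged
    ``artifact_removed`` (their ``peak_log_response`` is kept for audit but
    excluded from all downstream statistics).  Groups of fewer than 3
    replicates cannot support the test and pass through with a log notice.
    """
    df = peaks.copy()
    flagged = np.zeros(len(df), dtype=bool)
    for (cell, conc), sub in df.groupby(["cell_id", "concentration_nM"]):
        vals = sub["peak_log_response"].to_numpy()
        if vals.size < 3:
            logger.info(
                "group (cell=%s, %.4g nM): %d replicates, artifact test skipped",
                cell,
                conc,
                vals.size,
            )
            continue
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        outlier = np.abs(vals - med) > mad_threshold * max(mad, 1e-12)
        if outlier.all():
            warnings.warn(
                f"group (cell={cell}, {conc:.4g} nM): all replicates flagged; group dropped",
                stacklevel=2,
            )
        flagged[df.index.get_indexer(sub.index)] = outlier
    df.loc[flagged, "qc_flag"] = "artifact_removed"
    return df


def extract_peak_table(
    traces: pd.DataFrame,
    design: StimulusDesign,
    reference: object | None = None,
    window_s: float = 151.0,
    mad_threshold: float = DEFAULT_MAD_THRESHOLD,
    log_floor_fraction: float = LOG_FLOOR_FRACTION,
) -> pd.DataFrame:
    """Full trace-to-peak-table pipeline for a set of traces.

    Runs background removal, template-aligned peak detection (using the
    automatically selected or user-supplied ``reference`` cell's peak times)
    and artifact removal, and returns the standard peak table with natural-
    log peak heights.  Cells whose trace cannot be anchored are skipped with
    a warning.
    """
    if reference is None:
        reference = select_reference_trace(traces, design, window_s=window_s)
    ref_sub = traces[traces["cell_id"] == reference].sort_values("time_s")
    if ref_sub.empty:
        raise ValueError(f"reference cell {reference!r} not present in the trace set")
    ref_corr = remove_background(
        ref_sub["time_s"].to_numpy(), ref_sub["ratio"].to_numpy(), window_s=window_s
    )
    ref_peaks = detect_peaks(ref_sub["time_s"].to_numpy(), ref_corr, design)
    ref_times = ref_peaks["time_s"].to_numpy()

    k_rep = design.n_replicates
    rows = []
    for cell_id, sub in traces.groupby("cell_id"):
        sub = sub.sort_values("time_s")
        t = sub["time_s"].to_numpy()
        try:
            corrected = remove_background(t, sub["ratio"].to_numpy(), window_s=window_s)
            peaks = detect_peaks(t, corrected, design, reference_times=ref_times)
        except (DetectionError, ValueError) as exc:
            warnings.warn(f"cell {cell_id!r} skipped: {exc}", stacklevel=2)
            continue
        floor = log_floor_fraction * max(float(np.max(corrected)), 1e-12)
        for rec in peaks.itertuples():
            p = rec.pulse_index
            rows.append(
                {
                    "cell_id": cell_id,
                    "experiment_id": 0,
                    "concentration_nM": float(design.pulse_index_to_concentration(p)),
                    "replicate": (p - 1) % k_rep + 1,
                    "pulse_index": p,
                    "peak_log_response": math.log(max(rec.height, floor)),
                    "qc_flag": rec.qc_flag if rec.height > floor else "extrapolated",
                }
            )
    if not rows:
        raise DetectionError("peak extraction failed for every cell")
    return remove_artifacts(pd.DataFrame(rows), mad_threshold=mad_threshold)
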