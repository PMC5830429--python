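"""Stimulus designs for repeated-pulse agonist experiments.

A stimulus design is the input alphabet of the signaling channel: an ordered
list of agonist concentrations, each delivered as a short perfusion pulse and
repeated a fixed number of times, in ascending concentration order (ascending
order minimizes carry-over and keeps desensitization roughly monotone in
time).  The default reproduces the seven-point acetylcholine protocol used
throughout this package: 100 nM .. 10 uM, five 10-s pulses per concentration
with a 110-s wash in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

#: Default acetylcholine concentrations (nM), ascending.
DEFAULT_CONCENTRATIONS_NM = (100.0, 250.0, 500.0, 750.0, 1500.0, 3000.0, 10000.0)


@dataclass(frozen=True)
class StimulusDesign:
    """Ordered agonist pulse schedule.

    Parameters
    ----------
    concentrations_nM
        Tested agonist concentrations in nM, strictly increasing, > 0.
    n_replicates
        Number of consecutive pulses (replicates) per concentration, ``K``.
    pulse_duration_s
        Duration of each agonist pulse in seconds.
    gap_s
        Wash-out gap between consecutive pulses in seconds.
    """

    concentrations_nM: tuple[float, ...] = DEFAULT_CONCENTRATIONS_NM
    n_replicates: int = 5
    pulse_duration_s: float = 10.0
    gap_s: float = 110.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        if c.size < 2:
            raise ValueError("need at least two concentrations")
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("concentrations must be finite and positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.pulse_duration_s <= 0 or self.gap_s <= 0:
            raise ValueError("pulse timing must be positive")
        object.__setattr__(self, "concentrations_nM", tuple(float(x) for x in c))

    @property
    def n_concentrations(self) -> int:
        return len(self.concentrations_nM)

    @property
    def n_pulses(self) -> int:
        """Total pulse count x = N * K (35 for the default protocol)."""
        return self.n_concentrations * self.n_replicates

    @property
    def period_s(self) -> float:
        """Pulse-to-pulse period (stimulation plus wash)."""
        return self.pulse_duration_s + self.gap_s

    def pulse_onsets_s(self, start_s: float = 0.0) -> np.ndarray:
        """Onset time of every pulse, in schedule order."""
        return start_s + self.period_s * np.arange(self.n_pulses, dtype=float)

    def pulse_concentrations(self) -> np.ndarray:
        """Concentration (nM) of every pulse: K repeats of c1, then c2, ..."""
        return np.repeat(np.asarray(self.concentrations_nM), self.n_replicates)

    def pulse_index_to_concentration(self, pulse_index: np.ndarray) -> np.ndarray:
        """Map 1-based global pulse index to its concentration (nM)."""
        idx = np.asarray(pulse_index, dtype=int) - 1
        if np.any(idx < 0) or np.any(idx >= self.n_pulses):
            raise ValueError("pulse_index out of range")
        return self.pulse_concentrations()[idx]

    def to_dict(self) -> dict:
        return {
            "concentrations_nM": list(self.concentrations_nM),
            "n_replicates": self.n_replicates,
            "pulse_duration_s": self.pulse_duration_s,
            "gap_s": self.gap_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusDesign":
        return cls(
            concentrations_nM=tuple(d["concentrations_nM"]),
            n_replicates=int(d.get("n_replicates", 5)),
            pulse_duration_s=float(d.get("pulse_duration_s", 10.0)),
            gap_s=float(d.get("gap_s", 110.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StimulusDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
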