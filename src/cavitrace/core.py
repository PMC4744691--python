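"""Domain types shared across the package.

Sign convention: water potential (Ψ) is stored *signed*, in MPa, so values
are ≤ 0 under tension (e.g. -3.5 MPa).  Tension magnitudes (positive MPa)
are used only inside the Weibull arithmetic and in the cross-method
regression, where helpers expose the magnitude view explicitly.

Time is stored in seconds internally; the 1-min analysis grid used for
acoustic activity is built downstream in :mod:`cavitrace.activity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AEHit",
    "AESeries",
    "PsiSeries",
    "RateSeries",
    "VulnMeasurement",
    "SpeciesSummary",
    "plc_from_conductivity",
]


@dataclass(frozen=True)
class AEHit:
    """A single acoustic-emission hit.

    Parameters
    ----------
    time_s : float
        Seconds since the start of the recording (≥ 0).
    amplitude_db : float
        Peak amplitude in dB (sensor range 0–120 dB).
    energy : float, optional
        Arbitrary-unit signal energy, if the acquisition system exported it.
    """

    time_s: float
    amplitude_db: float
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"hit time must be >= 0, got {self.time_s}")
        if not (0.0 <= self.amplitude_db <= 120.0):
            raise ValueError(
                f"amplitude must be in [0, 120] dB, got {self.amplitude_db}"
            )


@dataclass
class AESeries:
    """An ordered stream of AE hits from one dehydrating sample."""

    hits: list[AEHit]
    sample_id: str = ""
    t_end_s: Optional[float] = None

    def __post_init__(self) -> None:
        times = [h.time_s for h in self.hits]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("hits must be sorted by time (nondecreasing)")
        last = times[-1] if times else 0.0
        if self.t_end_s is None:
            self.t_end_s = last
        elif self.t_end_s < last:
            raise ValueError(
                f"t_end_s={self.t_end_s} precedes last hit at {last} s"
            )

    def __len__(self) -> int:
        return len(self.hits)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([h.time_s for h in self.hits], dtype=float)

    @property
    def amplitudes_db(self) -> np.ndarray:
        return np.array([h.amplitude_db for h in self.hits], dtype=float)


@dataclass
class PsiSeries:
    """Sparse pressure-chamber water-potential readings over time.

    ``readings`` is a list of ``(time_s, psi_mpa)`` or
    ``(time_s, psi_mpa, se_mpa)`` tuples with Ψ signed (≤ 0).
    """

    readings: list[tuple]

    def __post_init__(self) -> None:
        times = [r[0] for r in self.readings]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("Ψ readings must be ordered by time")
        for r in self.readings:
            if r[1] > 0:
                raise ValueError(
                    f"signed Ψ must be <= 0 MPa, got {r[1]} (use the "
                    "magnitude-convention flag when reading such files)"
                )

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([r[0] for r in self.readings], dtype=float)

    @property
    def psi_mpa(self) -> np.ndarray:
        return np.array([r[1] for r in self.readings], dtype=float)

    @property
    def psi_magnitude_mpa(self) -> np.ndarray:
        """Tension-magnitude view of the readings (positive MPa)."""
        return -self.psi_mpa


@dataclass
class RateSeries:
    """Acoustic activity on a regular 1-min grid.

    ``raw_rate`` is hits·min⁻¹ obtained by window averaging;
    ``smoothed_rate`` is the Savitzky–Golay filtered version.
    """

    grid_times_min: np.ndarray
    raw_rate: np.ndarray
    smoothed_rate: Optional[np.ndarray] = None
    window_min: float = 15.0
    sg_order: Optional[int] = None
    sg_window: Optional[int] = None

    def __post_init__(self) -> None:
        self.grid_times_min = np.asarray(self.grid_times_min, dtype=float)
        self.raw_rate = np.asarray(self.raw_rate, dtype=float)
        if self.grid_times_min.shape != self.raw_rate.shape:
            raise ValueError("grid and raw_rate must have equal length")
        if len(self.grid_times_min) > 1:
            steps = np.diff(self.grid_times_min)
            if not np.allclose(steps, 1.0):
                raise ValueError("grid spacing must be exactly 1 min")
        if np.any(self.raw_rate < 0):
            raise ValueError("raw_rate must be nonnegative")
        if self.smoothed_rate is not None:
            self.smoothed_rate = np.asarray(self.smoothed_rate, dtype=float)
            if self.smoothed_rate.shape != self.raw_rate.shape:
                raise ValueError("smoothed_rate must match raw_rate length")


@dataclass(frozen=True)
class VulnMeasurement:
    """One destructive hydraulic measurement: Ψ and percent loss of
    conductivity (PLC)."""

    psi_mpa: float
    plc_percent: float
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.psi_mpa > 0:
            raise ValueError(f"signed Ψ must be <= 0, got {self.psi_mpa}")
        if not (0.0 <= self.plc_percent <= 100.0):
            raise ValueError(
                f"PLC must lie in [0, 100] after clipping, got {self.plc_percent}"
            )


@dataclass
class SpeciesSummary:
    """Species-level hydraulic (P50) and acoustic (P_maxrate) summary.

    Mirrors the columns of a published species table: means, 95% CIs and
    sample sizes for both parameters, plus the clade.  CIs are absent
    (None) where n < 3.
    """

    species: str
    p50_mpa: float
    p50_ci_lo: Optional[float] = None
    p50_ci_hi: Optional[float] = None
    n_p50: Optional[int] = None
    pmaxrate_mpa: Optional[float] = None
    pmax_ci_lo: Optional[float] = None
    pmax_ci_hi: Optional[float] = None
    n_pmax: Optional[int] = None
    clade: str = "angiosperm"

    def __post_init__(self) -> None:
        if self.clade not in ("angiosperm", "gymnosperm"):
            raise ValueError(f"clade must be angiosperm|gymnosperm, got {self.clade}")
        for lo, mean, hi, what in (
            (self.p50_ci_lo, self.p50_mpa, self.p50_ci_hi, "P50"),
            (self.pmax_ci_lo, self.pmaxrate_mpa, self.pmax_ci_hi, "P_maxrate"),
        ):
            if lo is not None and hi is not None and mean is not None:
                if not (lo <= mean <= hi):
                    raise ValueError(
                        f"{what} CI ({lo}, {hi}) does not bracket mean {mean}"
                    )


def plc_from_conductivity(k_native: float, k_max: float) -> float:
    """Percent loss of conductivity, ``100 * (1 - k_native / k_max)``.

    ``k_max`` is the conductivity after flushing out embolism; ``k_native``
    the conductivity before.  Noisy flow ratios occasionally put the raw
    value outside [0, 100]; such values are clipped with a warning, since
    curve fitting requires bounded PLC.
    """
    if k_max <= 0:
        raise ValueError(f"k_max must be > 0, got {k_max}")
    if k_native < 0:
        raise ValueError(f"k_native must be >= 0, got {k_native}")
    plc = 100.0 * (1.0 - k_native / k_max)
    if plc < 0.0 or plc > 100.0:
        warnings.warn(
            f"PLC {plc:.2f}% outside [0, 100]; clipped (noisy flow ratio)",
            stacklevel=2,
        )
        plc = float(np.clip(plc, 0.0, 100.0))
    return plc
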