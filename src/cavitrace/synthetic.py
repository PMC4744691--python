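"""Synthetic dehydration experiments with known ground truth.

The generative model mirrors how an AE dehydration run is understood
physically:

* Each of ``n_conduits`` xylem conduits carries a cavitation threshold Ψᵢ
  drawn from the distribution whose CDF is the true vulnerability curve,
  PLC(Ψ)/100 (inverse-CDF sampling).  A conduit emits exactly one AE hit
  at the first time the declining water potential reaches its threshold —
  cavitation of a conduit, large or small, produces one event.
* Non-conduit AE (fibres, rays, shrinkage micro-fracturing) continues and
  intensifies late in dehydration.  It is modelled as an inhomogeneous
  Poisson process whose intensity rises with a logistic onset once Ψ
  drops below ``noise_onset_mpa`` — an empirical stand-in, not a
  mechanistic source model.
* Hit amplitudes are drawn from a normal truncated to the sensor range;
  they matter only to exercise the amplitude filter.
* The branch dries along Ψ(t) = Ψ_min + (Ψ₀ − Ψ_min)·exp(−t/τ) by
  default (benchtop drying decelerates), or along a piecewise-linear
  trajectory when ``psi_knots`` is given — the linear option supports
  constant-rate analytic checks.
* Pressure-chamber readings are taken at a fixed interval with Gaussian
  reading error.

The truth record carries the generating parameters and the analytic mode
of the cavitation-threshold density, which is what the activity peak
estimates under constant-rate drying.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import truncnorm

from .core import AEHit, AESeries, PsiSeries, SpeciesSummary, VulnMeasurement
from .vulnerability import psi_at_plc, weibull_plc

__all__ = [
    "SimConfig",
    "SimTruth",
    "threshold_density_mode",
    "simulate_dehydration",
    "simulate_hydraulic_dataset",
    "simulate_species_panel",
]

AMP_TRUNC_LO_DB = 35.0
AMP_TRUNC_HI_DB = 99.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dehydration experiment.

    Defaults describe a typical mid-vulnerability temperate angiosperm
    branch dried on the bench over roughly two days: P50 = -3.5 MPa (the
    panel-wide mean), a moderate slope of 30% PLC per MPa, a few thousand
    cavitation-capable conduits in sensor range, Ψ relaxing from -0.5
    toward -9 MPa with a 10-h time constant, late-stage noise switching on
    around -6 MPa, and pressure-chamber readings every 30 min with
    0.05 MPa reading error.
    """

    p50_true_mpa: float = -3.5
    sx_true: float = 30.0
    x: float = 50.0
    n_conduits: int = 5000
    # Ψ trajectory: exponential plateau, or piecewise-linear via psi_knots
    psi0_mpa: float = -0.5
    psi_min_mpa: float = -9.0
    tau_min: float = 600.0
    psi_knots: Optional[tuple[tuple[float, float], ...]] = None
    t_end_min: Optional[float] = None
    # late-stage (non-conduit) AE
    noise_rate_max: float = 2.0  # hits per minute, asymptotic
    noise_onset_mpa: float = -6.0
    noise_width_mpa: float = 0.5
    # amplitudes
    amp_mean_db: float = 60.0
    amp_sd_db: float = 10.0
    # Ψ sampling
    psi_reading_interval_min: float = 30.0
    psi_reading_sd_mpa: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.psi_knots is None:
            if not (self.psi_min_mpa < self.psi0_mpa <= 0):
                raise ValueError(
                    f"need psi_min < psi0 <= 0, got {self.psi_min_mpa}, "
                    f"{self.psi0_mpa}"
                )
            if self.tau_min <= 0:
                raise ValueError(f"tau_min must be > 0, got {self.tau_min}")
        if self.n_conduits < 0:
            raise ValueError("n_conduits must be >= 0")
        for name in ("noise_rate_max", "noise_width_mpa", "psi_reading_sd_mpa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- trajectory ---------------------------------------------------

    def psi_of_t(self, t_min):
        """Signed Ψ (MPa) at time t (minutes)."""
        t = np.asarray(t_min, dtype=float)
        if self.psi_knots is not None:
            kt = np.array([k[0] for k in self.psi_knots])
            kv = np.array([k[1] for k in self.psi_knots])
            out = np.interp(t, kt, kv)
        else:
            out = self.psi_min_mpa + (self.psi0_mpa - self.psi_min_mpa) * np.exp(
                -t / self.tau_min
            )
        return out if out.ndim else float(out)

    def time_at_psi(self, psi_mpa: float) -> float:
        """First time (min) at which Ψ(t) <= ``psi_mpa``; inf if never."""
        if self.psi_knots is not None:
            kt = np.array([k[0] for k in self.psi_knots])
            kv = np.array([k[1] for k in self.psi_knots])
            if psi_mpa > kv[0]:
                return 0.0
            if psi_mpa < kv.min():
                return np.inf
            # Ψ nonincreasing along knots; invert by interpolation
            return float(np.interp(psi_mpa, kv[::-1], kt[::-1]))
        if psi_mpa >= self.psi0_mpa:
            return 0.0
        if psi_mpa <= self.psi_min_mpa:
            return np.inf
        frac = (psi_mpa - self.psi_min_mpa) / (self.psi0_mpa - self.psi_min_mpa)
        return float(-self.tau_min * np.log(frac))

    def duration_min(self) -> float:
        """Recording length: explicit ``t_end_min``, else the time for the
        trajectory to come within 0.05 MPa of its floor (capped at 10 τ),
        or the last knot of a piecewise-linear trajectory."""
        if self.t_end_min is not None:
            return float(self.t_end_min)
        if self.psi_knots is not None:
            return float(self.psi_knots[-1][0])
        t = self.time_at_psi(self.psi_min_mpa + 0.05)
        return float(min(t, 10.0 * self.tau_min))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated run."""

    p50_true_mpa: float
    sx_true: float
    threshold_mode_psi_mpa: float  # mode of the cavitation-threshold density
    expected_peak_time_min: float  # argmax of cavitation hit intensity
    expected_peak_psi_mpa: float  # Ψ at that time
    n_cavitation: int
    n_noise: int


def threshold_density_mode(px_mpa: float, sx: float, x: float = 50.0) -> float:
    """Signed Ψ at the mode of the cavitation-threshold density.

    The threshold CDF is PLC(Ψ)/100; differentiating the Weibull form in
    tension magnitude P gives a density proportional to
    ``u**(c-1) * exp(L0 * u**c)`` with ``u = P/Px``, ``c = Px*Sx/V`` and
    ``L0 = ln(1 - x/100)``, whose maximum is at
    ``u* = ((c-1) / (-L0 * c))**(1/c)`` for c > 1 (and at P = 0 for
    c <= 1, a monotone-decreasing density).
    """
    px = abs(px_mpa)
    v = (x - 100.0) * np.log(1.0 - x / 100.0)
    c = px * sx / v
    if c <= 1.0:
        return 0.0
    l0 = np.log(1.0 - x / 100.0)
    u_star = ((c - 1.0) / (-l0 * c)) ** (1.0 / c)
    return -float(px * u_star)


def _expected_peak_time(config: SimConfig) -> tuple[float, float]:
    """Argmax over t of the cavitation hit intensity f(Ψ(t))·|dΨ/dt|,
    located numerically on a fine grid plus local refinement."""
    t_end = config.duration_min()
    grid = np.linspace(0.0, t_end, 4001)
    psi = np.asarray(config.psi_of_t(grid))
    # hit intensity = d/dt F(Ψ(t)) with F the threshold CDF (PLC/100)
    cdf = weibull_plc(psi, config.p50_true_mpa, config.sx_true, config.x) / 100.0
    intensity = np.gradient(cdf, grid)
    i = int(np.argmax(intensity))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]

    def neg_intensity(t: float) -> float:
        h = max(t_end * 1e-6, 1e-6)
        f0 = weibull_plc(
            config.psi_of_t(max(t - h, 0.0)), config.p50_true_mpa, config.sx_true, config.x
        )
        f1 = weibull_plc(
            config.psi_of_t(min(t + h, t_end)), config.p50_true_mpa, config.sx_true, config.x
        )
        return -(f1 - f0)

    if hi > lo:
        res = minimize_scalar(neg_intensity, bounds=(lo, hi), method="bounded")
        t_peak = float(res.x)
    else:
        t_peak = float(grid[i])
    return t_peak, float(config.psi_of_t(t_peak))


def simulate_dehydration(
    config: SimConfig, seed: Optional[int] = None
) -> tuple[AESeries, PsiSeries, SimTruth]:
    """Generate one dehydration run: AE hit stream, Ψ readings, truth.

    ``seed`` overrides ``config.seed``; the same seed reproduces the run
    bit-exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t_end = config.duration_min()

    # cavitation component: one hit per conduit at threshold crossing
    u = rng.random(config.n_conduits)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    # vectorised inverse CDF of the Weibull threshold distribution
    px = abs(config.p50_true_mpa)
    v = (config.x - 100.0) * np.log(1.0 - config.x / 100.0)
    c = px * config.sx_true / v
    l0 = np.log(1.0 - config.x / 100.0)
    thresholds = -(px * (np.log(1.0 - u) / l0) ** (1.0 / c))
    if config.n_conduits:
        p99 = psi_at_plc(99.0, config.p50_true_mpa, config.sx_true, config.x)
        if config.time_at_psi(p99) > t_end:
            warnings.warn(
                "incomplete dehydration: the trajectory does not reach the "
                "99th-percentile cavitation threshold; the activity peak may "
                "be truncated",
                stacklevel=2,
            )
    cav_times = np.array([config.time_at_psi(p) for p in thresholds])
    cav_times = cav_times[np.isfinite(cav_times) & (cav_times <= t_end)]

    # late-stage noise: inhomogeneous Poisson by thinning
    noise_times = np.empty(0)
    if config.noise_rate_max > 0:
        n_cand = rng.poisson(config.noise_rate_max * t_end)
        cand = rng.uniform(0.0, t_end, size=n_cand)
        psi_c = np.asarray(config.psi_of_t(cand))
        accept_p = expit(
            (config.noise_onset_mpa - psi_c) / max(config.noise_width_mpa, 1e-9)
        )
        noise_times = cand[rng.random(n_cand) < accept_p]

    times_min = np.sort(np.concatenate([cav_times, noise_times]))
    n_hits = len(times_min)
    a, b = (
        (AMP_TRUNC_LO_DB - config.amp_mean_db) / config.amp_sd_db,
        (AMP_TRUNC_HI_DB - config.amp_mean_db) / config.amp_sd_db,
    )
    amps = truncnorm.rvs(
        a, b, loc=config.amp_mean_db, scale=config.amp_sd_db, size=n_hits,
        random_state=rng,
    )
    hits = [
        AEHit(time_s=float(t * 60.0), amplitude_db=float(amp))
        for t, amp in zip(times_min, amps)
    ]
    series = AESeries(hits=hits, sample_id="synthetic", t_end_s=t_end * 60.0)

    # pressure-chamber readings
    read_times = np.arange(0.0, t_end + 1e-9, config.psi_reading_interval_min)
    if read_times[-1] < t_end:
        read_times = np.append(read_times, t_end)
    psi_true = np.asarray(config.psi_of_t(read_times))
    psi_obs = np.minimum(
        psi_true + rng.normal(0.0, config.psi_reading_sd_mpa, size=len(read_times)),
        0.0,
    )
    psi_series = PsiSeries(
        readings=[
            (float(t * 60.0), float(p), config.psi_reading_sd_mpa)
            for t, p in zip(read_times, psi_obs)
        ]
    )

    t_peak, psi_peak = _expected_peak_time(config)
    truth = SimTruth(
        p50_true_mpa=config.p50_true_mpa,
        sx_true=config.sx_true,
        threshold_mode_psi_mpa=threshold_density_mode(
            config.p50_true_mpa, config.sx_true, config.x
        ),
        expected_peak_time_min=t_peak,
        expected_peak_psi_mpa=psi_peak,
        n_cavitation=len(cav_times),
        n_noise=len(noise_times),
    )
    return series, psi_series, truth


def simulate_hydraulic_dataset(
    config: SimConfig,
    psi_levels: Sequence[float],
    n_per_level: int = 1,
    plc_noise_sd: float = 5.0,
    seed: Optional[int] = None,
) -> list[VulnMeasurement]:
    """Destructive-style vulnerability data from the true curve.

    PLC at each Ψ level is the true Weibull value plus Gaussian noise,
    clipped to [0, 100] — emulating pooled benchtop measurements.
    """
    if len(psi_levels) == 0:
        raise ValueError("psi_levels must be nonempty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for psi in psi_levels:
        true_plc = weibull_plc(psi, config.p50_true_mpa, config.sx_true, config.x)
        for _ in range(n_per_level):
            plc = float(
                np.clip(true_plc + rng.normal(0.0, plc_noise_sd), 0.0, 100.0)
            )
            out.append(VulnMeasurement(psi_mpa=float(psi), plc_percent=plc))
    return out


def simulate_species_panel(
    n_species: int = 18,
    p50_range: tuple[float, float] = (-6.5, -1.5),
    offset_model: tuple[float, float, float] = (1.2, -0.1, 0.5),
    seed: Optional[int] = None,
    gymnosperm_fraction: float = 1.0 / 6.0,
) -> list[SpeciesSummary]:
    """A synthetic species panel for end-to-end regression tests.

    Species P50 values are uniform over ``p50_range`` (signed MPa).  In
    tension-magnitude space, |P_maxrate| = a·|P50| + b + N(0, sd) with
    ``offset_model = (a, b, sd)``, so :func:`compare_methods` should
    recover (a, b).
    """
    if n_species < 3:
        raise ValueError("need n_species >= 3")
    a, b, noise_sd = offset_model
    rng = np.random.default_rng(seed)
    lo, hi = min(p50_range), max(p50_range)
    p50 = rng.uniform(lo, hi, size=n_species)
    pmx_mag = a * np.abs(p50) + b + rng.normal(0.0, noise_sd, size=n_species)
    pmx_mag = np.maximum(pmx_mag, 0.05)
    n_gym = int(round(gymnosperm_fraction * n_species))
    out = []
    for i in range(n_species):
        out.append(
            SpeciesSummary(
                species=f"sim_species_{i:02d}",
                clade="gymnosperm" if i >= n_species - n_gym else "angiosperm",
                p50_mpa=float(p50[i]),
                n_p50=5,
                pmaxrate_mpa=-float(pmx_mag[i]),
                n_pmax=4,
            )
        )
    return out
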