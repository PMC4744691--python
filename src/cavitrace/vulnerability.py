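"""Weibull vulnerability-curve fitting and confidence intervals.

The curve is the reparameterised Weibull in which the parameters are
directly the quantities of interest: ``Px``, the water potential at x%
loss of conductivity, and ``Sx``, the slope of the PLC curve at ``Px`` in
% per MPa.  Writing P for the tension magnitude (P = |Ψ|, positive MPa),

    relK(P) = (1 - x/100) ** ((P / Px) ** (Px * Sx / V)),
    V       = (x - 100) * ln(1 - x/100),
    PLC(P)  = 100 * (1 - relK(P)),

so that PLC(Px) = x holds exactly for any parameter values and
d PLC / dP evaluated at Px equals Sx.  The classic two-parameter form
relK = exp(-(P/b)**c) is recovered by

    c = Px * Sx / V,   b = Px * (-ln(1 - x/100)) ** (-1/c).

Two species-level workflows are supported, matching how destructive and
non-destructive datasets differ: pooled data from benchtop drying are fit
once and bootstrapped (case resampling, percentile CI), while centrifuge
data allow per-sample fits whose parameters are averaged with a normal
CI (mean ± 1.96·SE, no CI below n = 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import VulnMeasurement

__all__ = [
    "VCFit",
    "weibull_plc",
    "psi_at_plc",
    "weibull_to_classic",
    "classic_to_weibull",
    "fit_vulnerability",
    "bootstrap_ci",
    "mean_ci",
    "aggregate_fits",
]


@dataclass
class VCFit:
    """A fitted vulnerability curve.

    ``px_mpa`` is signed (negative); ``sx`` is the slope at Px in % PLC
    per MPa (positive).  ``ci_lo``/``ci_hi`` are the 95% CI of ``px_mpa``,
    absent (None) when not computable.
    """

    x: float
    px_mpa: float
    sx: float
    residual_sse: float
    n_points: int
    ci_lo: Optional[float] = None
    ci_hi: Optional[float] = None
    method: str = "pooled_bootstrap"
    n_boot_failed: int = 0
    sample_id: Optional[str] = None

    def plc(self, psi_mpa) -> np.ndarray:
        """Evaluate the fitted curve at signed Ψ."""
        return weibull_plc(psi_mpa, self.px_mpa, self.sx, self.x)

    def psi_at(self, plc_percent: float) -> float:
        """Signed Ψ at an arbitrary PLC level (e.g. P12, P88)."""
        return psi_at_plc(plc_percent, self.px_mpa, self.sx, self.x)


def _check_params(px_mpa: float, sx: float, x: float) -> tuple[float, float]:
    if px_mpa == 0:
        raise ValueError("Px must be nonzero")
    if sx <= 0:
        raise ValueError(f"Sx must be > 0, got {sx}")
    if not (0.0 < x < 100.0):
        raise ValueError(f"x must lie strictly in (0, 100), got {x}")
    v = (x - 100.0) * np.log(1.0 - x / 100.0)  # positive
    return abs(px_mpa), v


def weibull_plc(psi_mpa, px_mpa: float, sx: float, x: float = 50.0):
    """PLC (%) at signed Ψ under the reparameterised Weibull curve."""
    px, v = _check_params(px_mpa, sx, x)
    p = np.abs(np.asarray(psi_mpa, dtype=float))
    c = px * sx / v
    relk = (1.0 - x / 100.0) ** ((p / px) ** c)
    out = 100.0 * (1.0 - relk)
    return out if out.ndim else float(out)


def psi_at_plc(plc_percent: float, px_mpa: float, sx: float, x: float = 50.0) -> float:
    """Signed Ψ at which the curve reaches ``plc_percent`` (inverse of
    :func:`weibull_plc`)."""
    px, v = _check_params(px_mpa, sx, x)
    if not (0.0 < plc_percent < 100.0):
        raise ValueError(f"PLC level must lie in (0, 100), got {plc_percent}")
    c = px * sx / v
    l0 = np.log(1.0 - x / 100.0)
    p = px * (np.log(1.0 - plc_percent / 100.0) / l0) ** (1.0 / c)
    return -float(p)


def weibull_to_classic(px_mpa: float, sx: float, x: float = 50.0) -> tuple[float, float]:
    """Convert (Px, Sx) to the classic Weibull (b, c) with
    relK = exp(-(P/b)^c); b in tension-magnitude MPa."""
    px, v = _check_params(px_mpa, sx, x)
    c = px * sx / v
    b = px * (-np.log(1.0 - x / 100.0)) ** (-1.0 / c)
    return float(b), float(c)


def classic_to_weibull(b: float, c: float, x: float = 50.0) -> tuple[float, float]:
    """Inverse of :func:`weibull_to_classic`; returns signed Px and Sx."""
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be positive")
    l0 = -np.log(1.0 - x / 100.0)
    px = b * l0 ** (1.0 / c)
    v = (x - 100.0) * np.log(1.0 - x / 100.0)
    sx = c * v / px
    return -float(px), float(sx)


def fit_vulnerability(
    data: Sequence[VulnMeasurement],
    x: float = 50.0,
    sample_id: Optional[str] = None,
) -> VCFit:
    """Unweighted nonlinear least squares of PLC on Ψ.

    Starting values: Px₀ is the Ψ of the data point whose PLC is nearest
    ``x``; Sx₀ from a local linear fit of PLC on tension around Px₀.  A
    warning (not an error) is issued when the data do not bracket the x%
    loss level, since the fitted Px is then an extrapolation.
    """
    if len(data) < 4:
        raise ValueError(f"need >= 4 measurements to fit, got {len(data)}")
    p = np.array([abs(m.psi_mpa) for m in data])
    plc = np.array([m.plc_percent for m in data])

    if plc.min() > x or plc.max() < x:
        warnings.warn(
            f"data do not bracket {x:g}% loss (PLC range "
            f"{plc.min():.1f}–{plc.max():.1f}%); Px is extrapolated",
            stacklevel=2,
        )

    i0 = int(np.argmin(np.abs(plc - x)))
    px0 = max(p[i0], 1e-3)
    # local slope around px0 in % per MPa
    order = np.argsort(p)
    ps, plcs = p[order], plc[order]
    k = max(min(5, len(ps)), 2)
    j0 = int(np.searchsorted(ps, px0))
    sl = slice(max(0, j0 - k // 2), min(len(ps), max(0, j0 - k // 2) + k))
    if np.ptp(ps[sl]) > 0:
        sx0 = float(np.polyfit(ps[sl], plcs[sl], 1)[0])
    else:
        sx0 = 25.0
    sx0 = float(np.clip(sx0, 1.0, 500.0))

    def model(pp, px, sx):
        return weibull_plc(-pp, -px, sx, x)

    try:
        popt, _ = curve_fit(
            model,
            p,
            plc,
            p0=[px0, sx0],
            bounds=([1e-4, 1e-3], [50.0, 5e3]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"vulnerability fit did not converge (start Px={-px0:.2f}, "
            f"Sx={sx0:.1f}; n={len(data)}): {exc}"
        ) from exc
    px_hat, sx_hat = popt
    resid = plc - model(p, px_hat, sx_hat)
    return VCFit(
        x=x,
        px_mpa=-float(px_hat),
        sx=float(sx_hat),
        residual_sse=float(np.sum(resid**2)),
        n_points=len(data),
        method="pooled_bootstrap",
        sample_id=sample_id,
    )


def bootstrap_ci(
    data: Sequence[VulnMeasurement],
    x: float = 50.0,
    n_boot: int = 999,
    seed: Optional[int] = None,
) -> tuple[float, float, int]:
    """95% percentile CI of Px by case resampling at the measurement level.

    Returns ``(ci_lo, ci_hi, n_failed)`` on signed Ψ.  Replicates whose
    fit fails to converge are dropped and counted; a warning is attached
    when more than 10% fail.
    """
    fit_vulnerability(data, x=x)  # must succeed on the full data
    rng = np.random.default_rng(seed)
    n = len(data)
    px_vals = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [data[i] for i in idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                px_vals.append(fit_vulnerability(sample, x=x).px_mpa)
        except (RuntimeError, ValueError):
            n_failed += 1
    if n_failed > 0.1 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap replicates failed to converge; "
            "CI may be unreliable",
            stacklevel=2,
        )
    lo, hi = np.percentile(px_vals, [2.5, 97.5])
    return float(lo), float(hi), n_failed


def mean_ci(values: Sequence[float]) -> tuple[float, Optional[float], Optional[float]]:
    """Sample mean with the normal-approximation 95% CI, mean ± 1.96·SE,
    where SE = sd/√n.  The CI is not computed for n < 3 (SE from one or
    two values is not meaningful); the mean is still returned."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mean_ci requires at least one value")
    mean = float(values.mean())
    if values.size < 3:
        return mean, None, None
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    return mean, mean - 1.96 * se, mean + 1.96 * se


def aggregate_fits(fits: Sequence[VCFit]) -> VCFit:
    """Species-level parameters from per-sample fits: mean Px and Sx with
    the normal CI on Px (absent for n < 3)."""
    if len(fits) == 0:
        raise ValueError("no fits to aggregate")
    xs = {f.x for f in fits}
    if len(xs) > 1:
        raise ValueError(f"cannot aggregate fits with different x levels: {xs}")
    px_mean, lo, hi = mean_ci([f.px_mpa for f in fits])
    sx_mean = float(np.mean([f.sx for f in fits]))
    return VCFit(
        x=fits[0].x,
        px_mpa=px_mean,
        sx=sx_mean,
        residual_sse=float(np.sum([f.residual_sse for f in fits])),
        n_points=len(fits),
        ci_lo=lo,
        ci_hi=hi,
        method="per_sample_mean",
    )
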