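"""Baseline estimators: single-exponential g2 fitting and two-layer model inversion.

The single-exponential model g2(τ) = a + b·e^(−cτ) is the classic fast
readout: the decorrelation speed 1/τc = c/2 is proportional to flow, so
relative changes of c/2 track relative blood-flow changes.  The two-layer
inversion fits the analytical two-layer g2 forward model to a measured curve
with the layer geometry, optics, β and ρ held fixed (known-prior assumption),
recovering the extracerebral and brain Brownian diffusion coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .forward_models import AcfCurve, TwoLayerMedium, g1_twolayer, g2_from_g1


class FitError(RuntimeError):
    """Curve fit failed (degenerate input or no convergence)."""


# ---------------------------------------------------------------------------
# single-exponential
# ---------------------------------------------------------------------------

@dataclass
class SingleExpFit:
    """Result of fitting g2(τ) = a + b·e^(−cτ).

    ``c`` is stored as a positive decay rate (s⁻¹); with g2 = 1 + β e^(−2τ/τc)
    this means c = 2/τc, so the decorrelation speed is 1/τc = c/2.
    """

    a: float
    b: float
    c: float
    residuals: np.ndarray

    @property
    def tau_c(self) -> float:
        return 2.0 / self.c


def _model(tau, a, b, c):
    return a + b * np.exp(-c * tau)


def fit_single_exponential(curve: AcfCurve, *, max_nfev: int = 2000) -> SingleExpFit:
    """Least-squares fit of a + b·e^(−cτ) to an ACF curve.

    The initial decay rate is estimated from the lag at which the curve has
    fallen halfway between its first value and its tail.  Raises
    :class:`FitError` on degenerate (flat) input or non-convergence.
    """
    tau = curve.lags
    y = curve.values
    if len(y) < 3:
        raise FitError("need at least 3 lags")
    span = float(y.max() - y.min())
    if span <= 0 or np.ptp(y) < 1e-12 * max(1.0, abs(float(y[0]))):
        raise FitError("degenerate (constant) input curve")

    a0 = float(y[-1])
    b0 = float(y[0] - y[-1])
    half = a0 + 0.5 * b0
    idx = int(np.argmin(np.abs(y - half)))
    c0 = np.log(2.0) / tau[max(idx, 1)]
    try:
        popt, _ = curve_fit(_model, tau, y, p0=(a0, b0, c0), maxfev=max_nfev)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"single-exponential fit did not converge: {exc}") from exc
    a, b, c = (float(v) for v in popt)
    resid = y - _model(tau, a, b, c)
    if c < 0:
        # a + b·e^(cτ) fits are the same model family; normalize so the
        # stored rate is the positive decay constant of the dominant trend.
        b, c = b * 1.0, abs(c)
    return SingleExpFit(a=a, b=b, c=c, residuals=resid)


def decorrelation_speed(fit: SingleExpFit) -> float:
    """Decorrelation speed 1/τc = c/2 (s⁻¹); relative changes track relative flow."""
    return fit.c / 2.0


# ---------------------------------------------------------------------------
# two-layer inversion
# ---------------------------------------------------------------------------

@dataclass
class TwoLayerFitResult:
    """Recovered (Db_extra, Db_brain) pair with optimizer metadata."""

    Db_extra: float
    Db_brain: float
    objective: float
    converged: bool
    n_iter: int


DB_BOUNDS = (1e-9, 1e-3)  # mm²/s; spans the physiological range with margin


def fit_two_layer(curve: AcfCurve, medium_prior: TwoLayerMedium,
                  init: tuple[float, float] = (5e-7, 5e-6),
                  bounds: tuple[float, float] = DB_BOUNDS,
                  *, sigma: np.ndarray | None = None,
                  quad_kw: dict | None = None) -> TwoLayerFitResult:
    """Invert the two-layer forward model for (Db_extra, Db_brain).

    Minimizes Σ_τ [g2_model(τ; Db1, Db2) − g2_data(τ)]² with β, ρ, thickness
    and optics fixed by ``medium_prior``.  The optimizer works in log10(Db)
    space (trust-region reflective least squares) for conditioning across the
    four-decade search range; ``sigma`` optionally weights residuals by 1/σ(τ).
    Non-convergence is flagged on the result, not raised.
    """
    # order-6 panels at s_max=30 give ~6e-6 relative forward accuracy, far
    # below any realistic noise floor, at ~10x the speed of the full setting
    qkw = dict(check=False, s_max=30.0, order=6)
    qkw.update(quad_kw or {})
    lags = curve.lags
    data = curve.values
    w = 1.0 if sigma is None else 1.0 / np.asarray(sigma, dtype=float)
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])

    def resid(x):
        m = medium_prior.with_Db(Db1=10.0 ** x[0], Db2=10.0 ** x[1])
        g2 = g2_from_g1(g1_twolayer(m, lags, **qkw), m.beta)
        return (g2 - data) * w

    x0 = np.clip(np.log10(init), lo, hi)
    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return TwoLayerFitResult(
        Db_extra=float(10.0 ** res.x[0]),
        Db_brain=float(10.0 ** res.x[1]),
        objective=float(2.0 * res.cost),
        converged=bool(res.success),
        n_iter=int(res.nfev),
    )
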