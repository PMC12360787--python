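"""Analytical field-autocorrelation forward models for diffuse correlation spectroscopy.

Implements the two-layer solution of the correlation diffusion equation (CDE)
for a slab (extracerebral) layer over a semi-infinite (brain) layer, and the
semi-infinite homogeneous closed form used as an independent oracle.

The CDE treats the unnormalized field autocorrelation G1(r, τ) like a photon
fluence with an extra, τ-dependent "dynamic absorption" term
2 μs' k0² α Db τ produced by the mean-square displacement ⟨Δr²(τ)⟩ = 6 Db τ of
moving scatterers.  In the two-layer geometry the equation is solved in the
spatial-frequency (Hankel) domain; the surface field is recovered by an
inverse Hankel transform with a J0 kernel.

Unit convention (consistent throughout the package): lengths in mm, τ in
seconds, Db in mm²/s, μa and μs' in mm⁻¹, wavelength supplied in nm.  The
photon diffusion coefficient is taken per unit speed, D = 1/(3 μs') (mm), so
every exponent is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate
from scipy.special import j0, jn_zeros


class InvalidParameterError(ValueError):
    """A physically or numerically inadmissible parameter value."""


class IntegrationError(RuntimeError):
    """Inverse Hankel quadrature failed to reach the requested tolerance."""

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerOptics:
    """Optical and dynamic properties of one tissue layer.

    Parameters
    ----------
    mua : absorption coefficient (mm⁻¹).
    musp : reduced scattering coefficient (mm⁻¹).
    Db : effective Brownian diffusion coefficient of moving scatterers (mm²/s).
    thickness : layer thickness (mm); ``inf`` for a terminal layer.
    alpha : fraction of scatterers that are moving (dimensionless, 1 here).
    """

    mua: float
    musp: float
    Db: float
    thickness: float = math.inf
    alpha: float = 1.0

    def __post_init__(self):
        if self.mua < 0:
            raise InvalidParameterError(f"mua must be >= 0, got {self.mua}")
        if self.musp <= 0:
            raise InvalidParameterError(f"musp must be > 0, got {self.musp}")
        if self.Db < 0:
            raise InvalidParameterError(f"Db must be >= 0, got {self.Db}")
        if self.thickness <= 0:
            raise InvalidParameterError("thickness must be > 0")

    @property
    def D(self) -> float:
        """Photon diffusion coefficient per unit speed, 1/(3 μs') (mm)."""
        return 1.0 / (3.0 * self.musp)


def effective_reflection_coefficient(n0: float, n_out: float = 1.0) -> float:
    """Effective reflection coefficient Reff of a tissue/air boundary.

    Computed from the exact angular integrals of the unpolarized Fresnel
    reflectance (the quantities commonly written Rφ and RJ):

        Reff = (Rφ + RJ) / (2 − Rφ + RJ)

    For n0 = 1.4 against air this evaluates to ≈ 0.493, the standard tissue
    value.
    """
    n = n0 / n_out

    def fresnel(cos_i: float) -> float:
        sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
        sin_t = n * sin_i
        if sin_t >= 1.0:
            return 1.0
        cos_t = math.sqrt(1.0 - sin_t * sin_t)
        rs = (n * cos_i - cos_t) / (n * cos_i + cos_t)
        rp = (n * cos_t - cos_i) / (n * cos_t + cos_i)
        return 0.5 * (rs * rs + rp * rp)

    r_phi, _ = integrate.quad(lambda t: 2.0 * math.sin(t) * math.cos(t) * fresnel(math.cos(t)),
                              0.0, math.pi / 2.0, limit=200)
    r_j, _ = integrate.quad(lambda t: 3.0 * math.sin(t) * math.cos(t) ** 2 * fresnel(math.cos(t)),
                            0.0, math.pi / 2.0, limit=200)
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


@dataclass(frozen=True)
class TwoLayerMedium:
    """Two-layer geometry: a finite extracerebral slab over a semi-infinite brain.

    ``rho`` is the source–detector separation on the surface (mm), ``beta``
    the Siegert coherence factor.  ``Reff`` defaults to the Fresnel value for
    ``n0``; derived boundary quantities (k0, z0, zb) are exposed as properties.
    """

    layer1: LayerOptics
    layer2: LayerOptics
    rho: float = 35.0
    wavelength: float = 785.0
    n0: float = 1.4
    beta: float = 0.5
    Reff: float | None = None

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise InvalidParameterError(f"beta must be in (0, 1], got {self.beta}")
        if self.rho <= 0 or self.wavelength <= 0:
            raise InvalidParameterError("rho and wavelength must be > 0")
        if not math.isfinite(self.layer1.thickness):
            raise InvalidParameterError("layer1 thickness must be finite")
        if self.Reff is None:
            object.__setattr__(self, "Reff", effective_reflection_coefficient(self.n0))

    @property
    def k0(self) -> float:
        """Wavenumber in the medium, 2π n0 / λ (mm⁻¹)."""
        return 2.0 * math.pi * self.n0 / (self.wavelength * 1e-6)

    @property
    def z0(self) -> float:
        """Depth of the equivalent isotropic source, 1/(μa,1 + μs,1') (mm)."""
        return 1.0 / (self.layer1.mua + self.layer1.musp)

    @property
    def zb(self) -> float:
        """Extrapolated-boundary distance, 2 D1 (1+Reff)/(1−Reff) (mm)."""
        return 2.0 * self.layer1.D * (1.0 + self.Reff) / (1.0 - self.Reff)

    def with_Db(self, Db1: float | None = None, Db2: float | None = None) -> "TwoLayerMedium":
        """Copy of this medium with one or both layer Db values replaced."""
        l1 = replace(self.layer1, Db=Db1) if Db1 is not None else self.layer1
        l2 = replace(self.layer2, Db=Db2) if Db2 is not None else self.layer2
        return replace(self, layer1=l1, layer2=l2)


@dataclass
class AcfCurve:
    """An autocorrelation curve on an ordered lag grid.

    ``kind`` tags the values as field autocorrelation (``g1``), intensity
    autocorrelation (``g2``), or min–max scaled g2 (``scaled``).
    """

    lags: np.ndarray
    values: np.ndarray
    kind: str = "g2"

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.values.shape:
            raise InvalidParameterError("lags and values must be 1-D and equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing")
        if self.kind not in ("g1", "g2", "scaled"):
            raise InvalidParameterError(f"unknown curve kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.lags)


# ---------------------------------------------------------------------------
# lag grid
# ---------------------------------------------------------------------------

def lag_grid(n: int = 31, step: float = 1.28e-6) -> np.ndarray:
    """Linearly spaced correlation lags [step, 2·step, …, n·step] (seconds).

    The default mirrors a linear-lag hardware autocorrelator with a 1.28 µs
    bin: 31 lags spanning 1.28–39.68 µs.
    """
    if n < 2:
        raise InvalidParameterError(f"need at least 2 lags, got {n}")
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    return step * np.arange(1, n + 1, dtype=float)


DEFAULT_LAGS = lag_grid()


# ---------------------------------------------------------------------------
# two-layer Hankel-domain kernel
# ---------------------------------------------------------------------------

def _alpha_sq(optics: LayerOptics, k0: float, tau, s):
    """α² = s² + (μa + 2 μs' k0² α Db τ) / D for one layer (broadcasting)."""
    mu_eff = optics.mua + 2.0 * optics.musp * k0 * k0 * optics.alpha * optics.Db * tau
    return s * s + mu_eff / optics.D


def g1_tilde_twolayer(s, tau, medium: TwoLayerMedium):
    """Hankel-domain surface kernel G̃1(s, z=0, τ) of the two-layer CDE.

    Evaluated in an exponentially rescaled form (only decaying exponentials
    appear) so sinh/cosh overflow can never occur:

        G̃1 = 1/(2 D1 α1) · [ (A−B)(e^{α1(z0−2l)} − e^{α1(z0−2(l+zb))}) / Δ
                              + e^{−α1 z0} − R e^{−α1 (z0+2 zb)} ]

    with A = D1 α1, B = D2 α2, Δ = (A+B) + (A−B) e^{−2α1(l+zb)} and
    R = [(A+B) + (A−B) e^{−2α1 l}] / Δ.  For identical layers (B = A, R = 1)
    this reduces to the semi-infinite image-source kernel
    [e^{−α z0} − e^{−α(z0+2zb)}]/(2Dα).

    ``s`` (mm⁻¹) and ``tau`` (s) broadcast against each other.
    """
    s = np.asarray(s, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(s < 0) or np.any(tau < 0):
        raise InvalidParameterError("s and tau must be >= 0")
    k0 = medium.k0
    l1, l2 = medium.layer1, medium.layer2
    z0, zb, l = medium.z0, medium.zb, l1.thickness

    a1 = np.sqrt(_alpha_sq(l1, k0, tau, s))
    a2 = np.sqrt(_alpha_sq(l2, k0, tau, s))
    A = l1.D * a1
    B = l2.D * a2
    L = l + zb

    e2L = np.exp(-2.0 * a1 * L)
    delta = (A + B) + (A - B) * e2L
    R = ((A + B) + (A - B) * np.exp(-2.0 * a1 * l)) / delta
    bracket = ((A - B) * (np.exp(a1 * (z0 - 2.0 * l)) - np.exp(a1 * (z0 - 2.0 * L))) / delta
               + np.exp(-a1 * z0) - R * np.exp(-a1 * (z0 + 2.0 * zb)))
    out = bracket / (2.0 * A)
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite two-layer kernel value", math.nan)
    return out


# ---------------------------------------------------------------------------
# inverse Hankel transform
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _hankel_nodes(rho: float, s_max: float, order: int):
    """Gauss–Legendre nodes/weights on panels split at the zeros of J0(sρ).

    Splitting at Bessel zeros keeps each panel free of sign changes of the
    oscillatory J0 factor, which is what makes fixed-order Gauss panels
    accurate at large ρ.  Returns (s nodes, weights · s · J0(sρ)).
    """
    n_zeros = int(np.ceil(s_max * rho / math.pi)) + 2
    edges = np.concatenate(([0.0], jn_zeros(0, n_zeros) / rho))
    edges = edges[edges <= s_max]
    if edges[-1] < s_max:
        edges = np.append(edges, s_max)
    x, w = leggauss(order)
    half = 0.5 * np.diff(edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights * nodes * j0(nodes * rho)


def _hankel_integral(medium: TwoLayerMedium, taus: np.ndarray,
                     s_max: float, order: int) -> np.ndarray:
    nodes, jweights = _hankel_nodes(medium.rho, s_max, order)
    kernel = g1_tilde_twolayer(nodes[:, None], taus[None, :], medium)
    return (jweights[:, None] * kernel).sum(axis=0) / (2.0 * math.pi)


def g1_twolayer(medium: TwoLayerMedium, tau, *, s_max: float = 60.0,
                order: int = 8, rtol: float = 1e-8, check: bool = True):
    """Normalized two-layer field autocorrelation g1(τ) = G1(ρ, 0, τ)/G1(ρ, 0, 0).

    G1 is the inverse Hankel transform (1/2π)∫ G̃1(s, τ) s J0(sρ) ds computed
    by panel Gauss–Legendre quadrature split at the zeros of J0(sρ).  With
    ``check`` the quadrature is repeated at double order and an
    :class:`IntegrationError` raised if the two disagree beyond ``rtol``
    relative to G1(0).
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau < 0):
        raise InvalidParameterError("tau must be >= 0")
    taus = np.concatenate(([0.0], tau))
    vals = _hankel_integral(medium, taus, s_max, order)
    if check:
        vals_hi = _hankel_integral(medium, taus, s_max, 2 * order)
        err = float(np.max(np.abs(vals - vals_hi)) / abs(vals_hi[0]))
        if err > rtol:
            raise IntegrationError(
                f"Hankel quadrature not converged (relative error {err:.2e} > {rtol:.0e})",
                err)
        vals = vals_hi
    g1 = vals[1:] / vals[0]
    return g1 if g1.size > 1 else float(g1[0])


# ---------------------------------------------------------------------------
# semi-infinite oracle
# ---------------------------------------------------------------------------

def g1_semiinfinite(optics: LayerOptics, rho: float, tau, *,
                    wavelength: float = 785.0, n0: float = 1.4,
                    Reff: float | None = None):
    """Closed-form normalized g1 of a homogeneous semi-infinite medium.

    Image-source solution with an extrapolated boundary:

        G1(τ) ∝ e^{−K(τ) r1}/r1 − e^{−K(τ) rb}/rb,
        K²(τ) = 3 μs' μa + 6 μs'² k0² α Db τ,

    r1 = √(ρ² + z0²), rb = √(ρ² + (z0 + 2 zb)²).  Serves as the independent
    oracle for both the two-layer quadrature (identical-layer limit) and the
    Monte Carlo engine.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidParameterError("tau must be >= 0")
    if Reff is None:
        Reff = effective_reflection_coefficient(n0)
    k0 = 2.0 * math.pi * n0 / (wavelength * 1e-6)
    z0 = 1.0 / (optics.mua + optics.musp)
    zb = 2.0 * optics.D * (1.0 + Reff) / (1.0 - Reff)
    r1 = math.hypot(rho, z0)
    rb = math.hypot(rho, z0 + 2.0 * zb)

    def G(t):
        K = np.sqrt(3.0 * optics.musp * optics.mua
                    + 6.0 * optics.musp ** 2 * k0 * k0 * optics.alpha * optics.Db * t)
        return np.exp(-K * r1) / r1 - np.exp(-K * rb) / rb

    return G(tau) / G(0.0)


# ---------------------------------------------------------------------------
# Siegert relation and curve synthesis
# ---------------------------------------------------------------------------

def g2_from_g1(g1, beta: float):
    """Siegert relation g2 = 1 + β |g1|².

    Accepts an array of g1 values or an :class:`AcfCurve` (returned as a
    ``g2``-kind curve).
    """
    if not (0.0 < beta <= 1.0):
        raise InvalidParameterError(f"beta must be in (0, 1], got {beta}")
    if isinstance(g1, AcfCurve):
        return AcfCurve(g1.lags, 1.0 + beta * np.abs(g1.values) ** 2, kind="g2")
    return 1.0 + beta * np.abs(np.asarray(g1, dtype=float)) ** 2


def g2_curve(medium: TwoLayerMedium, lags: np.ndarray = DEFAULT_LAGS, **quad_kw) -> AcfCurve:
    """Clean two-layer intensity autocorrelation g2(τ) on a lag grid."""
    g1 = g1_twolayer(medium, lags, **quad_kw)
    return AcfCurve(lags, g2_from_g1(g1, medium.beta), kind="g2")
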