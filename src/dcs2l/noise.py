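"""ACF scaling, empirical noise estimation, and noise synthesis.

The measurement chain this module models: an ensemble autocorrelator outputs
g2 frames on a fixed 31-lag grid; frames are min–max scaled to [1, 1.5];
per-frame single-exponential fits remove the (pulsatile) flow signal; the
across-frame standard deviation of the residual at each lag gives an
empirical noise profile σ(τ).  Scaling the mean profile by ±30% yields the
three noise levels used to corrupt clean training curves.  An analytic
shot-noise model (Koppel-type, linear-τ correlator) provides σ(τ) for
arbitrary count rate and integration time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward_models import AcfCurve, InvalidParameterError, TwoLayerMedium, g2_curve
from .fitting import FitError, SingleExpFit, fit_single_exponential


class DegenerateInputError(ValueError):
    """Input curve carries no dynamic range to scale or estimate from."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SigmaProfile:
    """Per-lag noise standard deviation σ(τ) of scaled g2 frames."""

    lags: np.ndarray
    sigma: np.ndarray
    level_tag: str = "mean"

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.lags.shape != self.sigma.shape:
            raise InvalidParameterError("lags and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise InvalidParameterError("sigma must be >= 0")

    def scaled(self, factor: float, tag: str) -> "SigmaProfile":
        return SigmaProfile(self.lags, factor * self.sigma, level_tag=tag)


@dataclass
class FrameStack:
    """A stack of g2 frames sharing one lag grid (n_frames × n_lags)."""

    lags: np.ndarray
    frames: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[1] != self.lags.shape[0]:
            raise InvalidParameterError("frames must be n_frames × n_lags")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def curve(self, i: int, kind: str = "g2") -> AcfCurve:
        return AcfCurve(self.lags, self.frames[i], kind=kind)


# ---------------------------------------------------------------------------
# min-max scaling of ACF curves
# ---------------------------------------------------------------------------

def scale_values(values: np.ndarray) -> np.ndarray:
    """Min–max scale to [1, 1.5]: x = (X − min)/(max − min)·0.5 + 1."""
    values = np.asarray(values, dtype=float)
    span = values.max(axis=-1, keepdims=True) - values.min(axis=-1, keepdims=True)
    if np.any(span <= 0):
        raise DegenerateInputError("cannot scale a constant curve")
    return (values - values.min(axis=-1, keepdims=True)) / span * 0.5 + 1.0


def scale_acf(curve: AcfCurve) -> AcfCurve:
    """Min–max scale an ACF curve to span exactly [1, 1.5] (idempotent)."""
    return AcfCurve(curve.lags, scale_values(curve.values), kind="scaled")


# ---------------------------------------------------------------------------
# empirical sigma estimation
# ---------------------------------------------------------------------------

def _hat_matrix(fit: SingleExpFit, tau: np.ndarray) -> np.ndarray:
    """Hat (projection) matrix of the linearized a + b·e^(−cτ) fit."""
    e = np.exp(-fit.c * tau)
    J = np.column_stack([np.ones_like(tau), e, -fit.b * tau * e])
    q, _ = np.linalg.qr(J)
    return q @ q.T


def _deconvolve_fit_absorption(var_resid: np.ndarray, H: np.ndarray,
                               n_iter: int = 50) -> np.ndarray:
    """Recover per-lag noise variances from fit-residual variances.

    A p-parameter least-squares fit maps noise n to residuals r = (I−H)n, so
    the observed residual variances are diag((I−H)Σ(I−H)ᵀ) with Σ = diag(σ²).
    With heteroscedastic σ(τ) the textbook 1/(1−h_jj) factor is biased; this
    fixed-point iteration inverts the full relation instead.
    """
    I = np.eye(H.shape[0])
    A = I - H
    sig2 = var_resid.copy()
    for _ in range(n_iter):
        model = np.einsum("ij,j,ij->i", A, sig2, A)
        sig2 = np.clip(sig2 + (var_resid - model), 0.0, None)
    return sig2


def estimate_sigma(stack: FrameStack, *, leverage_correction: bool = True,
                   level_tag: str = "mean") -> SigmaProfile:
    """Estimate σ(τ) from a stack of baseline frames.

    Each frame is min–max scaled, fitted with a + b·e^(−cτ), and the standard
    deviation of the residual across frames is taken at each lag.  Frames
    whose fit fails are dropped with a warning.  The leverage correction
    (default on) deconvolves the part of the noise the 3-parameter fit
    absorbs, using the hat matrix evaluated at the fit of the mean frame, so
    the estimate is unbiased wherever the min–max scaling leaves the noise
    intact (the pinned extreme lags carry no recoverable amplitude; see
    :func:`pinned_lag_fraction`).
    """
    if len(stack) < 2:
        raise InvalidParameterError("need at least 2 frames")
    tau = stack.lags
    residuals = []
    scaled_frames = []
    n_failed = 0
    for i in range(len(stack)):
        try:
            scaled = scale_values(stack.frames[i])
            fit = fit_single_exponential(AcfCurve(tau, scaled, kind="scaled"))
        except (FitError, DegenerateInputError):
            n_failed += 1
            continue
        residuals.append(fit.residuals)
        scaled_frames.append(scaled)
    if n_failed:
        warnings.warn(f"dropped {n_failed} frame(s) with failed fits")
    if not residuals:
        raise FitError("all frames failed the single-exponential fit")
    resid = np.asarray(residuals)
    var = resid.var(axis=0, ddof=1)
    if leverage_correction:
        mean_fit = fit_single_exponential(
            AcfCurve(tau, np.mean(scaled_frames, axis=0), kind="scaled"))
        H = _hat_matrix(mean_fit, tau)
        sigma = np.sqrt(_deconvolve_fit_absorption(var, H))
    else:
        sigma = np.sqrt(var)
    return SigmaProfile(tau, sigma, level_tag=level_tag)


def pinned_lag_fraction(stack: FrameStack) -> np.ndarray:
    """Fraction of frames in which each lag is the frame's min or max.

    Min–max scaling pins the extreme lags of every frame to exactly 1 and
    1.5, which deflates (and redistributes) the noise measured there; lags
    with a substantial pin fraction carry no recoverable noise amplitude.
    """
    counts = np.zeros(stack.lags.size)
    idx = np.argmax(stack.frames, axis=1)
    np.add.at(counts, idx, 1.0)
    idx = np.argmin(stack.frames, axis=1)
    np.add.at(counts, idx, 1.0)
    return counts / len(stack)


def empirical_sigma(stack: FrameStack, reference: np.ndarray) -> SigmaProfile:
    """Model-free σ(τ): across-frame std of scaled frames about a known clean curve.

    Oracle companion to :func:`estimate_sigma` for synthetic data where the
    clean scaled curve is known exactly — no fitting involved, so any
    discrepancy between the two isolates fit-induced bias.
    """
    scaled = scale_values(stack.frames)
    resid = scaled - scale_values(np.asarray(reference, dtype=float))
    return SigmaProfile(stack.lags, resid.std(axis=0, ddof=1), level_tag="empirical")


def make_noise_levels(profiles: list[SigmaProfile]) -> dict[str, SigmaProfile]:
    """Mean profile across sessions, scaled to {0.7, 1.0, 1.3}× (three levels)."""
    if not profiles:
        raise InvalidParameterError("need at least one profile")
    lags = profiles[0].lags
    mean = np.mean([p.sigma for p in profiles], axis=0)
    base = SigmaProfile(lags, mean, level_tag="mean")
    return {
        "minus30": base.scaled(0.7, "minus30"),
        "mean": base,
        "plus30": base.scaled(1.3, "plus30"),
    }


# ---------------------------------------------------------------------------
# noise injection
# ---------------------------------------------------------------------------

def draw_noise(level: SigmaProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian per-lag noise, independent across lags (n × n_lags)."""
    return rng.normal(0.0, 1.0, size=(n, level.sigma.size)) * level.sigma


def add_noise(clean: AcfCurve, level: SigmaProfile,
              seed: int | np.random.Generator) -> AcfCurve:
    """Scale a clean curve, add per-lag Gaussian noise, and rescale to [1, 1.5].

    Mirrors the training-data pipeline: clean g2 → min–max scale → + noise →
    min–max rescale, so the output is always a ``scaled``-kind curve.
    """
    if clean.lags.shape != level.lags.shape or not np.allclose(clean.lags, level.lags):
        raise InvalidParameterError("curve and noise level must share the lag grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scaled = scale_values(clean.values)
    noisy = scaled + draw_noise(level, 1, rng)[0]
    return AcfCurve(clean.lags, scale_values(noisy), kind="scaled")


# ---------------------------------------------------------------------------
# analytic correlation-noise model (linear-τ correlator)
# ---------------------------------------------------------------------------

def analytic_acf_sigma(g2: AcfCurve, count_rate: float, t_int: float,
                       beta: float = 0.5, bin_time: float = 1.28e-6) -> SigmaProfile:
    """Shot-noise σ(τ) of a linear-τ software/hardware correlator.

    Koppel-type variance estimate for correlator bin time T, photon rate I
    and total integration time t_int, evaluated at lags τ_m = m·T:

        σ(τ_m) = √(T/t_int) · [ β²( (1+e^{−2ΓT})(1+e^{−2Γτ}) +
                                     2m(1−e^{−2ΓT})e^{−2Γτ} ) / (1−e^{−2ΓT})
                                + 2⟨n⟩⁻¹ β (1+e^{−2Γτ})
                                + ⟨n⟩⁻²(1+β e^{−Γτ}) ]^{1/2}

    with ⟨n⟩ = I·T photons per bin and Γ the field decay rate, estimated here
    from a single-exponential fit of the supplied g2 curve (Γ = c/2).
    """
    if count_rate <= 0 or t_int <= 0:
        raise InvalidParameterError("count_rate and t_int must be > 0")
    fit = fit_single_exponential(g2)
    gamma = fit.c / 2.0
    tau = g2.lags
    T = bin_time
    m = tau / T
    n_mean = count_rate * T
    e2T = np.exp(-2.0 * gamma * T)
    e2t = np.exp(-2.0 * gamma * tau)
    e1t = np.exp(-gamma * tau)
    var = (beta ** 2 * ((1.0 + e2T) * (1.0 + e2t) + 2.0 * m * (1.0 - e2T) * e2t)
           / (1.0 - e2T)
           + 2.0 / n_mean * beta * (1.0 + e2t)
           + 1.0 / n_mean ** 2 * (1.0 + beta * e1t))
    sigma = np.sqrt(T / t_int) * np.sqrt(var)
    return SigmaProfile(tau, sigma, level_tag=f"analytic_{count_rate:g}Hz_{t_int:g}s")


# ---------------------------------------------------------------------------
# synthetic baseline sessions (no measured SPAD data are distributed)
# ---------------------------------------------------------------------------

def default_sigma_shape(lags: np.ndarray, peak: float = 0.02) -> np.ndarray:
    """Synthetic stand-in σ0(τ) for the empirical instrument noise profile.

    A smooth bump peaking mid-grid with suppressed endpoints (~0.3× peak),
    emulating the qualitative shape of min–max-scaled linear-lag correlator
    noise: the scaling pins the first and last lags, deflating their residual
    spread relative to the middle of the grid.  The peak value is set so the
    profile magnitude matches the analytic shot-noise model at a few kHz and
    minutes-scale integration.
    """
    u = np.linspace(0.0, 1.0, lags.size)
    return peak * (0.3 + 0.7 * np.sin(np.pi * u) ** 2)


def synthetic_baseline_sessions(medium: TwoLayerMedium | None, seed: int,
                                n_sessions: int = 5, n_frames: int = 1000,
                                sigma0: np.ndarray | None = None,
                                lags: np.ndarray | None = None,
                                clean_values: np.ndarray | None = None) -> list[FrameStack]:
    """Synthetic baseline recordings: scaled clean curve + Gaussian noise frames.

    Emulates resting-state sessions of an ensemble correlator so the
    σ-estimation pipeline can be exercised without measured data.  Frames are
    the *scaled* clean baseline curve plus zero-mean per-lag noise of profile
    ``sigma0`` (defaults to :func:`default_sigma_shape`).  ``clean_values``
    substitutes an explicit baseline curve (e.g. an exact single exponential
    for estimator-closure studies) for the two-layer curve of ``medium``.
    """
    from .forward_models import DEFAULT_LAGS

    lags = DEFAULT_LAGS if lags is None else lags
    rng = np.random.default_rng(seed)
    if clean_values is None:
        clean_values = g2_curve(medium, lags).values
    scaled = scale_values(clean_values)
    if sigma0 is None:
        sigma0 = default_sigma_shape(lags)
    profile = SigmaProfile(lags, sigma0)
    stacks = []
    for s in range(n_sessions):
        frames = scaled[None, :] + draw_noise(profile, n_frames, rng)
        stacks.append(FrameStack(lags, frames, meta={"session": s, "synthetic": True}))
    return stacks
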