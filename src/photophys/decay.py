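"""Multi-exponential fluorescence decay models and iterative-reconvolution primitives.

A TCSPC histogram records photon arrival times as counts per channel on a
uniform time grid. The physical decay law used throughout is

    I(t) = I0 * [ (1 - a1 - a2) exp(-t/tau1) + a1 exp(-t/tau2) + a2 exp(-t/tau3) ]

with amplitude fractions normalised to unity (the first amplitude is stored
implicitly). What the instrument measures is this law convolved with the
instrument response function (IRF), so model evaluation and causal
convolution with a (shifted, unit-normalised) IRF are the two primitives on
which all fitting is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "TimeAxis",
    "InstrumentResponse",
    "DecayTrace",
    "MultiExpParams",
    "evaluate_multiexp",
    "reconvolve",
    "fractional_intensities",
    "average_lifetime",
    "reduced_chisq",
]


@dataclass(frozen=True)
class TimeAxis:
    """Uniform time grid: origin ``t0`` (ns), channel width ``dt`` (ns), ``n`` channels."""

    t0: float
    dt: float
    n: int

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"channel width must be positive, got dt={self.dt}")
        if self.n < 8:
            raise ValueError(f"need at least 8 channels, got n={self.n}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def span(self) -> float:
        return self.dt * (self.n - 1)

    @classmethod
    def from_times(cls, t: np.ndarray, rtol: float = 1e-6) -> "TimeAxis":
        """Build an axis from an explicit time vector, rejecting non-uniform grids."""
        t = np.asarray(t, dtype=float)
        if t.ndim != 1 or t.size < 8:
            raise ValueError("time vector must be 1-D with at least 8 entries")
        steps = np.diff(t)
        dt = float(np.median(steps))
        if dt <= 0 or not np.allclose(steps, dt, rtol=rtol, atol=rtol * abs(dt)):
            raise ValueError("time grid is not uniform; resampling is not supported")
        return cls(t0=float(t[0]), dt=dt, n=t.size)


@dataclass(frozen=True)
class InstrumentResponse:
    """Measured IRF trace sharing the axis convention of the decay it deconvolves."""

    axis: TimeAxis
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.axis.n,):
            raise ValueError("IRF counts length does not match its time axis")
        if np.any(counts < 0):
            raise ValueError("IRF counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("IRF must contain counts")
        object.__setattr__(self, "counts", counts)

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.counts))


@dataclass(frozen=True)
class DecayTrace:
    """One TCSPC histogram with metadata (DNA identity/concentration, emission band)."""

    axis: TimeAxis
    counts: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.axis.n,):
            raise ValueError("decay counts length does not match its time axis")
        if np.any(counts < 0):
            raise ValueError("decay counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("decay counts must be integral (photon counts)")
        if counts.max() <= 0:
            raise ValueError("decay trace contains no counts")
        object.__setattr__(self, "counts", counts)

    @property
    def peak_counts(self) -> float:
        return float(self.counts.max())


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class MultiExpParams:
    """Parameters of a 1–3 component exponential decay.

    ``alpha`` stores the explicit amplitude fractions of components 2..ncomp;
    the first amplitude is implicitly ``1 - sum(alpha)``, matching the
    normalisation convention Σα = 1.
    """

    tau: tuple[float, ...]
    alpha: tuple[float, ...] = ()
    scale: float = 1.0
    shift: float = 0.0
    background: float = 0.0

    def __post_init__(self) -> None:
        tau = tuple(float(t) for t in np.atleast_1d(np.asarray(self.tau, dtype=float)))
        alpha = tuple(float(a) for a in np.atleast_1d(np.asarray(self.alpha, dtype=float))) if len(np.atleast_1d(self.alpha)) else ()
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "alpha", alpha)
        if not 1 <= len(tau) <= 3:
            raise InvalidParameterError("between 1 and 3 lifetime components supported")
        if any(t <= 0 for t in tau):
            raise InvalidParameterError(f"all lifetimes must be positive, got {tau}")
        if len(alpha) != len(tau) - 1:
            raise InvalidParameterError(
                f"expected {len(tau) - 1} explicit amplitudes for {len(tau)} components"
            )
        if any(a < 0 for a in alpha) or sum(alpha) > 1 + 1e-12:
            raise InvalidParameterError("amplitudes must be >= 0 with sum <= 1")
        if not (self.scale > 0):
            raise InvalidParameterError("scale I0 must be positive")

    @property
    def ncomp(self) -> int:
        return len(self.tau)

    @property
    def full_alpha(self) -> np.ndarray:
        """All amplitude fractions including the implicit first one; sums to 1."""
        a_rest = np.asarray(self.alpha, dtype=float)
        return np.concatenate([[1.0 - a_rest.sum()], a_rest])


def evaluate_multiexp(params: MultiExpParams, axis: TimeAxis) -> np.ndarray:
    """Per-channel model intensity of the multi-exponential decay law.

    Returns I0 * Σ_i α_i exp(-t/τ_i) + background on ``axis`` (t < 0 clamped
    to the t = 0 value so the law stays causal on axes that start negative).
    """
    t = np.maximum(axis.times, 0.0)
    tau = np.asarray(params.tau, dtype=float)
    alpha = params.full_alpha
    out = params.scale * (alpha[None, :] * np.exp(-t[:, None] / tau[None, :])).sum(axis=1)
    return out + params.background


def _shifted_irf(irf: InstrumentResponse, shift: float) -> np.ndarray:
    """IRF displaced by ``shift`` ns via linear interpolation, unit-normalised."""
    if abs(shift) >= irf.axis.span:
        raise ValueError("prompt shift exceeds the time-axis span")
    ch = np.arange(irf.axis.n, dtype=float)
    # shifting the IRF later in time by s means sampling it at (ch - s/dt)
    vals = np.interp(ch - shift / irf.axis.dt, ch, irf.counts, left=0.0, right=0.0)
    total = vals.sum()
    if total <= 0:
        raise ValueError("prompt shift moved the IRF entirely off the axis")
    return vals / total


def reconvolve(model: np.ndarray, irf: InstrumentResponse, shift: float = 0.0) -> np.ndarray:
    """Discrete causal convolution of the shifted, unit-normalised IRF with the model.

    Output has the same length as the input; the IRF is treated as the
    response kernel so a single-channel delta IRF returns the model unchanged.
    """
    model = np.asarray(model, dtype=float)
    if model.shape != (irf.axis.n,):
        raise ValueError(
            f"model length {model.shape} does not match IRF axis ({irf.axis.n} channels)"
        )
    kernel = _shifted_irf(irf, shift)
    return fftconvolve(kernel, model)[: irf.axis.n]


def fractional_intensities(alpha: Sequence[float], tau: Sequence[float]) -> np.ndarray:
    """Fractional steady-state emission per component: f_i = α_i τ_i / Σ_j α_j τ_j."""
    alpha = np.asarray(alpha, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if alpha.shape != tau.shape:
        raise ValueError("alpha and tau must have the same length")
    if np.any(tau <= 0):
        raise InvalidParameterError("lifetimes must be positive")
    weights = alpha * tau
    total = weights.sum()
    if total <= 0:
        raise InvalidParameterError("fractional intensities undefined for all-zero amplitudes")
    return weights / total


def average_lifetime(alpha: Sequence[float], tau: Sequence[float]) -> float:
    """Amplitude-weighted average lifetime τ̄ = Σ_j α_j τ_j (ns)."""
    alpha = np.asarray(alpha, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if alpha.shape != tau.shape:
        raise ValueError("alpha and tau must have the same length")
    if not np.isclose(alpha.sum(), 1.0, atol=1e-6):
        raise InvalidParameterError("amplitude fractions must sum to 1")
    return float(np.dot(alpha, tau))


class DegreesOfFreedomError(ValueError):
    pass


def reduced_chisq(
    observed: DecayTrace | np.ndarray,
    model: np.ndarray,
    n_free_params: int,
    fit_window: slice | tuple[int, int] | None = None,
) -> float:
    """Reduced chi-square of a fitted decay with Poisson (Neyman) weights 1/max(obs, 1).

    ``fit_window`` restricts the sum to a channel range — conventionally the
    channels after the IRF peak, where the reconvolved model is insensitive
    to the rising-edge details.
    """
    obs = observed.counts if isinstance(observed, DecayTrace) else np.asarray(observed, float)
    model = np.asarray(model, dtype=float)
    if obs.shape != model.shape:
        raise ValueError("observed and model lengths differ")
    if fit_window is None:
        window = slice(None)
    elif isinstance(fit_window, tuple):
        window = slice(*fit_window)
    else:
        window = fit_window
    o = obs[window]
    m = model[window]
    if o.size == 0:
        raise DegreesOfFreedomError("empty fit window")
    dof = o.size - n_free_params
    if dof <= 0:
        raise DegreesOfFreedomError(
            f"non-positive degrees of freedom: {o.size} channels, {n_free_params} parameters"
        )
    w = 1.0 / np.maximum(o, 1.0)
    return float(np.sum(w * (o - m) ** 2) / dof)
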