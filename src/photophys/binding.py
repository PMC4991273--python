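"""Steady-state emission titration analysis.

Covers fold enhancement of emission on DNA addition, stoichiometry by the
mole-ratio (breakpoint) method, and association constants from the exact
1:1 compound-per-binding-motif equilibrium. All DNA concentrations are in
binding-motif units: the motif is whatever DNA unit binds one compound
(five base pairs, five bases, or one G-quadruplex), so cooperative models
are never needed.

The 1:1 bound concentration comes from the quadratic mass balance

    x = ((D + L + 1/Ka) - sqrt((D + L + 1/Ka)^2 - 4 D L)) / 2

with D total motif, L total dye, and the observed signal is modelled as
I_free * (L - x) + I_bound * x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "EmissionSpectrum",
    "BindingCurve",
    "BindingFitResult",
    "BreakpointResult",
    "bound_concentration",
    "fold_enhancement",
    "integrate_band",
    "binding_curve_from_spectra",
    "mole_ratio_stoichiometry",
    "fit_1to1",
    "concentration_from_absorbance",
]

DEFAULT_BAND = (584.0, 634.0)


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission spectrum of a titration point (wavelength nm, intensity a.u.)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    dna_conc: float = 0.0
    dye_conc: float = 0.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelength and intensity must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)


@dataclass(frozen=True)
class BindingCurve:
    """Integrated emission vs DNA motif concentration over a stated band."""

    x: np.ndarray
    y: np.ndarray
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be matching 1-D arrays")
        if x.size < 5:
            raise ValueError("a binding curve needs at least 5 titration points")
        if np.any(np.diff(x) < 0):
            raise ValueError("DNA concentrations must be non-decreasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class BindingFitResult:
    Ka: float                       # association constant, M^-1 (motif basis)
    I_free: float                   # brightness per mole of free dye
    I_bound: float                  # brightness per mole of bound dye
    motif: str = ""                 # description of the binding motif
    sd_Ka: float = float("nan")     # std dev over repeats, if computed
    lower_bound_only: bool = False  # True when data were saturated throughout
    residual_norm: float = float("nan")


@dataclass(frozen=True)
class BreakpointResult:
    """Mole-ratio breakpoint: abscissa of the gradient change in motif-per-dye units."""

    ratio: float | None
    knee_conc: float | None
    found: bool
    sse_two_segment: float
    sse_single_line: float


def bound_concentration(dna_total: float | np.ndarray, dye_total: float, Ka: float) -> float | np.ndarray:
    """Bound-complex concentration from the exact 1:1 quadratic mass balance."""
    if Ka <= 0:
        raise ValueError("association constant must be positive")
    D = np.asarray(dna_total, dtype=float)
    L = float(dye_total)
    s = D + L + 1.0 / Ka
    x = 0.5 * (s - np.sqrt(s * s - 4.0 * D * L))
    x = np.clip(x, 0.0, np.minimum(D, L))
    return float(x) if np.isscalar(dna_total) else x


def integrate_band(spec: EmissionSpectrum, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Trapezoidal integral of intensity over the wavelength band (inclusive)."""
    lo, hi = band
    mask = (spec.wavelength >= lo) & (spec.wavelength <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} covers fewer than 2 wavelength samples")
    return float(np.trapezoid(spec.intensity[mask], spec.wavelength[mask]))


def fold_enhancement(first: EmissionSpectrum, last: EmissionSpectrum) -> float:
    """Integrated emission at the end of the titration over the compound-only spectrum."""
    if not np.array_equal(first.wavelength, last.wavelength):
        raise ValueError("spectra must share one wavelength grid")
    denom = float(np.trapezoid(first.intensity, first.wavelength))
    if denom <= 0:
        raise ValueError("initial spectrum integrates to zero; fold enhancement undefined")
    num = float(np.trapezoid(last.intensity, last.wavelength))
    return num / denom


def binding_curve_from_spectra(
    spectra: list[EmissionSpectrum], band: tuple[float, float] = DEFAULT_BAND
) -> BindingCurve:
    order = np.argsort([s.dna_conc for s in spectra], kind="stable")
    x = np.array([spectra[i].dna_conc for i in order])
    y = np.array([integrate_band(spectra[i], band) for i in order])
    return BindingCurve(x=x, y=y, band=band)


def _two_segment_sse(x: np.ndarray, y: np.ndarray, knee: float) -> float:
    """SSE of the best continuous two-segment line with the hinge at ``knee``."""
    A = np.column_stack([np.ones_like(x), x, np.maximum(x - knee, 0.0)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r)


def mole_ratio_stoichiometry(
    curve: BindingCurve, dye_conc: float, min_improvement: float = 0.5
) -> BreakpointResult:
    """Stoichiometry from the breakpoint of a titration curve (mole-ratio method).

    Fits a continuous two-segment line with the knee position free (grid over
    interior abscissae plus golden-section refinement) and reports the knee
    as a DNA-motif-per-dye ratio. If the two-segment model does not beat a
    single straight line by a model-selection margin (BIC), a no-breakpoint
    result is returned.
    """
    if curve.x.size < 6:
        raise ValueError("need at least 6 points spanning the breakpoint")
    if dye_conc <= 0:
        raise ValueError("dye concentration must be positive")
    # work on a normalised abscissa so optimiser tolerances are scale-free
    xscale = float(curve.x[-1]) or 1.0
    x, y = curve.x / xscale, curve.y
    # single-line reference fit
    A1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(A1, y, rcond=None)
    sse1 = float(np.sum((y - A1 @ coef1) ** 2))

    interior = np.linspace(x[1], x[-2], 101)
    sses = np.array([_two_segment_sse(x, y, k) for k in interior])
    k0 = interior[int(np.argmin(sses))]
    span = (x[-2] - x[1]) / 100.0
    res = minimize_scalar(
        lambda k: _two_segment_sse(x, y, k),
        bounds=(max(x[1], k0 - 2 * span), min(x[-2], k0 + 2 * span)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    knee = float(res.x) * xscale
    sse2 = float(res.fun)

    n = x.size
    eps = 1e-300
    bic1 = n * np.log(sse1 / n + eps) + 2 * np.log(n)
    bic2 = n * np.log(sse2 / n + eps) + 4 * np.log(n)
    if not (bic2 + min_improvement < bic1):
        return BreakpointResult(None, None, False, sse2, sse1)
    return BreakpointResult(knee / dye_conc, knee, True, sse2, sse1)


def fit_1to1(
    curve: BindingCurve,
    dye_conc: float,
    motif: str = "",
    Ka_init: float = 1.0e6,
) -> BindingFitResult:
    """Fit Ka, I_free, I_bound of the 1:1 compound-to-motif model.

    Signal model: y = I_free * (L - x) + I_bound * x with x the quadratic
    bound concentration; minimised by trust-region-reflective least squares
    on log10(Ka) to keep the constant positive across decades.
    """
    x_conc, y = curve.x, curve.y
    L = float(dye_conc)
    if L <= 0:
        raise ValueError("dye concentration must be positive")

    ymax = max(float(np.max(np.abs(y))), 1e-30)

    def model(theta: np.ndarray) -> np.ndarray:
        logKa, If, Ib = theta
        xb = bound_concentration(x_conc, L, 10.0 ** logKa)
        return If * (L - xb) + Ib * xb

    def resid(theta: np.ndarray) -> np.ndarray:
        return (model(theta) - y) / ymax

    If0 = y[0] / L if y[0] > 0 else ymax / L
    Ib0 = max(y[-1] / L, If0 * 1.5)
    theta0 = np.array([np.log10(Ka_init), If0, Ib0])
    sol = least_squares(
        resid,
        theta0,
        bounds=([0.0, 0.0, 0.0], [14.0, np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
    )
    logKa, If, Ib = sol.x
    Ka = float(10.0 ** logKa)

    # saturated-only data cannot pin Ka down, only bound it from below
    frac0 = bound_concentration(x_conc[x_conc > 0], L, Ka) / L if np.any(x_conc > 0) else np.array([])
    lower_only = bool(frac0.size and np.min(frac0) > 0.95)
    if lower_only:
        warnings.warn(
            "all titration points are near saturation; Ka is a lower bound only",
            stacklevel=2,
        )
    return BindingFitResult(
        Ka=Ka,
        I_free=float(If),
        I_bound=float(Ib),
        motif=motif,
        lower_bound_only=lower_only,
        residual_norm=float(np.linalg.norm(sol.fun * ymax)),
    )


def concentration_from_absorbance(A: float, epsilon: float, pathlength_cm: float = 1.0) -> float:
    """Beer–Lambert concentration c = A / (epsilon * l), in mol/L."""
    if A < 0:
        raise ValueError("absorbance must be non-negative")
    if epsilon <= 0 or pathlength_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    return A / (epsilon * pathlength_cm)
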