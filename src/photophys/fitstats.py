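"""Goodness-of-fit acceptance and F-statistic support-plane accuracy analysis.

A fitted lifetime's accuracy is probed by holding it at a grid of trial
values, re-optimising every other parameter, and comparing the constrained
reduced chi-square to the unconstrained minimum through the ratio

    F_chi = chisq_r(parm) / chisq_r(min)

Trial values whose F_chi stays below the critical threshold

    F_chi_crit = 1 + (p / v) * F(P; p, v)

are statistically indistinguishable from the best fit at significance P,
where p is the number of fitted parameters, v the degrees of freedom and
F(P; p, v) the upper-P critical value of Fisher's F distribution with
numerator dof p and denominator dof v. A model itself is conventionally
acceptable when chisq_r is below the upper-P reduced-chi-square quantile
(1.17 for P = 0.05, v = 200).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitting import GlobalFitResult, TitrationSeries, fit_global

__all__ = [
    "FChiSpec",
    "SupportPlane",
    "critical_fchi",
    "chisq_acceptance",
    "tau_support_plane",
]


@dataclass(frozen=True)
class FChiSpec:
    """Significance level P, fitted-parameter count p, degrees of freedom v."""

    P: float = 0.05
    p: int = 1
    v: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.P < 1:
            raise ValueError("significance level must be in (0, 1)")
        if self.p < 1 or self.v < 1:
            raise ValueError("p and v must be >= 1")


def critical_fchi(spec: FChiSpec, swap_dof: bool = False) -> float:
    """Critical F_chi threshold 1 + (p/v) F(P; p, v).

    The F critical value uses numerator dof p and denominator dof v — the
    convention standard for support-plane analysis. ``swap_dof`` evaluates
    the alternative (v, p) ordering for comparison.
    """
    dfn, dfd = (spec.v, spec.p) if swap_dof else (spec.p, spec.v)
    fcrit = stats.f.ppf(1.0 - spec.P, dfn, dfd)
    return float(1.0 + (spec.p / spec.v) * fcrit)


def chisq_acceptance(v: int, P: float = 0.05) -> float:
    """Largest acceptable reduced chi-square at significance P with v dof."""
    if v < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.chi2.ppf(1.0 - P, v) / v)


@dataclass(frozen=True)
class SupportPlane:
    """Reduced-chi-square profile of one shared lifetime over a fixed-value grid."""

    component: int
    grid: np.ndarray              # trial lifetimes (ns)
    chisq_profile: np.ndarray     # global chisq_r at each grid point
    chisq_min: float              # unconstrained minimum
    fchi: np.ndarray              # profile / minimum ratio
    threshold: float              # critical F_chi
    accepted: np.ndarray          # boolean sublevel set of the profile
    failed: np.ndarray            # grid points whose re-optimisation failed
    spec: FChiSpec = FChiSpec()

    @property
    def accepted_intervals(self) -> list[tuple[float, float]]:
        """Contiguous accepted grid runs as (lo, hi) lifetime ranges."""
        out: list[tuple[float, float]] = []
        run: list[float] = []
        for g, ok in zip(self.grid, self.accepted):
            if ok:
                run.append(float(g))
            elif run:
                out.append((run[0], run[-1]))
                run = []
        if run:
            out.append((run[0], run[-1]))
        return out

    def contains(self, tau: float) -> bool:
        return any(lo <= tau <= hi for lo, hi in self.accepted_intervals)


def tau_support_plane(
    series: TitrationSeries,
    fit: GlobalFitResult,
    component: int,
    grid: np.ndarray,
    P: float = 0.05,
    n_repeats: int = 1,
    fit_shift: bool | None = None,
    polish: bool = False,
) -> SupportPlane:
    """Profile one shared lifetime over ``grid``, re-optimising all else.

    Each grid point refits the series with ``component`` held at the trial
    value (warm-started from the unconstrained fit; with ``n_repeats`` > 1,
    additional cold starts are tried and the lowest constrained chi-square
    kept). The accepted set is every grid point whose F_chi ratio is below
    the critical threshold computed from the fit's recorded p and v.
    """
    if not fit.converged:
        raise ValueError("support-plane analysis requires a converged fit")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= series.irf.axis.dt):
        raise ValueError("grid lifetimes must exceed the channel width")
    if fit.fixed_mask[component]:
        raise ValueError("cannot profile a lifetime that was held fixed in the fit")
    if fit_shift is None:
        fit_shift = any(abs(pt.shift) > 1e-12 for pt in fit.per_trace)

    ncomp = fit.shared_tau.size
    base_fixed = {i: float(fit.shared_tau[i]) for i in range(ncomp) if fit.fixed_mask[i]}
    free_others = [
        i for i in range(ncomp) if not fit.fixed_mask[i] and i != component
    ]
    window = slice(*fit.window)

    profile = np.empty(grid.size)
    failed = np.zeros(grid.size, dtype=bool)
    ssr_min = fit.total_ssr
    for j, tau_fix in enumerate(grid):
        fixed = dict(base_fixed)
        fixed[component] = float(tau_fix)
        warm = fit.shared_tau[free_others] if free_others else None
        best_ssr = np.inf
        starts = [warm] + [
            np.geomspace(2 * series.irf.axis.dt, series.irf.axis.span / 3, len(free_others))
            * (1.5**r)
            for r in range(n_repeats - 1)
        ] if free_others else [None]
        for init in starts[: max(1, n_repeats)]:
            try:
                sub = fit_global(
                    series,
                    ncomp=ncomp,
                    fixed_free_dye_tau=None,
                    fixed=fixed,
                    init=init,
                    fit_shift=fit_shift,
                    fit_window=window,
                    polish=polish,
                    dof_policy=None,
                )
            except Exception:
                continue
            if sub.total_ssr < best_ssr:
                best_ssr = sub.total_ssr
        if not np.isfinite(best_ssr):
            failed[j] = True
            profile[j] = np.nan
            continue
        profile[j] = best_ssr / fit.dof_actual
        ssr_min = min(ssr_min, best_ssr)

    chisq_min = ssr_min / fit.dof_actual
    fchi = profile / chisq_min
    spec = FChiSpec(P=P, p=fit.p, v=fit.v)
    thr = critical_fchi(spec)
    accepted = np.where(np.isnan(fchi), False, fchi <= thr)
    return SupportPlane(
        component=component,
        grid=grid,
        chisq_profile=profile,
        chisq_min=chisq_min,
        fchi=fchi,
        threshold=thr,
        accepted=accepted,
        failed=failed,
        spec=spec,
    )
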