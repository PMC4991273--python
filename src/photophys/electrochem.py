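"""Cyclic-voltammetry analysis and photoinduced-electron-transfer energetics.

For quasi-reversible couples whose anodic/cathodic midpoint stays constant
with scan rate, the midpoint potential E_mid = (E_pa + E_pc)/2 serves as an
effective redox potential. Potentials measured against the Fc+/Fc couple
are converted to the NHE scale with the +0.64 V offset, and PET feasibility
is judged by the Rehm–Weller free energy

    dG = (E_ox(donor) - E_red(acceptor)) - dG_00 - e^2/(eps*d)

in eV for one electron: dG < 0 means quenching by electron transfer is
thermodynamically favourable. Redox potentials from computed Gibbs energies
use the standard thermodynamic cycle against the 4.4 V absolute NHE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = [
    "Voltammogram",
    "RedoxSummary",
    "PETInput",
    "PETResult",
    "ThermoCycleInput",
    "ScanRateDiagnostics",
    "FC_TO_NHE_V",
    "NHE_ABSOLUTE_V",
    "GUANINE_EOX_V",
    "HC_EV_NM",
    "extract_redox",
    "reference_to_nhe",
    "scan_rate_diagnostics",
    "rehm_weller_dG",
    "zero_zero_energy",
    "thermo_cycle_potential",
]

FC_TO_NHE_V = 0.64      # Fc+/Fc couple vs the normal hydrogen electrode
NHE_ABSOLUTE_V = 4.4    # absolute potential of the NHE
GUANINE_EOX_V = 1.3     # guanine oxidation potential, V vs NHE
HC_EV_NM = 1239.84      # photon energy conversion, eV * nm


@dataclass(frozen=True)
class Voltammogram:
    """One CV scan: potential sweep (forward + reverse), current, scan rate (V/s)."""

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    reference: str = "vs Fc+/Fc"

    def __post_init__(self) -> None:
        E = np.asarray(self.potential, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if E.ndim != 1 or E.shape != i.shape or E.size < 8:
            raise ValueError("potential and current must be matching 1-D sweeps")
        if not self.scan_rate > 0:
            raise ValueError("scan rate must be positive")
        object.__setattr__(self, "potential", E)
        object.__setattr__(self, "current", i)

    def segments(self) -> list[slice]:
        """Monotonic sweep segments, split where the sweep direction reverses."""
        dE = np.sign(np.diff(self.potential))
        dE[dE == 0] = 1
        breaks = np.flatnonzero(np.diff(dE) != 0) + 1
        edges = [0, *breaks.tolist(), self.potential.size - 1]
        segs = [slice(a, b + 1) for a, b in zip(edges[:-1], edges[1:]) if b - a >= 4]
        if len(segs) < 2:
            raise ValueError("voltammogram must contain at least 2 sweep segments")
        return segs


@dataclass(frozen=True)
class RedoxSummary:
    E_pa: float                 # anodic peak potential (V)
    E_pc: float                 # cathodic peak potential (V)
    i_pa: float                 # anodic peak current (A, baseline-subtracted)
    i_pc: float                 # cathodic peak current magnitude (A)
    E_mid: float                # (E_pa + E_pc) / 2
    peak_ratio: float           # i_pa / i_pc
    reference: str = "vs Fc+/Fc"
    reference_offset: float = 0.0
    reversible: bool = True


@dataclass(frozen=True)
class PETInput:
    """Inputs to the Rehm–Weller free-energy estimate, all on the NHE scale."""

    E_ox_donor: float = GUANINE_EOX_V   # V vs NHE
    E_red_acceptor: float = 0.0         # V vs NHE
    dG00: float | None = None           # S0->S1 energy (eV); computed from maxima if None
    lambda_abs_max: float | None = None  # nm
    lambda_em_max: float | None = None   # nm
    coulomb_term: float = 0.0           # e^2/(eps*d), eV; normally omitted


@dataclass(frozen=True)
class PETResult:
    dG: float            # eV
    favourable: bool     # dG < 0
    dG00: float          # eV actually used


@dataclass(frozen=True)
class ThermoCycleInput:
    """Gibbs-energy bookkeeping (eV) for a computed one-electron redox couple."""

    dG_gas: float               # gas-phase electron attachment/detachment dG
    dG_solv_initial: float      # solvation dG of the initial oxidation state
    dG_solv_final: float        # solvation dG of the final oxidation state
    n: int = 1
    absolute_ref: float = NHE_ABSOLUTE_V


@dataclass(frozen=True)
class ScanRateDiagnostics:
    slope_E: dict[str, float]
    slope_i: dict[str, float]
    r2_E: dict[str, float]
    r2_i: dict[str, float]
    E_mid_range: float          # max - min of E_mid across rates (V)
    peak_ratio_range: float
    summaries: tuple[RedoxSummary, ...] = field(default=())


def _segment_peak(E: np.ndarray, i: np.ndarray, anodic: bool, baseline_frac: float) -> tuple[float, float]:
    """Peak potential and baseline-subtracted peak current of one sweep segment."""
    s = i if anodic else -i
    n_base = max(2, int(baseline_frac * E.size))
    # pre-peak window = the start of the sweep (in sweep order)
    slope, intercept = np.polyfit(E[:n_base], s[:n_base], 1)
    corrected = s - (slope * E + intercept)
    k = int(np.argmax(corrected))
    return float(E[k]), float(corrected[k])


def extract_redox(v: Voltammogram, baseline_frac: float = 0.15, min_peak_snr: float = 3.0) -> RedoxSummary:
    """Locate the anodic/cathodic peak pair and summarise the couple.

    A linear baseline fitted over the first ``baseline_frac`` of each sweep
    segment is subtracted before peak finding. If only one peak rises above
    the baseline scatter the process is reported as irreversible, with the
    missing peak quantities set to NaN.
    """
    segs = v.segments()
    anodic_candidates: list[tuple[float, float]] = []
    cathodic_candidates: list[tuple[float, float]] = []
    for sl in segs:
        E, i = v.potential[sl], v.current[sl]
        rising = E[-1] > E[0]
        Ep, ip = _segment_peak(E, i, anodic=rising, baseline_frac=baseline_frac)
        n_base = max(2, int(baseline_frac * E.size))
        scatter = float(np.std((i if rising else -i)[:n_base])) + 1e-30
        entry = (Ep, ip) if ip > min_peak_snr * scatter else None
        if rising and entry:
            anodic_candidates.append(entry)
        elif not rising and entry:
            cathodic_candidates.append(entry)

    def best(c: list[tuple[float, float]]) -> tuple[float, float]:
        return max(c, key=lambda t: t[1]) if c else (float("nan"), float("nan"))

    E_pa, i_pa = best(anodic_candidates)
    E_pc, i_pc = best(cathodic_candidates)
    reversible = bool(anodic_candidates) and bool(cathodic_candidates)
    E_mid = (E_pa + E_pc) / 2.0
    ratio = i_pa / i_pc if reversible else float("nan")
    return RedoxSummary(
        E_pa=E_pa, E_pc=E_pc, i_pa=i_pa, i_pc=i_pc,
        E_mid=E_mid, peak_ratio=ratio, reference=v.reference, reversible=reversible,
    )


def reference_to_nhe(E_vs_fc: float, offset: float = FC_TO_NHE_V) -> float:
    """Convert a potential vs Fc+/Fc to the NHE scale: E + 0.64 V."""
    return E_vs_fc + offset


def scan_rate_diagnostics(voltammograms: list[Voltammogram], **extract_kw) -> ScanRateDiagnostics:
    """Regress peak potential and current on sqrt(scan rate) across a CV series.

    Linearity of peak current in sqrt(v) indicates diffusion control; a
    scan-rate-independent midpoint supports using E_mid as an effective
    redox potential.
    """
    if len(voltammograms) < 3:
        raise ValueError("need voltammograms at >= 3 scan rates")
    summaries = tuple(extract_redox(v, **extract_kw) for v in voltammograms)
    root_nu = np.sqrt([v.scan_rate for v in voltammograms])

    def fit(yvals: np.ndarray) -> tuple[float, float, float]:
        res = _st.linregress(root_nu, yvals)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)

    slope_E, slope_i, r2_E, r2_i = {}, {}, {}, {}
    for name, Es, Is in (
        ("anodic", [s.E_pa for s in summaries], [s.i_pa for s in summaries]),
        ("cathodic", [s.E_pc for s in summaries], [s.i_pc for s in summaries]),
    ):
        sE, _, rE = fit(np.asarray(Es))
        sI, _, rI = fit(np.asarray(Is))
        slope_E[name], r2_E[name] = sE, rE
        slope_i[name], r2_i[name] = sI, rI
    mids = np.array([s.E_mid for s in summaries])
    ratios = np.array([s.peak_ratio for s in summaries])
    return ScanRateDiagnostics(
        slope_E=slope_E, slope_i=slope_i, r2_E=r2_E, r2_i=r2_i,
        E_mid_range=float(mids.max() - mids.min()),
        peak_ratio_range=float(np.nanmax(ratios) - np.nanmin(ratios)),
        summaries=summaries,
    )


def zero_zero_energy(lambda_abs_max: float, lambda_em_max: float) -> float:
    """S0->S1 transition energy (eV) at the mean of absorption and emission maxima."""
    if lambda_abs_max <= 0 or lambda_em_max <= 0:
        raise ValueError("wavelengths must be positive")
    return HC_EV_NM / ((lambda_abs_max + lambda_em_max) / 2.0)


def rehm_weller_dG(inp: PETInput) -> PETResult:
    """Rehm–Weller free energy of photoinduced electron transfer (eV).

    dG = (E_ox - E_red) - dG_00 - coulomb_term, single electron; quenching
    is thermodynamically favourable iff dG < 0.
    """
    if inp.dG00 is not None:
        dG00 = float(inp.dG00)
    elif inp.lambda_abs_max is not None and inp.lambda_em_max is not None:
        dG00 = zero_zero_energy(inp.lambda_abs_max, inp.lambda_em_max)
    else:
        raise ValueError("provide dG00 directly or both spectral maxima")
    dG = (inp.E_ox_donor - inp.E_red_acceptor) - dG00 - inp.coulomb_term
    return PETResult(dG=float(dG), favourable=bool(dG < 0), dG00=dG00)


def thermo_cycle_potential(inp: ThermoCycleInput) -> float:
    """Redox potential (V vs NHE) from computed Gibbs energies via the thermodynamic cycle.

    The solution-phase reaction free energy is dG_gas + dG_solv(final)
    - dG_solv(initial); the absolute potential is -dG/(n) in eV per electron
    and the NHE scale follows by subtracting the 4.4 V absolute reference.
    """
    if inp.n < 1:
        raise ValueError("electron count must be >= 1")
    dG_solution = inp.dG_gas + inp.dG_solv_final - inp.dG_solv_initial
    E_abs = -dG_solution / inp.n
    return float(E_abs - inp.absolute_ref)
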