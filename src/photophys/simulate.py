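"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here under the
acquisition conditions the real experiments used: tri-exponential decays
convolved with a ~200 ps Gaussian IRF, recorded to at least 10 000 counts in
the peak channel with Poisson counting noise; emission-titration series
whose bound fraction follows the exact 1:1 compound-per-binding-motif
equilibrium; and reversible cyclic-voltammetry peak pairs with 59/n mV
anodic–cathodic separation and Randles–Sevcik sqrt(scan-rate) current
scaling.

All generators are pure functions of (ground truth, seed): the same inputs
reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .decay import (
    DecayTrace,
    InstrumentResponse,
    MultiExpParams,
    TimeAxis,
    evaluate_multiexp,
    reconvolve,
)
from .binding import EmissionSpectrum, bound_concentration
from .electrochem import Voltammogram

__all__ = [
    "SimConfig",
    "OLIGOS",
    "gen_irf",
    "gen_decay",
    "gen_titration_series",
    "gen_emission_titration",
    "gen_voltammogram",
]

# Oligonucleotide fixture bank: sequence and molar extinction coefficient
# (M^-1 cm^-1) for the duplex/single-strand/G-quadruplex panel used in the
# titration experiments. ds17 is the annealed duplex of the two listed strands.
OLIGOS: dict[str, dict] = {
    "ds17": {
        "sequence": ("CCAGTTCGTAGTAACCC", "GGGTTACTACGAACTGG"),
        "epsilon": 6600.0,
        "topology": "duplex",
    },
    "ss17": {
        "sequence": "CCAGTTCGTAGTAACCC",
        "epsilon": 8910.0,
        "topology": "single-strand",
    },
    "TBA": {
        "sequence": "GGTTGGTGTGGTTGG",
        "epsilon": 143300.0,
        "topology": "G-quadruplex",
    },
    "myc2345": {
        "sequence": "TGAGGGTGGGGAGGGTGGGGAA",
        "epsilon": 229900.0,
        "topology": "G-quadruplex",
    },
    "PDGF-A": {
        "sequence": "GGAGGCGGGGGGGGGGGGGCGGGGGCGGGGGCGGGGGAGGGGCGCGGC",
        "epsilon": 467400.0,
        "topology": "G-quadruplex",
    },
}


@dataclass(frozen=True)
class SimConfig:
    """Acquisition conditions for the synthetic experiments.

    Defaults mirror the real setup: 200 ps (FWHM) excitation/response,
    55 ps channels (220 ps available for the coarse-binning case), decays
    accumulated to 10 000 expected counts in the peak channel.
    """

    seed: int = 0
    irf_fwhm: float = 0.2
    dt: float = 0.055
    n_channels: int = 1024
    t0: float = 0.0
    irf_center: float = 2.0
    peak_counts: float = 10_000.0

    def __post_init__(self) -> None:
        if self.peak_counts < 100:
            raise ValueError("peak_counts must be at least 100")
        if not self.irf_fwhm > self.dt / 2:
            raise ValueError("IRF FWHM must exceed half a channel width")

    @property
    def axis(self) -> TimeAxis:
        return TimeAxis(t0=self.t0, dt=self.dt, n=self.n_channels)


def gen_irf(cfg: SimConfig) -> InstrumentResponse:
    """Discretised unit-area Gaussian IRF centred at ``cfg.irf_center``.

    A Gaussian stands in for a scatterer-measured instrument response; a
    file-based measured IRF can be substituted anywhere one is accepted.
    """
    axis = cfg.axis
    sigma = cfg.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    counts = np.exp(-0.5 * ((axis.times - cfg.irf_center) / sigma) ** 2)
    counts /= counts.sum()
    return InstrumentResponse(axis=axis, counts=counts)


def gen_decay(
    truth: MultiExpParams,
    irf: InstrumentResponse,
    cfg: SimConfig,
    label: str = "",
    meta: dict | None = None,
    rng: np.random.Generator | None = None,
) -> DecayTrace:
    """Poisson-sampled reconvolved decay with expected peak = ``cfg.peak_counts``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    model = evaluate_multiexp(replace(truth, scale=1.0, background=0.0), irf.axis)
    expected = reconvolve(model, irf, truth.shift)
    expected = np.clip(expected, 0.0, None)  # FFT round-off can dip below zero
    expected *= cfg.peak_counts / expected.max()
    expected += truth.background
    counts = rng.poisson(expected).astype(float)
    if counts.max() <= 0:  # pathological but possible at tiny peak_counts
        counts[int(np.argmax(expected))] = 1.0
    return DecayTrace(axis=irf.axis, counts=counts, label=label, meta=meta or {})


@dataclass(frozen=True)
class TitrationTruth:
    """Ground truth behind one synthetic DNA titration."""

    tau_free: float
    tau_bound: tuple[float, float]
    Ka: float
    dye_conc: float
    dna_conc: tuple[float, ...]
    bound_fraction: tuple[float, ...]
    alphas: tuple[tuple[float, ...], ...]
    bound_split: float


def gen_titration_series(
    cfg: SimConfig,
    dna_conc: np.ndarray | None = None,
    tau_free: float = 1.3,
    tau_bound: tuple[float, float] = (6.0, 12.0),
    Ka: float = 1.0e6,
    dye_conc: float = 2.0e-6,
    bound_split: float = 0.5,
):
    """Simulated lifetime titration: free dye plus two bound components.

    The bound fraction at each DNA point comes from the exact 1:1
    compound-to-motif mass balance; decay amplitudes are partitioned between
    the free component (1.3 ns class) and the two bound components, whose
    share of the bound population is ``bound_split`` vs its complement.

    Returns ``(TitrationSeries, TitrationTruth)``; import of the series type
    is deferred to avoid a circular module dependency.
    """
    from .fitting import TitrationSeries

    if dna_conc is None:
        dna_conc = dye_conc * np.array([0.0, 0.25, 0.5, 1.0, 1.5, 2.5, 4.0, 8.0])
    dna_conc = np.asarray(dna_conc, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    irf = gen_irf(cfg)
    traces = []
    fracs = []
    alphas = []
    for i, D in enumerate(dna_conc):
        x = bound_concentration(D, dye_conc, Ka)
        fb = x / dye_conc
        a_free = 1.0 - fb
        a2 = fb * bound_split
        a3 = fb * (1.0 - bound_split)
        truth = MultiExpParams(
            tau=(tau_free, tau_bound[0], tau_bound[1]),
            alpha=(a2, a3),
            scale=1.0,
        )
        traces.append(
            gen_decay(
                truth,
                irf,
                cfg,
                label=f"point{i}",
                meta={"dna_conc": float(D), "dye_conc": dye_conc},
                rng=rng,
            )
        )
        fracs.append(fb)
        alphas.append((a_free, a2, a3))
    series = TitrationSeries(
        traces=tuple(traces), irf=irf, dna_conc=tuple(dna_conc), dye_conc=dye_conc
    )
    truth_rec = TitrationTruth(
        tau_free=tau_free,
        tau_bound=tau_bound,
        Ka=Ka,
        dye_conc=dye_conc,
        dna_conc=tuple(dna_conc),
        bound_fraction=tuple(fracs),
        alphas=tuple(alphas),
        bound_split=bound_split,
    )
    return series, truth_rec


def gen_emission_titration(
    dna_conc: np.ndarray,
    dye_conc: float = 2.0e-6,
    Ka: float = 1.0e6,
    I_free: float = 1.0,
    I_bound: float = 4.0,
    noise: float = 0.02,
    seed: int = 0,
    band_center: float = 609.0,
    band_fwhm: float = 60.0,
    wavelength: np.ndarray | None = None,
) -> list[EmissionSpectrum]:
    """Emission spectra across a titration, Gaussian band shapes, 2 % multiplicative noise.

    Peak brightness scales as I_free*(L-x) + I_bound*x with x the 1:1 bound
    concentration, mimicking enhancement on binding (I_bound > I_free).
    """
    if wavelength is None:
        wavelength = np.arange(500.0, 801.0, 1.0)
    rng = np.random.default_rng(seed)
    sigma = band_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    shape = np.exp(-0.5 * ((wavelength - band_center) / sigma) ** 2)
    spectra = []
    for D in np.asarray(dna_conc, dtype=float):
        x = bound_concentration(D, dye_conc, Ka)
        amp = I_free * (dye_conc - x) + I_bound * x
        intensity = amp * shape * (1.0 + noise * rng.standard_normal(wavelength.size))
        spectra.append(
            EmissionSpectrum(
                wavelength=wavelength,
                intensity=np.clip(intensity, 0.0, None),
                dna_conc=float(D),
                dye_conc=dye_conc,
            )
        )
    return spectra


def _cv_wave(E: np.ndarray, E_peak: float, width: float) -> np.ndarray:
    # sech^2 bell: symmetric peak template with tunable half-width
    z = (E - E_peak) / width
    return 1.0 / np.cosh(z) ** 2


def gen_voltammogram(
    E0: float,
    scan_rate: float,
    cfg: SimConfig | None = None,
    n_electrons: int = 1,
    window: float = 0.4,
    i_p_ref: float = 1.0e-5,
    peak_width: float = 0.034,
    noise: float = 0.0,
    baseline_slope: float = 0.0,
    reference: str = "vs Fc+/Fc",
) -> Voltammogram:
    """Reversible CV peak pair: anodic/cathodic peaks at E0 ± 59/(2n) mV.

    Peak current scales with sqrt(scan_rate) (diffusion control); the
    forward (anodic) sweep runs from E0-window to E0+window and back.
    A parametric template, not a digital electrochemical simulation — it is
    sufficient for exercising peak extraction and scan-rate diagnostics.
    """
    seed = cfg.seed if cfg is not None else 0
    rng = np.random.default_rng(seed)
    half_sep = 0.0295 / n_electrons
    i_p = i_p_ref * np.sqrt(scan_rate)
    E_fwd = np.linspace(E0 - window, E0 + window, 400)
    E_rev = E_fwd[::-1]
    i_fwd = i_p * _cv_wave(E_fwd, E0 + half_sep, peak_width) + baseline_slope * (E_fwd - E0)
    i_rev = -i_p * _cv_wave(E_rev, E0 - half_sep, peak_width) + baseline_slope * (E_rev - E0)
    potential = np.concatenate([E_fwd, E_rev])
    current = np.concatenate([i_fwd, i_rev])
    if noise > 0:
        current = current + noise * i_p * rng.standard_normal(current.size)
    return Voltammogram(
        potential=potential, current=current, scan_rate=scan_rate, reference=reference
    )
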