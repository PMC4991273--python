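# Methods

This note records the models implemented, the numerical choices behind them,
what the synthetic-data generators do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Decay model and reconvolution

A TCSPC histogram is modelled as the causal convolution of a 1–3 component
exponential decay with the instrument response function (IRF):

    I(t) = I0 * [ (1 - a1 - a2) exp(-t/tau1) + a1 exp(-t/tau2) + a2 exp(-t/tau3) ]

Amplitude fractions are normalised to one, with the first stored implicitly
as 1 − Σαᵢ. Derived quantities are the fractional steady-state intensities
fᵢ = αᵢτᵢ/Σαⱼτⱼ and the amplitude-weighted average lifetime τ̄ = Σαⱼτⱼ.

Numerical choices:

- **Convolution** is performed by FFT on the uniform channel grid, truncated
  to the histogram length; it agrees with a direct O(n²) causal sum to
  better than 1e−10 relative error (asserted in the suite).
- **Prompt shift.** The IRF is commonly recorded at a different wavelength
  and through different filters than the emission, so a sub-channel time
  offset between IRF and decay is a fit parameter. It is implemented as
  linear interpolation of the IRF onto the shifted grid, followed by unit
  normalisation, so the decay scale I0 stays in counts.
- **Fit window.** Goodness of fit and the fitted objective are evaluated on
  the channels from the IRF peak onward; the rising edge contributes little
  information about lifetimes and is most sensitive to IRF imperfections.
  The window is configurable.
- **Time grids** must be uniform; non-uniform files are rejected rather than
  resampled (resampling would correlate the Poisson noise between channels).
- A constant background per channel is available as an optional offset but
  defaults to zero, matching the background-free decay law above.

## Fitting

Fits minimise the Poisson-weighted sum of squared residuals. Weights start
as Neyman weights 1/max(observed, 1); after the first converged pass they
are replaced by model-based weights 1/max(model, 1) and the fit is repeated
(one pass by default). Pure Neyman weighting systematically biases
lifetimes low whenever many tail channels hold few counts — downward noise
fluctuations receive inflated weight — and a single reweighting pass removes
most of that bias; the residual bias on the standard synthetic conditions is
measured by the acceptance script (fractions of a percent, versus roughly
−3 % without reweighting).

The optimiser is quasi-Newton (L-BFGS-B) over a transformed parameter space:

- lifetimes enter as log τ (positivity),
- prompt shifts in units of 0.1 ns (conditioning),
- per-trace amplitudes and scale are *projected out* at every objective
  evaluation by non-negative least squares (variable projection).

The projection keeps the outer nonlinear problem low-dimensional (the free
lifetimes plus, optionally, one shift per trace) and far more robust to
starting values than a joint search. A full-space quasi-Newton polish over
(log τ, amplitude logits, log scale, shift) then refines the projected
solution; both stages minimise the same objective, so the polish can only
confirm or improve it. Free lifetimes are initialised by the best
combination from a log-spaced grid over [2·dt, span/3]. Returned lifetimes
are sorted ascending with amplitudes permuted accordingly.

L-BFGS-B with numeric gradients frequently terminates in a line-search
breakdown at the finite-difference noise floor of an already-converged
solution; such terminations are recorded as converged when the objective
did not worsen. A genuinely poor fit still announces itself through the
reduced chi-square acceptance test.

**Global analysis** fits one shared lifetime vector across a titration
series with per-trace amplitudes, scales and shifts. The unbound-compound
lifetime can be held constant (defaults 1.28 ns for the short-lifetime
morpholino dye class and 15.75 ns for the long-lifetime propyl class, both
configurable — the literature quotes 1.3 ns in rounded form and 1.28 ns in
the fitting protocol, and this package keeps the protocol value as the
default). Whether scale and shift are shared across traces is not
standardised; they are per-trace here, which is the weaker assumption.

**Degrees-of-freedom policy.** Reduced chi-squares are computed with the
actual window dof. For the acceptance statistics (the χ²ᵣ < 1.17 rule and
the F-threshold), the conventional v = 200 per trace is used by default,
independent of channel count, with the actual-dof mode available
(`dof_policy=None`). The per-trace and global parameter counts p are always
derived from the declared free-parameter set, never hard-coded: the printed
p of a published fit depends on which scales/shifts were counted, so p is
whatever the configured fit actually varied.

## Support-plane accuracy analysis

One shared lifetime is profiled over a grid; at each grid value every other
parameter is re-optimised (warm-started from the unconstrained optimum,
with optional additional cold restarts keeping the lowest constrained
chi-square). The ratio F_chi = χ²ᵣ(parm)/χ²ᵣ(min) is compared against

    F_chi_crit = 1 + (p/v) * F(P; p, v)

where F(P; p, v) is the upper-P critical value of Fisher's F with numerator
dof p and denominator dof v. The printed forms of this threshold are
reproduced to within 0.002 under this argument order; the swapped order
(available via `swap_dof=True`) lands within about 0.005 and is retained
only for comparison.

The accepted region is reported as the union of contiguous accepted grid
runs, not forced into one interval: when two free lifetimes exist, the
profile of one of them revisits F ≈ 1 near the other's value (the label
exchange appears as a second local minimum), and collapsing the union would
hide exactly the multi-minimum structure the analysis is meant to expose.
Grid points whose re-optimisation fails are flagged, never dropped
silently. Because the v = 200-per-trace policy is generous relative to the
actual channel counts, the accepted intervals are conservative; the
acceptance script measures their empirical coverage (≈100 % over 200
simulated series, within the 95 ± 5 % band).

## Binding analysis

- **Fold enhancement** is the ratio of integrated spectra (trapezoidal, full
  recorded range) between the final and the compound-only titration point.
- **Mole-ratio stoichiometry** fits a continuous two-segment line with a free
  knee (coarse grid over the interior abscissae, then bounded scalar
  refinement on a normalised axis so tolerances are concentration-scale
  free). A breakpoint is reported only when the segmented model beats a
  single straight line by a BIC margin; otherwise the result is explicitly
  "no breakpoint". The knee is returned as a DNA-motif-per-dye ratio.
- **1:1 binding fits** use the exact quadratic mass-balance root for the
  bound concentration and the signal model I_free·(L−x) + I_bound·x, fitted
  by trust-region-reflective least squares on log10(Ka) (so the search is
  well-scaled across 10⁵–10⁷ M⁻¹). All concentrations are in binding-motif
  units — five base pairs, five bases, or one quadruplex per bound dye,
  supplied by the caller — which is what makes a non-cooperative 1:1 model
  applicable to every topology. Data entirely in saturation yield only a
  lower bound on Ka and are flagged as such.
- **Integration band** defaults to 584–634 nm (configurable), the band in
  which DAOTA-class emission responds most strongly.
- Dilution correction is assumed handled by the acquisition protocol (dye is
  added with the titrant); raw-data correction is left to the caller.

## Electrochemistry and PET

- Peaks are located per sweep segment after subtracting a linear baseline
  fitted over the first 15 % of the segment (configurable); a peak must
  exceed three times the baseline scatter to count. A couple missing one
  peak is reported as irreversible with the observed peak only — as for
  amine-centred oxidations in the 1.1–1.3 V region.
- The midpoint potential (E_pa + E_pc)/2 defines the effective redox
  potential for quasi-reversible couples whose midpoint is scan-rate
  independent; `scan_rate_diagnostics` checks exactly that, plus linearity
  of peak current in √ν (diffusion control).
- Energy bookkeeping is in eV throughout, so the n·F division of the
  thermodynamic cycle appears as a division by n, and the Rehm–Weller
  expression is a plain sum of potentials and energies. The 0–0 transition
  energy is taken as the photon energy at the arithmetic mean of the
  absorption and emission maxima, E = 1239.84/((λ_abs + λ_em)/2) eV — the
  natural reading of estimating the crossing point between the two band
  maxima; the Coulomb term e²/(εd) defaults to zero (screened in high-ionic-
  strength aqueous buffer).
- The thermodynamic-cycle sign convention is E_abs = −ΔG_solution/n with
  ΔG_solution = ΔG_gas + ΔG_solv(final) − ΔG_solv(initial), referenced to
  NHE by subtracting 4.4 V. Published renderings of these equations are
  often typographically mangled; the convention here is the standard cycle
  (reduction free energy made more negative by better solvation of the
  reduced state raises the reduction potential).

## Synthetic data

The generators emulate the acquisition conditions of the real experiments:

- **IRF**: discretised unit-area Gaussian, 200 ps FWHM by default, standing
  in for a scatterer-measured response. Channel width defaults to 55 ps with
  1024 channels (56 ns span); a 220 ps coarse-binning mode mirrors detectors
  whose channel spacing is comparable to the IRF.
- **Decays**: the reconvolved model is scaled to 10⁴ expected counts in the
  peak channel and Poisson-sampled. Afterpulsing, pile-up and dead-time are
  *not* simulated, so passing recovery tests demonstrates correctness of the
  estimator under ideal counting statistics, not robustness to detector
  artefacts.
- **Lifetime titrations**: the bound fraction at each DNA point follows the
  exact 1:1 motif equilibrium; amplitudes are split between the free
  component (1.3 ns class) and two bound components at 6.0 and 12.0 ns —
  values chosen to mimic the observed short/long bound components of
  G-quadruplex-bound dyes without asserting their true values, and well
  separated (≥2.5×) so the three-component fit is identifiable. The default
  series has 8 points from 0 to 16 μM motif at 2 μM dye.
- **Emission titrations**: Gaussian band (centre 609 nm, FWHM 60 nm) whose
  amplitude follows I_free·(L−x) + I_bound·x with I_bound/I_free = 4, plus
  2 % multiplicative Gaussian noise — typical fluorimeter repeatability.
  Wavelength-dependent noise and inner-filter effects are not modelled.
- **Voltammograms**: a parametric reversible template — symmetric sech²
  peaks at E₀ ± 59/(2n) mV with Randles–Ševčík √ν current scaling — not a
  digital electrochemistry simulation. It exercises peak extraction,
  referencing and diagnostics; it cannot test kinetic peak-shape analysis.

All generators are pure functions of (ground truth, seed); identical inputs
give bit-identical outputs.

## Problem sizes used in the checks

The recovery and coverage checks run at the acquisition conditions above:
20 independent 8-trace titrations for lifetime recovery; 100 12-point noisy
titrations per decade of Ka for binding recovery; 200 4-trace bi-exponential
series (512 channels) for support-plane coverage, profiling the single free
lifetime on a 0.5 ns grid from 2 to 17 ns. The bi-exponential layout makes
each constrained re-fit a pure linear problem, which is what allows a
200-replicate coverage study to run in well under a minute.

## Known limitations

- No Poisson maximum-likelihood (deviance) fitting mode; weighted least
  squares with one reweighting pass is accurate at ≥10³ peak counts but not
  for very sparse histograms.
- No stretched-exponential or lifetime-distribution models; no anisotropy.
- Support-plane coverage is conservative (near 100 %) under the v = 200
  policy with modern channel counts; switch to actual dof for sharper
  intervals.
- The mole-ratio breakpoint is only meaningful for tight binding
  (Ka·[dye] ≫ 1); for soft isotherms the knee underestimates sharpness and
  the 1:1 fit is the right tool.
- The CV reader expects pre-converted two-column CSV; vendor binary formats
  are out of scope.
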