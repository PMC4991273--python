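# photophys

Quantitative photophysics of DNA-binding fluorescent probes.

Fluorescence-lifetime probes of G-quadruplex DNA — cationic dyes such as the
diazaoxatriangulenium (DAOTA) family — report DNA topology through changes in
their excited-state lifetime rather than their intensity. Characterising such
a probe takes three quantitative workflows, all of which this package
implements as a tested, reusable library with a thin CLI:

1. **Time-correlated single-photon counting (TCSPC) analysis.** Decay
   histograms are fitted by iterative reconvolution of a multi-exponential
   decay law with the measured instrument response function (IRF),

   *I*(*t*) = *I*₀ [(1 − α₁ − α₂) e^(−t/τ₁) + α₁ e^(−t/τ₂) + α₂ e^(−t/τ₃)],

   with Σα = 1. Titration series are fitted by *global analysis* — lifetimes
   shared across all traces, amplitudes free per trace, optionally holding the
   free-dye lifetime constant — and each fit reports fractional intensities
   *f*ᵢ = αᵢτᵢ/Σαⱼτⱼ, the average lifetime τ̄ = Σαⱼτⱼ, and the reduced
   chi-square. Lifetime accuracy is quantified by F-statistic **support-plane
   analysis**: one lifetime is profiled over a grid, everything else
   re-optimised, and trial values with
   *F*&chi; = χ²ᵣ(parm)/χ²ᵣ(min) ≤ 1 + (*p*/*v*)·*F*(*P*; *p*, *v*)
   are statistically indistinguishable from the minimum.

2. **Emission-titration binding analysis.** Integrated band emission vs DNA
   concentration gives the fold enhancement, the binding stoichiometry by the
   mole-ratio (breakpoint) method, and the association constant *K*ₐ from the
   exact 1:1 compound-per-binding-motif quadratic mass balance
   *x* = ((D + L + 1/Kₐ) − √((D + L + 1/Kₐ)² − 4DL))/2.

3. **Electrochemistry and photoinduced electron transfer (PET).** Reversible
   couples are summarised by the midpoint potential E₁/₂ = (E_pa + E_pc)/2
   with scan-rate diagnostics (√ν current scaling, midpoint constancy),
   referenced to NHE via the Fc⁺/Fc offset (+0.64 V), and PET feasibility is
   judged by the Rehm–Weller energy ΔG = e[E_ox − E_red] − ΔG₀,₀ − e²/(εd):
   quenching is thermodynamically favourable iff ΔG < 0. Redox potentials from
   computed Gibbs energies use the standard thermodynamic cycle against the
   4.4 V absolute NHE.

A synthetic-data module generates every input with known ground truth under
realistic acquisition conditions (tri-exponential decays convolved with a
200 ps IRF, ≥10⁴ peak counts, Poisson noise; 1:1 binding titrations;
reversible CV peak pairs), so the whole chain is testable end to end.

## Worked example

Simulate a DNA lifetime/emission titration (true lifetimes 1.3, 6.0, 12.0 ns;
*K*ₐ = 10⁶ M⁻¹; dye 2 μM) and analyse it:

```bash
photophys simulate --out demo --seed 7 --ka 1e6
photophys fit-global demo/series.csv --irf demo/irf.csv --free-dye-tau 1.3 --out fit.json
photophys titrate demo/spectra.csv --manifest demo/spectra_manifest.csv --dye-conc 2e-6 --out titr.json
```

The global fit report (`fit.json`) contains

```
shared_tau      [1.3, 6.08, 12.054]     # ns; 1.3 held fixed, bound lifetimes recovered
global_chisq_r  0.936                   # acceptable: below the 1.17 cut (P=0.05, v=200)
p, v            34, 1600                # fitted parameters, policy degrees of freedom
per_trace[0].f  [1.000, 0.000, 0.000]   # compound only: all emission from the free dye
per_trace[7].f  [0.012, 0.339, 0.649]   # DNA-saturated: emission dominated by bound dye
per_trace[7].tau_bar  8.43              # ns, average lifetime at the end of the titration
```

i.e. the free-dye fractional intensity collapses from 100 % to ~1 % across
the titration while the average lifetime climbs from 1.3 to 8.4 ns — the
lifetime contrast such probes are used for. The emission analysis
(`titr.json`) prints

```
fold_enhancement          3.81          # emission gain at the end of the titration (truth: ×4 at saturation)
Ka_per_M                  9.96e5        # recovered association constant (truth: 1e6)
breakpoint_motif_per_dye  1.61          # mole-ratio breakpoint (soft knee at Ka·[dye] ≈ 2)
```

The same operations are available as library calls (`photophys.fit_global`,
`photophys.tau_support_plane`, `photophys.fit_1to1`,
`photophys.extract_redox`, `photophys.rehm_weller_dG`, ...), which the CLI
wraps one-to-one.

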