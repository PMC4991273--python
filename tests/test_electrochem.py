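"""CV peak extraction, scan-rate diagnostics and PET energetics."""

import numpy as np
import pytest

from photophys.electrochem import (
    FC_TO_NHE_V,
    GUANINE_EOX_V,
    PETInput,
    ThermoCycleInput,
    Voltammogram,
    extract_redox,
    reference_to_nhe,
    rehm_weller_dG,
    scan_rate_diagnostics,
    thermo_cycle_potential,
    zero_zero_energy,
)
from photophys.simulate import SimConfig, gen_voltammogram


class TestExtractRedox:
    def test_generator_round_trip_within_5mV(self):
        for E0 in (-0.30, 0.07, -0.9):
            s = extract_redox(gen_voltammogram(E0, 0.1, SimConfig(seed=0)))
            assert s.E_mid == pytest.approx(E0, abs=0.005)
            assert s.reversible

    def test_midpoint_is_arithmetic_mean(self):
        s = extract_redox(gen_voltammogram(0.07, 0.1, SimConfig(seed=0)))
        assert s.E_mid == pytest.approx((s.E_pa + s.E_pc) / 2)

    def test_symmetric_pair_unit_peak_ratio(self):
        s = extract_redox(gen_voltammogram(-0.30, 0.2, SimConfig(seed=0)))
        assert s.peak_ratio == pytest.approx(1.0, abs=0.02)

    def test_current_scaling_and_potential_shift_invariance(self):
        v = gen_voltammogram(-0.30, 0.1, SimConfig(seed=0))
        s0 = extract_redox(v)
        scaled = Voltammogram(potential=v.potential, current=5.0 * v.current,
                              scan_rate=v.scan_rate)
        assert extract_redox(scaled).E_mid == pytest.approx(s0.E_mid, abs=1e-9)
        shifted = Voltammogram(potential=v.potential + 0.25, current=v.current,
                               scan_rate=v.scan_rate)
        assert extract_redox(shifted).E_mid == pytest.approx(s0.E_mid + 0.25, abs=1e-9)

    def test_single_anodic_peak_reported_irreversible(self):
        E = np.concatenate([np.linspace(0.8, 1.4, 200), np.linspace(1.4, 0.8, 200)])
        i = np.where(np.arange(400) < 200, 1e-5 * np.exp(-(((E - 1.2) / 0.04) ** 2)), 0.0)
        s = extract_redox(Voltammogram(potential=E, current=i, scan_rate=0.1))
        assert not s.reversible
        assert s.E_pa == pytest.approx(1.2, abs=0.01)
        assert np.isnan(s.E_pc)


@pytest.fixture(scope="module")
def series():
    return [gen_voltammogram(-0.30, r, SimConfig(seed=0)) for r in (0.05, 0.1, 0.2, 0.4, 0.8)]


class TestScanRateDiagnostics:
    def test_diffusion_controlled_current_scaling(self, series):
        d = scan_rate_diagnostics(series)
        assert d.r2_i["anodic"] > 0.999 and d.r2_i["cathodic"] > 0.999
        assert d.slope_i["anodic"] > 0

    def test_midpoint_constant_across_rates(self, series):
        d = scan_rate_diagnostics(series)
        assert d.E_mid_range < 0.005
        assert d.peak_ratio_range < 0.05

    def test_rate_independent_peaks_zero_slope(self):
        # same template at every rate: no current growth with sqrt(rate)
        vs = [
            Voltammogram(potential=v.potential, current=gen_voltammogram(
                -0.3, 0.1, SimConfig(seed=0)).current, scan_rate=v.scan_rate)
            for v in (gen_voltammogram(-0.3, r, SimConfig(seed=0)) for r in (0.05, 0.2, 0.8))
        ]
        d = scan_rate_diagnostics(vs)
        assert d.slope_i["anodic"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_rates_rejected(self, series):
        with pytest.raises(ValueError, match="3"):
            scan_rate_diagnostics(series[:2])


class TestReferenceConversion:
    def test_offset_applied_exactly(self):
        assert reference_to_nhe(0.0) == pytest.approx(0.64)
        assert reference_to_nhe(-0.64) == pytest.approx(0.0)

    def test_round_trip_identity(self):
        E = -0.937
        assert reference_to_nhe(E) - FC_TO_NHE_V == pytest.approx(E)


class TestRehmWeller:
    def test_cancellation_boundary(self):
        r = rehm_weller_dG(PETInput(E_ox_donor=1.0, E_red_acceptor=-1.2, dG00=2.2))
        assert r.dG == pytest.approx(0.0, abs=1e-12)
        assert not r.favourable

    def test_reported_potentials_give_favourable_quenching(self):
        # guanine donor at 1.3 V vs NHE against the two triangulenium
        # core reduction potentials
        for e_red, expected in ((-0.26, -0.64), (-0.61, -0.29)):
            r = rehm_weller_dG(PETInput(E_red_acceptor=e_red, dG00=2.2))
            assert r.dG == pytest.approx(expected, abs=1e-9)
            assert r.favourable

    def test_affine_coefficients_by_finite_differences(self):
        base = PETInput(E_ox_donor=1.3, E_red_acceptor=-0.5, dG00=2.0, coulomb_term=0.1)
        f0 = rehm_weller_dG(base).dG
        h = 1e-3
        for fieldname, slope in (
            ("E_ox_donor", +1.0), ("E_red_acceptor", -1.0),
            ("dG00", -1.0), ("coulomb_term", -1.0),
        ):
            kw = {**base.__dict__, fieldname: getattr(base, fieldname) + h}
            assert (rehm_weller_dG(PETInput(**kw)).dG - f0) / h == pytest.approx(slope)

    def test_easier_reduction_makes_transfer_more_favourable(self):
        # raising the acceptor reduction potential strictly lowers dG
        dgs = [
            rehm_weller_dG(PETInput(E_red_acceptor=e, dG00=2.2)).dG
            for e in (-0.8, -0.4, 0.0, 0.4)
        ]
        assert np.all(np.diff(dgs) < 0)

    def test_dG00_from_spectral_maxima(self):
        r = rehm_weller_dG(
            PETInput(E_red_acceptor=-0.5, lambda_abs_max=500, lambda_em_max=600)
        )
        assert r.dG00 == pytest.approx(1239.84 / 550, rel=1e-9)


class TestZeroZeroEnergy:
    def test_degenerate_mean(self):
        assert zero_zero_energy(620, 620) == pytest.approx(2.0, abs=1e-3)

    def test_mean_wavelength_energy(self):
        assert zero_zero_energy(500, 600) == pytest.approx(2.254, abs=1e-3)

    def test_strictly_decreasing_in_each_wavelength(self):
        assert zero_zero_energy(510, 600) < zero_zero_energy(500, 600)
        assert zero_zero_energy(500, 610) < zero_zero_energy(500, 600)


class TestThermoCycle:
    def test_reference_cancellation(self):
        inp = ThermoCycleInput(dG_gas=-4.4, dG_solv_initial=0.0, dG_solv_final=0.0)
        assert thermo_cycle_potential(inp) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        inp = ThermoCycleInput(dG_gas=-5.0, dG_solv_initial=0.0, dG_solv_final=0.0)
        assert thermo_cycle_potential(inp) == pytest.approx(0.60)

    def test_equal_solvation_terms_cancel(self):
        a = ThermoCycleInput(dG_gas=-5.0, dG_solv_initial=-1.3, dG_solv_final=-1.3)
        b = ThermoCycleInput(dG_gas=-5.0, dG_solv_initial=0.0, dG_solv_final=0.0)
        assert thermo_cycle_potential(a) == pytest.approx(thermo_cycle_potential(b))


class TestPipelineOrdering:
    def test_quenching_favourable_for_both_reported_cores(self):
        # full chain: reversible CV generated at the Fc-referenced value of
        # each printed potential -> extract -> NHE -> Rehm-Weller
        for e_nhe in (-0.26, -0.61):
            v = gen_voltammogram(e_nhe - FC_TO_NHE_V, 0.1, SimConfig(seed=0))
            s = extract_redox(v)
            e_red = reference_to_nhe(s.E_mid)
            r = rehm_weller_dG(
                PETInput(E_ox_donor=GUANINE_EOX_V, E_red_acceptor=e_red, dG00=2.2)
            )
            assert r.favourable
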