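"""Band profiles, ionization weighting and the side-chain library."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protir.spectral_model import (
    BandParams,
    IonizationState,
    LibraryError,
    ParameterError,
    SideChainEntry,
    SideChainLibrary,
    Spectrum,
    WavenumberGrid,
    apply_revised_positions,
    band_area,
    band_profile,
    default_library,
    ionized_fraction,
    residue_spectrum,
    total_sidechain_spectrum,
)


class TestBandProfile:
    @pytest.mark.parametrize("fg", [0.0, 0.3, 0.5, 1.0])
    def test_peak_equals_intensity_and_half_maximum_at_half_width(self, fg, fine_grid):
        band = BandParams(1673.0, 20.0, 1.0, fg)
        s = band_profile(band, fine_grid)
        assert s.value_at(1673.0) == pytest.approx(1.0, abs=1e-12)
        # both components reach half maximum at nu0 +/- w/2, for any mix
        assert s.value_at(1683.0) == pytest.approx(0.5, abs=1e-12)
        assert s.value_at(1663.0) == pytest.approx(0.5, abs=1e-12)

    def test_value_one_fwhm_from_centre(self, fine_grid):
        # G = 2^-4, L = 1/5 at delta = w: 2*(0.5/16 + 0.5/5) = 0.2625
        band = BandParams(1673.0, 20.0, 2.0, 0.5)
        s = band_profile(band, fine_grid)
        assert s.value_at(1693.0) == pytest.approx(0.2625, abs=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ParameterError):
            BandParams(1650.0, 0.0, 1.0, 0.5)
        with pytest.raises(ParameterError):
            BandParams(1650.0, -3.0, 1.0, 0.5)

    @pytest.mark.parametrize("band", [
        BandParams(1600.0, 20.0, 1.0, 0.0),
        BandParams(1600.0, 30.0, 2.5, 1.0),
        BandParams(1600.0, 44.0, 0.7, 0.5),
    ])
    def test_numerical_area_matches_closed_form(self, band):
        # Lorentzian tails are heavy: integrate over a very wide range
        grid = WavenumberGrid.regular(band.position - 4000, band.position + 4000, 0.25)
        s = band_profile(band, grid)
        num = np.trapezoid(s.absorbance, grid.values)
        assert num == pytest.approx(band_area(band), rel=5e-3)


class TestIonizedFraction:
    @pytest.mark.parametrize("ph,pka,expected", [
        (4.0, 4.0, 0.5),
        (6.0, 4.0, 1.0 / (1.0 + 1e-2)),
        (3.0, 4.0, 1.0 / (1.0 + 10.0)),
    ])
    def test_henderson_hasselbalch(self, ph, pka, expected):
        assert ionized_fraction(ph, pka) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(pka=st.floats(0, 14), d1=st.floats(-6, 6), d2=st.floats(0.01, 6))
    def test_strictly_increasing_in_ph(self, pka, d1, d2):
        lo = ionized_fraction(pka + d1, pka)
        hi = ionized_fraction(pka + d1 + d2, pka)
        assert 0.0 < lo < hi < 1.0


class TestResidueSpectrum:
    def test_arginine_maxima_at_band_positions(self, library, fine_grid):
        s = residue_spectrum(library["R"], 7.0, fine_grid)
        y = s.absorbance
        # 1673 is the global maximum (strong nu_as band); the 1633 neighbour
        # pulls the apex down-slope by about a wavenumber
        assert fine_grid.values[np.argmax(y)] == pytest.approx(1673.0, abs=2.0)

    def test_aspartate_protonated_form_dominated_by_carbonyl(self, library, fine_grid):
        s = residue_spectrum(library["D"], 1.0, fine_grid)  # pH << pKa
        assert fine_grid.values[np.argmax(s.absorbance)] == pytest.approx(1729.0, abs=1.0)
        # the ionized COO- band at 1570 is essentially absent
        assert s.value_at(1570.0) < 0.2 * s.value_at(1729.0)

    def test_midpoint_ph_mixes_states_linearly(self, library, fine_grid):
        entry = library["D"]
        s_mid = residue_spectrum(entry, entry.pKa, fine_grid)
        neutral = sum(band_profile(b, fine_grid).absorbance for b in entry.state("neutral").bands)
        ionized = sum(band_profile(b, fine_grid).absorbance for b in entry.state("ionized").bands)
        np.testing.assert_allclose(s_mid.absorbance, 0.5 * neutral + 0.5 * ionized,
                                   rtol=0, atol=1e-14)

    @pytest.mark.parametrize("res", list("RDEKYHQN"))
    @pytest.mark.parametrize("ph", [2.0, 7.0, 12.0])
    def test_nonnegative_everywhere(self, library, fine_grid, res, ph):
        assert residue_spectrum(library[res], ph, fine_grid).absorbance.min() >= 0.0

    def test_ionizable_entry_requires_both_states(self):
        with pytest.raises(LibraryError):
            SideChainEntry("D", (IonizationState("neutral", (BandParams(1729, 30, 1, 0.5),)),),
                           pKa=4.0)


class TestTotalSidechain:
    def test_zero_composition_gives_zero_spectrum(self, library, window_grid):
        s = total_sidechain_spectrum({"G": 12, "A": 30}, library, 7.0, window_grid)
        assert np.all(s.absorbance == 0.0)

    def test_linear_and_additive(self, library, window_grid):
        one = total_sidechain_spectrum({"R": 1, "Y": 1}, library, 7.0, window_grid)
        r = residue_spectrum(library["R"], 7.0, window_grid)
        y = residue_spectrum(library["Y"], 7.0, window_grid)
        np.testing.assert_allclose(one.absorbance, r.absorbance + y.absorbance, atol=1e-14)
        two = total_sidechain_spectrum({"R": 2, "Y": 2}, library, 7.0, window_grid)
        np.testing.assert_allclose(two.absorbance, 2 * one.absorbance, atol=1e-14)

    def test_permutation_invariant(self, library, window_grid):
        a = total_sidechain_spectrum({"R": 1.0, "D": 2.0, "Y": 0.5}, library, 7.0, window_grid)
        b = total_sidechain_spectrum({"Y": 0.5, "R": 1.0, "D": 2.0}, library, 7.0, window_grid)
        np.testing.assert_allclose(a.absorbance, b.absorbance, rtol=1e-12)

    def test_unknown_weight_raises_but_weak_absorber_skipped(self, library, window_grid):
        # Gly is standard but not in the library: skipped as negligible
        s = total_sidechain_spectrum({"G": 5.0}, library, 7.0, window_grid)
        assert np.all(s.absorbance == 0.0)
        with pytest.raises(LibraryError):
            total_sidechain_spectrum({"G": 5.0}, library, 7.0, window_grid, skip_missing=())


class TestRevisedPositions:
    def test_shifts_glu_and_tyr(self):
        free = default_library(revised=False)
        glu = [b.position for b in free["E"].state("ionized").bands]
        tyr = [b.position for b in free["Y"].state("neutral").bands]
        assert 1559.0 in glu and 1518.0 in tyr
        rev = apply_revised_positions(free)
        assert 1570.0 in [b.position for b in rev["E"].state("ionized").bands]
        assert 1514.0 in [b.position for b in rev["Y"].state("neutral").bands]
        # only positions change
        assert rev["E"].state("ionized").bands[0].intensity == free["E"].state("ionized").bands[0].intensity

    def test_idempotent(self):
        once = apply_revised_positions(default_library(revised=False))
        twice = apply_revised_positions(once)
        assert once.to_frame().drop(columns="assignment").equals(
            twice.to_frame().drop(columns="assignment"))

    def test_missing_band_reported(self):
        lib = default_library(revised=False)
        # remove Glu's ionized band entirely
        entry = lib["E"]
        broken = SideChainEntry("E", (entry.state("neutral"), IonizationState("ionized")),
                                pKa=entry.pKa, is_base=entry.is_base)
        with pytest.raises(LibraryError, match="COO"):
            apply_revised_positions(lib.with_entry(broken))


class TestLibraryIO:
    def test_csv_round_trip_lossless(self, library, tmp_path):
        path = tmp_path / "bands.csv"
        library.to_csv(path)
        back = SideChainLibrary.from_csv(path)
        assert set(back.residues) == set(library.residues)
        for res in library.residues:
            a, b = library[res], back[res]
            assert a.pKa == b.pKa and a.is_base == b.is_base
            for sa, sb in zip(a.states, b.states):
                assert sa.label == sb.label
                assert sa.bands == sb.bands

    def test_required_residues_enforced(self):
        lib = default_library()
        entries = {k: v for k, v in lib.entries.items() if k != "E"}
        with pytest.raises(LibraryError, match="E"):
            SideChainLibrary(entries).validate()

    def test_absent_residue_lookup_is_an_error(self, library):
        with pytest.raises(LibraryError):
            library["W"]
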