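"""Filtration, spectrum statistics, collimation and PSF round trips."""

import numpy as np
import pytest

from mrtsim import beamline, source
from mrtsim.beamline import (ApertureConfig, FilterElement, PhaseSpace,
                             collimate, filtration_stack, percent_difference,
                             read_psf, spectrum_stats, transmit, write_psf)
from mrtsim.errors import ConfigurationError, GeometryError, PSFFormatError
from mrtsim.source import PhotonBatch, Spectrum


@pytest.fixture(scope="module")
def raw3(machine, wiggler3):
    return source.source_spectrum(machine, wiggler3, horizontal_acceptance=4.56e-4)


def test_tilted_paddle_effective_thickness():
    f = FilterElement("hd_graphite", 5.0, 45.0)
    assert f.effective_thickness == pytest.approx(7.07, rel=0.01)
    assert FilterElement("graphene", 0.45, 90.0).effective_thickness == pytest.approx(0.45)


class TestTransmit:
    def test_empty_stack_is_identity(self, raw3):
        out = transmit(raw3, [])
        assert np.array_equal(out.fluence_per_bin, raw3.fluence_per_bin)

    def test_exponential_multiplicativity(self, raw3):
        two_thin = transmit(raw3, [FilterElement("copper", 1.0), FilterElement("copper", 1.0)])
        one_thick = transmit(raw3, [FilterElement("copper", 2.0)])
        num = np.abs(two_thin.fluence_per_bin - one_thick.fluence_per_bin)
        assert np.all(num <= 1e-12 * np.maximum(one_thick.fluence_per_bin, 1.0))

    def test_transmission_bounded_and_monotone_in_thickness(self, raw3):
        thin = transmit(raw3, [FilterElement("aluminium", 1.0)])
        thick = transmit(raw3, [FilterElement("aluminium", 3.0)])
        nz = raw3.fluence_per_bin > 0
        t_thin = thin.fluence_per_bin[nz] / raw3.fluence_per_bin[nz]
        t_thick = thick.fluence_per_bin[nz] / raw3.fluence_per_bin[nz]
        assert np.all((t_thin > 0) & (t_thin <= 1))
        assert np.all(t_thick <= t_thin)

    def test_filtration_hardens_spectrum(self, raw3):
        before = spectrum_stats(raw3)[1]
        after = spectrum_stats(transmit(raw3, filtration_stack(3.0)))[1]
        assert after >= before

    def test_unknown_material_named_in_error(self, raw3):
        with pytest.raises(ConfigurationError, match="beryllium-oxide"):
            transmit(raw3, [FilterElement("beryllium-oxide", 1.0)])


class TestSpectrumStats:
    def test_delta_spectrum(self):
        edges = np.arange(40.0, 301.0, 0.5)
        f = np.zeros(edges.size - 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        f[np.argmin(np.abs(centers - 80.0))] = 3.0
        mode, mean, total = spectrum_stats(Spectrum(edges, f))
        assert mode == pytest.approx(79.75)  # centre of the one occupied bin
        assert mean == pytest.approx(79.75)
        assert total == pytest.approx(3.0)

    def test_uniform_spectrum_mean_is_midpoint(self):
        edges = np.linspace(40.0, 300.0, 261)
        mode, mean, _ = spectrum_stats(Spectrum(edges, np.ones(edges.size - 1)))
        assert mean == pytest.approx(170.0)

    def test_all_zero_spectrum_rejected(self):
        sp = Spectrum(np.array([40.0, 50.0, 60.0]), np.zeros(2))
        with pytest.raises(ConfigurationError):
            spectrum_stats(sp)


class TestPercentDifference:
    @pytest.mark.parametrize("a,b,expected,tol", [
        (94.63, 91.91, 2.92, 0.005),
        (70.73, 69.54, 1.70, 0.005),
        (61.9, 62.1, 0.32, 0.005),
    ])
    def test_mean_referenced_values(self, a, b, expected, tol):
        assert percent_difference(a, b) == pytest.approx(expected, abs=tol)

    def test_symmetric_and_zero_on_equal(self):
        assert percent_difference(5.0, 5.0) == 0.0
        assert percent_difference(3.0, 4.0) == percent_difference(4.0, 3.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


def _uniform_fan(n, half_angle=10.0 / 33.4e3, energy=100.0):
    """Horizontal fan spanning exactly +-10 mm at the 33.4 m scoring plane."""
    dy = np.linspace(-half_angle, half_angle, n)
    return PhotonBatch(energy=np.full(n, energy), dy=dy, dz=np.zeros(n), weight=np.ones(n))


class TestCollimate:
    def test_msc_open_fraction(self):
        """Fully absorbing septa leave slit_width/pitch = 50/400 of a flat beam."""
        batch = _uniform_fan(200_001)
        ap = ApertureConfig(bda_height=2.014, mask_width=20.0, msc_enabled=True)
        psf = collimate(batch, ap)
        assert len(psf) / len(batch) == pytest.approx(0.125, abs=0.002)

    def test_fully_open_preserves_count(self):
        batch = _uniform_fan(5000)
        ap = ApertureConfig(bda_height=2.014, mask_width=20.0, msc_enabled=False)
        psf = collimate(batch, ap)
        assert len(psf) == len(batch)
        assert np.all(psf.weight > 0)

    def test_taller_bda_accepts_more(self, machine, wiggler3, raw3):
        div = source.DivergenceModel(gamma=machine.gamma, critical_energy_kev=18.34,
                                     horizontal_half_angle=4.56e-4)
        batch = source.sample_photons(raw3, 100_000, 9, div)
        small = collimate(batch, ApertureConfig(bda_height=0.532, msc_enabled=False))
        tall = collimate(batch, ApertureConfig(bda_height=1.053, msc_enabled=False))
        assert len(tall) > len(small)

    def test_septa_transmission_attenuates_weight(self):
        batch = _uniform_fan(10_000)
        ap = ApertureConfig(bda_height=2.014, msc_enabled=True, septa_transmission=0.1)
        psf = collimate(batch, ap)
        assert len(psf) == len(batch)  # nothing removed, septa photons carried
        assert set(np.round(np.unique(psf.weight), 12)) == {0.1, 1.0}

    def test_scoring_plane_upstream_rejected(self):
        batch = _uniform_fan(10)
        with pytest.raises(GeometryError):
            collimate(batch, ApertureConfig(), scoring_plane_distance=30.0)

    def test_records_satisfy_invariants(self):
        batch = _uniform_fan(1000)
        psf = collimate(batch, ApertureConfig(bda_height=1.053, msc_enabled=True))
        norm = psf.dx**2 + psf.dy**2 + psf.dz**2
        assert np.all(np.abs(norm - 1.0) < 1e-9)
        # pol_x follows from orthogonality; the full vector must be unit length
        pol_x = -(psf.pol_y * psf.dy + psf.pol_z * psf.dz) / psf.dx
        pol_norm = pol_x**2 + psf.pol_y**2 + psf.pol_z**2
        assert np.all(np.abs(pol_norm - 1.0) < 1e-9)
        assert np.all(psf.energy >= 40.0)
        assert np.all(psf.weight > 0)


def test_aperture_config_validation():
    with pytest.raises(ConfigurationError):
        ApertureConfig(bda_height=1.5)
    with pytest.raises(ConfigurationError):
        ApertureConfig(mask_width=12.0)
    with pytest.raises(ConfigurationError):
        ApertureConfig(msc_slit_width=500.0, msc_pitch=400.0)
    with pytest.raises(ConfigurationError):
        ApertureConfig(septa_transmission=1.5)


@pytest.mark.parametrize("suffix", [".h5", ".csv"])
def test_psf_round_trip(tmp_path, suffix):
    batch = _uniform_fan(500)
    psf = collimate(batch, ApertureConfig(bda_height=2.014, msc_enabled=True))
    path = tmp_path / f"beam{suffix}"
    write_psf(path, psf)
    back = read_psf(path)
    for name in ("y", "z", "dy", "dz", "energy", "pol_y", "pol_z", "weight"):
        assert np.array_equal(getattr(back, name), getattr(psf, name)), name
    assert back.distance_m == psf.distance_m


def test_truncated_psf_raises_parse_error(tmp_path):
    batch = _uniform_fan(100)
    psf = collimate(batch, ApertureConfig(bda_height=2.014, msc_enabled=False))
    path = tmp_path / "beam.csv"
    write_psf(path, psf)
    text = path.read_text().splitlines()
    (tmp_path / "broken.csv").write_text("\n".join(text[:-1] + [text[-1][: len(text[-1]) // 2]]))
    with pytest.raises(PSFFormatError):
        read_psf(tmp_path / "broken.csv")


def test_psf_streaming_chunks(tmp_path):
    batch = _uniform_fan(1000)
    psf = collimate(batch, ApertureConfig(bda_height=2.014, msc_enabled=False))
    path = tmp_path / "beam.h5"
    write_psf(path, psf)
    total = 0
    for chunk in beamline.iter_psf(path, chunk_size=128):
        assert len(chunk) <= 128
        total += len(chunk)
    assert total == len(psf)


def test_vertical_acceptance_monotone_in_height(machine, raw3):
    div = source.DivergenceModel(gamma=machine.gamma, critical_energy_kev=18.34,
                                 horizontal_half_angle=4.56e-4)
    small = beamline.vertical_acceptance(raw3, div, 0.532)
    tall = beamline.vertical_acceptance(raw3, div, 2.014)
    nz = raw3.fluence_per_bin > 0
    assert np.all(small.fluence_per_bin[nz] < tall.fluence_per_bin[nz])
    assert np.all(tall.fluence_per_bin[nz] <= raw3.fluence_per_bin[nz])
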