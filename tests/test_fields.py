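import numpy as np
import pytest

import pinnasonar as ps
from pinnasonar.fields import DirectionalField


class TestWavelengthUtilities:
    def test_wavelength_values(self):
        assert ps.wavelength_mm(80.0) == pytest.approx(343.0 / 80.0)
        assert ps.wavelength_mm(40.0) == pytest.approx(2 * ps.wavelength_mm(80.0))

    def test_nodes_per_wavelength(self):
        # 0.5 mm mesh edges still sample a 110 kHz wave more than 4x
        assert ps.nodes_per_wavelength(0.5, 110.0) > 4.0
        assert ps.nodes_per_wavelength(1.0, 110.0) == pytest.approx(
            ps.nodes_per_wavelength(0.5, 110.0) / 2
        )


class TestTwoSourceEmission:
    def test_maximum_straight_ahead(self, head_config, partition256):
        em = ps.two_source_emission(head_config, 80.0, partition256)
        peak = partition256.cell_centers[np.argmax(em.gain_db)]
        assert abs(peak[0]) < 15.0  # on the zero-path-difference meridian

    def test_matches_phasor_oracle(self, head_config, partition64):
        # independent oracle: explicit complex phasor sum per cell
        em = ps.two_source_emission(head_config, 80.0, partition64)
        k = 2 * np.pi / ps.wavelength_mm(80.0)
        offset = em.gain_db - _raw_two_source_db(head_config, partition64, k)
        # normalization is a common shift; pattern must match to 1e-6 dB
        assert np.ptp(offset) < 1e-6

    def test_first_null_position(self, head_config):
        # fine azimuth scan at el=0: first null where sin(az) = lambda/(2 d)
        lam = ps.wavelength_mm(80.0)
        az = np.arange(0.0, 90.0, 0.1)
        k = 2 * np.pi / lam
        amp = 2 * np.abs(np.cos(k * 4.2 / 2 * np.sin(np.deg2rad(az))))
        null_az = az[np.argmin(amp)]
        assert null_az == pytest.approx(
            np.rad2deg(np.arcsin(lam / (2 * 4.2))), abs=0.1
        )

    def test_coincident_sources_are_isotropic(self, partition64):
        cfg = ps.SyntheticHeadConfig(source_spacing_mm=1e-9)
        em = ps.two_source_emission(cfg, 80.0, partition64)
        assert np.ptp(em.gain_db) < 1e-6

    def test_zero_frequency_rejected(self, head_config, partition64):
        with pytest.raises(ValueError):
            ps.two_source_emission(head_config, 0.0, partition64)


def _raw_two_source_db(cfg, partition, k):
    half = cfg.source_spacing_mm / 2.0
    gains = []
    floor_amp = 2.0 * 10 ** (-cfg.beam_dynamic_range_db / 20)
    for v in partition.unit_vectors:
        phase = k * half * v[1]
        amp = abs(np.exp(1j * phase) + np.exp(-1j * phase))
        gains.append(20 * np.log10(max(amp, floor_amp)))
    return np.array(gains)


class TestParametricBeam:
    def test_beamwidth_halves_when_frequency_doubles(self):
        part = ps.partition_hemisphere(8192)  # fine grid for width readout
        axis = ps.Direction(0, 0)
        b40 = ps.parametric_beam(9.0, 40.0, axis, 0.0, part)
        b80 = ps.parametric_beam(9.0, 80.0, axis, 0.0, part)
        assert _halfpower_width(b40, part) == pytest.approx(
            2 * _halfpower_width(b80, part), rel=0.1
        )

    def test_axis_gain_is_cap(self, partition256):
        beam = ps.parametric_beam(9.0, 60.0, ps.Direction(0, 0), 12.0, partition256)
        assert beam.gain_db.max() == pytest.approx(12.0, abs=0.2)

    def test_far_off_axis_reaches_floor_for_large_aperture(self, partition64):
        beam = ps.parametric_beam(500.0, 80.0, ps.Direction(0, 0), 0.0, partition64)
        rim = np.abs(partition64.cell_centers[:, 0]) > 80
        assert np.all(beam.gain_db[rim] <= beam.floor_db + 1e-6)

    def test_halfpower_solid_angle_shrinks_with_frequency(self):
        part = ps.partition_hemisphere(4096)
        axis = ps.Direction(0, 0)
        widths = [
            _halfpower_width(ps.parametric_beam(9.0, f, axis, 0.0, part), part)
            for f in (30.0, 50.0, 70.0, 90.0)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_sidelobe_plateau_bounds_falloff(self, partition256):
        beam = ps.parametric_beam(
            9.0, 100.0, ps.Direction(0, 0), 0.0, partition256,
            sidelobe_level_db=15.0, sidelobe_ripple_db=4.0,
        )
        assert beam.gain_db.min() >= -15.0 - 4.0 - 1e-9


def _halfpower_width(beam, partition):
    above = beam.gain_db >= beam.gain_db.max() - 3.0
    return np.sqrt(above.sum() * partition.cell_solid_angle_sr)


class TestNormalizeEmission:
    def test_uniform_field(self, partition64):
        f = DirectionalField(partition64, 60.0, np.zeros(64), "emission")
        out = ps.normalize_emission(f)
        assert np.allclose(out.linear_power, 1.0 / (2 * np.pi))

    def test_power_integral_is_one(self, head_config, partition256):
        em, _, _ = ps.synthetic_head_fields(head_config, 80.0, partition256)
        total = em.linear_power.sum() * partition256.cell_solid_angle_sr
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, head_config, partition64):
        em = ps.two_source_emission(head_config, 60.0, partition64)
        again = ps.normalize_emission(em)
        assert np.allclose(again.gain_db, em.gain_db)

    def test_two_cell_hand_normalization(self):
        part = ps.partition_hemisphere(2)
        powers_db = 10 * np.log10([3.0, 1.0])
        f = DirectionalField(part, 60.0, powers_db, "emission")
        out = ps.normalize_emission(f)
        frac = out.linear_power / out.linear_power.sum()
        assert frac == pytest.approx([0.75, 0.25])
        assert out.linear_power.sum() * part.cell_solid_angle_sr == pytest.approx(1.0)

    def test_rejects_non_emission_and_zero_power(self, partition64):
        h = DirectionalField(partition64, 60.0, np.zeros(64), "hearing_left")
        with pytest.raises(ValueError):
            ps.normalize_emission(h)


class TestCombineAhrtf:
    def test_identity_element(self, head_config, partition64):
        _, hl, _ = ps.synthetic_head_fields(head_config, 60.0, partition64)
        em0 = DirectionalField(partition64, 60.0, np.zeros(64), "emission")
        out = ps.combine_ahrtf(em0, hl)
        assert np.allclose(out.gain_db, hl.gain_db)
        assert out.role == "ahrtf_left"

    def test_db_additivity_and_commutativity(self, partition64, rng):
        a = DirectionalField(partition64, 60.0, rng.normal(size=64), "emission")
        b = DirectionalField(partition64, 60.0, rng.normal(size=64), "hearing_right")
        ab = ps.combine_ahrtf(a, b)
        assert np.allclose(ab.gain_db, a.gain_db + b.gain_db)
        # -3 dB emission and -4 dB hearing give a -7 dB round trip
        assert ab.gain_db[0] == pytest.approx(a.gain_db[0] + b.gain_db[0])

    def test_mismatch_rejected(self, partition64, partition16):
        a = DirectionalField(partition64, 60.0, np.zeros(64), "emission")
        b = DirectionalField(partition16, 60.0, np.zeros(16), "hearing_left")
        with pytest.raises(ValueError):
            ps.combine_ahrtf(a, b)
        c = DirectionalField(partition64, 80.0, np.zeros(64), "hearing_left")
        with pytest.raises(ValueError):
            ps.combine_ahrtf(a, c)


class TestDirectivityTradeoff:
    def test_average_gain_drops_as_beam_narrows(self, partition256):
        # after normalizing to max 0 dB, a narrower lobe has a lower
        # hemisphere-average gain: focusing trades periphery for center
        means = []
        for f in (30.0, 60.0, 90.0):
            beam = ps.parametric_beam(9.0, f, ps.Direction(0, 0), 0.0, partition256)
            g = beam.gain_db - beam.gain_db.max()
            means.append(g.mean())
        assert means[0] > means[1] > means[2]
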